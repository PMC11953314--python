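{
 "normal_survival_probability": 0.9689715,
 "seed": 20240,
 "synthetic": true,
 "note": "synthetic stand-in for the published OG-TSG arm-score table, calibrated so the normal diploid genome survival probability equals the constant above"
}
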