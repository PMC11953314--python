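arm	score
1p	-0.5908487498344244
1q	-0.05437246409556637
2p	-0.8631032708990047
2q	1.4084096517636822
3p	0.1517192945264181
3q	0.879186135571135
4p	-1.293768588230196
4q	-0.8150010327317476
5p	1.3242258481107791
5q	-0.030731104105519047
6p	-1.793719340788669
6q	0.02692563402805108
7p	0.6410282469924147
7q	0.41026767553524907
8p	-0.2745061477397673
8q	-0.32006291664454134
9p	0.46086172201217784
9q	-0.8819342868119788
10p	0.46264684513645865
10q	-0.9406745623366757
11p	-1.6722562752219912
11q	-0.20343502987986528
12p	-0.9408545381559765
12q	-0.9315265351841147
13p	1.0576815423896582
13q	0.7529523522176025
14p	1.6952715201656565
14q	0.7486732903833921
15p	-0.6563244458756725
15q	1.3357573059631143
16p	1.0192971172689054
16q	0.9927235742726417
17p	-1.721451638520427
17q	0.2599256249649753
18p	1.4888862701152932
18q	-1.0275637368522277
19p	2.1430466420321266
19q	0.7246733230382967
20p	-0.011890597688339416
20q	0.2480164749758571
21p	1.5087900695870056
21q	0.45138077739214444
22p	-0.4203202619316148
22q	1.1578104418077628
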