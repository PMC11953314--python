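# Methods

This note documents the model implemented by `cinsim`, the choices made
where the design was genuinely open, and what the test suite does and does
not establish.  It states no empirical numbers beyond those the tests and
`scripts/acceptance.py` themselves compute.

## Genome representation

A cell's genome is a diploid interval adjacency graph.  Nodes are
breakpoint ends with a chromosome (autosomes only), haplotype (`A`/`B`),
1-based coordinate and orientation (`+`/HEAD = right side of an interval,
`-`/TAIL = left side).  Each node belongs to exactly one interval edge and
carries at most one junction edge; junction-less non-telomeric nodes are
unrepaired break ends.  Derivative chromosomes are maximal alternating
interval/junction walks; a circular derivative closes with one extra
adjacency.  All coordinates are 1-based closed internally; BED/BEDPE
writers emit 0-based half-open records.

Decisions worth recording:

* **Telomere status is a node property**: a path end is telomeric iff it
  sits at coordinate 1 or the chromosome length.  Mitotic breaks inside
  annotated telomere repeats therefore do not confer telomere status.
* **Centromere count is per traversal**, not per distinct reference
  centromere: a sister-fused derivative traverses the same reference
  centromere twice and is dicentric, which is what makes bridges form.
  Since breaks are never placed inside centromeres, a centromere is always
  wholly contained in one interval.
* **Infinite sites per lineage**: the set of used break positions is
  inherited by daughters; proposals colliding with a used position are
  resampled.  Different lineages may break the same position.
* **Bin copy numbers** assign each segment to bins `floor((start-1)/B)` …
  `floor((end-1)/B)`; fully covered bins add the segment CN, partially
  covered end bins add `CN * overlap / effective_bin_size`, where the
  trailing bin of a chromosome is clipped to the chromosome end.  The
  clipping keeps a pristine genome at exactly the ploidy in every bin,
  which the percentage-of-genome-altered (PGA) statistic relies on.

## Cell cycle

**G1 (breakage).** The cycle introduces `n` DSBs — fixed, or Poisson with
mean `r` — while the cell's division index does not exceed `n_d`
(`n_d = 0`: first division only; `None`: every cycle).  A chromosome is
drawn from `p_c` (uniform default; "biased" mode gives one chromosome 2/3
and splits 1/3 over the rest), then a molecule-level position uniform over
the cell's current material on that chromosome, rejecting telomere,
centromere and used positions.  Alternatively positions are sampled
without replacement from a breakpoint catalog, weighted by frequency.

**G1 (repair).** With `E` eligible ends (all free ends by default, or only
this cycle's under `repair_scope="new"`), `floor((1-f_u)·E/2)` pairs are
joined; an odd eligible count strands one end.  Uniform mode pairs at
random.  Distance mode picks an end uniformly and its partner with weight
`p_r` for the same-break sibling, `1/|b1-b2|` for ends on the same
chromosome *and haplotype*, and `1/1e9` otherwise — homologues are treated
as different molecules, the conservative reading of distance-dependent
contact.  Rejoining a break's own two ends restores a reference adjacency
and is not emitted as an SV.  Junctions merging two distinct derivatives
are logged as chromosome fusions.

**S/G2.** The graph is copied exactly.  Every linear derivative missing a
telomere is joined to its sister copy at each broken end, producing
fold-back (head-to-head/tail-to-tail) junctions; a derivative missing both
telomeres thereby circularises — acentric circles are ecDNA.  Every base
doubles; no junction is formed for intact or circular derivatives.

**M.** With probability `p_w`, and at most once per lineage, the whole
replicated genome passes to one daughter (WGD) and the sibling dies.
Otherwise: monocentric sister pairs split one copy per daughter; every
acentric path (linear or circular, ecDNA included) goes independently to a
uniformly chosen daughter, producing reciprocal gains and losses; a
derivative with `k ≥ 2` centromeres receives one break uniformly placed in
each gap between adjacent centromeres (never inside a centromere; cyclic
gaps for circular paths), yielding `k` monocentric derivatives — for
`k = 2` they are forced into different daughters, otherwise each is placed
randomly.  Each such derivative then draws `n_l ~ Poisson(m_l)`; if
`n_l > 0` local fragmentation is applied with probability 0.5
(independently per derivative — the description is singular and silent on
multiple derivatives), cutting `n_l` extra positions and scattering all
pieces randomly.  Mitotic break positions respect the used-position set
and centromere exclusion but may fall in telomeric repeats.

## Fitness and population dynamics

Survival probability is `P = exp(d Σ c_i s_i + c)` (clamped at 1) with
`d = 0.00039047`, `c = -0.036132164`, `c_i` the arm-level (default) or
chromosome-level average total copy number and `s_i` the per-region
oncogene/tumour-suppressor score.  `α = P^S` (selection strength `S > 0`,
monotone for `S ≤ 15`) parameterises the offspring distribution
`((1-α)², α(1-α), α²)`, giving mean offspring `α(1+α)` and net growth
`b - d = ln(α(1+α))`.  A daughter's selection coefficient is computed
against the **normal baseline** `α₀` (not its immediate parent — the
natural reading of the defining ratio, and it keeps `s` comparable across
the tree); its net growth is `(1+s)` times the baseline's with the death
rate held fixed, so birth rates stay non-negative for `s > -1` (clamped to
0 below).  Under selection the default baseline is `b₀ = ln(α₀(1+α₀))`,
`d₀ = 0`, which makes the growth identity hold exactly along the lineage;
neutral mode keeps user-set constant rates (default `b = 1`, `d = 0`).

Note a sign subtlety of the ratio definition: if the baseline were placed
below the root of `α(1+α) = 1` (a shrinking population), the ratio flips
sign and a fitter daughter would get `s < 0`.  The model never operates
there — the normal genome sits at `α₀ ≈ 0.969^S`.

Populations grow from one pristine cell by rejection-kinetic Monte Carlo:
time advances by `Exp(n · r_max)` per proposal, a uniform candidate is
accepted with probability `(b_i + d_i)/r_max` against a running upper
bound `r_max`, and accepted events divide (running a full cell cycle) or
kill the cell.  The scheme is exact for the target continuous-time
process for any valid upper bound.  The run stops at `N` living cells, at
extinction, or at a configurable event guard.  Lineage (parents, children,
event times) is recorded and exported as Newick.

## Summary statistics

For `N` cells: WGD fraction; fractions of pooled SV calls that are
deletion-like, duplication-like, inverted (both fold-back orientations)
and intra-chromosomal (complement of inter-chromosomal — the alternative
reading, a distance-thresholded subset, is not used); the breakpoint
frequency spectrum (distinct `(chrom, pos, orientation)` keyed by the
number of carrying cells, normalised, length `N`); PGA on total
copy-number bins (ploidy 2, or 4 after WGD; a bin counts if altered in
*any* cell); and the mean and SD of pairwise divergence on
haplotype-specific bins — the fraction of all haplotype bins where the two
cells differ *and* at least one deviates from its ploidy (the total-bin
denominator is the literal reading; an altered-bins-only denominator
would inflate sparse genomes).  A single-cell population reports zero
divergence with a flag.

Chromothripsis is flagged per chromosome per cell when (a) at least six
intra-chromosomal SVs form a set in which each member's span crosses
(overlaps without containment) at least one other, and (b) at least seven
consecutive copy-number segments alternate between exactly two states —
any two values qualify.  This is a deliberately minimal stand-in for
dedicated detectors, used for smoke-testing only.

## ABC SMC

The sampler is the standard population scheme: an initial population of
plain prior draws, then repeated resample–perturb–accept rounds with a
component-wise Gaussian kernel (SD = √2 × weighted SD of the previous
population, truncated to the uniform prior support by resampling) and
importance weights `1/Σ_j w_j K(θ|θ_j)`.  Tolerances follow the median of
the previous population's accepted distances; the run stops at the target
tolerance (0.2 default, 0.5 optional), at the simulation budget (1e6
default), or when the tolerance improves by less than 5%.  The distance is
Euclidean with each component scaled by `max(|obs|, 0.01)`; the floor
keeps near-zero components from dominating.  Failed simulations
(extinction before `N` cells) count against the budget and are rejected.
During inference the nuisance parameters are fixed: distance repair with
`p_r = 0`, no local fragmentation, DSBs every cycle, `S = 1`.  Posterior
predictive checks resimulate at weighted posterior draws; `P_w` is the
fraction of components whose observed value lies within two predictive
SDs (zero-SD components require exact equality).

The reference implementation the original protocol delegated to (an
external ABC library) does not document its kernel or distance; the
choices above are standard, documented, and not claimed identical.

## Synthetic data and calibration

Everything external has a bundled synthetic stand-in, generated
deterministically:

* a 2×10-kb toy reference (500-bp telomeres, centred centromere) small
  enough for per-base brute-force oracles;
* a 44-arm score table whose raw standard-normal scores are shifted so the
  normal diploid genome's survival probability equals the published
  constant 0.9689715 exactly (the required score total is obtained by
  inverting the survival formula at `c_i = 2`); the computed constant is
  declared in a JSON sidecar and asserted bit-for-bit;
* a breakpoint catalog with power-law frequency weights.

What green tests do *not* establish: the synthetic score table has no
biological content (only its calibrated total matters), the toy genome has
none of the size heterogeneity of real chromosomes, and random DSB
positions lack the fragile-site clustering of real breakpoint catalogs.

## Scaled-down validation and known limitations

* The parameter-recovery study (grid of `(r, f_u, p_w)` truths, `N = 10`
  cells) runs at 50 particles / 1200 simulations / 60 predictive draws per
  dataset — minutes instead of the hours the full protocol needs.  At this
  budget all true values are recovered within two posterior SDs, but the
  tolerance schedule plateaus well above the full protocol's target, and
  the posterior predictive `P_w = 1` rate stays below the full-scale
  figure; the corresponding acceptance test is expected to fail and is
  left failing rather than loosened.  Posteriors at this scale are wide,
  so recovery-within-2-SD is a weak claim.
* Sequence content is out of scope: no FASTA, no junction homology, no
  replication-timing or S-phase breakage, no sex chromosomes.
* The rate model ties selection to arm-level dosage only; SV-size-,
  gene-level or ecDNA-copy-based fitness terms are not modelled.
* Bridge-break positions are uniform in the inter-centromeric gap; real
  bridge resolution is mechanically biased.
* `P_w` and the fit diagnostics assume the observed record uses the same
  vector layout and bin size as the simulator.
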