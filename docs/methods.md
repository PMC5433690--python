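# Methods

## The scoring model

Each tissue section is read by two blinded scorers; each scorer counts the
percent of positively stained cells in five high-power fields (HPF, ×400)
per marker (CD23, IgD). The section-level rate per scorer is the
arithmetic mean of the five HPF values; the panel-level rate per marker is
the mean of the two scorers' rates. Scorer reconciliation by averaging is
a design choice: the source protocol reports inter-observer variation
below 5 percentage points but does not state how readings were merged.
Averaging is symmetric, and under < 5 pp discordance the ordinal bin can
move by at most one step — which the `scorer_concordant` flag surfaces.
The 5 pp rule is interpreted as a strict absolute difference in percentage
points (relative differences are undefined at 0%).

The **expression score** bins the panel rate onto {0, 1, 2, 3}. The
published bins are integer ranges (0; 1–10; 11–20; ≥ 21), while HPF
averaging yields real rates, so the bins are read as half-open continuous
intervals — 0, (0, 10], (10, 20], (20, 100] — which preserves the printed
behavior at every integer and assigns every real rate to exactly one
score. A rate of 0.5% therefore scores 1: any staining leaves the zero
bin.

The **LF structure score** maps the four ordinal descriptions of follicle
integrity (from "no staining or few scattered positive cells" to "most
follicles intact") onto {0, 1, 2, 3} by identity.

The **combined expression score** merges the two marker scores. How the
published analysis merged CD23 and IgD is not stated; the default is the
arithmetic mean, which keeps the combined score on the same 0–3 scale
(half-integer steps) and is symmetric in two markers that are strongly
correlated in practice. `min`, `max` and `sum` are selectable
alternatives.

The **combination score** is the sum of the combined expression score and
the LF score, spanning [0, 6]. It is monotone in all three inputs and
equals 0 only for a completely negative, structureless sample. Low values
indicate malignant-type (MALToma-like) disease; high values indicate
reactive hyperplasia.

## Statistical battery

Categorical clinical features are compared with Pearson's chi-square
**without** continuity correction; on 2×2 tables with any expected cell
below 5 the two-tailed Fisher exact test is auto-selected. This pairing
reproduces the published pairwise p-values at printed precision on every
row that can be checked from the printed counts (e.g. sex RFH vs MALToma
0.002, laterality overall 0.001, pain 1.00, motility impairment ALH vs
MALToma 0.005); the Yates-corrected statistic does not, so correction is
off by default and available via flag. Rows whose published p-values are
not reproduced by any provided method — the age pairwise values other
than RFH vs MALToma, and a few symptom rows, which evidently depend on
the unavailable per-subject data — are reported as flags on the summary,
never forced.

The Fisher two-tailed p sums hypergeometric probabilities over the
fixed-margin family for every table whose probability does not exceed the
observed one, with a relative tie tolerance of 1 + 1e-7 on the float
probabilities. The implementation computes whole margin families at once
from the vectorized hypergeometric pmf; tests verify exact agreement both
with an independent log-factorial enumeration oracle for **all** 2×2
tables with N ≤ 60 and with an established reference implementation on
random tables.

Age comparisons use the pooled-variance Student *t* (Welch available),
from raw values or from published (n, mean, SD) summaries; the two code
paths are independent and agree to ten significant digits. A one-way
ANOVA from summaries with Fisher-LSD post-hoc is provided for the overall
three-group comparison. Pairwise comparisons of k groups are corrected by
the α/n rule: the effective level is α divided by the number of pairs
(α/3 for three groups), and significance flags always use the effective
level.

Duration until diagnosis is printed only as per-group ranges (plus one
group mean in the text), so no duration significance tests are computed
on the fixture; on per-patient cohorts Student's *t* is the default, with
the caveat that the variable is heavily right-skewed.

## Diagnostic evaluation

A classifier partitions the combination-score axis into three half-open
bands — MALToma-like, ALH-like, RFH-like from low to high; a score equal
to a cut-point belongs to the lower band. Cut-points are fitted by
exhaustive search over all ordered pairs on the half-integer score grid,
maximizing balanced accuracy against the histological diagnosis labels;
ties break toward the widest MALToma-like band (then the widest ALH-like
band), making the fit deterministic.

Sensitivity against the IgH-clonality gold standard is score-positive
cases divided by clonality-evaluable cases per diagnosis group, where
evaluable means a clonal or polyclonal PCR result; samples whose DNA
failed quality control, or that were never tested, are excluded from all
counts. The published decision rule behind the reported group
sensitivities is not recoverable from the printed record; here
"score-positive" means classification into the lowest (MALToma-like)
band — the score asserts clonal-type proliferation — and this
reconstruction is a declared design choice, as is the denominator
definition (all evaluable cases in the group, matching the printed 21
and 17). Specificity, PPV and NPV can be derived from the reported
confusion counts but are artifact extensions, not published quantities.

## Synthetic cohorts

The generator emulates the study's data-generating structure per group
(defaults in parentheses follow the published 125-patient series, group
sizes 54/28/43):

- **Age** (years): normal, truncated to the printed ranges by rejection
  sampling (RFH 55.92 ± 12.85 on 13–82; ALH 60.44 ± 12.99 on 23–77;
  MALToma 64.95 ± 12.16 on 35–93).
- **Sex, laterality**: Bernoulli at the published proportions.
- **Anatomical sites**: independent Bernoulli per site at the published
  marginals, rejection-conditioned on at least one site (the record model
  requires a non-empty site set). Conditioning inflates each marginal to
  p / (1 − P(no site)); the analytic conditional value is the recovery
  target. Multi-compartment involvement emerges (rather than being
  forced) at roughly the published rate.
- **Symptoms**: independent Bernoulli at the published marginals.
- **Duration** (months): log-uniform within the printed per-group range.
- **CD23/IgD rates** (%): a bivariate standard normal latent with
  correlation ρ, scaled to per-group means/SDs and clamped to [0, 100].
  The per-group rate distributions and within-group correlations were
  never published; the defaults (RFH 32–35 ± 12, ρ = 0.85; ALH 9 ± 7 and
  MALToma 3 ± 3.5, ρ = 0.65) are calibration choices that spread RFH over
  the full 0–3 expression scale, keep ALH/MALToma mostly at 0–1, and give
  a pooled correlation comfortably above 0.5.
- **Scoring noise**: each scorer reading = true rate + a per-scorer
  offset (SD 1.0 pp) + per-HPF jitter (SD 2.0 pp), clamped per reading.
  These defaults were chosen analytically so that the two scorers' rates
  differ by < 5 pp with probability ≈ 0.992, honoring the reported
  inter-observer bound.
- **LF category**: per-group categorical (RFH mostly 2–3, MALToma mostly
  0–1).
- **Clonality**: a QC-failure draw at the published degradation rate
  (52/125) marks samples untestable; tested samples are clonal with the
  published per-group fractions (0/35, 8/17, 18/21).

One integer seed drives everything through fixed per-field child streams,
so adding a field never reshuffles earlier draws and the same config +
seed reproduces the same CSV bit for bit.

### What recovery checks mean

Truncation (ages) and clamping (rates) shift sample moments away from the
configured parent parameters — e.g. the ALH age range cuts about 10% of
the upper tail. Parameter recovery therefore compares moment estimates
against **analytic expectations under the generator** (scipy's truncated-
normal mean; a closed-form clamped-normal mean propagated through the
measurement-noise clamp by quadrature), which verifies that the generator
delivers exactly the distribution it claims. The latent ρ is asserted via
the observed Pearson r only for RFH, where clamping mass (~0.4%) and
noise attenuation (~0.6%) are within the ±0.05 assertion band; for the
low-rate groups clamping attenuates r materially and the estimate is
reported, not asserted.

Passing these tests shows the pipeline is self-consistent at scale; it
does **not** show that real cohorts follow these distributions. In
particular real site/symptom co-occurrence is not independent, real IHC
rates are not clamped Gaussians, and real scorer error is not unbiased —
the generator captures the published marginal structure only.

## Numerical choices and problem sizes

- Fisher tie tolerance 1 + 1e-7 (relative, on pmf values); family-at-a-
  time evaluation makes the exhaustive N ≤ 60 verification cheap.
- Expression-score bin edges are closed on the right; classifier bands
  are closed on the right (boundary scores fall to the lower band).
- Threshold fitting enumerates the half-integer grid [0, 6); degenerate
  inputs (single class, constant scores) raise informative errors.
- p-values are formatted publication-style: three decimals, "< 0.001"
  below 0.0005.
- Moment-recovery checks run 100 replicates at 5,000 subjects per group
  (a marginal passes when within 3 SE in ≥ 95 replicates); the
  sensitivity calibration runs 200 replicates at the study's own group
  sizes. Both scales keep the full suite under a minute of simulation
  while leaving standard errors small relative to the assertion bands.

## Known limitations

- The fixture holds group-level counts only; analyses that need
  per-subject values (raw-rate correlations such as the published overall
  r = 0.729, score–age correlation, Fig-level score means) cannot be
  reproduced from it and are covered only by qualitative-ordering checks
  on synthetic cohorts.
- The positivity rule and band cut-points are reconstructions; reported
  synthetic sensitivities characterize the reconstruction, not the
  original unstated rule.
- Missing data are preserved as absent, never imputed; records missing a
  marker or the LF category simply carry absent scores and are excluded
  from score-dependent denominators.
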