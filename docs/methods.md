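# Methods

## The measurement problem

A multi-reader sTILs annotation study asks J pathologists to annotate L
preselected ROIs from K breast-biopsy cases. Each annotation is a label from
a four-term vocabulary plus, when the label is evaluable (*intratumoral
stroma* or *invasive margin*), a density estimate X_jkl ∈ [0, 100]. There is
no reference standard: agreement must be characterised from the annotations
alone. The package treats ROIs as independent observations and readers as
exchangeable; correlation of ROIs within a case is deliberately not modelled
(a case identifier is carried on every record so that a variance-component
analysis can be added later without a schema change).

## Agreement statistics

**Per-ROI summaries.** For each ROI with at least `min_readers` (default 2)
density estimates we compute the sample mean, the sample variance with the
n−1 denominator, and CV = sd / mean. CV is undefined at mean 0; such ROIs
are excluded from the CV curve only. The variance- and CV-vs-mean curves
partition the summaries, ordered by mean with ties broken by ROI id, into
`n_bins` equal-count groups: with N summaries the first bins hold
⌊N/n_bins⌋ ROIs and the N mod n_bins leftovers go one each to the
highest-mean bins (so 495 ROIs in deciles gives five bins of 49 then five of
50). Equal-count (rather than equal-width) bins keep the bin averages
comparable under the strongly low-skewed density distribution.

**Pairwise MSD/RMSD.** The mean squared difference MSD = E[(X_j'kl −
X_jkl)²] is estimated per ROI as the mean over all unordered reader pairs,
which equals exactly 2 s² for that ROI's sample variance s² (an algebraic
identity, verified in the tests against brute-force pair enumeration). The
overall MSD is the unweighted mean of per-ROI MSDs over qualifying ROIs;
with exactly two readers everywhere this coincides with the pooled mean of
squared differences.

**Two-reader analysis.** For a chosen pair (by default the two readers whose
annotations cover the whole catalog on one platform):

* *paired observations* count ROIs where both readers agree on
  evaluability; per bin, ROIs where both estimates fall in the same bin —
  observations are lost when estimates cross bins;
* *averaged observations* assign every co-evaluable ROI to the bin of the
  mean of the two estimates (9% and 11% average to 10% → low), so the bin
  counts always sum to the co-evaluable count;
* RMSD is computed over all co-evaluable ROIs and within each averaged bin;
* Bland–Altman panels per averaged bin plot differences against means with
  bias m̄ and limits of agreement m̄ ± 2·√(RMSD² − m̄²). Since RMSD² = m̄² +
  (1/n)Σ(d_i − m̄)², the half-width is twice the n-denominator SD of the
  differences; RMSD² − m̄² is clamped at 0 against floating-point roundoff.
  The difference direction is (lexicographically smaller reader id) − (the
  other), overridable.

Per-bin m̄ and limits use averaged-bin membership, the same partition as the
per-bin RMSD. No confidence intervals are attached to the limits: with the
sparse moderate/high bins typical of these studies they would be
uninterpretable, and interval construction belongs to a full multi-reader
multi-case analysis that is out of scope here.

**Duplicates.** A reader annotating the same ROI twice on one platform is an
error by default; the `latest` policy (keep the greatest timestamp) supports
ingesting raw exports where readers revisited ROIs.

## Workload summaries

Mean and sample SD of per-ROI annotation seconds are reported per platform
and pooled. Reader counts are platform-local and the pooled row sums them,
so a reader active on two platforms counts twice there — the convention used
in multi-platform study tabulations, documented on the output. Microscope
hardware overhead (stage movement, slide registration) is a supplied
constant per platform, never estimated from the records, because annotation
software does not record it. Projection:
`hours = (annotation_s + hardware_s) × n_ROIs / 3600`, rounded to 2 dp in
tables. Durations above 10 minutes are flagged as probable interruptions but
never trimmed — recorded times only measure time on the input screen.
A batch "pass" is one (reader, platform) covering at least a configurable
fraction (default 100%) of the batch's ROIs.

## Synthetic study generator

The generator emulates the statistical structure observed in multi-reader
pilot data, with every choice exposed in `SyntheticConfig`:

| parameter | default | rationale |
|---|---|---|
| n_cases × rois_per_case, n_batches | 64 × 10, 8 | the 640-ROI, 8-batch split-plot-style design |
| n_readers | 10 | a digital-platform reader pool |
| p_roi_evaluable | 0.73 | observed fraction of evaluable ROIs |
| bin_weights | 0.71 / 0.21 / 0.08 | averaged-observation bin distribution |
| sigma_by_bin | 3.27 / 10.08 / 18.56 | per-bin two-reader RMSD ÷ √2 |
| p_label_concord | 0.9 | readers reproduce the catalog label 90% of the time |
| duration_log_mean, duration_log_sd | log 30 − 0.405, 0.9 | lognormal mean 30 s, SD ≈ 33.5 s |

Each ROI draws an evaluability flag, a label within the evaluable or
non-evaluable pair (weights 0.94/0.06 and 0.36/0.64, the observed label
ratios), and — if evaluable — a latent bin from `bin_weights` and a latent
density μ uniform within the bin. Each reader × ROI draws a label
(concordant with probability `p_label_concord`, otherwise uniform over the
other three), and an evaluable-labelled reading of an evaluable ROI reports
`round(clip(μ + bias_j + ε, 0, 100))` with ε ~ N(0, σ(μ)). A reader who
mislabels a truly non-evaluable ROI as evaluable reports a uniform low-bin
density (the confusion case). σ(μ) is piecewise-constant per latent bin —
the simplest model consistent with three observed RMSD levels — with an
optional linear σ(μ) = a + bμ for smooth variance curves, and an optional
per-reader additive bias enabling nonzero Bland–Altman bias. Randomness
comes from a single `numpy.random.default_rng(seed)` (PCG64), so identical
configs reproduce studies exactly.

**What the generator does not emulate.** Real readers skip ROIs and batches
unevenly (the generator gives complete coverage; incompleteness is exercised
in tests by deleting records), show training and ordering effects, differ by
platform, and produce non-Gaussian disagreement near 0% beyond what
clamp-and-round induces. Passing pipeline tests on synthetic data therefore
demonstrates correctness of the statistics, not that real annotation data
satisfies the generator's assumptions.

**Noise-SD recovery and boundary bias.** Under the generator, the two-reader
RMSD within a latent bin estimates √2·σ_bin. Clamping to [0, 100] biases
this downward near the scale ends, so recovery checks draw latents from
interior sub-ranges (`latent_ranges`: low (8, 10), moderate (30, 40), high
(46, 54), chosen to minimise clamp bias) and group squared differences by
the *latent* bin — averaged-observation membership would misassign boundary
ROIs whose noisy means cross bins. A residual limitation is irreducible: in
the high bin σ = 18.56 places every admissible latent within ~2.7 σ of a
clamp boundary, leaving a bias of about −0.15 to −0.2 on the recovered RMSD
(≈26.25); together with a Monte-Carlo standard error of σ/√n ≈ 0.26 at
5,000 ROIs per bin, individual seeded recovery runs scatter around a value
slightly below √2·σ. Rounding to integer densities adds a negligible
+1/6 to each reader's variance.

## Problem sizes and numerical choices

The reproduction script and tests use ~5,000 ROIs per bin (one 15,000-ROI
two-reader study) for recovery, a 640-ROI ten-reader default study for the
variance/CV-curve checks, and 1,000 random instances for the MSD identity —
sizes at which the law-of-large-numbers tolerances quoted in the tests hold
while everything completes in seconds. Bin edges are low [0, 10], moderate
(10, 40], high (40, 100] on the real line, so fractional means of integer
estimates always have a bin and mean(9, 11) = 10 is low. Densities are
stored as floats and never rounded on input. Label matching is case- and
whitespace-insensitive with a small alias table, since different annotation
platforms export different spellings. Reports use fixed orderings (sorted
ids, fixed column sets) and fixed rounding so repeated runs are byte-stable.

## Known limitations

* No variance-component or U-statistic multi-reader multi-case estimation,
  no kappa-style ordinal/nominal agreement, no ROI-within-case correlation.
* The percent-tumor-associated-stroma field is carried and validated but not
  analysed.
* The adapter for externally deposited exports maps columns by a
  configurable table; layouts it has not seen may need an explicit
  `column_map`.
* Projections assume the supplied per-ROI times generalise; recorded times
  exclude interruptions and microscope stage movement, so they are planning
  estimates, not measurements of total effort.
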