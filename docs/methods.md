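# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Data model

A profiling experiment is a Ct matrix (miRNA × sample) with explicit
missingness: a well that never crossed the fluorescence threshold carries no
number at all, not a sentinel Ct. Ct is treated throughout as the log2-scale
quantity (one cycle ≈ one doubling of template), so differences of Ct are
log2 ratios and no conversion to linear quantities is needed before
computing stability scores or fold changes. I/O is lossless by design:
values above the detection limit are preserved on read, and usability is
decided by the detection stage, never by the parser.

## Detection

A miRNA is detected in a group when its Ct is ≤ `ct_threshold` (default
35.0 cycles, the conventional reliability bound for TaqMan miRNA assays) in
at least ⌈`min_frac`·n⌉ of the group's n samples. The default
`min_frac = 0.8` reproduces the 4-of-5 rule at n = 5 and scales to other
cohort sizes (n = 8 → 7, n = 12 → 10); an absolute minimum can override the
fraction. A missing Ct can never satisfy the bound and counts as
not-detected for that sample — the only consistent reading of the rule.
Detection is monotone by construction: raising the threshold or lowering
the minimum can only grow the detected set, and the test suite asserts
this. The three-group Venn partition assigns each detected miRNA to exactly
one of 7 regions by its detection signature; k ≠ 3 groups is an error
rather than a silent generalization.

## Reference-miRNA selection

Candidates are restricted to miRNAs observed in **every** sample: an
endogenous control that drops out anywhere is useless as a normalizer.

**geNorm M** is implemented as the direct mean pairwise variation:
V_jk = SD across samples of (Ct_j − Ct_k), M_j = mean over partners. The
classic iterative worst-gene elimination is available
(`genorm_stepwise`) for comparison but is not part of the default ranking,
which uses the single-pass M value. Pairwise differences cancel per-sample
additive offsets, so M is blind to loading variation — a property the test
suite asserts in both directions (M invariant, CV score not).

**NormFinder ρ** follows the published model-based estimator. With I
candidates and groups g of size n_g:

1. sample-center the data: d_igj = Ct_igj − mean_i(Ct_igj);
2. per gene × group, the raw residual variance s²_ig (ddof = 1) is
   bias-corrected for the centering step, which mixes 1/I of every other
   gene's noise into each residual:
   σ̂²_ig = (s²_ig − s̄²_g/(I−1)) / (1 − 2/I), floored at zero;
3. intergroup deviations z_ig = m_ig − mean_g(m_ig) (m_ig the gene's group
   mean of centered data) have prior variance γ² estimated by moments with
   (I−1)(G−1) degrees of freedom, and each z_ig is shrunk by its sampling
   variance: ẑ_ig = z_ig · γ²/(γ² + σ̂²_ig/n_g);
4. the stability value averages the absolute shrunken intergroup effect
   and the intragroup uncertainty: ρ_i = mean_g(|ẑ_ig| + √(σ̂²_ig/n_g)).

The final combination in step 4 is the one genuinely open choice: an
alternative uses the posterior SD of the intergroup effect instead of
√(σ̂²_ig/n_g), but that variant collapses to ρ ≡ 0 whenever the moment
estimate of γ² is zero (e.g. homogeneous groups), destroying the ranking
exactly where a stability measure is most needed. The form used here stays
discriminative in that limit, where it reduces to the corrected intragroup
SD — the natural no-group stability measure (exposed via
`use_groups=False`). The implementation is verified against an independent
step-by-step loop recomputation on a frozen 6×15 fixture
(`tests/data/normfinder_synthetic_6x15.csv`, synthetic by construction) and by
structural properties (a gene tracking the sample offsets exactly attains
the minimal ρ; group relabeling with equal n changes nothing).

**CV score.** CV_j = SD_j/mean_j of raw Ct over samples, scaled by the sum
of all candidates' CVs so scores sum to 1. The scaling denominator is read
as the sum over candidate miRNAs: a per-sample sum is not defined for a
per-miRNA score, and the sum-to-one convention makes the third coordinate
commensurate with M and ρ. Unlike the other two scores the CV is
deliberately offset-sensitive: it penalizes candidates whose raw signal
wanders with loading, which is information the other scores discard.

**SSS** = √(M² + ρ² + CV-score²), the Euclidean distance from the origin in
score space; M is already a per-gene average, so it enters as-is.
Candidates are ranked ascending; ties break lexicographically by miRNA id
for determinism. The top k = 3 become the reference set, matching standard
multi-housekeeper practice.

## Normalization and fold change

Global-mean ΔCt subtracts each sample's mean Ct over a basis set. The
basis defaults to the reliably-detected set inside the pipeline: averaging
over censored, unreliable wells would inject censoring bias into the
normalizer. Reference ΔCt subtracts the arithmetic mean of the reference
Cts (= geometric mean of linear abundances). Missing Ct propagates to
missing ΔCt and is never imputed.

ΔΔCt is the difference of group-mean ΔCt for an ordered pair (numerator,
denominator); fc = 2^−ΔΔCt is reported as a positive ratio with a
direction label (up if fc > 1), which makes fc(A,B)·fc(B,A) = 1 exactly. A
miRNA needs ≥ 2 observed ΔCt per group to be evaluable; otherwise it is
flagged, not silently dropped. In the offsets-only no-noise limit the two
strategies give identical ΔΔCt (asserted to 1e-9): both normalizers then
recover the per-sample offset exactly.

## Differential expression

Profiling calls use a two-sided pooled-variance Student's t on ΔCt per
comparison and strategy (the pooled form is the default because that is
what the plain name "Student's t" denotes; Welch is available). The
significance gate is fc ≥ 2.5 or ≤ 0.4 **and** p ≤ 0.05, applied to each
strategy's own fold change; the consensus call requires both strategies to
pass with the same direction. No multiple-testing correction gates any
call — a Benjamini–Hochberg column is emitted for information only. The
2.5-fold gate dominates the realized false-positive rate: under null
simulations the raw t rejects at ≈ α, but almost no null miRNA reaches a
2.5-fold estimate at n = 5 with 0.3-Ct noise, so the realized FPR is far
below α and the consensus FPR is bounded by each strategy's on every seed
(both measured by the acceptance script).

Degenerate t inputs (zero pooled variance) get p = 1 when the group means
agree and p = 0 otherwise, so constant matrices behave sensibly instead of
propagating NaN.

Validation calls use the Mann–Whitney U test on 2^−ΔCt: exact null
distribution when n_a + n_b ≤ 20 with no ties, normal approximation with
tie and continuity correction otherwise (mid-p is not used; the switch is
deterministic). Two identical samples give p = 1 by convention. The fold
change reported at validation is the ratio of group means of 2^−ΔCt, and a
hit is validated only when its direction matches the profiling call and
p ≤ 0.05. The AH–plasma cross-compartment association uses Spearman rank
correlation (the association is not assumed linear on the 2^−ΔCt scale);
constant inputs are flagged invalid rather than raised, since flat assays
are routine.

## Enrichment arithmetic

Percentages are rounded half-up (`decimal.ROUND_HALF_UP`) to match printed
enrichment tables, which round 0.55 → 0.6 rather than banker's 0.5 → 0.5.
The over-representation p is the plain upper-tail hypergeometric
P(X ≥ k); the conservative EASE-style variant (discounting one hit) is
available behind a flag but is not the default because it is a specific
annotation service's convention, not the textbook test. The module never
queries annotation services: live databases drift between versions, so the
user-exported counts file is the reproducibility boundary.

## Synthetic data

Ct_ij = baseline_i + offset_j + shift(group(j), i) + ε_ij, with additive
Gaussian noise on the Ct (log) scale — the standard qPCR error model.
Defaults emulate a 378-assay profiling card with three groups of five:
baselines uniform on 22–34 Ct, per-sample offsets SD 0.5 Ct (pipetting /
input-amount variation large enough that unnormalized comparisons visibly
fail, which is the point of the normalization stage), technical noise SD
0.3 Ct, three planted stable miRNAs at noise SD 0.05 with baselines 22–28
(comfortably inside the quantifiable range), and a detection limit at Ct 35
with deterministic censoring above it plus 20 % Bernoulli dropout within
one Ct below it. Planted group shifts are expressed in Ct units (positive
shift = lower expression); the default DE plan plants eight 2.5-fold
DME-down shifts. Every bundle carries its ground truth (stable set, DE
table, true offsets, pre-censoring Ct) so recovery is scored by set
algebra, not by eye.

What the generator does **not** emulate: amplification-efficiency
differences between assays, plate/batch layout effects, heavy-tailed or
correlated technical noise, hemolysis and other pre-analytic artifacts, and
any relationship between abundance and noise. Passing recovery tests
therefore demonstrates that the pipeline's inference is correct under its
own assumptions — not that those assumptions hold on any particular real
dataset.

### Simulation experiment sizes

The recovery experiments run 100 independent seeds each. Reference
recovery uses the full default card (378 assays, censoring on); the
planted trio is recovered whenever it occupies the top-3 of the SSS
ranking. The DE operating-characteristics experiment uses the default card
with eight 3-fold DME shifts and baselines drawn on 22–31 so that planted
rows stay inside the quantifiable range — the experiment is designed to
measure the caller's recall and false-positive rate, and letting plants
straddle the detection limit would confound those quantities with
censoring attrition (a real phenomenon, but a different one, exercised by
the detection tests). A planted shift counts as recalled when the miRNA is
consensus-significant with the true direction in at least one comparison
involving the shifted group. One caveat worth knowing: global-mean
normalization absorbs part of a planted shift in proportion to the planted
fraction of the panel (8/378 ≈ 2 % here, a ~0.03-Ct attenuation); on small
panels with many true changes this bias grows and the reference strategy
becomes the more trustworthy of the two — one reason the consensus rule
exists.

## Pipeline determinism

Every stage is a pure function of its inputs and configuration; outputs are
written with fixed column orders and full-precision floats, and the run
manifest records SHA-256 checksums of all inputs and outputs. Re-running a
stage on identical inputs reproduces identical checksums, which the test
suite and the acceptance script both verify. The plasma stage only ever
receives AH-validated miRNAs; that gating is asserted at run time, not just
tested.

## Known limitations

- No efficiency correction (Pfaffl) or inter-plate calibration; inputs are
  assumed to be comparable called Ct values.
- The stability ranking needs ≥ 3 complete candidates and every group ≥ 2
  samples; studies outside those minima need a different design, not looser
  defaults.
- BestKeeper and bootstrap confidence intervals on stability ranks are out
  of scope.
- The Venn partition is fixed at three groups.
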