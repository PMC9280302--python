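# Methods

## The analysis model

The pipeline treats a two-group lesion study (lesioned "ich" vs "sham") as
three coupled analyses over a fixed ROI atlas.

**Atlas.** An ordered list of named regions with hemisphere labels and
bilateral pairing. The default is 9 left/right pairs (striatum, thalamus,
hippocampus, amygdala, frontal, parietal, temporal, occipital and cingulate
cortices; 18 regions). The exact label set of a registration atlas varies
between installations, so the atlas is a YAML config with a built-in
default rather than a constant. `lesion_side` (default `right`, the side
of the blood injection) resolves "ipsilateral" once, centrally; every
downstream quantity inherits it.

**Behavioral scores.** All scores are literal implementations of the
standard definitions, with both eligibility filters read strictly:

- spontaneous alternation = 100 × (entries into the least recently visited
  arm, scanning from visit 3) / (visits − 2); an animal is scored only with
  *strictly more than* 15 visits. A never-visited arm counts as least
  recently visited (last-visit time −∞). Two arms can tie at −∞ only at
  visit 2, which is never scored, so no further tie-break is needed.
- novel-arm time = 100 × novel / (start + novel + other). The alternative
  normalization novel/(start+other) is grammatically defensible; it is
  exposed as the `novel_arm_denominator` switch, with all-three the
  default (group means above 50% are consistent with either reading, and
  the all-three form is bounded in [0, 100]).
- discrimination index = (novel − familiar)/(novel + familiar) exploration
  time; sessions with under 10 s of sample-phase exploration (inclusive
  threshold: exactly 10 s is eligible) are excluded.
- open-arm time = 100 × open / total session time.

**Two-group comparison.** Each sample is screened with a plain
Kolmogorov–Smirnov test against a normal fitted to that sample; if both
pass at α = 0.05 an equal-variance two-sided Student t-test is used,
otherwise a two-sided Mann–Whitney U. The KS gate deliberately uses
estimated parameters without the Lilliefors correction — this matches the
named test but makes the gate conservative (it under-rejects normality);
the choice is recorded here as a known approximation. Paired day-to-day
hematoma comparisons apply the same gate to the paired differences
(one-sample t vs Wilcoxon signed-rank); day comparisons are paired because
the same animals are imaged at each timepoint.

**ROI measures.** Lateralization index = ipsilateral/contralateral volume
per bilateral pair (midline regions skipped; zero ipsilateral volume is a
legal lesion cavity, zero contralateral volume is an error). Volumes are
normalized by the whole-brain volume supplied with the table — never
recomputed from region sums, since atlas regions cover only part of the
brain. PET frames are arithmetically averaged per region before SUVw
(= uptake / whole-brain mean uptake). Cohort filters exclude deaths first,
then lesioned animals with initial volume strictly below 10 mm³ (exactly
10 mm³ is included); shams bypass the volume filter. A contralateral
sanity check (per-region group comparison of raw contralateral volumes) is
emitted alongside the lateralization output: significant rows flag
segmentation/registration problems rather than biology.

## The permutation network comparison

Within each group, the "network" is the k×k matrix of Pearson correlations
of a regional measure across subjects (SUVw for metabolic connectivity,
whole-brain-normalized volumes for the atrophy-related network — the
latter permutes subjects' normalized-volume vectors, the natural analogue
of relabeling subjects in the metabolic analysis). Correlations are mapped
to Fisher Z = arctanh(r), with r clamped to ±(1 − 1e−7) so the map is
total; the statistic per edge is the unstandardized ΔZ = Z_A − Z_B
(group sizes are equal by design and the permutation null absorbs scale;
`statistic="dz_standardized"` divides by √(1/(n_A−3) + 1/(n_B−3))).

The null pools all subjects and re-splits them into pseudo-groups of the
original sizes, recomputing both correlation matrices per relabeling.
Two-sided p per edge uses the add-one estimator
p = (1 + #{|ΔZ_null| ≥ |ΔZ_obs|}) / (n_used + 1), bounded below by
1/(n_used + 1). Exact mode enumerates all C(n, n_A) splits when that count
is at most 20,000, excluding the observed split (whose contribution is the
add-one term); Monte-Carlo mode samples splits uniformly *with*
replacement, observed split included. This pairing makes the Monte-Carlo
p an unbiased-to-O(1/n) estimator of the exact p — excluding the observed
split from the Monte-Carlo stream instead would bias p downward by up to
1/C(n, n_A) (0.05 at 3+3), which is why that design was not used.

Numerical choices: relabelings are drawn over a lexicographically sorted
copy of the pooled rows, and each group's rows are canonically sorted
before the observed correlation, so results are bit-identical under
subject reordering and group-label swap (ΔZ negates, p unchanged). A
region that becomes constant *inside* a permutation replicate is scored
with r = 0 for its edges (counted, warned once) rather than aborting a
10,000-replicate run; zero variance in the observed data is a hard error.
No correction across edges is applied by default, matching per-edge
reporting at p < 0.05; a Benjamini–Hochberg option exists behind
`fdr=True`. The direction of a significant edge follows the sign of
ΔZ_obs.

**Power caveat.** Under the alternative the pooled sample is a mixture, so
the permutation null of ΔZ is wider than the analytic
√(2/(n−3)) normal approximation; edge-wise power is correspondingly lower
than textbook two-sample-z calculations suggest (for a planted latent
r = 0.8 vs 0 at n = 20/20, measured power is ≈ 0.75 where the analytic
approximation predicts ≈ 0.84). This is a property of the
pooled-relabeling construction itself, shared by any faithful
implementation of it.

## The synthetic cohort generator

What it emulates: per-group mean shifts and interregional covariance of
regional volumes (mm³) and FDG uptake (SUV) over the 18-region atlas,
Markov Y-maze visits, object-exploration splits, and acute hematoma
resorption.

- **Measurements** are multivariate normal on the log scale, then
  exponentiated: strictly positive, and multiplicative group effects are
  exact on the log-mean — natural for an analysis reporting ratios.
  Default per-hemisphere baselines (mm³): striatum 45, thalamus 55,
  hippocampus 50, amygdala 20, frontal 90, parietal 70, temporal 80,
  occipital 60, cingulate 35 — a plausible partition of the ~1,600 mm³
  whole-brain volume implied by the overhead factor below. Default log-sd
  0.05 (≈5% coefficient of variation, typical for automated rodent
  volumetry). Whole-brain volume = 1.6 × sum of atlas regions (regions
  are a subset of brain). Correlations are planted on the latent Gaussian;
  the Pearson correlation of the exponentiated values is attenuated by a
  factor ≈ (e^{rσ²}−1)/(e^{σ²}−1)/r, negligible at σ = 0.05. Requested
  edge sets are validated by a smallest-eigenvalue check (tolerance
  −1e−10, with projection onto the PSD cone for round-off).
- **Calibrated volumetry preset**: ipsilateral striatal factors 0.66
  (lesioned) and 0.97 (sham), so expected lateralization indices match
  those group means up to e^{σ²} ≈ 1.003.
- **Y-maze walks**: first arm uniform; each step moves to one of the two
  arms other than the current one — the least recently visited of the two
  with probability `p_alternate`, else the other. For long sessions the
  alternation score estimates 100·p_alternate, giving a direct
  generator/metric consistency check. Inter-visit gaps are exponential
  (mean 15 s, ~32 visits in an 8-minute session).
- **Exploration trials**: the novel share of a fixed exploration budget is
  Beta with mean = preference and concentration 20, clamped to (0, 1);
  E[DI] = 2·preference − 1.
- **Hematoma series**: day-0 truncated normal (mean 23.35 mm³, sd 9.50,
  floor 0.5 mm³); day 3 = day 0 × N(1, 0.05); day 7 = day 0 ×
  N(0.596, 0.05) — a mean resorption of ≈ 40%. The day-7 spread is
  modeled as a fraction of each animal's day-0 volume (preserving the
  day-0 coefficient of variation) rather than as an independent scatter.
- **Behavioral presets** (group means): p_alternate 0.581/0.707,
  novel-arm fraction 0.487/0.64, object preference 0.57/0.665
  (DI 0.14/0.33), open-arm fraction 0.132/0.150 for lesioned/sham
  respectively. Per-subject parameters are Beta-jittered around the group
  mean; per-subject spreads are calibrated to group means only, since
  per-animal behavioral variances are not identifiable from group
  summaries.

What it does *not* emulate, hence what passing tests do not show about
real data: no sex-specific effect sizes (sexes alternate 1:1 but share
parameters), no lesion-size–outcome coupling, no spatial autocorrelation
beyond the planted edges, no measurement drift between imaging sessions,
no attrition correlated with severity, and no voxel-level structure.
Recovery results certify the estimator and its calibration, not the
biology.

Seeding: one root integer seed; per-group and per-subject sub-streams are
spawned from a `SeedSequence`, so cohorts are reproducible and adding
subjects does not reshuffle existing ones. Pipeline stages derive their
seeds from the run seed by fixed offsets so any stage can be rerun in
isolation.

## Validation problem sizes

The suite validates the engine at sizes chosen to make Monte-Carlo error
small relative to the asserted tolerances while keeping the default run
quick: type-I calibration uses 200 null cohorts of 20+20 subjects with
1,000 permutations each (per-edge rate asserted within ±0.01 of 0.05);
exact-oracle equivalence uses 3+3 subjects (20 enumerable splits) against
100,000 Monte-Carlo draws (±0.02); planted-edge recovery uses 100 seeded
cohorts at n = 20/20; generator consistency checks use 500–1,000 seeded
draws. `scripts/acceptance.py` recomputes the calibration number from
scratch with the same design.

## Known limitations

- The KS normality gate with fitted parameters is anticonservative toward
  the t-branch (see above); with n ≳ 30 per group the practical impact on
  the reported p is small.
- Correlation networks at n = 12–32 subjects per group carry large
  sampling variance per edge; edge lists at p < 0.05 without correction
  should be read as descriptive, not confirmatory (the `fdr` option
  exists for the stricter reading).
- The permutation engine assumes complete subjects × regions tables;
  missing values are rejected, not imputed, because pairwise deletion
  would silently change the effective n per edge.
- No voxel-level analysis: inputs are ROI summaries produced by upstream
  segmentation/registration tooling.
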