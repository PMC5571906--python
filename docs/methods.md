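# Methods

This note documents the models, rules and numerical choices behind
`vocompare`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Consensus compounds ("RT ranges")

Peak lists from replicate chromatograms of one method are merged by
single-linkage clustering on retention time with threshold `rt_tol`:
sort all peaks, cut wherever two consecutive RTs differ by more than
`rt_tol`.  In one dimension this equals the transitive closure of
|RT_i − RT_j| ≤ `rt_tol`, so the partition is deterministic and independent
of input order; the package's tests verify exact equivalence against a
brute-force transitive-closure oracle.  "Narrow span of retention times" is
not a quantity with an agreed value; `rt_tol` defaults to 0.05 min, roughly
2–5× the run-to-run RT repeatability of the emulated instruments, and is
configurable everywhere.

A cluster may end up holding two peaks from the same chromatogram (one
compound yields one peak per chromatogram, so this indicates a too-generous
tolerance or co-elution).  The member nearest the cluster's median RT is
kept, ties toward the earlier peak; the surplus peak is reassigned to the
nearest other cluster that lacks that sample, or becomes a singleton.  After
reassignment the receiving cluster's RT span can exceed the gap bound; the
gap property is therefore guaranteed only for inputs without same-sample
duplicates, which is how the property-based tests generate data.

**Occurrence filter.** A cluster is retained iff it is present in at least
`ceil(min_frac × n_samples)` distinct samples, `min_frac` = 0.5: a compound
of the animal's odor should recur in at least half of the method's
chromatograms.

**Blank correction.** For each retained cluster the nearest blank-sample
cluster within `rt_tol` is located; the cluster survives iff its mean area
(over member peaks, one per chromatogram) exceeds the blank's, or no blank
counterpart exists — absence from blanks is the strongest evidence of animal
origin.  The comparison statistic is the mean because the per-cluster
summary used elsewhere in the pipeline is also the mean area; median or
maximum would be defensible alternatives and the code isolates the choice in
one place.  Removed clusters are reported with the blocking blank cluster,
never silently dropped.

## Annotation

The match factor between two stick spectra is `round(999 · cos θ)` with
weights `w = intensity^0.5 · (m/z)^1.0` (the classical library-search
weighting; exponents configurable).  Sticks are paired greedily by nearest
m/z within `mz_tol` (default 0.3 u — unit-resolution quadrupole data);
unpaired sticks contribute nothing to the numerator but remain in the norms,
so 999 requires identical spectra and disjoint spectra score 0.  The
implementation is cross-checked in the test suite against
`matchms.similarity.CosineGreedy` with the same exponents.

A cluster is named after a library entry only if that entry is the top hit
with score > `min_score` (default 700) in **more than half of the cluster's
member samples** (count ties break toward the higher mean score).  The
majority is taken over the cluster's own members rather than all samples of
the dataset, because a compound absent from a chromatogram cannot vote on
its identity; the fraction is configurable.  Only the top hit per spectrum
is eligible — accepting any sufficiently scoring hit in the candidate list
is a flag away (`majority of top hits` is the stricter, default reading).

Volatility: boiling point < 250 °C (760 mmHg) ⇒ `volatile`; the boundary
value is assigned to `semi_or_nonvolatile` because volatility is defined by
the strict inequality.  Boiling points quoted with uncertainty ("95±3")
classify on the central value.  Origin classes come from a curated metadata
table with case-insensitive lookup and shorthand aliases (`exo`,
`pot endo`, `pot metab`); unknown names and unknown labels map to
`unclassified`.

## Cross-instrument overlap

Candidate pairs must share at least `n_diagnostic` = 2 of each side's
`top_k` = 8 most intense consensus-spectrum ions (greedy nearest-m/z pairing
within `mz_tol`).  The two most intense shared ions are reported as the
pair's diagnostic ions; how a human analyst picks "two specific m/z" is
never algorithmic in practice, and taking the most intense shared fragments
is the reproducible operationalisation.  Among candidates the final pairing
is the longest chain strictly increasing in retention time on both sides
(dynamic programming, O(n²)), with cardinality ties broken toward the
largest summed shared-ion intensity agreement; the DP is tested for exact
agreement with exhaustive search on small instances.  The elution-order
constraint assumes comparable (non-polar) stationary phases on both
instruments.

Rank correlations use Spearman's ρ with average ranks.  For n ≤ 9 the
two-sided p-value comes from the exact permutation distribution (all n!
permutations, vectorised); above that the usual t approximation is used.  A
side with zero rank variance yields a `degenerate` status with ρ = NaN
rather than a number.

The bundled 18-compound reference table contains exactly one
elution-order-discordant compound; `elution_order_outliers` finds the
compounds outside the longest order-concordant chain, breaking ties by
removing the later-eluting member of a discordant pair.  With either member
removed the remaining 17 pairs correlate with ρ = 1.

## Common-vs-unique mixed model

Response: natural-log relative peak area (peak area / chromatogram peak
sum).  Fixed effect: the set label (common to both instruments vs unique to
the finer one).  Random structure: intercepts and set-label slopes for the
chromatogram (sample) and for the animal, slopes uncorrelated with
intercepts.  In `statsmodels` this is encoded as variance components over
dummy-coded factors (`0 + C(sample)`, `0 + C(sample):is_common`, likewise
for animal) within a single trivial group, which reproduces the
`(1 + set ∥ g)` structure of the standard mixed-model packages.

Both the full and the null model (fixed effect dropped, random structure
kept) are fitted by **maximum likelihood**, not REML — REML likelihoods are
not comparable across fixed-effect structures, so the LRT on the fixed
effect requires ML.  χ² = 2(ℓ_full − ℓ_null) is referred to χ²(1).  Note
the null drops the *fixed* effect: the set label is the predictor of
interest, and dropping a random term instead would test a different
hypothesis.  Optimisation uses Powell first (derivative-free; robust at
variance-component boundaries, where gradient-based optimisers frequently
flag spurious non-convergence), falling back to L-BFGS/BFGS if Powell steps
into a singular covariance.  Non-convergence is reported via a flag on the
result; the fit is never silently replaced by a simpler model.  A response
with zero variance and equal group means yields χ² = 0 (full and null
saturate identically).

Calibration and power are established by resimulation with
`simulate_relative_area_records`: 6 animals × 12 samples (2 replicates
each), 8 common + 8 unique compounds per chromatogram, intercept −8 (rel.
areas ≈ 3·10⁻⁴), animal/sample intercept SDs 0.4/0.3, slope SDs 0.15,
residual SD 0.6 — moderate heterogeneity consistent with the pipeline's own
synthetic data, and variance levels at which a 2-unit log shift is
estimable to ±0.3.  Under the null, the LRT's empirical type-I error at
α = 0.05 falls in [0.02, 0.09] over 500 simulations; under a +2 log-shift
the effect is recovered within ±0.3 with p < 0.01 in ≥ 90% of seeds.  These
are the sizes run by the test suite and the acceptance script; they complete
in about two minutes on one CPU.

## The synthetic-data generator

`generate_dataset` emulates the study design: five methods
(cotton swabs, mobile GC-MS, TD tubes with mixed bed, Tenax TA, XAD-4), six
animals × two replicates per method (five animals for XAD-4, giving its 10
samples), and three blanks per method (blank counts per method are a free
choice of this package).  The latent panel holds 60 compounds with boiling
points uniform on 80–400 °C — straddling the 250 °C threshold — origin-class
proportions 12/34/50/4 % (exogenous / potentially endogenous / potentially
metabolized / unclassified, matching the composition of a typical curated
body-odor compound set), and mean log areas ~N(13, 1.8²) (areas ≈ 4·10⁵,
within the range printed in real peak tables).

Mechanisms, and why they are there:

* **Elution**: elution order equals boiling-point order (non-polar columns),
  with a jittered minimum gap (≥ 0.25 index units) between consecutive
  compounds so that distinct compounds stay chromatographically resolvable —
  the recovery contract of the consensus stage is meaningless if the panel
  itself co-elutes.  Each method maps the shared elution coordinate through
  its own strictly increasing affine-plus-curvature RT map (validated over
  the panel range at configuration time) plus Gaussian jitter (default
  0.01 min), so zero-jitter cross-method elution order is exactly preserved.
* **Detection**: P(detect) = logistic((log A − 13)/1.5 + logit(sensitivity)).
  Sensitivity is thereby the detection probability for a compound of median
  abundance; sensitivity 1 gives certain detection (the noiseless limit);
  and detection is increasing in abundance, which is what makes an
  insensitive instrument's profile collapse onto the most abundant
  compounds — the effect the mixed model is designed to detect.
* **Coverage**: a method only ever emits compounds whose boiling point lies
  in its volatility window (mobile: < 250 °C only; cotton: ≥ 170 °C; TD
  tubes: essentially everything), never violated, by construction.
* **Areas**: log-normal around the compound mean plus animal-level (SD 0.3)
  and chromatogram-level (SD 0.2) effects plus residual noise (SD 0.5) — the
  variance structure the mixed model assumes.
* **Blanks**: every exogenous panel compound appears in every blank at
  log(2) higher mean log area than in animal samples, so the blank filter
  has true positives; non-exogenous compounds never appear in blanks, so it
  has true negatives; Poisson(2) pure-noise peaks per blank exercise the
  no-counterpart path.
* **Spectra**: 5–25 sticks at distinct integer m/z in [30, 300], base peak
  999, with mild multiplicative intensity noise (SD 0.08) per observation.
  The library contains every panel compound plus 15 decoys.

Determinism: all randomness derives from one master seed through
counter-based child streams per (stage, method, sample), so identical
configuration gives byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: peak-picking errors and deconvolution artifacts
(inputs are peak tables, not raw signal), retention-time drift within a
sequence (jitter is i.i.d.), co-elution and shared fragment ions between
panel compounds, matrix effects, compound-specific response factors that
differ *between* methods (areas are generated from one shared mean, so
cross-method area correlations in synthetic data are higher than the
near-zero correlations typical of real adsorbent comparisons), and bacterial
metabolization dynamics.

## Recovery accounting

Recovery of the simulated panel is measured after clustering + occurrence
filtering, per method, against the truth's detectable sets.  The blank
filter is deliberately excluded from this count: at full sensitivity it
removes the exogenous subset (that is its job), so post-blank counts cannot
equal |detectable| on a panel that contains contaminants.  The blank filter
is instead validated directly with truth labels: on a noiseless dataset it
removes exactly the exogenous clusters and keeps everything else.

## Known limitations

* Single-linkage RT clustering can chain through dense peak fields if
  `rt_tol` is large relative to peak spacing; there is no model-based
  deconvolution.
* The cross-instrument matcher requires shared fragment ions within a unit
  tolerance; it will not align instruments with strongly differing
  fragmentation (e.g. soft vs hard ionisation).
* The mixed model assumes log-normal relative areas; zero/censored areas are
  not modelled (the generator never produces them, real integrators do).
* Exact permutation p-values are limited to n ≤ 9 pairs (9! permutations);
  larger n uses the t approximation.
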