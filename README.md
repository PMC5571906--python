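# vocompare

Comparing methods for sampling mammalian body odor by GC-MS.

Untargeted volatile profiling of animal body odor can be done with very
different front ends — cotton swabs rubbed over the skin, thermal-desorption
(TD) tubes packed with adsorbents such as Tenax TA or XAD resins, or a mobile
GC-MS that samples air directly through its own desorption trap.  Each choice
trades off sensitivity, volatility coverage and contamination.  `vocompare`
implements the data-analysis side of such a method comparison as a tested,
reusable pipeline for chemical ecologists:

1. **Consensus compounds** ("RT ranges"): peaks recurring within a narrow
   retention-time span across a method's replicate chromatograms are merged
   into one consensus compound by gap-based single-linkage clustering at a
   tolerance `rt_tol` (default 0.05 min); a compound must occur in at least
   half of the method's samples to count.
2. **Blank correction**: a compound is attributed to the animal only if its
   mean peak area in animal samples exceeds that of the matching feature in
   blank (no-animal) samples; features absent from blanks are kept.
3. **Annotation and classification**: identities are assigned by spectral
   library search using a NIST-style match factor
   `999 · cos(√I·m/z weighting)` on the 0–999 scale, accepted only when one
   entry is the top hit with score > 700 in a majority of member samples.
   Compounds are volatile if their boiling point is < 250 °C (760 mmHg), and
   carry an origin class (exogenous / potentially endogenous / potentially
   metabolized / unclassified) from a curated metadata table.
4. **Cross-instrument overlap**: compounds are matched between two
   instruments using two diagnostic fragment ions plus elution order — the
   maximum-cardinality order-preserving matching, computed by dynamic
   programming — and validated by Spearman rank correlations of retention
   times (ρ ≈ 1 if assignments are right) and of relative mean areas.
5. **Common-vs-unique statistics**: with relative peak area
   *a<sub>i</sub> / Σ<sub>j</sub> a<sub>j</sub>* per chromatogram as
   response, a linear mixed model `log(rel area) ~ set + (1 + set ∥ sample)
   + (1 + set ∥ animal)` (uncorrelated intercepts/slopes, ML fit) tests by
   likelihood-ratio whether compounds detected by both instruments are the
   more abundant ones.

Because raw chromatograms from such studies are rarely deposited, the package
ships a first-class synthetic-data generator (`vocompare.synthetic_data`)
that emulates the study design — six animals × two replicates per method,
per-method blanks, method-specific sensitivity, volatility windows and
retention-time maps, contaminants shared between blanks and samples — with
full ground truth, so every stage is testable end to end.  A curated
18-compound cross-instrument reference table
(`vocompare.datasets.cross_instrument_reference`) provides a real-data worked
example.

## Worked example

```sh
vocompare simulate --seed 1 --out demo
# wrote 1975 peaks for 5 methods to demo/peaks.csv

cat > demo/config.yaml <<EOF
peaks: demo/peaks.csv
library: demo/library.msp
metadata: demo/metadata.csv
EOF
vocompare run --config demo/config.yaml --out demo/run
```

prints

```
cotton: 24 compounds, 7 volatile (29%)
mobile: 12 compounds, 12 volatile (100%)
td_mix: 51 compounds, 24 volatile (47%)
td_tenax: 44 compounds, 20 volatile (45%)
td_xad4: 38 compounds, 14 volatile (37%)
overlap mobile vs td_mix: 12 common, 0 unique to mobile, 39 unique to td_mix
mixed model: effect=0.725 chi2=12.42 df=1 p=4.24e-04
```

Reading the output: the mixed-bed TD tube recovers the largest compound
inventory; the mobile GC-MS sees the fewest compounds but exclusively
volatiles; cotton swabs skew toward semi-/non-volatiles.  Every compound the
mobile instrument detected was also found in the TD profile, and the
mixed-model effect (+0.73 on the natural-log scale, χ² = 12.4, df = 1,
p < 0.001) shows the shared compounds are systematically more abundant —
the less sensitive instrument catches the top of the abundance distribution.
The run directory contains per-method profile CSVs, the matched-pair table,
and `manifest.json` with per-stage counts, the config hash and the seed.

The same analysis is available as a library:

```python
import vocompare as vc

ds = vc.generate_dataset(seed=1)
profile, provenance = vc.build_method_profile(ds.peaks_for_method("td_mix"))
annotated = vc.annotate_profile(profile, ds.library)
```

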