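# metaline

Untargeted LC–MS metabolomics in Python: from centroided mzML runs to an
aligned, deisotoped, gap-filled data matrix, through reference-database
identification with a weighted composite score, to adduct/in-source-fragment
clustering, trend analysis, statistics, quantification and pathway
projection.

It is aimed at metabolomics practitioners who want the complete
processing-and-annotation chain as a scriptable library (plus a thin
`metaline` CLI), with every stage testable against a built-in synthetic-study
generator that knows its own ground truth.

## The method

**Processing.** Each run is reduced to extracted-ion chromatograms by
ppm-tolerance m/z binning; Savitzky–Golay smoothing, rolling-minimum baseline
subtraction and an S/N threshold yield per-sample peaks. Retention times are
corrected by promoting high-intensity features present in all samples to
anchors and warping monotonically to their median RT. Grouped columns are
scanned for isotopologue patterns on the 1.0033548/z spacing grid (with a
carbon-count plausibility bound on the A+1/A ratio); A+n columns are hidden
from identification but kept for isotope scoring. A dual-threshold gap
filler recovers peaks whose apex lies between the conversion ("low") and
processing ("high") thresholds into empty matrix cells. A virtual *Super
Sample* holds, per feature, the average detected area and the
occurrence-merged MS/MS spectrum; identification runs on it, so its cost
scales with features, not samples.

**Identification.** Candidates are drawn from a reference database
(SDF/MSP imports, in-house libraries built from standards runs, optionally
cleaned by an in-silico MS/MS validator). Each candidate is scored with

    OS = (x·S_M + y·S_IP + z·S_F + w·S_CCS) / N,    N = x + y + z + w

where S_M is a linear ppm-decay mass score, S_IP a cosine similarity of
isotopologue envelopes, S_F a greedy-matched cosine on square-root
intensities, and S_CCS a linear percent-difference score; default weights
are x=30, y=10, z=60, w=0, and an inapplicable score contributes 0 while
its weight stays in N (a mass-only match therefore scores OS = 30).
Annotations are colored green (OS > 60), orange (candidates at OS ≤ 60) or
red (no candidate), starred by OS bands, and assigned a Schymanski-style
level. A second run inspects peaks coeluting with each identified compound
for further adducts and neutral-loss in-source fragments, accepting them on
mass, isotope-pattern and across-sample trend coherence (Pearson r ≥ 0.8 by
default) and promoting them to light-green ("p-high"). Approved annotations
are finally merged into per-compound adduct/ISF clusters, using the
parent-ion rule (a coeluter whose m/z appears in a higher-m/z feature's
MS/MS is its in-source fragment).

**Analysis.** Fold change with Welch t-tests and Benjamini–Hochberg
correction, ANOVA, PCA / PLS-DA and consensus PCA (multiblock NIPALS),
hypothesis-driven trend matching and K-means / bisecting K-means trend
clustering, weighted calibration curves for quantification, a
biotransformation-rule search for xenobiotic metabolites, and projection of
annotations onto metabolite/enzyme pathway graphs.

## Worked example

Simulate a 2-group study (5 compounds, two adducts and a water-loss ISF
each, 3 replicates per group), process it and identify against the matching
reference database:

```python
from metaline import simdata, features, annotate

compounds = simdata.default_compound_library(5)
for i, c in enumerate(compounds):
    c.adducts = ("[M+H]+", "[M+Na]+")
    c.isf_losses = ("H2O",)
    c.group_means = {"control": 1.0, "treated": 1.0 + 0.6 * i}

runs, truth = simdata.simulate_study(compounds, {"control": 3, "treated": 3},
                                     noise_sigma=0.1, seed=7, k_isotopologues=2)
matrix = features.process_study(runs, {"snr_min": 3.0})
db = simdata.reference_db_for(compounds)

anns = annotate.identify_run1(matrix, db, rt_tol=0.2)
anns = annotate.extend_run2(anns, matrix, db, rt_tol=0.1)
links = annotate.detect_isf(matrix, rt_tol=0.1)
clusters = annotate.cluster_adducts(anns, matrix, links, rt_tol=0.1)
```

This prints, for the first two compounds (30 features total from 6 runs,
5 clusters):

```
      feature compound     adduct   S_M  S_IP   S_F    OS       color  stars level  run  cluster_id
128.0706@1.00   cmpd00     [M+H]+ 100.0 100.0 100.0 100.0       green      4     1    1           1
110.0600@1.00   cmpd00 [M+H]+-H2O 100.0 100.0   NaN  40.0 light-green      2    2b    2           1
150.0525@1.00   cmpd00    [M+Na]+ 100.0 100.0   NaN  40.0 light-green      1    2b    2           1
142.0863@1.25   cmpd01     [M+H]+ 100.0 100.0 100.0 100.0       green      4     1    1           2
...
```

Each protonated monoisotopic feature is matched by mass, isotope pattern
and MS/MS (OS 100, green, level 1 since the library carries RTs); the
sodiated adduct and the water-loss in-source fragment carry no reference
spectrum, so their OS comes from mass + isotope evidence alone — the second
run promotes them to light-green on coelution and shared trend, and
clustering ties all three features of each compound together.

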