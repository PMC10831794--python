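# Methods

This note records the models, parameter choices and numerical decisions
behind `metaline`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Mass and isotope arithmetic

All masses derive from one hard-coded table of monoisotopic masses
(1H = 1.0078250319, 12C = 12 exactly, 14N = 14.0030740052,
16O = 15.9949146221, electron = 0.000548579909, 13C−12C = 1.0033548378 Da;
further elements in `chem.MONOISOTOPIC_MASS`). Adduct m/z is
`(n·M + Δm − z·m_e)/|z|` with the delta formula parsed from the bracket
notation (`[M+H]+`, `[2M+Na]+`, `[M−NH3+H]−`, …). Because every route goes
through the same table, identities such as
`mz([M+H]+) − mz([M−NH3+H]+) = m(NH3)` hold exactly.

Isotope patterns are computed by exact polynomial expansion: each element's
natural isotope distribution (indexed by neutron offset) is raised to its
atom count by repeated convolution and the element polynomials are
convolved together; the first k isotopologues are reported on the
1.0033548/|z| Da spacing grid, normalized to base peak 1. Tests verify the
expansion against full enumeration for small formulas and against the
binomial closed form for pure carbon at 50 atoms (≤ 1e−6).

## In-silico fragmentation

The fragmenter is deliberately simple: acyclic single-bond cuts (and pairs
of cuts at depth 2) on the explicit-hydrogen structure, valences refilled
with hydrogens at the cut sites, plus a fixed neutral-loss list (H2O, NH3,
CO, CO2, HCOOH) applied to the (de)protonated parent and to every cut
fragment. Fragment ions are reported as formula mass ∓ one electron. Ring
cleavage, hydrogen-rearrangement scoring and collision-energy modeling are
out of scope; the fragmenter's job here is validation (assigning elemental
compositions to observed peaks) rather than spectrum prediction, and for
that the simple cut-and-loss enumeration is sufficient and auditable.

Biotransformation rules (oxidation +O, reduction +H2, demethylation −CH2,
dehydration −H2O, hydrolysis +H2O, glucuronidation +C6H8O6, sulfation +SO3,
acetylation +C2H2O) operate on structures when available, using SMARTS
preconditions to check that a plausible site exists; with a bare formula
the delta arithmetic still runs but candidates are flagged
`verified_site=False`. Compositions are allowed to depth 2 and candidates
with negative element counts are discarded.

## Processing chain

* **EIC binning** — peaks from all MS1 scans are sorted by m/z and split
  where the gap between neighbours exceeds twice the ppm tolerance
  (default 5 ppm). This is O(n log n) and deterministic.
* **Peak detection** — Savitzky–Golay smoothing (window 7, order 2),
  rolling-minimum baseline (window 101 scans, wide enough that Gaussian
  flanks are not eaten), noise as 1.4826·MAD of the corrected trace, local
  maxima kept at S/N ≥ 5 and apex ≥ the processing ("high") threshold.
  Peak bounds walk outward to 0.5 % of apex or the first valley; the area
  is the trapezoidal integral of the baseline-corrected raw signal. On a
  noiseless Gaussian the recovered area is within ~0.2 % of truth.
* **RT correction** — anchors are features matched across *all* samples
  within tolerance, taken top-down by intensity (default 20); each sample
  gets a monotone piecewise-linear warp of the *shift* to the median anchor
  RT, so retention times outside the anchor range receive the constant edge
  correction rather than being clamped. Batch metadata switches between
  intra- and inter-batch tolerances. Fewer than 3 anchors ⇒ identity warp
  with a warning.
* **Grouping** — greedy, seeded by the most intense unassigned trace, one
  member per sample within m/z ppm and RT tolerance; because seeds are
  processed in a deterministic intensity order, grouping is invariant to
  input order.
* **Isotope clustering** — columns spaced by n·1.0033548/z (z up to 2) and
  coeluting are grouped when the A+1/A area ratio does not exceed
  `(m/z·z/12)·0.0108·1.3` — the envelope bound from the largest carbon
  count compatible with the mass, with a 1.3 safety margin for integration
  error. A+n columns are hidden from identification but retained so the
  observed envelope can be scored.
* **Gap filling** — an empty cell is filled only from a peak at the feature
  coordinates whose apex lies in `[low, high)`; peaks ≥ high already made
  columns and peaks < low were removed at conversion and are gone. The two
  thresholds default to 0 (no filling) because real defaults are
  instrument-specific; the tests exercise the contract with explicit
  values.
* **Super Sample** — per feature, the mean over cells carrying signal
  (detected, gap-filled or reintegrated — gap-filled cells are real
  measurements, so they count), plus an MS/MS merge that clusters peaks
  within an absolute m/z tolerance and keeps those present in ≥ 50 % of
  the contributing spectra. Occurrence (not intensity) voting was chosen
  because the goal is noise rejection, and a peak's presence across
  replicates is the more robust witness than its fluctuating intensity.

Every derived matrix stores its parent and the operation label with
parameters; pure matrix filters can be replayed from the root to reproduce
a leaf, and the session manifest records the chain.

## Scoring and confidence

Partial-score shapes are this package's own choices, constrained by the
worked behavior they must reproduce: S_M = 100·(1 − |Δppm|/tol) so an exact
mass gives 100; S_IP and S_F are cosine similarities (S_F on square-root
intensities with greedy closest-pair matching, cross-checked against
matchms in the tests); S_CCS = 100·(1 − |Δ%|/tol%). An inapplicable score
contributes 0 with its weight kept in N — this is forced by the mass-only
case: 30·100/100 = 30 only if N stays 100. Colors: green strictly above
OS 60, orange for candidates at or below, red with no candidate,
light-green for second-run promotions. Stars: 1★ < 40 ≤ 2★ < 60 ≤ 3★ < 80
≤ 4★. Levels: 1 (mass + RT + MS/MS against an in-house record), 2a
(mass + library MS/MS), 2b (run-2 promotion), 3 (mass-only or ambiguous),
4 (formula-plausible), 5 (unknown).

Run 2 accepts a coeluting candidate on three joint conditions: mass within
tolerance, isotope-envelope cosine ≥ 50 when an observed envelope exists,
and Pearson trend correlation with the anchor ≥ 0.8. Two profiles whose
coefficient of variation is below 0.1 % are treated as trivially correlated
(r undefined on constants; flat profiles share the same absent trend) —
this matters only for noise-free simulations. Run 2 never demotes a run-1
annotation; red placeholders are replaced by the promotion.

## Trend analysis, statistics, quantification

Trend vectors default to replicate-group means in label order,
z-standardized; constant profiles are excluded from correlation. Cluster
quality is the percentage of members correlating ≥ 0.8 with the cluster
mean ("highly correlated" quantified as the same 0.8 default used for
matching). K-means uses k-means++ with 10 restarts and a caller-supplied
seed; bisecting K-means exposes a non-committing split preview.

Consensus PCA follows the CPCA-W iteration (block loadings regressed on the
super score, block scores re-projected, super weights from the block-score
matrix, deflation by the super score). With one block it reduces to PCA
(asserted to 1e−8); with several unscaled blocks its super scores equal PCA
of the concatenated matrix, which the tests use as an independent oracle.
Sign convention everywhere: the largest-|loading| entry of a component is
positive.

Calibration fits are weighted least squares (weights 1, 1/x, 1/x²) for
linear or quadratic models; inverse prediction picks the root inside the
calibrated range and flags extrapolations. Fold changes use Welch t-tests
with Benjamini–Hochberg correction; significance stars at
P ≤ 0.05/0.01/0.001/0.0001.

Pathway graphs are a small JSON dialect (typed metabolite/enzyme nodes,
relation edges). Projection marks matched nodes detected (gray) and, under
a two-label comparison, up (red) / down (blue) using explicit log2FC and p
thresholds — the coloring criteria are parameters because "increased /
decreased" is a study-level decision.

## The synthetic-study generator

`simdata.simulate_study` emits, per compound: each requested adduct at its
exact theoretical m/z with the compound's natural isotope envelope,
optional in-source fragments coeluting at the same RT (at 0.4× the parent
adduct's response), Gaussian chromatographic peaks (FWHM 0.1 min, scan
interval 0.01 min), per-sample areas = base area × group mean × lognormal
noise (σ 0.15 by default), optional uniform noise peaks, blanks with a
configurable contamination fraction, and one DDA MS/MS scan at the
protonated-adduct apex carrying the compound's deterministic reference
fragments (small-neutral-loss ions with fixed relative intensities). An
emission floor suppresses peaks below a given apex intensity, creating
ground-truth-known gaps. The companion `reference_db_for` builds the
complete matching database (formulas, RTs, the same fragment spectra), so
end-to-end recovery against a complete library is exact by construction.

What this does **not** emulate: chimeric MS/MS, ion suppression and matrix
effects, mass-accuracy drift, peak-shape asymmetry, real fragmentation
chemistry, or retention-time nonlinearity beyond what the warp model
corrects. Passing tests therefore demonstrate the correctness of the
bookkeeping and the algorithms' contracts, not instrument-level robustness;
thresholds that are instrument-specific (conversion/processing intensities)
default to "off" and must be set per study.

Problem sizes in the test suite (20 compounds × 4 ion species × 2
isotopologues × 6 samples for the recovery study; 10 seeds for the
stochastic suites) were chosen as the smallest sizes at which the studied
effects are unambiguous, keeping the default suite fast.

## Known limitations

* Ion-mobility data: CCS values are carried and scored, but no drift-time
  processing is performed.
* The second run scores promotions on mass + isotope evidence only; a
  promoted feature acquires fragment evidence only after MS/MS import and
  validator confirmation.
* `fragment_in_silico` requires a structure; formula-only records validate
  against neutral-loss ions of the precursor, a much weaker check.
* The QC normalization LOESS needs ≥ 3 QC injections and interpolates
  linearly between them; sparse QC coverage at the batch edges
  extrapolates the edge factor.
* Polarity merging is a column union; cross-polarity reconciliation happens
  only through identification and adduct clustering.
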