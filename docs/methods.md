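# Methods

## The binning model

A full-scan LC-MS run is a sequence of MS1 scans, each a list of
(m/z, intensity) points. `massbin` treats profile and centroid acquisitions
identically — every downstream quantity is a sum over points, which is well
defined for both, so no centroiding is performed.

The fingerprint of a run on a grid `(mass_lo, mass_hi, bin_size)` is the
vector whose i-th entry is the summed intensity of all points, in all
scans, with m/z in bin i. The bin count is
`N = ceil((mass_hi - mass_lo) / bin_size)`, which reduces to
`mass range / bin size` when the range divides evenly (m/z 100–1500 at
size 2 → 700). Bins are half-open `[lo, hi)` with the last bin closed at
`mass_hi`, and edges are anchored at the user's `mass_lo` rather than at
the instrument scan floor; with the conventional `mass_lo = 100` this
produces the familiar even-numbered labels (`608_610`, `370_372`, ...).
Points outside the grid are dropped and counted, never clipped into the end
bins, so the conservation law

    sum(bin values) + discarded intensity == total ion current

holds to 1e-9 relative and is asserted in the tests. Because edges of a
size-s grid are a subset of the size-1 edges (for integer s dividing the
range), fine fingerprints aggregate exactly to coarse ones; this
refinement identity is also tested (sizes 1 → 2, 10, 50).

Two deliberately different interval conventions coexist:

* **User EICs are closed** `[lo, hi]`: a window written "608–610" is
  expected to contain an ion at exactly 610.
* **Bins (and the per-bin EIC export) are half-open**, so the per-bin EIC
  series sum exactly to the bin totals and no point is counted twice.

The averaged mass spectrum over an RT window pools the points of all scans
in the window, groups them by m/z rounded to `mz_decimals` (default 2,
matching unit-resolution ion-trap data), and divides each group's sum by
the number of scans — a per-scan average, so spectra from windows of
different widths are comparable.

## The statistics chain

Preprocessing of a samples × bins matrix runs in a fixed order, enforced by
provenance flags (steps may be skipped, never reordered or repeated):

1. **IQR filter** — features are ranked by interquartile range across
   samples and the lowest fraction removed: 5% for ≤ 250 features, 10% for
   ≤ 500, 25% for ≤ 1000, 40% above that; the removal count is
   `floor(f·N)` with ties broken by feature order. At 700 features this
   removes 175 (25%). A commonly cited count for this scenario is 176 —
   one more than `floor(0.25·700)`; the floor rule is used here and the
   one-variable discrepancy accepted as unresolvable from the rule alone.
2. **Sum normalization** — each row divided by its total, correcting for
   global signal differences (tissue mass, injection volume). Rows then
   sum to 1.
3. **log₂ transform** — `x → log2(x + c)` with a single pseudocount
   `c = (smallest positive value in the table) / 2`. Binned data can
   contain exact zeros (empty bins, filtered tables); a constant
   pseudocount preserves within-row ordering everywhere.
4. **Autoscaling** — per feature, subtract the mean and divide by the
   sample standard deviation (n−1). Constant features are set to zero with
   a warning rather than producing NaNs.

**PCA** is computed by SVD of the column-centered table (centering is a
no-op after autoscaling); explained-variance fractions are the normalized
squared singular values. Sign ambiguity is fixed deterministically: each
component's largest-|loading| feature is made positive. The tests verify
scores and fractions against a brute-force eigendecomposition of the
covariance matrix at 1e-8.

**Volcano** — the fold change is the ratio of group means on the
*sum-normalized pre-log* table, where a ratio is meaningful; the p-value is
a two-sided **Welch** t-test on the *transformed* table, where normality is
more plausible. Welch's unequal-variance form is the robust default since
autoscaling equalizes total, not within-group, variance. Default
thresholds: fold ≥ 4 (or ≤ 1/4) and p < 1e-10. No multiple-testing
correction is applied by default (the conventional readout is raw p against
a stringent threshold); Benjamini–Hochberg adjustment is available behind
the `fdr` flag. Features whose denominator group mean is zero are reported
as infinite fold change with an explicit flag. When both groups are exactly
constant the t-statistic is undefined; p is set to 1 if the means agree and
0 if they differ (a deterministic difference).

**HCA** — dissimilarity is `d = 1 − r` (Pearson correlation between item
profiles; an item with zero variance is an error naming the item), and
merging follows Ward's criterion applied directly to these unsquared
dissimilarities — the classic Lance–Williams "ward.D" recurrence, chosen
so merge heights are reproducible across implementations. Internally
scipy's Ward linkage is run on `sqrt(d)` and the heights squared back,
which is algebraically identical; the tests check the heights against a
naive Lance–Williams implementation at 1e-9.

`run_group_analysis` chains all of the above and, given an output
directory, writes five CSVs (filtered table, scores, loadings, volcano
table, linkage) and three PNGs (score plot, volcano, dendrogram). With a
single group the volcano is skipped with a notice; PCA and HCA still run.

## The synthetic-data generator

`simulate_run` builds each scan from Gaussian elution profiles:
`A · exp(−(t − t0)² / (2σ_t²))` at the peak's m/z (five profile-mode points
with unit-sum Gaussian weights when `mz_sigma > 0`, so amplitude is
conserved), optional satellite ions (e.g. a [2M−1] dimer at a given
relative amplitude), plus a baseline of points at uniform m/z with
exponentially distributed intensities — heavier-tailed than Gaussian and
non-negative, as instrument baseline is. Noise-free totals therefore have
closed forms, which the tests exploit as exact oracles.

`simulate_two_group_study` emulates a 12-vs-11 replicate design:

| parameter | default | rationale |
|---|---|---|
| groups | 12 "HL" vs 11 "LL" | the canonical unbalanced two-group design |
| grid | m/z 100–1500, size 2 | standard full-scan grid, 700 bins |
| shared peaks | 60, amplitude ~1e5 (0.5–2×) | a plausibly busy plant-extract chromatogram |
| spiked peaks | 10, base amplitude 2e4, ×8 in HL | differential features; kept small relative to total signal so sum normalization dilutes the fold only marginally |
| sample-to-sample variation | log-normal, CV 15% | typical biological replicate scatter |
| baseline | 40 points/scan, exponential mean = 1% of max amplitude | visible but subordinate baseline |
| time axis | 600 s sampled every 5 s (121 scans) | dense enough for ~6 s peak widths; sized for fast simulation |

Spiked peaks sit at the centers of distinct bins holding no shared peak, so
the truth manifest's `spiked_bins` are exactly the differential features.
Everything is deterministic under a seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: isotope envelopes and adducts, retention-time
drift (irrelevant to the bin statistic by construction, but relevant to the
EIC views), detector saturation, heteroscedastic electronic noise,
correlated biological variation between compounds, and real null
distributions wider than log-normal. Recovery rates measured here are an
upper bound on what field data would give.

## Numerical and design choices

* RT is stored in seconds (the mzML convention) and displayed in minutes
  (the reporting convention); the CSV column is `time_min`.
* Only MS1 scans are loaded; MSn scans are dropped with a logged count.
* mzML is read by a small streaming reader (lxml) that handles 32/64-bit,
  zlib-compressed, indexed and plain documents; mzXML via pyteomics; ANDI
  netCDF (netCDF-3 classic) via scipy. mzData is rejected as obsolete.
* Scans whose point lists are empty contribute zeros to every chromatogram
  so all series from a run share one time axis.
* Bin labels print edges at `%g` precision (`100_102`), and a matrix CSV
  can be read back into a `BinMatrix` from its labels alone.
* Grid aggregation tolerates 1e-9 edge mismatch and requires coarse edges
  to be a subset of fine edges; anything else is an error, not a guess.
* PCA `n_components` is capped at `min(n_samples − 1, n_features)`.
* All stochastic tests fix seeds; the library itself contains no hidden
  randomness.

## Known limitations

* The IQR filter's off-by-one relative to the commonly cited 176/700 (see
  above).
* Sample-level HCA on 1 − correlation is noise-dominated when only a few
  of hundreds of features are informative: with 10 spiked bins among 525
  retained features the k=2 cut usually — but not at every seed — recovers
  the groups. PC1 two-means clustering is the robust readout and is the
  one measured by the acceptance script.
* Variable-width or overlapping bins, retention-time binning, peak
  deconvolution, PLS-DA and metabolite annotation are out of scope.
* No vendor raw formats; no mzML writing beyond the minimal internal
  serializer used by the synthetic exporter.
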