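"""Differential profiling of multi-sample feature tables.

The statistics chain applied to a two-group bin matrix (or any non-negative
feature table), in the fixed order

    IQR filter -> sum normalization -> log2 transform -> autoscaling

followed by PCA (scores, loadings, explained variance), a volcano analysis
(fold change + Welch t-test, default thresholds 4-fold and p < 1e-10) and
agglomerative hierarchical clustering on 1 - Pearson correlation with
Ward's linkage.  The preprocessing order is enforced via provenance flags on
the table: steps may be skipped but never reordered or re-applied.

Fold changes are computed on the sum-normalized (pre-log) table, where a
ratio of group means is meaningful; significance is computed on the
log2-transformed/autoscaled table, where the t-test's normality assumption
is more nearly satisfied.  Welch's unequal-variance form is used because
autoscaling does not guarantee equal within-group variance.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .binning import BinMatrix

logger = logging.getLogger(__name__)

_STEPS = ("filtered", "normalized", "log2", "autoscaled")

#: IQR filter removal fraction by feature count, mirroring the variable-count
#: dependent schedule used by standard metabolomics preprocessing.
IQR_FRACTION_SCHEDULE = ((250, 0.05), (500, 0.10), (1000, 0.25))
IQR_FRACTION_LARGE = 0.40

DEFAULT_FC_THRESHOLD = 4.0
DEFAULT_P_THRESHOLD = 1e-10


class PreprocessingOrderError(RuntimeError):
    """A preprocessing step was applied out of order or twice."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples x features table with group labels and preprocessing provenance."""

    samples: list[str]
    groups: list[str]
    feature_labels: list[str]
    values: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if not (len(self.samples) == len(self.groups) == n):
            raise ValueError("samples and groups must match the row count")
        if len(self.feature_labels) != p:
            raise ValueError("feature_labels must match the column count")
        ranks = [_STEPS.index(s) for s in self.provenance]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError(f"invalid provenance {self.provenance}")

    @classmethod
    def from_bin_matrix(cls, matrix: BinMatrix) -> "FeatureTable":
        return cls(samples=list(matrix.samples), groups=list(matrix.groups),
                   feature_labels=matrix.grid.labels(),
                   values=matrix.values.copy())

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def group_names(self) -> list[str]:
        out: list[str] = []
        for g in self.groups:
            if g not in out:
                out.append(g)
        return out

    def _check_step(self, step: str) -> None:
        if step in self.provenance:
            raise PreprocessingOrderError(f"table is already {step}")
        rank = _STEPS.index(step)
        later = [s for s in self.provenance if _STEPS.index(s) > rank]
        if later:
            raise PreprocessingOrderError(
                f"cannot apply {step!r} after {later[0]!r}; the order is "
                + " -> ".join(_STEPS))

    def _with(self, step: str, values: np.ndarray,
              feature_labels: Optional[list[str]] = None) -> "FeatureTable":
        return FeatureTable(
            samples=list(self.samples), groups=list(self.groups),
            feature_labels=feature_labels if feature_labels is not None
            else list(self.feature_labels),
            values=values, provenance=self.provenance + (step,))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample", self.samples)
        return df


# ---------------------------------------------------------------------------
# Preprocessing steps
# ---------------------------------------------------------------------------


def iqr_filter_fraction(n_features: int) -> float:
    """Removal fraction for the interquartile-range filter, by feature count."""
    for bound, frac in IQR_FRACTION_SCHEDULE:
        if n_features <= bound:
            return frac
    return IQR_FRACTION_LARGE


def iqr_filter(table: FeatureTable) -> FeatureTable:
    """Drop the lowest-IQR features (near-constant, mostly baseline signal).

    Features are ranked by interquartile range across samples and the lowest
    fraction ``f`` removed, where ``f`` follows :func:`iqr_filter_fraction`
    (e.g. 25% of a 700-feature table).  Removal count is ``floor(f * N)``;
    IQR ties are broken by feature order, lower-index features removed first.
    """
    table._check_step("filtered")
    n = table.n_features
    k = math.floor(iqr_filter_fraction(n) * n)
    iqr = np.percentile(table.values, 75, axis=0) - np.percentile(
        table.values, 25, axis=0)
    order = np.argsort(iqr, kind="stable")  # stable: ties by feature order
    drop = set(order[:k].tolist())
    keep = [j for j in range(n) if j not in drop]
    logger.info("IQR filter removed %d of %d features (%.0f%%)",
                k, n, 100 * k / n if n else 0)
    return table._with("filtered", table.values[:, keep],
                       [table.feature_labels[j] for j in keep])


def sum_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample's features by that sample's total; rows sum to 1.

    Puts samples on a common scale, correcting e.g. for differences in
    tissue mass between samples.
    """
    table._check_step("normalized")
    if table.values.min() < 0:
        raise ValueError("sum normalization requires non-negative values")
    totals = table.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(
            f"sample {table.samples[zero[0]]!r} has zero total intensity")
    return table._with("normalized", table.values / totals[:, None])


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Apply ``x -> log2(x + c)`` with pseudocount c = min positive value / 2.

    The pseudocount guards the zeros that filtered or synthetic tables can
    contain; being constant across the table, it preserves the ordering of
    values everywhere.
    """
    table._check_step("log2")
    if "normalized" not in table.provenance:
        raise PreprocessingOrderError("log2_transform expects a sum-normalized table")
    if table.values.min() < 0:
        raise ValueError("log2 transform requires non-negative values")
    positive = table.values[table.values > 0]
    if len(positive) == 0:
        raise ValueError("table has no positive values to transform")
    c = positive.min() / 2.0
    return table._with("log2", np.log2(table.values + c))


def autoscale(table: FeatureTable) -> FeatureTable:
    """Standardize each feature to mean 0, sd 1 (n-1 denominator).

    Constant features cannot be scaled; they are set to all-zero with a
    logged warning.
    """
    table._check_step("autoscaled")
    if "log2" not in table.provenance:
        raise PreprocessingOrderError("autoscale expects a log2-transformed table")
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant features set to zero during autoscaling",
                       int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    scaled = (table.values - mean) / sd_safe
    scaled[:, constant] = 0.0
    return table._with("autoscaled", scaled)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Principal-component scores, loadings and explained variance."""

    scores: np.ndarray                      # samples x components
    loadings: np.ndarray                    # features x components
    explained_variance_fraction: np.ndarray
    samples: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    feature_labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(table: FeatureTable, n_components: int = 2) -> PcaResult:
    """PCA by SVD of the (column-centered) preprocessed table.

    Sign convention: each component's largest-|loading| feature is made
    positive, so results are deterministic across SVD implementations.
    Centering is a no-op on an autoscaled table.
    """
    n, p = table.values.shape
    max_comp = min(n - 1, p) if n > 1 else 1
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for a {n}x{p} table")
    X = table.values - table.values.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    for j in range(n_components):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=frac[:n_components],
                     samples=list(table.samples), groups=list(table.groups),
                     feature_labels=list(table.feature_labels))


def top_loadings(pca_result: PcaResult, component: int = 0, k: int = 30,
                 normalized_table: Optional[FeatureTable] = None) -> pd.DataFrame:
    """The k features with the largest |loading| on one component, ranked.

    When a sum-normalized table is supplied, each feature's direction
    (up/down in the first group) is assigned from the sign of the group-mean
    difference of its normalized values.
    """
    if not (0 <= component < pca_result.n_components):
        raise ValueError(f"component {component} does not exist")
    load = pca_result.loadings[:, component]
    order = np.argsort(-np.abs(load), kind="stable")[:k]
    df = pd.DataFrame({
        "feature": [pca_result.feature_labels[i] for i in order],
        "loading": load[order],
        "abs_loading": np.abs(load[order]),
        "rank": np.arange(1, len(order) + 1),
    })
    if normalized_table is not None:
        gnames = normalized_table.group_names()
        if len(gnames) == 2:
            ga = np.array(normalized_table.groups) == gnames[0]
            label_ix = {f: i for i, f in
                        enumerate(normalized_table.feature_labels)}
            direction = []
            for f in df["feature"]:
                j = label_ix.get(f)
                if j is None:
                    direction.append("unknown")
                    continue
                diff = (normalized_table.values[ga, j].mean()
                        - normalized_table.values[~ga, j].mean())
                direction.append(f"up_in_{gnames[0]}" if diff > 0
                                 else f"down_in_{gnames[0]}")
            df["direction"] = direction
    return df


# ---------------------------------------------------------------------------
# Volcano
# ---------------------------------------------------------------------------


@dataclass
class VolcanoResult:
    """Per-feature fold change, Welch p-value and significance flags."""

    feature_labels: list[str]
    fold_change: np.ndarray
    log2_fc: np.ndarray
    p_value: np.ndarray
    significant_up: np.ndarray
    significant_down: np.ndarray
    fc_undefined: np.ndarray
    fc_thresh: float
    p_thresh: float
    numerator: str
    denominator: str

    @property
    def significant(self) -> np.ndarray:
        return self.significant_up | self.significant_down

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_labels,
            "fold_change": self.fold_change,
            "log2_fc": self.log2_fc,
            "p_value": self.p_value,
            "significant_up": self.significant_up,
            "significant_down": self.significant_down,
        })


def welch_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch (unequal-variance) t-test p-values, column-wise.

    Columns where both groups are constant get p = 1 when the means agree
    and p = 0 otherwise (a deterministic difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def volcano(normalized_table: FeatureTable, transformed_table: FeatureTable,
            fc_thresh: float = DEFAULT_FC_THRESHOLD,
            p_thresh: float = DEFAULT_P_THRESHOLD,
            numerator: Optional[str] = None,
            fdr: bool = False) -> VolcanoResult:
    """Two-group volcano analysis.

    Fold change is the ratio of group means on the sum-normalized (pre-log)
    table, ``numerator`` group over the other (default: first group label
    encountered).  The p-value is a two-sided Welch t-test on the
    transformed table.  A feature is significantly up when
    ``FC >= fc_thresh`` and ``p < p_thresh``, significantly down when
    ``FC <= 1/fc_thresh`` and ``p < p_thresh``.  With ``fdr=True`` the
    p-values are Benjamini-Hochberg adjusted before thresholding (off by
    default: the conventional readout is raw p against a stringent
    threshold).
    """
    if "normalized" not in normalized_table.provenance:
        raise ValueError("fold changes require the sum-normalized table")
    if "log2" in normalized_table.provenance:
        raise ValueError("fold changes must be computed on the pre-log table")
    if "log2" not in transformed_table.provenance:
        raise ValueError("the t-test requires the log2-transformed table")
    if normalized_table.feature_labels != transformed_table.feature_labels:
        raise ValueError("the two tables must describe the same features")
    if normalized_table.groups != transformed_table.groups:
        raise ValueError("the two tables must carry the same group labels")
    gnames = normalized_table.group_names()
    if len(gnames) != 2:
        raise ValueError(f"volcano requires exactly two groups, got {gnames}")
    if numerator is None:
        numerator = gnames[0]
    if numerator not in gnames:
        raise ValueError(f"numerator {numerator!r} is not a group label")
    denominator = gnames[1] if numerator == gnames[0] else gnames[0]
    ga = np.array(normalized_table.groups) == numerator
    if ga.sum() < 2 or (~ga).sum() < 2:
        raise ValueError("volcano requires at least two samples per group")

    mean_a = normalized_table.values[ga].mean(axis=0)
    mean_b = normalized_table.values[~ga].mean(axis=0)
    fc_undefined = mean_b == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(fc_undefined,
                      np.where(mean_a > 0, np.inf, np.nan),
                      mean_a / np.where(fc_undefined, 1.0, mean_b))
        log2_fc = np.log2(fc)
    if fc_undefined.any():
        logger.warning("%d features have a zero denominator group mean; "
                       "fold change reported as inf", int(fc_undefined.sum()))

    p = welch_ttest(transformed_table.values[ga], transformed_table.values[~ga])
    p_eff = _bh_adjust(p) if fdr else p
    with np.errstate(invalid="ignore"):
        sig_up = (fc >= fc_thresh) & (p_eff < p_thresh)
        sig_down = (fc <= 1.0 / fc_thresh) & (p_eff < p_thresh)
    sig_up &= ~np.isnan(fc)
    sig_down &= ~np.isnan(fc)
    return VolcanoResult(
        feature_labels=list(normalized_table.feature_labels),
        fold_change=fc, log2_fc=log2_fc, p_value=p,
        significant_up=sig_up, significant_down=sig_down,
        fc_undefined=fc_undefined, fc_thresh=fc_thresh, p_thresh=p_thresh,
        numerator=numerator, denominator=denominator)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class HcaResult:
    """Agglomerative clustering on 1 - Pearson correlation, Ward's linkage.

    ``linkage`` is a scipy-format (n-1) x 4 merge table whose heights are the
    Ward criterion applied directly (Lance-Williams recurrence) to the
    unsquared dissimilarities.
    """

    linkage: np.ndarray
    items: list[str]
    axis: str
    distance: str = "1 - pearson"
    method: str = "ward (unsquared dissimilarities)"

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the tree into k clusters."""
        return hierarchy.fcluster(self._scipy_linkage(), t=k,
                                  criterion="maxclust")

    def _scipy_linkage(self) -> np.ndarray:
        z = self.linkage.copy()
        z[:, 2] = np.sqrt(np.maximum(z[:, 2], 0.0))  # back to scipy's scale
        return z


def correlation_dissimilarity(profiles: np.ndarray,
                              items: Sequence[str]) -> np.ndarray:
    """Pairwise d = 1 - Pearson correlation between the rows of ``profiles``."""
    sd = profiles.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if len(flat):
        raise ValueError(
            f"item {items[flat[0]]!r} has zero variance; its Pearson "
            "correlation is undefined")
    corr = np.corrcoef(profiles)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)  # clip float noise below zero


def hca(table: FeatureTable, axis: str = "samples") -> HcaResult:
    """Hierarchical cluster analysis of samples or features.

    Dissimilarity is 1 - Pearson correlation between item profiles; merging
    follows Ward's criterion applied to the unsquared dissimilarities (the
    classic Lance-Williams "ward.D" recurrence), so merge heights are
    reproducible across implementations.  Internally scipy's Ward linkage is
    run on the square roots of the dissimilarities and the reported heights
    squared back, which is algebraically the same recurrence.
    """
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    if axis == "samples":
        profiles, items = table.values, list(table.samples)
    else:
        profiles, items = table.values.T, list(table.feature_labels)
    if profiles.shape[0] < 2:
        raise ValueError(f"need at least two {axis} to cluster")
    d = correlation_dissimilarity(profiles, items)
    z = hierarchy.linkage(squareform(np.sqrt(d), checks=False), method="ward")
    z[:, 2] = z[:, 2] ** 2
    return HcaResult(linkage=z, items=items, axis=axis)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class GroupAnalysisResult:
    """All artifacts of a two-group bin analysis."""

    filtered: FeatureTable
    normalized: FeatureTable
    transformed: FeatureTable
    scaled: FeatureTable
    pca: PcaResult
    volcano: Optional[VolcanoResult]
    hca_samples: HcaResult
    manifest: dict[str, str] = field(default_factory=dict)


def preprocess(table: FeatureTable, apply_filter: bool = True) -> tuple[
        FeatureTable, FeatureTable, FeatureTable, FeatureTable]:
    """Run the fixed chain filter -> normalize -> log2 -> autoscale.

    Returns the four successive tables (the first equals the input when
    ``apply_filter`` is false).
    """
    filtered = iqr_filter(table) if apply_filter else table
    normalized = sum_normalize(filtered)
    transformed = log2_transform(normalized)
    scaled = autoscale(transformed)
    return filtered, normalized, transformed, scaled


def run_group_analysis(matrix: BinMatrix, out_dir: Optional[str] = None,
                       fc_thresh: float = DEFAULT_FC_THRESHOLD,
                       p_thresh: float = DEFAULT_P_THRESHOLD,
                       n_components: int = 2,
                       apply_filter: bool = True,
                       make_plots: bool = True) -> GroupAnalysisResult:
    """The automatic outputs of a group bin analysis.

    Preprocesses the matrix, then computes PCA, the volcano analysis and a
    sample dendrogram.  With ``out_dir`` set, writes the filtered table,
    PCA scores and loadings, volcano table and linkage as CSV, plus score
    plot, volcano plot and dendrogram as PNG; the returned manifest maps
    artifact names to paths.  A single-group matrix skips the volcano with a
    logged notice; PCA and HCA still run.
    """
    table = FeatureTable.from_bin_matrix(matrix)
    filtered, normalized, transformed, scaled = preprocess(
        table, apply_filter=apply_filter)
    n_comp = min(n_components, max(1, min(scaled.n_samples - 1,
                                          scaled.n_features)))
    pca_res = pca(scaled, n_components=n_comp)
    gnames = table.group_names()
    volcano_res: Optional[VolcanoResult] = None
    if len(gnames) == 2 and min(
            sum(1 for g in table.groups if g == name) for name in gnames) >= 2:
        volcano_res = volcano(normalized, scaled, fc_thresh=fc_thresh,
                              p_thresh=p_thresh)
    else:
        logger.info("volcano analysis skipped: requires exactly two groups "
                    "with at least two samples each (got %s)", gnames)
    hca_res = hca(scaled, axis="samples")

    manifest: dict[str, str] = {}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

        def _csv(name: str, df: pd.DataFrame) -> None:
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=False, lineterminator="\n")
            manifest[name] = path

        _csv("filtered_table.csv", filtered.to_dataframe())
        scores_df = pd.DataFrame(
            pca_res.scores,
            columns=[f"PC{j + 1}" for j in range(pca_res.n_components)])
        scores_df.insert(0, "group", pca_res.groups)
        scores_df.insert(0, "sample", pca_res.samples)
        _csv("pca_scores.csv", scores_df)
        load_df = pd.DataFrame(
            pca_res.loadings,
            columns=[f"PC{j + 1}" for j in range(pca_res.n_components)])
        load_df.insert(0, "feature", pca_res.feature_labels)
        _csv("pca_loadings.csv", load_df)
        if volcano_res is not None:
            _csv("volcano.csv", volcano_res.to_dataframe())
        link_df = pd.DataFrame(hca_res.linkage,
                               columns=["left", "right", "height", "size"])
        _csv("hca_linkage.csv", link_df)

        if make_plots:
            from . import plotting

            path = os.path.join(out_dir, "pca_scores.png")
            plotting.plot_pca_scores(pca_res, path)
            manifest["pca_scores.png"] = path
            if volcano_res is not None:
                path = os.path.join(out_dir, "volcano.png")
                plotting.plot_volcano(volcano_res, path)
                manifest["volcano.png"] = path
            path = os.path.join(out_dir, "dendrogram.png")
            plotting.plot_dendrogram(hca_res, path)
            manifest["dendrogram.png"] = path

    return GroupAnalysisResult(filtered=filtered, normalized=normalized,
                               transformed=transformed, scaled=scaled,
                               pca=pca_res, volcano=volcano_res,
                               hca_samples=hca_res, manifest=manifest)
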