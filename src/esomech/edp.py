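"""Statistical workflow for the paired expression panel.

Mirrors the standard analysis of a paired diagnostic-panel experiment:
a call-rate filter to drop poorly detected genes, two-way hierarchical
clustering (Euclidean distance, Ward linkage), PCA of the top three
variance components, per-gene paired t-tests with Benjamini-Hochberg
step-up adjustment, fold-change set logic (Venn of genes dysregulated
beyond a threshold), and the volcano table behind the usual
log2FC / -log10 adjusted-p plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .panel import PanelMatrix

__all__ = [
    "FilteredPanel",
    "ClusterResult",
    "PCAResult",
    "DEResult",
    "VennResult",
    "call_rate_filter",
    "hierarchical_cluster",
    "pca_top3",
    "paired_de",
    "fold_change_sets",
    "volcano_table",
]


@dataclass
class FilteredPanel:
    panel: PanelMatrix
    retained_genes: list
    threshold: float

    @property
    def values(self) -> pd.DataFrame:
        return self.panel.values.loc[self.retained_genes]

    @property
    def call_flags(self) -> pd.DataFrame:
        return self.panel.call_flags.loc[self.retained_genes]


def call_rate_filter(panel: PanelMatrix, threshold: float = 0.5) -> FilteredPanel:
    """Retain genes whose fraction of detected calls across samples is at
    least ``threshold`` (a 50% call-rate filter by default)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rates = panel.call_flags.mean(axis=1)
    retained = list(rates.index[rates >= threshold])
    if not retained:
        warnings.warn("call-rate filter retained no genes")
    return FilteredPanel(panel=panel, retained_genes=retained, threshold=threshold)


@dataclass
class ClusterResult:
    linkage: np.ndarray      # scipy linkage matrix (merge tree with heights)
    order: list              # leaf labels in dendrogram order
    labels: list


def hierarchical_cluster(matrix: pd.DataFrame, axis: int = 0) -> ClusterResult:
    """Agglomerative clustering with Euclidean distance and Ward linkage.

    ``axis=0`` clusters rows (genes), ``axis=1`` columns (samples); calling
    with both axes gives the two-way clustering used for panel heat maps.
    Deterministic for a fixed input order.
    """
    X = matrix.to_numpy(float) if axis == 0 else matrix.to_numpy(float).T
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, order=order, labels=labels)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame    # samples x components
    variance_fractions: np.ndarray
    n_components: int
    rank_deficient: bool = False


def pca_top3(matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Per-sample coordinates on the top principal components of the
    samples x genes matrix (columns of ``matrix`` are samples).

    Components are ordered by explained variance. The sign convention fixes
    each component so that its largest-magnitude gene loading is positive,
    making coordinates reproducible across runs.
    """
    X = matrix.to_numpy(float).T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < 4:
        raise ValueError("need >= 4 samples for a 3-component PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    n_comp = min(n_components, rank)
    rank_deficient = n_comp < n_components
    total_var = float(np.sum(s**2))
    coords = np.empty((n_samples, n_comp))
    for j in range(n_comp):
        sign = 1.0 if Vt[j, np.argmax(np.abs(Vt[j]))] >= 0 else -1.0
        coords[:, j] = sign * U[:, j] * s[j]
    var_frac = (s[:n_comp] ** 2) / total_var if total_var > 0 else np.zeros(n_comp)
    return PCAResult(
        coordinates=pd.DataFrame(
            coords, index=matrix.columns, columns=[f"PC{j + 1}" for j in range(n_comp)]
        ),
        variance_fractions=var_frac,
        n_components=n_comp,
        rank_deficient=rank_deficient,
    )


@dataclass
class DEResult:
    """Per-gene paired differential-expression table.

    ``table`` columns: mean_log2_diff (treated - vehicle), p_raw (paired
    two-tailed t), p_adj (Benjamini-Hochberg), fold_change (2**mean_log2_diff),
    n_pairs. Genes with fewer than two complete pairs carry NaN statistics
    and are excluded from the BH adjustment.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def significant(self) -> list:
        sig = self.table["p_adj"] < self.alpha
        return list(self.table.index[sig.fillna(False)])


def _paired_differences(
    panel_values: pd.DataFrame,
    call_flags: Optional[pd.DataFrame],
    samples: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene treated-minus-vehicle log2 differences with undetected
    entries treated as missing (the pair is dropped for that gene)."""
    donors = list(dict.fromkeys(samples["donor_id"]))
    by = samples.set_index(["donor_id", "arm"])["sample_id"]
    veh_cols = [by[(d, "vehicle")] for d in donors]
    trt_cols = [by[(d, "treated")] for d in donors]
    diffs = panel_values[trt_cols].to_numpy(float) - panel_values[veh_cols].to_numpy(float)
    if call_flags is not None:
        ok = call_flags[trt_cols].to_numpy(bool) & call_flags[veh_cols].to_numpy(bool)
    else:
        ok = np.ones_like(diffs, dtype=bool)
    return diffs, ok


def paired_de(
    panel: Union[PanelMatrix, FilteredPanel],
    alpha: float = 0.05,
    use_call_flags: bool = True,
) -> DEResult:
    """Paired two-tailed t-test per gene on log2 values (treated vs vehicle
    within donor), BH step-up adjustment across testable genes.

    Donors missing either arm's detection call for a gene are dropped for
    that gene; genes left with < 2 complete pairs are reported with NaN
    statistics. Raises if the design has < 2 complete donor pairs overall.
    """
    if isinstance(panel, FilteredPanel):
        values, flags, samples = panel.values, panel.call_flags, panel.panel.samples
    else:
        values, flags, samples = panel.values, panel.call_flags, panel.samples
    if len(set(samples["donor_id"])) < 2:
        raise ValueError("paired analysis needs >= 2 donor pairs")
    diffs, ok = _paired_differences(values, flags if use_call_flags else None, samples)

    n_genes = diffs.shape[0]
    mean_d = np.full(n_genes, np.nan)
    p_raw = np.full(n_genes, np.nan)
    n_pairs = ok.sum(axis=1)
    complete = ok.all(axis=1)
    if np.any(complete) and diffs.shape[1] >= 2:
        d = diffs[complete]
        mean_d[complete] = d.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_1samp(d, 0.0, axis=1).pvalue
        # zero-variance rows: p undefined; exact-equality convention
        degenerate = np.ptp(d, axis=1) == 0
        p[degenerate] = np.where(d[degenerate, 0] == 0, 1.0, 0.0)
        p_raw[complete] = p
    for i in np.flatnonzero(~complete):
        dd = diffs[i, ok[i]]
        if dd.size < 2:
            continue
        mean_d[i] = dd.mean()
        if np.ptp(dd) == 0:
            p_raw[i] = 1.0 if dd[0] == 0 else 0.0
        else:
            p_raw[i] = stats.ttest_1samp(dd, 0.0).pvalue
    p_adj = np.full(n_genes, np.nan)
    testable = ~np.isnan(p_raw)
    if np.any(testable):
        p_adj[testable] = multipletests(p_raw[testable], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_log2_diff": mean_d,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "fold_change": np.power(2.0, mean_d),
            "n_pairs": n_pairs,
        },
        index=values.index,
    )
    return DEResult(table=table, alpha=alpha)


def _fold_change_magnitudes(de: Union[DEResult, Mapping[str, float]]) -> pd.Series:
    if isinstance(de, DEResult):
        fc = de.table["fold_change"]
    else:
        fc = pd.Series(dict(de), dtype=float)
    with np.errstate(divide="ignore"):
        return pd.Series(np.maximum(fc, 1.0 / fc), index=fc.index)


@dataclass
class VennResult:
    only_a: list
    only_b: list
    both: list
    threshold: float

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.only_b), len(self.both))


def fold_change_sets(
    de_a: Union[DEResult, Mapping[str, float]],
    de_b: Union[DEResult, Mapping[str, float]],
    threshold: float = 5.0,
) -> VennResult:
    """Venn logic on genes dysregulated beyond a fold-change threshold.

    A gene qualifies when its linear fold-change magnitude (max(FC, 1/FC))
    is strictly greater than the threshold (>5-fold by default; exactly
    5.0 is excluded)."""
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    mag_a = _fold_change_magnitudes(de_a)
    mag_b = _fold_change_magnitudes(de_b)
    set_a = set(mag_a.index[mag_a > threshold])
    set_b = set(mag_b.index[mag_b > threshold])
    return VennResult(
        only_a=sorted(set_a - set_b),
        only_b=sorted(set_b - set_a),
        both=sorted(set_a & set_b),
        threshold=threshold,
    )


def volcano_table(de: DEResult, fc_threshold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene (log2 fold change, -log10 adjusted p, significance flag);
    flagged iff adjusted p < alpha and fold-change magnitude > threshold."""
    mag = _fold_change_magnitudes(de)
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(de.table["p_adj"])
    return pd.DataFrame(
        {
            "log2_fold_change": de.table["mean_log2_diff"],
            "neg_log10_p_adj": neg_log_p,
            "significant": (de.table["p_adj"] < alpha) & (mag > fc_threshold),
        },
        index=de.table.index,
    )
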