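"""Pooled affected-vs-unaffected ("dual") methylation comparison.

All affected samples (children plus affected parents) are pooled into one
group and the unaffected parents into the other, as if they were two
phenotype cohorts.  The arm provides:

* unsupervised hierarchical clustering of the highest-variance CpGs (probe
  and sample leaf orderings for a heatmap);
* a per-probe two-sample t-test (Welch by default) with Benjamini-Hochberg
  FDR correction across all tested probes;
* per-gene group mean betas restricted to CpG-island probes;
* the piecewise-linear rescaling of mean betas onto [-1, 1] used for
  dual-color pathway annotation: betas in [0, 0.5] map to [-1, 0] and betas
  in [0.5, 1] map to [0, 1], each piece through the standard range map
  ``y = C + (x - A)(D - C)/(B - A)``.  Both pieces coincide with the single
  affine map ``y = 2x - 1``.

A gene whose two rescaled group means differ by more than a tolerance is
flagged *dual* — the machine-readable equivalent of a two-color gene box in
a rendered pathway diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import TrioDesign

__all__ = [
    "GroupDesign",
    "RescaleSpec",
    "rescale_beta",
    "gene_group_means",
    "dual_color_table",
    "sitewise_ttest",
    "ClusteringResult",
    "top_variance_clustering",
]

AFFECTED_POOL = "affected_pool"
UNAFFECTED_POOL = "unaffected_pool"


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of sample ids to the affected and unaffected pools."""

    affected: tuple[str, ...]
    unaffected: tuple[str, ...]

    def __post_init__(self):
        if not self.affected or not self.unaffected:
            raise ValueError("both pools must be non-empty")
        if set(self.affected) & set(self.unaffected):
            raise ValueError("a sample cannot belong to both pools")

    @classmethod
    def from_trios(cls, trios: Sequence[TrioDesign]) -> "GroupDesign":
        affected = tuple(
            s for t in trios for s in (t.child, t.affected_parent)
        )
        unaffected = tuple(t.unaffected_parent for t in trios)
        return cls(affected, unaffected)

    @property
    def mapping(self) -> dict[str, str]:
        out = {s: AFFECTED_POOL for s in self.affected}
        out.update({s: UNAFFECTED_POOL for s in self.unaffected})
        return out


@dataclass(frozen=True)
class RescaleSpec:
    """Linear range map ``y = C + (x - A)(D - C)/(B - A)`` from [A, B] onto
    [C, D]."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.b > self.a and self.d > self.c):
            raise ValueError("rescale spec requires B > A and D > C")

    def apply(self, x):
        x_arr = np.asarray(x, dtype=float)
        y = self.c + (x_arr - self.a) * (self.d - self.c) / (self.b - self.a)
        return float(y) if y.ndim == 0 else y


_LOWER = RescaleSpec(0.0, 0.5, -1.0, 0.0)
_UPPER = RescaleSpec(0.5, 1.0, 0.0, 1.0)


def rescale_beta(x):
    """Piecewise rescaling of beta values onto [-1, 1].

    [0, 0.5] maps onto [-1, 0] and [0.5, 1] onto [0, 1]; the two pieces
    agree at 0.5 and jointly equal the affine map ``2x - 1``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0) | (x_arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    y = np.where(x_arr < 0.5, _LOWER.apply(x_arr), _UPPER.apply(x_arr))
    return float(y) if y.ndim == 0 else y


def gene_group_means(
    bm: pd.DataFrame, ann: pd.DataFrame, design: GroupDesign
) -> pd.DataFrame:
    """Per-gene mean beta of each pool over CpG-island probes only.

    A probe annotated to several genes contributes to each of them; genes
    without any island probe in the matrix are absent from the result.
    Missing measurements are ignored in the means.  Invariant to probe and
    sample order.

    Returns a DataFrame indexed by gene with columns ``mean_affected``,
    ``mean_unaffected`` and ``n_probes`` (supporting island probes).
    """
    for sample in (*design.affected, *design.unaffected):
        if sample not in bm.columns:
            raise KeyError(f"sample {sample!r} not in beta matrix")
    island = ann.index[ann["island_relation"] == "Island"]
    island = island.intersection(bm.index)
    gene_probes: dict[str, list[str]] = {}
    for probe in island:
        for gene in ann.at[probe, "genes"]:
            gene_probes.setdefault(gene, []).append(probe)
    rows = []
    for gene in sorted(gene_probes):
        probes = gene_probes[gene]
        aff = bm.loc[probes, list(design.affected)].to_numpy(dtype=float)
        una = bm.loc[probes, list(design.unaffected)].to_numpy(dtype=float)
        rows.append(
            (gene, float(np.nanmean(aff)), float(np.nanmean(una)), len(probes))
        )
    out = pd.DataFrame(
        rows, columns=["gene", "mean_affected", "mean_unaffected", "n_probes"]
    ).set_index("gene")
    return out


def dual_color_table(
    means: pd.DataFrame, pathway_genes: Iterable[str], tol: float = 0.05
) -> pd.DataFrame:
    """Rescaled group means for the pathway genes present in *means*.

    ``dual`` is set when the two rescaled means differ by more than ``tol``
    on the [-1, 1] axis — the gene would be rendered with two colors.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    genes = sorted(set(pathway_genes) & set(means.index))
    sub = means.loc[genes]
    scaled_a = rescale_beta(sub["mean_affected"].to_numpy(dtype=float))
    scaled_u = rescale_beta(sub["mean_unaffected"].to_numpy(dtype=float))
    scaled_a = np.atleast_1d(scaled_a)
    scaled_u = np.atleast_1d(scaled_u)
    return pd.DataFrame(
        {
            "mean_affected": sub["mean_affected"].to_numpy(),
            "mean_unaffected": sub["mean_unaffected"].to_numpy(),
            "scaled_affected": scaled_a,
            "scaled_unaffected": scaled_u,
            "dual": np.abs(scaled_a - scaled_u) > tol,
        },
        index=pd.Index(genes, name="gene"),
    )


def sitewise_ttest(
    bm: pd.DataFrame, design: GroupDesign, equal_var: bool = False
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-probe two-sample t-test between the pools, with BH-FDR.

    Welch's unequal-variance statistic is used by default.  Probes with
    fewer than two non-missing values in either pool are skipped and listed
    with a reason.  Probes where both pools are exactly constant get t = 0,
    p = 1 when the means agree and p = 0 otherwise (the test is degenerate
    there).  BH adjustment runs across all tested probes.

    Returns ``(results, skipped)`` where results is indexed by probe id with
    columns ``t``, ``raw_p`` and ``fdr_p``.
    """
    aff = bm[list(design.affected)].to_numpy(dtype=float)
    una = bm[list(design.unaffected)].to_numpy(dtype=float)
    n_aff = np.sum(~np.isnan(aff), axis=1)
    n_una = np.sum(~np.isnan(una), axis=1)
    testable = (n_aff >= 2) & (n_una >= 2)
    skipped = [
        (probe, "fewer_than_two_values_per_group")
        for probe in bm.index[~testable]
    ]
    aff_t, una_t = aff[testable], una[testable]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, raw_p = stats.ttest_ind(
            aff_t, una_t, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    raw_p = np.asarray(raw_p, dtype=float)
    # degenerate zero-variance probes: scipy reports NaN
    var_a = np.nanvar(aff_t, axis=1)
    var_u = np.nanvar(una_t, axis=1)
    mean_a = np.nanmean(aff_t, axis=1)
    mean_u = np.nanmean(una_t, axis=1)
    flat = (var_a == 0) & (var_u == 0)
    same = flat & (mean_a == mean_u)
    diff = flat & (mean_a != mean_u)
    t_stat[same] = 0.0
    raw_p[same] = 1.0
    t_stat[diff] = np.where(mean_a[diff] > mean_u[diff], np.inf, -np.inf)
    raw_p[diff] = 0.0
    if raw_p.size:
        fdr_p = multipletests(raw_p, method="fdr_bh")[1]
    else:
        fdr_p = raw_p
    results = pd.DataFrame(
        {"t": t_stat, "raw_p": raw_p, "fdr_p": fdr_p},
        index=pd.Index(bm.index[testable], name="probe_id"),
    )
    return results, skipped


@dataclass(frozen=True)
class ClusteringResult:
    """Leaf orderings of the variance-ranked heatmap clustering."""

    selected_probes: tuple[str, ...]
    probe_order: tuple[str, ...]
    sample_order: tuple[str, ...]


def top_variance_clustering(
    bm: pd.DataFrame,
    k: int,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of the k highest-variance probes and of the
    samples.

    Probes are ranked by cross-sample variance (sample variance, ddof=1);
    ties — e.g. a constant matrix — are broken by probe id.  Probes with any
    missing value are excluded before ranking.  Average linkage on Euclidean
    distances by default; leaf orderings of both dendrograms are returned.
    """
    complete = bm.dropna(axis=0)
    if k > complete.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {complete.shape[0]} probes with complete data"
        )
    if k < 1:
        raise ValueError("k must be at least 1")
    variances = complete.var(axis=1, ddof=1)
    ranked = sorted(complete.index, key=lambda p: (-variances[p], p))
    selected = ranked[:k]
    sub = complete.loc[selected]
    values = sub.to_numpy(dtype=float)
    if k == 1:
        probe_order = tuple(selected)
    else:
        link = hierarchy.linkage(values, method=linkage_method, metric=metric)
        probe_order = tuple(sub.index[i] for i in hierarchy.leaves_list(link))
    if sub.shape[1] == 1:
        sample_order = tuple(sub.columns)
    else:
        link_s = hierarchy.linkage(values.T, method=linkage_method, metric=metric)
        sample_order = tuple(sub.columns[i] for i in hierarchy.leaves_list(link_s))
    return ClusteringResult(tuple(selected), probe_order, sample_order)
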