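"""Active-subnetwork search and pathway enrichment on a PPI network.

Given per-gene p-values, each gene receives the standard-normal upper-tail
quantile z = Phi^-1(1 - p).  A connected subgraph ("active subnetwork") is
scored by the aggregate z_A = (sum z_i) / sqrt(k) over its k members, and
subnetworks are grown by a deterministic greedy seed-and-extend: from each
of the top-scoring seed genes, repeatedly add the neighboring node that
maximizes z_A, as long as z_A does not decrease and a size cap is respected.
Accepted subnetworks may overlap each other by at most a configurable
fraction (of the smaller set; default 50%).

Each accepted subnetwork is then tested against every pathway gene set with
a two-sided (enrichment/depletion) hypergeometric test — the minimum-
likelihood two-sided p, computed in exact integer arithmetic — and the
per-subnetwork p-values are Bonferroni-corrected.  A pathway significant in
at least one subnetwork enters the final list once, through its most
significant occurrence.  Greedy search is a reproducible, desk-scale
stand-in for the simulated-annealing module searches used by the original
active-modules literature; it is not claimed optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubNetwork",
    "PathwayResult",
    "PathwayCollection",
    "CrossTrioSummary",
    "gene_z",
    "aggregate_z",
    "overlap_fraction",
    "find_active_subnetworks",
    "hypergeom_two_sided",
    "bonferroni_adjust",
    "test_pathways",
    "collect_significant_pathways",
    "rank_pathways",
    "summarize_across_trios",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_universe",
    "write_universe",
    "write_pathway_results",
]

ENRICHED = "enriched"
DEPLETED = "depleted"

#: p-value substituted for network genes without a score (just below 1, so
#: they join a subnetwork only when topology demands it).
UNSCORED_P = 1.0 - 1e-9


def gene_z(p: float) -> float:
    """Standard-normal upper-tail quantile z = Phi^-1(1 - p), p in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p-value must lie strictly in (0, 1): {p}")
    return float(stats.norm.isf(p))


def aggregate_z(zs: Sequence[float]) -> float:
    """Aggregate subnetwork score z_A = (sum z_i) / sqrt(k)."""
    k = len(zs)
    if k == 0:
        raise ValueError("cannot aggregate an empty z-score list")
    return float(sum(zs) / math.sqrt(k))


def overlap_fraction(a: Iterable[str], b: Iterable[str]) -> float:
    """Overlap of two gene sets as a fraction of the smaller set."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap_fraction requires non-empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


@dataclass(frozen=True)
class SubNetwork:
    members: frozenset[str]
    z_a: float
    seed_gene: str

    def __len__(self) -> int:
        return len(self.members)


def find_active_subnetworks(
    net: nx.Graph,
    scores: Mapping[str, float],
    *,
    max_size: int = 50,
    n_subnetworks: int = 5,
    max_overlap: float = 0.5,
    n_seeds: int = 20,
) -> list[SubNetwork]:
    """Greedy seed-and-extend search for high-scoring connected subgraphs.

    Seeds are the ``n_seeds`` network genes with the highest z (ties by gene
    id).  From each seed, the neighbor that maximizes the new z_A is added
    while z_A does not decrease and the subnetwork stays within
    ``max_size`` members.  A grown candidate is accepted only if its overlap
    with every previously accepted subnetwork is at most ``max_overlap``;
    the search stops after ``n_subnetworks`` acceptances.  Fully
    deterministic.
    """
    if net.number_of_nodes() == 0:
        return []
    z = {
        node: gene_z(min(max(scores.get(node, UNSCORED_P), 1e-300), UNSCORED_P))
        for node in net.nodes
    }
    seeds = sorted(net.nodes, key=lambda g: (-z[g], g))[:n_seeds]
    accepted: list[SubNetwork] = []
    for seed in seeds:
        if len(accepted) >= n_subnetworks:
            break
        members = {seed}
        zsum = z[seed]
        z_a = zsum
        frontier = {n for n in net[seed] if n not in members}
        while len(members) < max_size and frontier:
            best = min(frontier, key=lambda g: (-z[g], g))
            new_z_a = (zsum + z[best]) / math.sqrt(len(members) + 1)
            if new_z_a < z_a:
                break
            members.add(best)
            zsum += z[best]
            z_a = new_z_a
            frontier.discard(best)
            frontier.update(n for n in net[best] if n not in members)
        candidate = frozenset(members)
        if all(
            overlap_fraction(candidate, sub.members) <= max_overlap
            for sub in accepted
        ):
            accepted.append(SubNetwork(candidate, z_a, seed))
    return accepted


def hypergeom_two_sided(
    overlap: int,
    subnet_size: int,
    pathway_size: int,
    background_size: int,
    method: str = "min_likelihood",
) -> tuple[float, str]:
    """Two-sided hypergeometric test of a subnetwork/pathway overlap.

    Draws ``subnet_size`` genes from a universe of ``background_size`` of
    which ``pathway_size`` belong to the pathway; ``overlap`` is the observed
    count.  The default two-sided p sums the point probabilities of every
    outcome no more likely than the observed one (minimum-likelihood
    method); ``method="doubling"`` doubles the smaller tail instead.  Point
    probabilities are compared in exact integer arithmetic, so the selection
    of outcomes is unambiguous.

    Returns ``(p, direction)`` with direction ``enriched`` when the overlap
    is at or above its expectation ``subnet_size * pathway_size /
    background_size`` and ``depleted`` otherwise.
    """
    n, K, N, k = subnet_size, pathway_size, background_size, overlap
    if min(n, K, N, k) < 0 or K > N or n > N:
        raise ValueError("inconsistent hypergeometric configuration")
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    if not k_min <= k <= k_max:
        raise ValueError(
            f"overlap {k} outside the hypergeometric support [{k_min}, {k_max}]"
        )
    weights = {
        j: math.comb(K, j) * math.comb(N - K, n - j) for j in range(k_min, k_max + 1)
    }
    total = math.comb(N, n)
    if method == "min_likelihood":
        mass = sum(w for w in weights.values() if w <= weights[k])
    elif method == "doubling":
        upper = sum(w for j, w in weights.items() if j >= k)
        lower = sum(w for j, w in weights.items() if j <= k)
        mass = min(total, 2 * min(upper, lower))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(Fraction(mass, total))
    direction = ENRICHED if Fraction(k) >= Fraction(n * K, N) else DEPLETED
    return min(p, 1.0), direction


def bonferroni_adjust(raw_ps: Sequence[float]) -> list[float]:
    """Bonferroni family-wise correction: ``min(1, m * p)`` pointwise."""
    if len(raw_ps) == 0:
        return []
    return list(multipletests(raw_ps, method="bonferroni")[1])


@dataclass(frozen=True)
class PathwayResult:
    pathway: str
    subnetwork_id: int
    overlap: int
    subnet_size: int
    pathway_size: int
    raw_p: float
    bonferroni_p: float
    direction: str


@dataclass(frozen=True)
class PathwayCollection:
    """Named pathway gene sets over an explicit background universe.

    Sets are intersected with the background on construction; sets that
    become empty are dropped.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def create(cls, sets: Mapping[str, Iterable[str]],
               background: Iterable[str]) -> "PathwayCollection":
        bg = frozenset(background)
        if not bg:
            raise ValueError("empty background universe")
        trimmed = {
            name: frozenset(genes) & bg for name, genes in sets.items()
        }
        return cls({n: g for n, g in trimmed.items() if g}, bg)


def test_pathways(
    subnetworks: Sequence[SubNetwork],
    pathways: PathwayCollection,
    method: str = "min_likelihood",
) -> list[PathwayResult]:
    """Hypergeometric test of every subnetwork against every pathway.

    The Bonferroni multiplicity m is the number of pathways tested per
    subnetwork.
    """
    results: list[PathwayResult] = []
    names = sorted(pathways.sets)
    N = len(pathways.background)
    for sub_id, sub in enumerate(subnetworks):
        members = sub.members & pathways.background
        raws = []
        metas = []
        for name in names:
            pset = pathways.sets[name]
            k = len(members & pset)
            p, direction = hypergeom_two_sided(
                k, len(members), len(pset), N, method=method
            )
            raws.append(p)
            metas.append((name, k, len(members), len(pset), direction))
        for (name, k, n_sub, n_path, direction), raw, bonf in zip(
            metas, raws, bonferroni_adjust(raws)
        ):
            results.append(
                PathwayResult(name, sub_id, k, n_sub, n_path, raw, float(bonf), direction)
            )
    return results


def _best_per_pathway(results: Iterable[PathwayResult]) -> dict[str, PathwayResult]:
    best: dict[str, PathwayResult] = {}
    for res in results:
        cur = best.get(res.pathway)
        if cur is None or (res.bonferroni_p, res.subnetwork_id) < (
            cur.bonferroni_p,
            cur.subnetwork_id,
        ):
            best[res.pathway] = res
    return best


def collect_significant_pathways(
    results: Iterable[PathwayResult], alpha: float = 0.05
) -> list[PathwayResult]:
    """Final pathway list: significant in at least one subnetwork, reported
    once through the minimum-Bonferroni occurrence (ties to the lower
    subnetwork id), sorted by ascending p."""
    best = _best_per_pathway(results)
    kept = [r for r in best.values() if r.bonferroni_p <= alpha]
    return sorted(kept, key=lambda r: (r.bonferroni_p, r.pathway))


def rank_pathways(results: Iterable[PathwayResult]) -> list[PathwayResult]:
    """All pathways through their best occurrence, sorted by ascending
    Bonferroni p (then raw p, then name); used for rank reporting."""
    best = _best_per_pathway(results)
    return sorted(best.values(), key=lambda r: (r.bonferroni_p, r.raw_p, r.pathway))


@dataclass(frozen=True)
class CrossTrioSummary:
    n_trios: int
    #: pathway -> number of trios in which it reached the final list
    counts: dict[str, int]
    #: family-pool top pathways by ascending Bonferroni p
    pool_top: tuple[PathwayResult, ...]


def summarize_across_trios(
    per_trio: Mapping[str, Sequence[PathwayResult]],
    pool_results: Sequence[PathwayResult] = (),
    top_n: int = 10,
) -> CrossTrioSummary:
    """Count, per pathway, the trios whose final list contains it, and keep
    the family pool's ``top_n`` most significant pathways."""
    counts: dict[str, int] = {}
    for trio_id in sorted(per_trio):
        for res in per_trio[trio_id]:
            counts[res.pathway] = counts.get(res.pathway, 0) + 1
    pool_top = tuple(
        sorted(pool_results, key=lambda r: (r.bonferroni_p, r.pathway))[:top_n]
    )
    return CrossTrioSummary(len(per_trio), counts, pool_top)


# ---------------------------------------------------------------------------
# plain-text interfaces


def read_edge_list(path) -> nx.Graph:
    """Two-column TSV edge list of gene symbols; self-loops and duplicate
    edges are dropped."""
    g = nx.Graph()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected two columns")
            a, b = parts[0], parts[1]
            if a != b:
                g.add_edge(a, b)
    return g


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT pathway file: name, description, then tab-separated member genes."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected name, description, genes")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate pathway {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{line_no}: pathway {name!r} has no genes")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_universe(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_universe(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(set(genes)):
            fh.write(gene + "\n")


def write_pathway_results(results: Sequence[PathwayResult], path) -> None:
    pd.DataFrame(
        [
            (
                r.pathway,
                r.subnetwork_id,
                r.overlap,
                r.subnet_size,
                r.pathway_size,
                r.raw_p,
                r.bonferroni_p,
                r.direction,
            )
            for r in results
        ],
        columns=[
            "pathway",
            "subnetwork_id",
            "overlap",
            "subnet_size",
            "pathway_size",
            "raw_p",
            "bonferroni_p",
            "direction",
        ],
    ).to_csv(path, sep="\t", index=False)
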