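"""Synthetic methylation-array cohorts with planted trio-differential events.

The generator produces every input the pipeline consumes — a probe
manifest, a trio beta matrix, a detection-p matrix, a protein-interaction
network and a pathway collection — together with a ledger of the planted
truth, so recovery can be scored exactly.

Background beta values come from a two-component Beta mixture (defaults
Beta(0.5, 10) and Beta(10, 0.5), weight 0.5), reproducing the strongly
bimodal marginal distribution of methylation arrays.  Two correlation
structures are available via ``component_mode``:

* ``"probe"`` (default) — the mixture component is drawn once per probe and
  shared by every sample, then each sample's beta is an independent draw
  from that component.  This mirrors real arrays, where a CpG's methylation
  state is largely probe-intrinsic and consistent across individuals;
  crossing from one extreme state to the other by chance is vanishingly
  rare (~2e-8 per probe and trio under the defaults), so trio-differential
  calls are essentially all planted.
* ``"sample"`` — every (probe, sample) beta is an independent mixture draw.
  Individuals are then uncorrelated at each CpG and the trio rule fires by
  chance at the analytic rate ``P(hyper)^2 P(hypo) + P(hypo)^2 P(hyper)``
  (~22% under the defaults); this mode exists to validate the chance-
  qualifier accounting, not to emulate real cohorts.

Planted events overwrite the affected pair with draws from a tight extreme
band and the unaffected parent with the opposite band, alternating the
direction, so every planted event satisfies the trio rule by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import SEX_CHROMOSOMES, TrioDesign
from .trio import AFFECTED_HYPER, AFFECTED_HYPO, HYPO_MAX, HYPER_MIN

__all__ = [
    "TrioSimParams",
    "NetworkSimParams",
    "PlantedTruth",
    "trio_designs",
    "simulate_manifest",
    "simulate_trio_betas",
    "choose_planted_genes",
    "probes_for_genes",
    "simulate_network_pathways",
    "simulate_detection_p",
    "analytic_chance_qualifier_rate",
    "write_truth",
]

PLANTED_PATHWAY_NAME = "PLANTED_PATHWAY"


@dataclass(frozen=True)
class TrioSimParams:
    """Study conditions for the simulated trio cohort.

    Defaults emulate the structure of a 13-trio, genome-wide 450K analysis
    at a desk-scale probe count: 13 trios (39 samples), 20,000 probes over
    2,000 genes, 0.2% of probes planted as trio-differential per trio, with
    the affected pair planted in [0.85, 1] and the unaffected parent in
    [0, 0.15] (or mirrored).
    """

    n_trios: int = 13
    n_probes: int = 20_000
    n_genes: int = 2_000
    planted_fraction: float = 0.002
    background_components: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, 10.0),
        (10.0, 0.5),
    )
    mixture_weight: float = 0.5
    affected_band: tuple[float, float] = (0.85, 1.0)
    unaffected_band: tuple[float, float] = (0.0, 0.15)
    component_mode: str = "probe"
    seed: int = 0

    def __post_init__(self):
        if self.n_trios < 1 or self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_trios, n_probes and n_genes must be positive")
        if not 0.0 <= self.planted_fraction < 1.0:
            raise ValueError("planted_fraction must lie in [0, 1)")
        if not 0.0 < self.mixture_weight < 1.0:
            raise ValueError("mixture_weight must lie in (0, 1)")
        lo, hi = self.affected_band
        if not HYPER_MIN <= lo < hi <= 1.0:
            raise ValueError(
                f"affected band must lie within the hyper interval "
                f"[{HYPER_MIN}, 1]: {self.affected_band}"
            )
        lo, hi = self.unaffected_band
        if not 0.0 <= lo < hi <= HYPO_MAX:
            raise ValueError(
                f"unaffected band must lie within the hypo interval "
                f"[0, {HYPO_MAX}]: {self.unaffected_band}"
            )
        if self.component_mode not in {"probe", "sample"}:
            raise ValueError("component_mode must be 'probe' or 'sample'")


@dataclass(frozen=True)
class NetworkSimParams:
    """Erdos-Renyi PPI background plus a clique module on the planted genes."""

    n_genes: int = 2_000
    edge_probability: float = 0.005
    planted_module_size: int = 30
    n_decoy_pathways: int = 49
    decoy_size_range: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.edge_probability < 1.0:
            raise ValueError("edge_probability must lie in [0, 1)")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module cannot exceed the gene universe")
        lo, hi = self.decoy_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("invalid decoy size range")

    @classmethod
    def for_universe(cls, n_genes: int, seed: int = 0, **overrides) -> "NetworkSimParams":
        """Defaults scaled down to a small gene universe."""
        module = overrides.pop(
            "planted_module_size", min(30, max(2, n_genes // 5))
        )
        hi = min(60, n_genes)
        lo = min(20, hi)
        return cls(
            n_genes=n_genes,
            planted_module_size=module,
            decoy_size_range=overrides.pop("decoy_size_range", (lo, hi)),
            seed=seed,
            **overrides,
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ledger of everything the generator planted.

    ``dm_events`` are the planted (probe, trio, direction) triples;
    ``background_qualifiers`` are the (probe, trio, direction) triples that
    satisfy the trio rule by chance, computed post hoc with a direct scan of
    the background draws.  Chance qualifiers are legitimate rule-level
    positives (the rule is deterministic) but are excluded from
    pathway-recovery scoring.
    """

    dm_events: frozenset[tuple[str, str, str]]
    background_qualifiers: frozenset[tuple[str, str, str]]
    planted_pathway: str | None = None
    planted_pathway_genes: frozenset[str] = frozenset()

    def with_pathway(self, name: str, genes: Iterable[str]) -> "PlantedTruth":
        return replace(self, planted_pathway=name,
                       planted_pathway_genes=frozenset(genes))


def trio_designs(n_trios: int) -> list[TrioDesign]:
    """Canonical sample-id layout of the simulated cohort."""
    return [
        TrioDesign(
            f"trio{i:02d}",
            f"trio{i:02d}_child",
            f"trio{i:02d}_aff_parent",
            f"trio{i:02d}_unaff_parent",
        )
        for i in range(1, n_trios + 1)
    ]


def simulate_manifest(
    n_probes: int,
    n_genes: int,
    promoter_fraction: float = 0.3,
    island_fraction: float = 0.3,
    multi_gene_fraction: float = 0.05,
    n_rs: int = 5,
    n_sex: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic 450K-style probe annotation table.

    Probes are assigned to genes round-robin; each probe-gene link draws a
    promoter region group (TSS200/TSS1500) with probability
    ``promoter_fraction`` and a gene-body-side group otherwise; the island
    relation is ``Island`` with probability ``island_fraction``.  A small
    number of ``rs``-named and X/Y probes are included to exercise the
    filters, and a fraction of probes carry a second gene link.
    """
    if n_genes < 1 and n_probes > 0:
        raise ValueError("cannot annotate probes without genes")
    for frac in (promoter_fraction, island_fraction, multi_gene_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if n_rs + n_sex >= n_probes:
        raise ValueError("n_probes too small for the requested rs/sex probes")
    rng = np.random.default_rng(seed)
    n_cg = n_probes - n_rs
    probe_ids = [f"cg{i:08d}" for i in range(n_cg)]
    probe_ids += [f"rs{i:07d}" for i in range(n_rs)]
    genes = [f"G{(i % n_genes):04d}" for i in range(n_probes)]
    other_groups = ("5'UTR", "1stExon", "Body", "3'UTR")
    other_islands = ("N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

    def draw_group() -> str:
        if rng.random() < promoter_fraction:
            return "TSS200" if rng.random() < 0.5 else "TSS1500"
        return other_groups[rng.integers(len(other_groups))]

    records = []
    for i, probe in enumerate(probe_ids):
        if i < n_cg - n_sex:
            chrom = str(i % 22 + 1)
        elif i < n_cg:  # last autosome-free cg probes live on X/Y
            chrom = "X" if (i - (n_cg - n_sex)) % 2 == 0 else "Y"
        else:
            chrom = str(i % 22 + 1)
        gene_links = [genes[i]]
        group_links = [draw_group()]
        if rng.random() < multi_gene_fraction:
            second = f"G{((i + 1) % n_genes):04d}"
            if second not in gene_links:
                gene_links.append(second)
                group_links.append(draw_group())
        island = (
            "Island"
            if rng.random() < island_fraction
            else other_islands[rng.integers(len(other_islands))]
        )
        records.append(
            (probe, chrom, tuple(gene_links), tuple(group_links), island)
        )
    ann = pd.DataFrame.from_records(
        records,
        columns=["probe_id", "chromosome", "genes", "region_groups", "island_relation"],
    ).set_index("probe_id")
    return ann


def _rule_qualifiers(
    values: np.ndarray, probes: pd.Index, trios: Sequence[TrioDesign],
    columns: dict[str, int]
) -> set[tuple[str, str, str]]:
    """Direct scan of the trio rule over a value matrix."""
    out: set[tuple[str, str, str]] = set()
    for trio in trios:
        c = values[:, columns[trio.child]]
        pa = values[:, columns[trio.affected_parent]]
        pu = values[:, columns[trio.unaffected_parent]]
        hyper = (c >= HYPER_MIN) & (pa >= HYPER_MIN) & (pu <= HYPO_MAX)
        hypo = (c <= HYPO_MAX) & (pa <= HYPO_MAX) & (pu >= HYPER_MIN)
        for idx in np.flatnonzero(hyper):
            out.add((probes[idx], trio.trio_id, AFFECTED_HYPER))
        for idx in np.flatnonzero(hypo):
            out.add((probes[idx], trio.trio_id, AFFECTED_HYPO))
    return out


def simulate_trio_betas(
    params: TrioSimParams,
    manifest: pd.DataFrame | None = None,
    candidate_probes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Trio beta matrix with planted differential events and its truth ledger.

    When a manifest is given, its probes define the matrix rows (its length
    must match ``params.n_probes``) and planting avoids rs/X/Y probes so the
    planted signal survives the standard filters.  ``candidate_probes``
    optionally restricts planting further (e.g. to probes of a chosen gene
    set).  A pure function of (params, manifest, candidate_probes).
    """
    rng = np.random.default_rng(params.seed)
    trios = trio_designs(params.n_trios)
    samples = [s for t in trios for s in t.samples]
    columns = {s: i for i, s in enumerate(samples)}
    if manifest is not None:
        if len(manifest) != params.n_probes:
            raise ValueError(
                f"manifest has {len(manifest)} probes, params say {params.n_probes}"
            )
        probes = manifest.index
    else:
        probes = pd.Index(
            [f"cg{i:08d}" for i in range(params.n_probes)], name="probe_id"
        )
    shape = (params.n_probes, len(samples))
    (a0, b0), (a1, b1) = params.background_components
    comp0 = rng.beta(a0, b0, size=shape)
    comp1 = rng.beta(a1, b1, size=shape)
    if params.component_mode == "probe":
        take0 = rng.random(params.n_probes) < params.mixture_weight
        values = np.where(take0[:, None], comp0, comp1)
    else:
        take0 = rng.random(shape) < params.mixture_weight
        values = np.where(take0, comp0, comp1)

    if candidate_probes is not None:
        probe_set = set(probes)
        eligible = [p for p in candidate_probes if p in probe_set]
        if len(eligible) != len(candidate_probes):
            raise ValueError("candidate_probes must be a subset of the probe ids")
    elif manifest is not None:
        on_sex = manifest["chromosome"].isin(SEX_CHROMOSOMES)
        eligible = [
            p
            for p, sex in zip(manifest.index, on_sex)
            if not sex and not str(p).startswith("rs")
        ]
    else:
        eligible = list(probes)
    eligible = sorted(eligible)
    probe_pos = {p: i for i, p in enumerate(probes)}

    n_plant = int(round(params.planted_fraction * params.n_probes))
    if n_plant > len(eligible):
        raise ValueError(
            f"cannot plant {n_plant} events per trio: only {len(eligible)} "
            f"eligible probes"
        )
    dm_events: set[tuple[str, str, str]] = set()
    aff_lo, aff_hi = params.affected_band
    una_lo, una_hi = params.unaffected_band
    for trio in trios:
        chosen = rng.choice(len(eligible), size=n_plant, replace=False)
        for j, probe_idx in enumerate(sorted(chosen)):
            probe = eligible[probe_idx]
            row = probe_pos[probe]
            direction = AFFECTED_HYPER if j % 2 == 0 else AFFECTED_HYPO
            pair = rng.uniform(aff_lo, aff_hi, size=2)
            lone = rng.uniform(una_lo, una_hi)
            if direction == AFFECTED_HYPO:
                pair = 1.0 - pair  # mirror the bands for the hypo direction
                lone = 1.0 - lone
            values[row, columns[trio.child]] = pair[0]
            values[row, columns[trio.affected_parent]] = pair[1]
            values[row, columns[trio.unaffected_parent]] = lone
            dm_events.add((probe, trio.trio_id, direction))
    all_qualifiers = _rule_qualifiers(values, probes, trios, columns)
    planted_pairs = {(p, t) for p, t, _ in dm_events}
    background = frozenset(
        q for q in all_qualifiers if (q[0], q[1]) not in planted_pairs
    )
    bm = pd.DataFrame(values, index=probes, columns=samples)
    bm.index.name = "probe_id"
    return bm, PlantedTruth(frozenset(dm_events), background)


def analytic_chance_qualifier_rate(params: TrioSimParams) -> float:
    """Exact probability that a background probe/trio triple satisfies the
    trio rule, under the generator's mixture model and component mode."""
    w = params.mixture_weight
    comps = params.background_components
    weights = (w, 1.0 - w)
    hypo = [stats.beta.cdf(HYPO_MAX, a, b) for a, b in comps]
    hyper = [stats.beta.sf(HYPER_MIN, a, b) for a, b in comps]
    if params.component_mode == "sample":
        p_hypo = sum(wi * h for wi, h in zip(weights, hypo))
        p_hyper = sum(wi * h for wi, h in zip(weights, hyper))
        return p_hyper**2 * p_hypo + p_hypo**2 * p_hyper
    return sum(
        wi * (hy**2 * ho + ho**2 * hy)
        for wi, ho, hy in zip(weights, hypo, hyper)
    )


def choose_planted_genes(
    manifest: pd.DataFrame, n: int, seed: int = 0, require_promoter: bool = True
) -> tuple[str, ...]:
    """Pick the genes whose probes will carry the planted signal.

    Candidates are genes with at least two autosomal cg probes and, by
    default, at least one promoter-linked probe — so the promoter-restricted
    arm of the pipeline sees the planted signal too.
    """
    from .io import PROMOTER_GROUPS

    probe_count: dict[str, int] = {}
    has_promoter: dict[str, bool] = {}
    on_sex = manifest["chromosome"].isin(SEX_CHROMOSOMES)
    for probe, sex in zip(manifest.index, on_sex):
        if sex or str(probe).startswith("rs"):
            continue
        for gene, group in zip(
            manifest.at[probe, "genes"], manifest.at[probe, "region_groups"]
        ):
            probe_count[gene] = probe_count.get(gene, 0) + 1
            if group in PROMOTER_GROUPS:
                has_promoter[gene] = True
    candidates = sorted(
        g
        for g, cnt in probe_count.items()
        if cnt >= 2 and (not require_promoter or has_promoter.get(g, False))
    )
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} genes satisfy the planting requirements"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=n, replace=False)
    return tuple(sorted(candidates[i] for i in picked))


def probes_for_genes(
    manifest: pd.DataFrame, genes: Iterable[str]
) -> tuple[str, ...]:
    """Autosomal cg probes annotated to any of *genes* (sorted)."""
    wanted = set(genes)
    on_sex = manifest["chromosome"].isin(SEX_CHROMOSOMES)
    out = [
        probe
        for probe, sex in zip(manifest.index, on_sex)
        if not sex
        and not str(probe).startswith("rs")
        and wanted & set(manifest.at[probe, "genes"])
    ]
    return tuple(sorted(out))


def simulate_network_pathways(
    params: NetworkSimParams,
    universe: Sequence[str],
    planted_genes: Sequence[str],
    planted_name: str = PLANTED_PATHWAY_NAME,
):
    """PPI network and pathway collection with one planted pathway.

    The network is an Erdos-Renyi graph over the (sorted) gene universe plus
    a full clique on the planted genes; the pathway collection holds one
    pathway equal to the planted gene set and random decoy pathways drawn
    without replacement from the universe.

    Returns ``(graph, pathway_sets, planted_name)`` where ``pathway_sets``
    is a name -> frozenset mapping (build a
    :class:`~triomethyl.enrichment.PathwayCollection` with the universe as
    background).
    """
    genes = sorted(set(universe))
    planted = sorted(set(planted_genes))
    if not set(planted) <= set(genes):
        raise ValueError("planted genes must be a subset of the universe")
    if len(genes) != params.n_genes:
        raise ValueError(
            f"universe has {len(genes)} genes, params say {params.n_genes}"
        )
    base = nx.fast_gnp_random_graph(
        len(genes), params.edge_probability, seed=params.seed
    )
    graph = nx.relabel_nodes(base, dict(enumerate(genes)))
    for i, a in enumerate(planted):
        for b in planted[i + 1:]:
            graph.add_edge(a, b)
    rng = np.random.default_rng(params.seed)
    sets: dict[str, frozenset[str]] = {planted_name: frozenset(planted)}
    lo, hi = params.decoy_size_range
    for d in range(params.n_decoy_pathways):
        while True:
            size = int(rng.integers(lo, hi + 1))
            members = frozenset(
                genes[i] for i in rng.choice(len(genes), size=size, replace=False)
            )
            if members != sets[planted_name]:
                break
        sets[f"DECOY_{d:03d}"] = members
    return graph, sets, planted_name


def simulate_detection_p(
    probe_ids: Sequence[str],
    sample_ids: Sequence[str],
    bad_probe_ids: Sequence[str] = (),
    bad_sample_ids: Sequence[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Detection-p matrix: clean entries ~ U(0, 0.01), rows/columns of the
    designated bad probes/samples ~ U(0.5, 1)."""
    probe_index = pd.Index(probe_ids, name="probe_id")
    if not set(bad_probe_ids) <= set(probe_ids):
        raise ValueError("bad_probe_ids must be a subset of probe_ids")
    if not set(bad_sample_ids) <= set(sample_ids):
        raise ValueError("bad_sample_ids must be a subset of sample_ids")
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.0, 0.01, size=(len(probe_ids), len(sample_ids)))
    dp = pd.DataFrame(vals, index=probe_index, columns=list(sample_ids))
    for probe in bad_probe_ids:
        dp.loc[probe] = rng.uniform(0.5, 1.0, size=len(sample_ids))
    for sample in bad_sample_ids:
        dp[sample] = rng.uniform(0.5, 1.0, size=len(probe_ids))
    return dp


def write_truth(truth: PlantedTruth, path) -> None:
    """Truth ledger TSV: probe, trio, direction, planted flag."""
    rows = [(p, t, d, True) for p, t, d in truth.dm_events]
    rows += [(p, t, d, False) for p, t, d in truth.background_qualifiers]
    pd.DataFrame(
        sorted(rows), columns=["probe_id", "trio_id", "direction", "planted"]
    ).to_csv(path, sep="\t", index=False)
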