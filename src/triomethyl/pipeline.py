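"""End-to-end orchestration of the trio and dual analysis arms.

Two layers are provided.  The in-memory layer (:func:`trio_gene_lists`,
:func:`enrich_gene_list`, :func:`run_recovery`) operates on pandas/networkx
objects and is what the tests and the simulation study drive.  The file
layer (:func:`run_trio_pipeline`, :func:`run_dual_pipeline`,
:func:`run_simulation_study`) reads the plain-text input formats, runs the
in-memory layer and writes deterministic TSV/JSON artifacts plus a run log;
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from . import dual as dual_mod
from . import enrichment as enr
from . import io as tmio
from . import simulate as sim
from . import trio as trio_mod

__all__ = [
    "PipelineConfig",
    "trio_gene_lists",
    "enrich_gene_list",
    "run_trio_pipeline",
    "run_dual_pipeline",
    "run_recovery",
    "run_simulation_study",
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and tuning knobs for a pipeline run.

    ``scope`` selects the trio-arm aggregation level: ``genome_wide``,
    ``promoter`` or ``both``.
    """

    beta: str | None = None
    manifest: str | None = None
    trio_sheet: str | None = None
    detection_p: str | None = None
    network: str | None = None
    gmt: str | None = None
    universe: str | None = None
    out_dir: str = "triomethyl_out"
    seed: int = 0
    hypo_max: float = trio_mod.HYPO_MAX
    hyper_min: float = trio_mod.HYPER_MIN
    alpha: float = 0.05
    fdr: float = 0.05
    scope: str = "both"
    p_floor: float = 1e-6
    max_size: int = 50
    n_subnetworks: int = 5
    max_overlap: float = 0.5
    n_seeds: int = 20
    dual_k: int = 1000
    dual_tol: float = 0.05
    dual_pathways: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.hypo_max < self.hyper_min <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= hypo_max < hyper_min <= 1")
        if self.scope not in {"both", *trio_mod.SCOPES}:
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def scopes(self) -> tuple[str, ...]:
        return trio_mod.SCOPES if self.scope == "both" else (self.scope,)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# in-memory layer


def trio_gene_lists(
    bm: pd.DataFrame,
    ann: pd.DataFrame,
    trios: Sequence[tmio.TrioDesign],
    scope: str,
    hypo_max: float = trio_mod.HYPO_MAX,
    hyper_min: float = trio_mod.HYPER_MIN,
) -> tuple[list[trio_mod.DMGList], trio_mod.DMGList]:
    """Per-trio DMG lists and their family pool for one scope."""
    lists = [
        trio_mod.build_dmg_list(bm, t, ann, scope, hypo_max, hyper_min)
        for t in trios
    ]
    pool = trio_mod.build_family_pool(lists)
    return lists, pool


def enrich_gene_list(
    dmg: trio_mod.DMGList,
    net: nx.Graph,
    pathways: enr.PathwayCollection,
    config: PipelineConfig,
) -> tuple[list[enr.SubNetwork], list[enr.PathwayResult], list[enr.PathwayResult]]:
    """Subnetwork search plus pathway testing for one DMG list.

    Returns (subnetworks, all pathway results, significant final list).
    """
    scores = trio_mod.scores_to_pvalues(dmg, floor=config.p_floor)
    subnetworks = enr.find_active_subnetworks(
        net,
        scores,
        max_size=config.max_size,
        n_subnetworks=config.n_subnetworks,
        max_overlap=config.max_overlap,
        n_seeds=config.n_seeds,
    )
    results = enr.test_pathways(subnetworks, pathways)
    significant = enr.collect_significant_pathways(results, alpha=config.alpha)
    return subnetworks, results, significant


def _load_pathway_collection(config: PipelineConfig,
                             net: nx.Graph,
                             scored_genes: set[str]) -> enr.PathwayCollection:
    sets = enr.read_gmt(config.gmt)
    if config.universe:
        background = enr.read_universe(config.universe)
    else:
        background = frozenset(net.nodes) | scored_genes
    return enr.PathwayCollection.create(sets, background)


# ---------------------------------------------------------------------------
# file layer


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _loggable_config(config: PipelineConfig) -> dict:
    """Config dict with paths relativized to the output directory, so the
    run log is byte-identical regardless of where the run was rooted."""
    out = Path(config.out_dir).resolve()
    logged = asdict(config)
    for key, value in logged.items():
        if isinstance(value, str) and key != "scope":
            path = Path(value).resolve()
            if path == out:
                logged[key] = "."
            elif path.is_relative_to(out):
                logged[key] = str(path.relative_to(out))
    return logged


def run_trio_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Filter -> select -> score -> aggregate -> pool -> enrich -> summarize.

    Writes, per scope, one DMG TSV per trio plus the family pool, pathway
    result TSVs, a cross-trio summary TSV, and a JSON run log.  Returns the
    artifact paths keyed by short names.
    """
    for name in ("beta", "manifest", "trio_sheet", "network", "gmt"):
        if getattr(config, name) is None:
            raise ValueError(f"trio pipeline requires the {name!r} input path")
    bm = tmio.read_beta_matrix(config.beta)
    ann = tmio.read_manifest(config.manifest)
    trios = tmio.read_trio_sheet(config.trio_sheet)
    if not trios:
        raise ValueError("trio sheet contains no trios")
    for t in trios:
        for s in t.samples:
            if s not in bm.columns:
                raise ValueError(f"trio {t.trio_id!r}: sample {s!r} not in beta matrix")
    dp = tmio.read_detection_p(config.detection_p) if config.detection_p else None
    filtered, report = tmio.filter_probes(bm, ann, dp)
    if report.removed_samples:
        lost = set(report.removed_samples)
        dropped = [t for t in trios if lost & set(t.samples)]
        if dropped:
            warnings.warn(
                f"{len(dropped)} trio(s) dropped: a member sample failed the "
                f"reliability filter"
            )
            trios = [t for t in trios if not (lost & set(t.samples))]
            if not trios:
                raise ValueError("no trio survived the sample reliability filter")
    net = enr.read_edge_list(config.network)

    out = Path(config.out_dir)
    artifacts: dict[str, str] = {}
    log: dict = {
        "package": "triomethyl",
        "version": __version__,
        "stage_counts": {
            "input_probes": report.n_input_probes,
            "input_samples": report.n_input_samples,
            "removed_probes": report.counts,
            "removed_samples": len(report.removed_samples),
            "retained_probes": report.n_retained_probes,
        },
        "config": _loggable_config(config),
        "n_trios": len(trios),
    }
    per_scope_lists: dict[str, list[trio_mod.DMGList]] = {}
    for scope in config.scopes:
        scope_dir = out / "trio" / scope
        scope_dir.mkdir(parents=True, exist_ok=True)
        lists, pool = trio_gene_lists(
            filtered, ann, trios, scope, config.hypo_max, config.hyper_min
        )
        per_scope_lists[scope] = lists
        per_trio_final: dict[str, list[enr.PathwayResult]] = {}
        pathways = None
        for dmg in [*lists, pool]:
            path = scope_dir / f"dmg_{dmg.owner}.tsv"
            trio_mod.write_dmg_list(dmg, path)
            artifacts[f"dmg_{scope}_{dmg.owner}"] = str(path)
            if pathways is None:
                pathways = _load_pathway_collection(
                    config, net, {e.gene for l in lists for e in l.entries}
                )
            _, results, significant = enrich_gene_list(dmg, net, pathways, config)
            rpath = scope_dir / f"pathways_{dmg.owner}.tsv"
            enr.write_pathway_results(significant, rpath)
            artifacts[f"pathways_{scope}_{dmg.owner}"] = str(rpath)
            if dmg.owner == pool.owner:
                pool_final = significant
            else:
                per_trio_final[dmg.owner] = significant
        summary = enr.summarize_across_trios(per_trio_final, pool_final)
        spath = scope_dir / "summary.tsv"
        pd.DataFrame(
            sorted(
                ((p, n) for p, n in summary.counts.items()),
                key=lambda x: (-x[1], x[0]),
            ),
            columns=["pathway", "n_trios"],
        ).to_csv(spath, sep="\t", index=False)
        artifacts[f"summary_{scope}"] = str(spath)
        log[f"n_dmg_{scope}"] = {l.owner: len(l) for l in [*lists, pool]}
        log[f"n_significant_pathways_{scope}"] = {
            "family_pool": len(pool_final),
            **{t: len(v) for t, v in per_trio_final.items()},
        }
    log_path = out / "trio" / "run_log.json"
    _write_json(log, log_path)
    artifacts["run_log"] = str(log_path)
    return artifacts


def run_dual_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Pooled-group arm: clustering orderings, sitewise tests, island gene
    means and dual-color tables for the requested pathways."""
    for name in ("beta", "manifest", "trio_sheet"):
        if getattr(config, name) is None:
            raise ValueError(f"dual pipeline requires the {name!r} input path")
    bm = tmio.read_beta_matrix(config.beta)
    ann = tmio.read_manifest(config.manifest)
    trios = tmio.read_trio_sheet(config.trio_sheet)
    if not trios:
        raise ValueError("trio sheet contains no trios")
    design = dual_mod.GroupDesign.from_trios(trios)
    dp = tmio.read_detection_p(config.detection_p) if config.detection_p else None
    filtered, _ = tmio.filter_probes(bm, ann, dp)

    out = Path(config.out_dir) / "dual"
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    k = min(config.dual_k, filtered.dropna(axis=0).shape[0])
    clustering = dual_mod.top_variance_clustering(filtered, k)
    cpath = out / "clustering.tsv"
    pd.DataFrame(
        {
            "axis": ["probe"] * len(clustering.probe_order)
            + ["sample"] * len(clustering.sample_order),
            "position": list(range(len(clustering.probe_order)))
            + list(range(len(clustering.sample_order))),
            "id": list(clustering.probe_order) + list(clustering.sample_order),
        }
    ).to_csv(cpath, sep="\t", index=False)
    artifacts["clustering"] = str(cpath)

    tests, _skipped = dual_mod.sitewise_ttest(filtered, design)
    tpath = out / "site_tests.tsv"
    tests.to_csv(tpath, sep="\t")
    artifacts["site_tests"] = str(tpath)

    means = dual_mod.gene_group_means(filtered, ann, design)
    mpath = out / "gene_means.tsv"
    means.to_csv(mpath, sep="\t")
    artifacts["gene_means"] = str(mpath)

    gmt_sets = enr.read_gmt(config.gmt) if config.gmt else {}
    for name in config.dual_pathways:
        if name not in gmt_sets:
            warnings.warn(f"pathway {name!r} not found in GMT, skipped")
            continue
        table = dual_mod.dual_color_table(means, gmt_sets[name], tol=config.dual_tol)
        ppath = out / f"dual_color_{name}.tsv"
        table.to_csv(ppath, sep="\t")
        artifacts[f"dual_color_{name}"] = str(ppath)

    _write_json(
        {
            "package": "triomethyl",
            "version": __version__,
            "n_tested_probes": int(tests.shape[0]),
            "n_fdr_significant": int((tests["fdr_p"] <= config.fdr).sum()),
            "n_genes_with_island_probes": int(means.shape[0]),
            "clustering_k": k,
        },
        out / "run_log.json",
    )
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts


# ---------------------------------------------------------------------------
# simulation study


def run_recovery(
    trio_params: sim.TrioSimParams,
    net_params: sim.NetworkSimParams,
    config: PipelineConfig | None = None,
    scope: str = trio_mod.GENOME_WIDE,
) -> dict:
    """Generate one synthetic cohort, run the trio arm in memory and score
    recovery of the planted truth.

    Returns a dict with the planted-event sensitivity, the chance-qualifier
    rate among background probes, the planted pathway's rank by Bonferroni p
    in the family-pool enrichment, and supporting counts.
    """
    config = config or PipelineConfig()
    manifest = sim.simulate_manifest(
        trio_params.n_probes, trio_params.n_genes, seed=trio_params.seed
    )
    planted_genes = sim.choose_planted_genes(
        manifest, net_params.planted_module_size, seed=trio_params.seed
    )
    candidates = sim.probes_for_genes(manifest, planted_genes)
    bm, truth = sim.simulate_trio_betas(trio_params, manifest, candidates)
    truth = truth.with_pathway(sim.PLANTED_PATHWAY_NAME, planted_genes)
    trios = sim.trio_designs(trio_params.n_trios)
    filtered, report = tmio.filter_probes(bm, manifest)

    qualifying: set[tuple[str, str, str]] = set()
    lists = []
    for t in trios:
        scored = trio_mod.score_trio(
            filtered, t, config.hypo_max, config.hyper_min
        )
        for probe, direction in zip(scored.index, scored["direction"]):
            qualifying.add((probe, t.trio_id, direction))
        lists.append(
            trio_mod.DMGList.from_entries(
                t.trio_id, scope, trio_mod.aggregate_to_genes(scored, manifest, scope)
            )
        )
    pool = trio_mod.build_family_pool(lists)

    n_planted = len(truth.dm_events)
    recovered = len(truth.dm_events & qualifying)
    sensitivity = recovered / n_planted if n_planted else None
    n_background_triples = (
        report.n_retained_probes * trio_params.n_trios - n_planted
    )
    chance = len(qualifying - truth.dm_events)

    universe = sorted({f"G{i:04d}" for i in range(trio_params.n_genes)})
    net, sets, planted_name = sim.simulate_network_pathways(
        net_params, universe, planted_genes
    )
    pathways = enr.PathwayCollection.create(sets, universe)
    _, results, significant = enrich_gene_list(pool, net, pathways, config)
    ranking = enr.rank_pathways(results)
    rank = next(
        (i + 1 for i, r in enumerate(ranking) if r.pathway == planted_name), None
    )
    return {
        "scope": scope,
        "n_planted_events": n_planted,
        "n_recovered_events": recovered,
        "sensitivity": sensitivity,
        "n_chance_qualifiers": chance,
        "chance_qualifier_rate": chance / n_background_triples
        if n_background_triples
        else None,
        "analytic_chance_rate": float(sim.analytic_chance_qualifier_rate(trio_params)),
        "family_pool_n_genes": len(pool),
        "planted_pathway": planted_name,
        "planted_pathway_rank": rank,
        "planted_pathway_bonferroni_p": next(
            (r.bonferroni_p for r in ranking if r.pathway == planted_name), None
        ),
        "n_significant_pathways": len(significant),
    }


def run_simulation_study(
    out_dir,
    trio_params: sim.TrioSimParams | None = None,
    net_params: sim.NetworkSimParams | None = None,
    config: PipelineConfig | None = None,
    write_inputs: bool = True,
) -> dict:
    """Full simulation study: generate inputs, write them in every pipeline
    file format, run both arms from those files and score recovery.

    The recovery report (a pure function of the parameters and seeds) is
    written to ``<out_dir>/recovery_report.json``.
    """
    trio_params = trio_params or sim.TrioSimParams()
    net_params = net_params or sim.NetworkSimParams(n_genes=trio_params.n_genes)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = run_recovery(trio_params, net_params, config)
    report_promoter = run_recovery(
        trio_params, net_params, config, scope=trio_mod.PROMOTER
    )
    report = {
        "genome_wide": report,
        "promoter": report_promoter,
        "trio_params": asdict(trio_params),
        "net_params": asdict(net_params),
    }
    _write_json(report, out / "recovery_report.json")

    if write_inputs:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        manifest = sim.simulate_manifest(
            trio_params.n_probes, trio_params.n_genes, seed=trio_params.seed
        )
        planted_genes = sim.choose_planted_genes(
            manifest, net_params.planted_module_size, seed=trio_params.seed
        )
        candidates = sim.probes_for_genes(manifest, planted_genes)
        bm, truth = sim.simulate_trio_betas(trio_params, manifest, candidates)
        truth = truth.with_pathway(sim.PLANTED_PATHWAY_NAME, planted_genes)
        trios = sim.trio_designs(trio_params.n_trios)
        universe = sorted({f"G{i:04d}" for i in range(trio_params.n_genes)})
        net, sets, _ = sim.simulate_network_pathways(
            net_params, universe, planted_genes
        )
        dp = sim.simulate_detection_p(
            list(bm.index), list(bm.columns), seed=trio_params.seed
        )
        tmio.write_beta_matrix(bm, inputs / "beta.tsv")
        tmio.write_manifest(manifest, inputs / "manifest.csv")
        tmio.write_trio_sheet(trios, inputs / "trios.csv")
        tmio.write_detection_p(dp, inputs / "detection_p.tsv")
        enr.write_edge_list(net, inputs / "network.tsv")
        enr.write_gmt(sets, inputs / "pathways.gmt")
        enr.write_universe(universe, inputs / "universe.txt")
        sim.write_truth(truth, inputs / "truth.tsv")

        file_config = PipelineConfig(
            beta=str(inputs / "beta.tsv"),
            manifest=str(inputs / "manifest.csv"),
            trio_sheet=str(inputs / "trios.csv"),
            detection_p=str(inputs / "detection_p.tsv"),
            network=str(inputs / "network.tsv"),
            gmt=str(inputs / "pathways.gmt"),
            universe=str(inputs / "universe.txt"),
            out_dir=str(out),
            seed=trio_params.seed,
            dual_pathways=[sim.PLANTED_PATHWAY_NAME],
            **(
                {}
                if config is None
                else {
                    k: getattr(config, k)
                    for k in (
                        "hypo_max",
                        "hyper_min",
                        "alpha",
                        "fdr",
                        "scope",
                        "p_floor",
                        "max_size",
                        "n_subnetworks",
                        "max_overlap",
                        "n_seeds",
                        "dual_k",
                        "dual_tol",
                    )
                }
            ),
        )
        run_trio_pipeline(file_config)
        run_dual_pipeline(file_config)
    return report
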