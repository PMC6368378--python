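"""Trio-based differential methylation scoring (TbSSch).

The core idea: within a family trio (affected child ``C``, affected parent
``PA``, unaffected parent ``PU``) a CpG is *trio-differential* when the
affected pair sits in one extreme methylation state and the unaffected
parent in the opposite one.  States are called from the beta value with the
conventional stringent cutoffs — hypo-methylated for beta in [0, 0.2],
hyper-methylated for beta in [0.8, 1.0], intermediate otherwise.

A qualifying CpG is scored with the trio-based scoring scheme (TbSSch),
which measures how far the three betas sit from the 0.5 midline, normalized
to land in [0.6, 1.0] given the state cutoffs:

* affected pair hyper, unaffected parent hypo::

      TbSSch = [(C - 0.5) + (PA - 0.5) + (0.5 - PU)] / 1.5

* affected pair hypo, unaffected parent hyper::

      TbSSch = [(0.5 - C) + (0.5 - PA) + (PU - 0.5)] / 1.5

Scored CpGs are aggregated to genes through the probe annotation (a probe
annotated to several genes supports each of them; a gene keeps the maximum
score over its supporting CpGs), optionally restricted to promoter links
(TSS200/TSS1500).  Per-trio gene lists are pooled into a *family pool* that
keeps the genes recurring in more than one trio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PROMOTER_GROUPS, TrioDesign

__all__ = [
    "HYPO",
    "INTERMEDIATE",
    "HYPER",
    "AFFECTED_HYPER",
    "AFFECTED_HYPO",
    "call_state",
    "select_trio_dm_cpgs",
    "tbssch",
    "score_trio",
    "DMGEntry",
    "DMGList",
    "aggregate_to_genes",
    "build_dmg_list",
    "build_family_pool",
    "scores_to_pvalues",
    "write_dmg_list",
]

HYPO = "hypo"
INTERMEDIATE = "intermediate"
HYPER = "hyper"

AFFECTED_HYPER = "affected_hyper"
AFFECTED_HYPO = "affected_hypo"

GENOME_WIDE = "genome_wide"
PROMOTER = "promoter"
SCOPES = (GENOME_WIDE, PROMOTER)

#: Default state cutoffs: hypo iff beta <= HYPO_MAX, hyper iff beta >= HYPER_MIN.
HYPO_MAX = 0.2
HYPER_MIN = 0.8


def call_state(beta: float, hypo_max: float = HYPO_MAX,
               hyper_min: float = HYPER_MIN) -> str:
    """Classify a beta value as ``hypo``, ``intermediate`` or ``hyper``.

    Both cutoff intervals are closed: ``beta <= hypo_max`` is hypo and
    ``beta >= hyper_min`` is hyper, so the boundary triples that attain the
    minimal TbSSch of 0.6 are representable.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value out of [0, 1]: {beta}")
    if beta <= hypo_max:
        return HYPO
    if beta >= hyper_min:
        return HYPER
    return INTERMEDIATE


def select_trio_dm_cpgs(
    bm: pd.DataFrame,
    trio: TrioDesign,
    hypo_max: float = HYPO_MAX,
    hyper_min: float = HYPER_MIN,
) -> pd.DataFrame:
    """Probes satisfying the trio differential rule for one trio.

    A probe qualifies when child and affected parent are both hyper-methylated
    and the unaffected parent hypo-methylated (direction ``affected_hyper``),
    or the mirror image (``affected_hypo``).  Probes with a missing beta in
    any of the three samples are skipped; their count is stored in
    ``result.attrs["n_missing_skipped"]``.

    Returns a DataFrame indexed by probe id with columns ``C``, ``PA``,
    ``PU`` (the three betas) and ``direction``.
    """
    for sample in trio.samples:
        if sample not in bm.columns:
            raise KeyError(f"trio {trio.trio_id!r}: sample {sample!r} not in matrix")
    c = bm[trio.child].to_numpy(dtype=float)
    pa = bm[trio.affected_parent].to_numpy(dtype=float)
    pu = bm[trio.unaffected_parent].to_numpy(dtype=float)
    complete = ~(np.isnan(c) | np.isnan(pa) | np.isnan(pu))
    hyper_dir = (
        complete & (c >= hyper_min) & (pa >= hyper_min) & (pu <= hypo_max)
    )
    hypo_dir = (
        complete & (c <= hypo_max) & (pa <= hypo_max) & (pu >= hyper_min)
    )
    mask = hyper_dir | hypo_dir
    out = pd.DataFrame(
        {
            "C": c[mask],
            "PA": pa[mask],
            "PU": pu[mask],
            "direction": np.where(hyper_dir[mask], AFFECTED_HYPER, AFFECTED_HYPO),
        },
        index=bm.index[mask],
    )
    out.index.name = "probe_id"
    out.attrs["trio_id"] = trio.trio_id
    out.attrs["n_missing_skipped"] = int((~complete).sum())
    return out


def tbssch(c, pa, pu, direction):
    """TbSSch score of a qualifying trio beta triple.

    Accepts scalars or aligned arrays.  ``direction`` is ``affected_hyper``
    or ``affected_hypo`` (scalar or array).  For scalar input the direction
    is checked against the called states; arrays are assumed to come from
    :func:`select_trio_dm_cpgs`.
    """
    scalar = np.isscalar(c) and np.isscalar(pa) and np.isscalar(pu)
    c_arr = np.asarray(c, dtype=float)
    pa_arr = np.asarray(pa, dtype=float)
    pu_arr = np.asarray(pu, dtype=float)
    dir_arr = np.asarray(direction)
    if scalar:
        expect = {
            AFFECTED_HYPER: (HYPER, HYPER, HYPO),
            AFFECTED_HYPO: (HYPO, HYPO, HYPER),
        }
        if direction not in expect:
            raise ValueError(f"unknown direction {direction!r}")
        states = tuple(call_state(float(v)) for v in (c_arr, pa_arr, pu_arr))
        if states != expect[direction]:
            raise ValueError(
                f"states {states} inconsistent with direction {direction!r}"
            )
    # evaluated on a decimal-scaled axis (x10) so betas with two-decimal
    # precision — in particular the 0.2/0.8 cutoff triples — score exactly
    hyper_score = ((10 * c_arr - 5) + (10 * pa_arr - 5) + (5 - 10 * pu_arr)) / 15
    hypo_score = ((5 - 10 * c_arr) + (5 - 10 * pa_arr) + (10 * pu_arr - 5)) / 15
    score = np.where(dir_arr == AFFECTED_HYPER, hyper_score, hypo_score)
    if scalar:
        return float(score)
    return score


def score_trio(
    bm: pd.DataFrame,
    trio: TrioDesign,
    hypo_max: float = HYPO_MAX,
    hyper_min: float = HYPER_MIN,
) -> pd.DataFrame:
    """Select and score the trio-differential CpGs of one trio.

    Returns a DataFrame indexed by probe id with columns ``direction`` and
    ``tbssch``; ``attrs`` carries the trio id and the missing-skip count.
    """
    selected = select_trio_dm_cpgs(bm, trio, hypo_max=hypo_max, hyper_min=hyper_min)
    scored = pd.DataFrame(
        {
            "direction": selected["direction"],
            "tbssch": tbssch(
                selected["C"].to_numpy(),
                selected["PA"].to_numpy(),
                selected["PU"].to_numpy(),
                selected["direction"].to_numpy(),
            ),
        },
        index=selected.index,
    )
    scored.attrs.update(selected.attrs)
    return scored


@dataclass(frozen=True)
class DMGEntry:
    """One differentially methylated gene with its supporting CpGs."""

    gene: str
    tbssch: float
    #: tuple of (probe_id, direction, score) triples
    support: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        if self.support and not math.isclose(
            self.tbssch, max(s for _, _, s in self.support)
        ):
            raise ValueError(
                f"gene {self.gene!r}: entry score is not the max of its support"
            )


@dataclass(frozen=True)
class DMGList:
    """Scored gene list for one trio or the family pool.

    Entries are sorted by descending score, ties broken by gene symbol, so
    that serialized lists are reproducible byte for byte.
    """

    owner: str
    scope: str
    entries: tuple[DMGEntry, ...]

    @classmethod
    def from_entries(cls, owner: str, scope: str,
                     entries: Iterable[DMGEntry]) -> "DMGList":
        if scope not in SCOPES:
            raise ValueError(f"unknown scope {scope!r}")
        ordered = tuple(sorted(entries, key=lambda e: (-e.tbssch, e.gene)))
        genes = [e.gene for e in ordered]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in DMG list")
        return cls(owner, scope, ordered)

    @property
    def genes(self) -> dict[str, DMGEntry]:
        return {e.gene: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "owner": self.owner,
                "scope": self.scope,
                "gene": [e.gene for e in self.entries],
                "tbssch": [e.tbssch for e in self.entries],
                "n_support": [len(e.support) for e in self.entries],
                "directions": [
                    ";".join(sorted({d for _, d, _ in e.support}))
                    for e in self.entries
                ],
                "probes": [
                    ";".join(sorted({p for p, _, _ in e.support}))
                    for e in self.entries
                ],
            }
        )


def aggregate_to_genes(
    scored: pd.DataFrame,
    ann: pd.DataFrame,
    scope: str = GENOME_WIDE,
) -> list[DMGEntry]:
    """Aggregate scored CpGs to gene level.

    Every probe-gene annotation link contributes the probe's score to that
    gene; under ``scope="promoter"`` only TSS200/TSS1500 links are kept.  A
    gene's score is the maximum over its supporting CpGs.  CpGs without any
    (in-scope) gene link are dropped.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    support: dict[str, list[tuple[str, str, float]]] = {}
    genes_col = ann["genes"]
    groups_col = ann["region_groups"]
    for probe, direction, score in zip(
        scored.index, scored["direction"], scored["tbssch"]
    ):
        if probe not in genes_col.index:
            continue
        for gene, group in zip(genes_col[probe], groups_col[probe]):
            if scope == PROMOTER and group not in PROMOTER_GROUPS:
                continue
            support.setdefault(gene, []).append((probe, direction, float(score)))
    return [
        DMGEntry(gene, max(s for _, _, s in sup), tuple(sorted(sup)))
        for gene, sup in support.items()
    ]


def build_dmg_list(
    bm: pd.DataFrame,
    trio: TrioDesign,
    ann: pd.DataFrame,
    scope: str = GENOME_WIDE,
    hypo_max: float = HYPO_MAX,
    hyper_min: float = HYPER_MIN,
) -> DMGList:
    """Full per-trio pass: select, score and aggregate to a sorted DMG list."""
    scored = score_trio(bm, trio, hypo_max=hypo_max, hyper_min=hyper_min)
    return DMGList.from_entries(trio.trio_id, scope, aggregate_to_genes(scored, ann, scope))


def build_family_pool(lists: Sequence[DMGList], owner: str = "family_pool") -> DMGList:
    """Pool per-trio DMG lists: keep genes present in more than one list.

    The pooled score of a gene is the maximum over all of its occurrences;
    the support records of every contributing list are merged (deduplicated).
    All input lists must share the same scope.
    """
    if len(lists) < 2:
        raise ValueError("family pool requires at least two trio DMG lists")
    scopes = {l.scope for l in lists}
    if len(scopes) != 1:
        raise ValueError(f"mixed scopes in family pool input: {sorted(scopes)}")
    occurrences: dict[str, list[DMGEntry]] = {}
    for lst in lists:
        for entry in lst.entries:
            occurrences.setdefault(entry.gene, []).append(entry)
    pooled = [
        DMGEntry(
            gene,
            max(e.tbssch for e in entries),
            tuple(sorted({s for e in entries for s in e.support})),
        )
        for gene, entries in occurrences.items()
        if len(entries) >= 2
    ]
    return DMGList.from_entries(owner, scopes.pop(), pooled)


def scores_to_pvalues(dmg: DMGList, floor: float = 1e-6) -> dict[str, float]:
    """Map TbSSch gene scores to nominal p-values for enrichment input.

    No canonical mapping exists for a bounded separation score; this package
    uses the convention ``p = clamp(1 - score, floor, 1)``, which is strictly
    decreasing in the score and keeps p in ``(0, 1]``.  It is an ordering
    device for the downstream subnetwork search, not a calibrated tail
    probability.
    """
    return {e.gene: float(min(max(1.0 - e.tbssch, floor), 1.0)) for e in dmg.entries}


def write_dmg_list(dmg: DMGList, path) -> None:
    dmg.to_frame().to_csv(path, sep="\t", index=False)
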