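"""Reading, validation and filtering of methylation-array inputs.

The central in-memory objects are plain pandas objects:

* a *beta matrix* is a ``DataFrame`` of methylation fractions in [0, 1]
  (``NaN`` marks a missing measurement), indexed by probe id with one column
  per sample;
* a *detection-p matrix* shares the same axes and holds per-measurement
  detection p-values;
* a *probe annotation* table (see :func:`read_manifest`) carries, per probe,
  the chromosome, the gene symbols the probe is assigned to, the gene-region
  group of each assignment (TSS200, TSS1500, 5'UTR, 1stExon, Body, 3'UTR) and
  the CpG-island relation.

Beta values are computed from methylated/unmethylated fluorescence
intensities as ``M / (M + U + 100)`` — the standard Illumina beta with an
offset of 100 in the denominator, which keeps low-intensity probes away from
the extremes and bounds the value strictly below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BETA_OFFSET",
    "MISSING_MARKER",
    "REGION_GROUPS",
    "PROMOTER_GROUPS",
    "ISLAND_RELATIONS",
    "SEX_CHROMOSOMES",
    "TrioDesign",
    "FilterReport",
    "compute_beta",
    "validate_beta_matrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_detection_p",
    "write_detection_p",
    "read_manifest",
    "write_manifest",
    "read_trio_sheet",
    "write_trio_sheet",
    "filter_probes",
    "greedycut_like",
]

#: Denominator offset of the Illumina beta value.
BETA_OFFSET = 100.0

#: Text marker for missing values in all tabular matrix files.
MISSING_MARKER = "NA"

REGION_GROUPS = frozenset({"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"})
PROMOTER_GROUPS = frozenset({"TSS200", "TSS1500"})
ISLAND_RELATIONS = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)
AUTOSOMES = frozenset(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = frozenset({"X", "Y"})

MANIFEST_COLUMNS = (
    "IlmnID",
    "CHR",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
)


def compute_beta(m, u, offset: float = BETA_OFFSET):
    """Methylation fraction ``M / (M + U + offset)`` from signal intensities.

    Accepts scalars or arrays; intensities must be non-negative.  The result
    lies in ``[0, 1)`` — the offset keeps it strictly below 1.
    """
    m_arr = np.asarray(m, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if np.any(m_arr < 0) or np.any(u_arr < 0):
        raise ValueError("signal intensities must be non-negative")
    if offset <= 0:
        raise ValueError("offset must be positive")
    beta = m_arr / (m_arr + u_arr + offset)
    if beta.ndim == 0:
        return float(beta)
    return beta


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


def validate_beta_matrix(bm: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *bm* violates the beta-matrix invariants."""
    _check_unique(bm.index, "probe ids")
    _check_unique(bm.columns, "sample ids")
    vals = bm.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        r, c = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValueError(
            f"beta value out of [0, 1] at probe {bm.index[r]!r}, "
            f"sample {bm.columns[c]!r}: {vals[r, c]}"
        )


def _read_matrix(path, missing: str, what: str, on_out_of_range: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[missing], keep_default_na=False
    )
    _check_unique(df.index, "probe ids")
    _check_unique(df.columns, "sample ids")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {what} file {path}: {exc}") from exc
    df = df.astype(float)
    vals = df.to_numpy()
    bad = ((vals < 0) | (vals > 1)) & ~np.isnan(vals)
    if np.any(bad):
        if on_out_of_range == "missing":
            df = df.mask(bad)
        else:
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"value out of [0, 1] in {what} file at probe {df.index[r]!r}, "
                f"sample {df.columns[c]!r}: {vals[r, c]}"
            )
    df.index.name = "probe_id"
    return df


def read_beta_matrix(path, missing: str = MISSING_MARKER,
                     on_out_of_range: str = "error") -> pd.DataFrame:
    """Read a probes-by-samples beta matrix from TSV.

    Parameters
    ----------
    path : path-like
        TSV file with probe ids in the first column and sample ids as header.
    missing : str
        Text marker flagged as a missing measurement.
    on_out_of_range : {"error", "missing"}
        Whether a value outside [0, 1] aborts the read or is marked missing.
    """
    if on_out_of_range not in {"error", "missing"}:
        raise ValueError("on_out_of_range must be 'error' or 'missing'")
    return _read_matrix(path, missing, "beta matrix", on_out_of_range)


def write_beta_matrix(bm: pd.DataFrame, path) -> None:
    bm.to_csv(path, sep="\t", na_rep=MISSING_MARKER, index_label="probe_id")


def read_detection_p(path, missing: str = MISSING_MARKER) -> pd.DataFrame:
    """Read a detection-p matrix (same dialect as the beta matrix)."""
    return _read_matrix(path, missing, "detection-p matrix", "error")


write_detection_p = write_beta_matrix


def normalize_chromosome(label: str) -> str:
    """Accept ``'chrX'``/``'X'`` dialects; return the bare label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label in {"x", "y"}:
        label = label.upper()
    if label not in AUTOSOMES | SEX_CHROMOSOMES:
        raise ValueError(f"unrecognized chromosome label: {label!r}")
    return label


def _split_semicolon(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(part.strip() for part in cell.split(";"))


def read_manifest(path) -> pd.DataFrame:
    """Parse a 450K-style probe manifest CSV into an annotation table.

    Expected columns: ``IlmnID``, ``CHR``, ``UCSC_RefGene_Name``,
    ``UCSC_RefGene_Group``, ``Relation_to_UCSC_CpG_Island``.  Gene symbols and
    region groups are semicolon-joined, aligned lists; an empty island
    relation is read as ``OpenSea``.

    Returns a DataFrame indexed by probe id with columns ``chromosome``
    (normalized label), ``genes`` (tuple of symbols), ``region_groups``
    (tuple aligned with ``genes``) and ``island_relation``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"manifest is missing columns {missing_cols}")
    records = []
    for row in raw.itertuples(index=False):
        probe = getattr(row, "IlmnID")
        genes = _split_semicolon(getattr(row, "UCSC_RefGene_Name"))
        groups = _split_semicolon(getattr(row, "UCSC_RefGene_Group"))
        if len(genes) != len(groups):
            raise ValueError(
                f"probe {probe!r}: {len(genes)} gene symbol(s) but "
                f"{len(groups)} region group(s)"
            )
        bad_groups = set(groups) - REGION_GROUPS
        if bad_groups:
            raise ValueError(f"probe {probe!r}: unknown region group(s) {bad_groups}")
        island = getattr(row, "Relation_to_UCSC_CpG_Island").strip() or "OpenSea"
        if island not in ISLAND_RELATIONS:
            raise ValueError(f"probe {probe!r}: unknown island relation {island!r}")
        records.append(
            (probe, normalize_chromosome(getattr(row, "CHR")), genes, groups, island)
        )
    ann = pd.DataFrame.from_records(
        records,
        columns=["probe_id", "chromosome", "genes", "region_groups", "island_relation"],
    ).set_index("probe_id")
    _check_unique(ann.index, "manifest probe ids")
    return ann


def write_manifest(ann: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "IlmnID": ann.index,
            "CHR": ann["chromosome"].to_numpy(),
            "UCSC_RefGene_Name": [";".join(g) for g in ann["genes"]],
            "UCSC_RefGene_Group": [";".join(g) for g in ann["region_groups"]],
            "Relation_to_UCSC_CpG_Island": ann["island_relation"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class TrioDesign:
    """Sample-id triple of one family: affected child, affected parent,
    unaffected parent."""

    trio_id: str
    child: str
    affected_parent: str
    unaffected_parent: str

    def __post_init__(self):
        ids = (self.child, self.affected_parent, self.unaffected_parent)
        if len(set(ids)) != 3:
            raise ValueError(f"trio {self.trio_id!r}: sample ids are not distinct")

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.child, self.affected_parent, self.unaffected_parent)


def read_trio_sheet(path) -> list[TrioDesign]:
    """Read a trio sample sheet CSV with columns
    ``trio_id,child,affected_parent,unaffected_parent``."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["trio_id", "child", "affected_parent", "unaffected_parent"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"trio sheet is missing columns {missing}")
    trios = [
        TrioDesign(r.trio_id, r.child, r.affected_parent, r.unaffected_parent)
        for r in raw.itertuples(index=False)
    ]
    ids = [t.trio_id for t in trios]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trio ids in trio sheet")
    return trios


def write_trio_sheet(trios: Sequence[TrioDesign], path) -> None:
    pd.DataFrame(
        [(t.trio_id, t.child, t.affected_parent, t.unaffected_parent) for t in trios],
        columns=["trio_id", "child", "affected_parent", "unaffected_parent"],
    ).to_csv(path, index=False)


@dataclass
class FilterReport:
    """Reconciliation of probe/sample removals performed by
    :func:`filter_probes`."""

    n_input_probes: int
    n_input_samples: int
    removed_probes: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed_probes:
            out[reason] = out.get(reason, 0) + 1
        return out

    @property
    def n_retained_probes(self) -> int:
        return self.n_input_probes - len(self.removed_probes)

    @property
    def n_retained_samples(self) -> int:
        return self.n_input_samples - len(self.removed_samples)


def greedycut_like(dp: pd.DataFrame, p_threshold: float = 0.05,
                   stop_fraction: float = 0.05) -> tuple[list[str], list[str]]:
    """Iterative removal of unreliable probes/samples from a detection-p
    matrix.

    At every step the probe (row) or sample (column) with the highest
    fraction of entries above ``p_threshold`` is removed, until every row and
    column has an unreliable fraction of at most ``stop_fraction``.  Ties are
    broken probe-before-sample, then by lexicographic id, making the
    procedure fully deterministic.  Re-running on its own output removes
    nothing (idempotent).

    Returns ``(removed_probe_ids, removed_sample_ids)``.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    if not 0 <= stop_fraction < 1:
        raise ValueError("stop_fraction must lie in [0, 1)")
    work = dp.copy()
    removed_probes: list[str] = []
    removed_samples: list[str] = []
    while work.shape[0] and work.shape[1]:
        unreliable = work.to_numpy() > p_threshold
        row_frac = unreliable.mean(axis=1)
        col_frac = unreliable.mean(axis=0)
        worst = max(row_frac.max(initial=0.0), col_frac.max(initial=0.0))
        if worst <= stop_fraction:
            break
        row_ids = [work.index[i] for i in np.flatnonzero(row_frac == worst)]
        if row_ids:  # probes win ties against samples
            victim = min(row_ids)
            removed_probes.append(victim)
            work = work.drop(index=victim)
        else:
            victim = min(work.columns[i] for i in np.flatnonzero(col_frac == worst))
            removed_samples.append(victim)
            work = work.drop(columns=victim)
    if work.shape[0] == 0 or work.shape[1] == 0:
        warnings.warn(
            "greedycut removed every probe or every sample: the detection-p "
            "matrix is degenerate",
            stacklevel=2,
        )
    return removed_probes, removed_samples


def filter_probes(
    bm: pd.DataFrame,
    ann: pd.DataFrame,
    dp: pd.DataFrame | None = None,
    *,
    p_threshold: float = 0.05,
    stop_fraction: float = 0.05,
    drop_unannotated: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard probe filters to a beta matrix.

    Removes, in this order of reported reason: probes with an ``rs``
    identifier (SNP control probes), probes on the X/Y chromosomes, and —
    when a detection-p matrix is supplied — probes/samples flagged by
    :func:`greedycut_like` (reason ``unreliable``).  Probes absent from the
    annotation are retained with zero gene links unless ``drop_unannotated``.
    """
    report = FilterReport(bm.shape[0], bm.shape[1])
    chrom = ann["chromosome"].reindex(bm.index)
    removed: dict[str, str] = {}
    for probe in bm.index:
        if str(probe).startswith("rs"):
            removed[probe] = "rs_identifier"
        elif chrom.get(probe) in SEX_CHROMOSOMES:
            removed[probe] = "sex_chromosome"
        elif drop_unannotated and pd.isna(chrom.get(probe)):
            removed[probe] = "unannotated"
    kept = bm.drop(index=list(removed))
    if dp is not None:
        dp_aligned = dp.reindex(index=kept.index, columns=kept.columns)
        if dp_aligned.isna().to_numpy().any():
            raise ValueError(
                "detection-p matrix does not cover every retained probe/sample"
            )
        bad_probes, bad_samples = greedycut_like(
            dp_aligned, p_threshold=p_threshold, stop_fraction=stop_fraction
        )
        for probe in bad_probes:
            removed[probe] = "unreliable"
        kept = kept.drop(index=bad_probes, columns=bad_samples)
        report.removed_samples = list(bad_samples)
    report.removed_probes = sorted(removed.items())
    return kept, report
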