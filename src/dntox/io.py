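"""Reading and writing of plate time-series tables, pathway maps and networks.

The canonical on-disk form of a live-cell-array experiment is a long
(tidy) table with one row per (well, treatment, time point) and columns

    plate, well, role, gene, od, treatment, time, value

Roles are ``promoter`` (a promoter-GFP fusion strain), ``promoterless``
(reporter plasmid without a promoter; measures autofluorescence) and
``empty`` (no cells; sets detection cutoffs).  Networks are exported as
Cytoscape-style SIF files or as TSV edge lists with a strength column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord",
    "LcaExperiment",
    "PathwayMap",
    "REQUIRED_COLUMNS",
    "SIF_RELATIONS",
    "read_lca_table",
    "write_lca_table",
    "read_pathway_map",
    "write_network",
    "read_network",
]

ROLES = ("promoter", "promoterless", "empty")
REQUIRED_COLUMNS = ("plate", "well", "role", "gene", "od", "treatment", "time", "value")

#: relation vocabulary used in SIF exports
SIF_RELATIONS = (
    "stimulates", "inhibits",
    "gained_stimulates", "gained_inhibits",
    "lost_stimulates", "lost_inhibits",
)


@dataclass
class WellRecord:
    """One plate well: role, optional gene, pre-treatment OD and the
    fluorescence series of every treatment."""

    plate_id: str
    well_id: str
    role: str
    gene: str | None = None
    od: float | None = None
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"well {self.well_id}: unknown role {self.role!r}")
        if self.role == "promoter" and not self.gene:
            raise ValidationError(f"well {self.well_id}: promoter well without a gene")
        if self.role != "promoter" and self.gene:
            raise ValidationError(f"well {self.well_id}: role {self.role} must not carry a gene")
        if self.role != "empty" and (self.od is None or not self.od > 0):
            raise ValidationError(f"well {self.well_id}: non-empty well needs od > 0, got {self.od}")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}


@dataclass
class LcaExperiment:
    """A complete plate experiment: wells x time points x treatments."""

    wells: list[WellRecord]
    treatments: list[tuple[str, float]]       # (label, concentration), control first
    time_points: np.ndarray

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.validate()

    # -- accessors --------------------------------------------------------
    def treatment_labels(self) -> list[str]:
        return [label for label, _ in self.treatments]

    def concentration(self, label: str) -> float:
        return dict(self.treatments)[label]

    def control_label(self) -> str:
        return self.treatments[0][0]

    def wells_by_role(self, role: str) -> list[WellRecord]:
        return [w for w in self.wells if w.role == role]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if np.any(np.diff(self.time_points) <= 0):
            raise ValidationError("time points must be strictly increasing")
        T = len(self.time_points)
        if T < 3:
            raise ValidationError(f"need at least 3 time points, got {T}")
        concs = [c for _, c in self.treatments]
        if sum(1 for c in concs if c == 0) != 1:
            raise ValidationError("exactly one treatment must have concentration 0 (control)")
        if self.treatments[0][1] != 0:
            raise ValidationError("control (concentration 0) must be the first treatment")
        labels = set(self.treatment_labels())
        ragged = []
        for w in self.wells:
            if set(w.series) != labels:
                ragged.append(w.well_id)
                continue
            if any(len(v) != T for v in w.series.values()):
                ragged.append(w.well_id)
        if ragged:
            raise ValidationError(f"wells with ragged/missing series: {sorted(ragged)}")
        roles = {w.role for w in self.wells}
        if "promoterless" not in roles:
            raise ValidationError("experiment must contain at least one promoterless well")
        if "empty" not in roles:
            raise ValidationError("experiment must contain at least one empty well")


@dataclass
class PathwayMap:
    """Many-to-many gene -> pathway membership."""

    entries: list[tuple[str, str, str]]       # (pathway_id, pathway_name, gene)

    def __post_init__(self) -> None:
        seen, dedup = set(), []
        for pid, name, gene in self.entries:
            key = (pid, gene)
            if key in seen:
                continue
            seen.add(key)
            dedup.append((pid, name, gene))
        self.entries = dedup

    def pathway_ids(self) -> list[str]:
        out, seen = [], set()
        for pid, _, _ in self.entries:
            if pid not in seen:
                seen.add(pid)
                out.append(pid)
        return out

    def name_of(self, pathway_id: str) -> str:
        for pid, name, _ in self.entries:
            if pid == pathway_id:
                return name
        raise KeyError(pathway_id)

    def genes_of(self, pathway_id: str) -> set[str]:
        return {g for pid, _, g in self.entries if pid == pathway_id}

    def pathways_of(self, gene: str) -> set[str]:
        return {pid for pid, _, g in self.entries if g == gene}


# ---------------------------------------------------------------------------
# tidy LCA tables
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_lca_table(path, layout: dict[str, str] | None = None,
                   concentrations: dict[str, float] | None = None) -> LcaExperiment:
    """Read a tidy plate table into an :class:`LcaExperiment`.

    Parameters
    ----------
    path : path-like
        TSV (tab) or CSV (comma) file with a header row.
    layout : dict, optional
        Maps canonical column names (``plate``, ``well``, ...) to the
        actual column names used in the file.
    concentrations : dict, optional
        Treatment label -> numeric concentration.  When omitted, labels
        must themselves parse as numbers (the control is concentration 0).
    """
    df = _read_table(path)
    layout = layout or {}
    rename = {layout.get(c, c): c for c in REQUIRED_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    bad_roles = set(df["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown well role(s): {sorted(bad_roles)}")

    labels = list(pd.unique(df["treatment"].astype(str)))
    if concentrations is None:
        try:
            concentrations = {lab: float(lab) for lab in labels}
        except ValueError as exc:
            raise FormatError(
                "treatment labels are not numeric; supply a concentrations mapping"
            ) from exc
    unknown = set(labels) - set(map(str, concentrations))
    if unknown:
        raise FormatError(f"no concentration given for treatment(s): {sorted(unknown)}")
    treatments = sorted(((lab, float(concentrations[lab])) for lab in labels),
                        key=lambda lc: lc[1])

    time_points = np.sort(df["time"].unique().astype(float))

    wells = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=True):
        role = str(grp["role"].iloc[0])
        gene = grp["gene"].iloc[0]
        gene = None if pd.isna(gene) or gene == "" else str(gene)
        od = grp["od"].iloc[0]
        od = None if pd.isna(od) else float(od)
        series = {}
        for lab, sub in grp.groupby(grp["treatment"].astype(str)):
            sub = sub.sort_values("time")
            series[str(lab)] = sub["value"].to_numpy(dtype=float)
        wells.append(WellRecord(plate_id=str(plate), well_id=str(well), role=role,
                                gene=gene, od=od, series=series))
    return LcaExperiment(wells=wells, treatments=treatments, time_points=time_points)


def write_lca_table(experiment: LcaExperiment, path) -> None:
    """Write the canonical long-format table (inverse of :func:`read_lca_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    rows = []
    for w in experiment.wells:
        for label in experiment.treatment_labels():
            for t, v in zip(experiment.time_points, w.series[label]):
                rows.append({
                    "plate": w.plate_id, "well": w.well_id, "role": w.role,
                    "gene": w.gene if w.gene is not None else "",
                    "od": w.od if w.od is not None else "",
                    "treatment": label, "time": t, "value": v,
                })
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# pathway maps
# ---------------------------------------------------------------------------

def read_pathway_map(path) -> PathwayMap:
    """Read a 2- or 3-column delimited table: pathway_id[, pathway_name], gene.

    Duplicate (pathway, gene) rows are deduplicated with a log message.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"pathway map {path} is empty") from exc
    if df.empty:
        raise FormatError(f"pathway map {path} is empty")
    if df.shape[1] == 2:
        df.columns = ["pathway_id", "gene"]
        df["pathway_name"] = df["pathway_id"]
    elif df.shape[1] == 3:
        df.columns = ["pathway_id", "pathway_name", "gene"]
    else:
        raise FormatError(f"pathway map must have 2 or 3 columns, got {df.shape[1]}")
    entries = list(df[["pathway_id", "pathway_name", "gene"]].itertuples(index=False, name=None))
    n_dup = len(entries) - len({(p, g) for p, _, g in entries})
    if n_dup:
        logger.info("pathway map %s: deduplicated %d repeated (pathway, gene) rows", path, n_dup)
    return PathwayMap(entries=entries)


def write_pathway_map(pmap: PathwayMap, path) -> None:
    pd.DataFrame(pmap.entries, columns=["pathway_id", "pathway_name", "gene"]).to_csv(
        path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _edge_rows(edges):
    """Yield (source, target, sign, status, strength) from an EdgeSet or a
    DifferentialNetwork."""
    if hasattr(edges, "gained"):        # DifferentialNetwork
        for e in edges.gained:
            yield e.source, e.target, e.sign, "gained", e.strength
        for e in edges.lost:
            yield e.source, e.target, e.sign, "lost", e.strength
    else:
        for e in edges:
            yield e.source, e.target, e.sign, "", e.strength


def _relation(sign: int, status: str) -> str:
    base = "stimulates" if sign >= 0 else "inhibits"
    return f"{status}_{base}" if status else base


def write_network(edges, path, format: str = "sif") -> None:
    """Export an edge set or differential network.

    ``sif``: one line per edge, ``source <relation> target`` with relation
    drawn from :data:`SIF_RELATIONS`.  ``tsv``: header plus a strength
    column.
    """
    path = Path(path)
    if format == "sif":
        lines = [f"{s}\t{_relation(sign, status)}\t{t}"
                 for s, t, sign, status, _ in _edge_rows(edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "tsv":
        rows = [{"source": s, "target": t, "relation": _relation(sign, status),
                 "strength": strength}
                for s, t, sign, status, strength in _edge_rows(edges)]
        pd.DataFrame(rows, columns=["source", "target", "relation", "strength"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network(path, format: str = "sif"):
    """Re-parse an exported network into (source, target, sign, status[, strength])
    tuples; the inverse of :func:`write_network` up to edge ordering."""
    path = Path(path)
    out = []

    def decode(rel: str) -> tuple[int, str]:
        if rel not in SIF_RELATIONS:
            raise FormatError(f"unknown relation token {rel!r}")
        status, _, base = rel.rpartition("_") if "_" in rel else ("", "", rel)
        return (1 if base == "stimulates" else -1), status

    if format == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            s, rel, t = line.split("\t")
            sign, status = decode(rel)
            out.append((s, t, sign, status))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            sign, status = decode(row.relation)
            out.append((row.source, row.target, sign, status, float(row.strength)))
    else:
        raise FormatError(f"unknown network format {format!r}")
    return out
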