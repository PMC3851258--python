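"""Pathway perturbation degree, concentration-response and toxicity threshold.

A pathway's perturbation degree at an exposure concentration is the
arithmetic mean, over its differentially expressed member genes, of each
gene's fraction of changed network edges at that concentration.  A
pathway responds to the chemical in a concentration-dependent manner when
its degree at the high concentration strictly exceeds the degrees at both
the mid and the low concentrations.  The toxicity threshold is the
largest tested concentration at which no responsive pathway is perturbed
relative to the control; if perturbation is already present at the lowest
tested concentration, the threshold lies below the tested range and the
sentinel :data:`BELOW_LOWEST` is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .diffnet import GeneEdgeStats
from .errors import ConfigurationError, ParameterError
from .io import PathwayMap

__all__ = [
    "PathwayPerturbation",
    "ThresholdResult",
    "BELOW_LOWEST",
    "map_genes_to_pathways",
    "perturbation_degree",
    "pathway_perturbation_table",
    "concentration_response_pathways",
    "toxicity_threshold",
    "load_reference_degrees",
]

#: sentinel returned when perturbation exists already at the lowest tested dose
BELOW_LOWEST = "below lowest tested"


@dataclass
class PathwayPerturbation:
    pathway_id: str
    pathway_name: str
    genes: set[str]
    degree: dict[float, float]        # concentration -> degree in [0, 1]


@dataclass
class ThresholdResult:
    responsive_pathways: list[str]
    threshold: float | str            # a tested concentration or BELOW_LOWEST


def map_genes_to_pathways(genes: set[str], pmap: PathwayMap
                          ) -> tuple[dict[str, set[str]], set[str]]:
    """Intersect each pathway's membership with ``genes``.

    Returns (pathway_id -> member genes, unmapped genes); pathways with an
    empty intersection are omitted.
    """
    mapping = {}
    for pid in pmap.pathway_ids():
        members = pmap.genes_of(pid) & set(genes)
        if members:
            mapping[pid] = members
    mapped = set().union(*mapping.values()) if mapping else set()
    return mapping, set(genes) - mapped


def perturbation_degree(pathway_genes: set[str], pct_change: dict[str, float]) -> float:
    """Mean fraction of changed edges over the pathway's genes."""
    if not pathway_genes:
        raise ParameterError("perturbation degree is undefined for an empty gene set")
    return sum(pct_change[g] for g in pathway_genes) / len(pathway_genes)


def pathway_perturbation_table(
    filtered_genes: set[str],
    stats_by_conc: dict[float, dict[str, GeneEdgeStats]],
    pmap: PathwayMap,
) -> tuple[list[PathwayPerturbation], set[str]]:
    """Per-pathway degrees at every exposure concentration.

    ``stats_by_conc`` maps each non-control concentration to the per-gene
    edge statistics of that treatment's differential network.
    """
    mapping, unmapped = map_genes_to_pathways(filtered_genes, pmap)
    table = []
    for pid, members in mapping.items():
        degree = {
            conc: perturbation_degree(members, {g: s.pct_change for g, s in stats.items()})
            for conc, stats in stats_by_conc.items()
        }
        table.append(PathwayPerturbation(
            pathway_id=pid, pathway_name=pmap.name_of(pid),
            genes=members, degree=degree,
        ))
    return table, unmapped


def concentration_response_pathways(
    perturbations: list[PathwayPerturbation],
    concentrations: tuple[float, float, float],
) -> list[PathwayPerturbation]:
    """Pathways whose degree at the high concentration strictly exceeds the
    degrees at both the mid and the low concentrations."""
    low, mid, high = concentrations
    if not (low < mid < high):
        raise ParameterError("concentrations must be ordered low < mid < high")
    kept = []
    for p in perturbations:
        missing = [c for c in (low, mid, high) if c not in p.degree]
        if missing:
            raise ConfigurationError(
                f"pathway {p.pathway_id} lacks degrees at concentration(s) {missing}")
        if p.degree[high] > p.degree[mid] and p.degree[high] > p.degree[low]:
            kept.append(p)
    return kept


def toxicity_threshold(responsive: list[PathwayPerturbation],
                       concentrations: list[float],
                       epsilon: float = 0.0) -> ThresholdResult:
    """Largest tested concentration up to which no responsive pathway is
    perturbed beyond ``epsilon``.

    ``concentrations`` must be sorted ascending with the control (0)
    first.  If a responsive pathway is perturbed already at the lowest
    non-control concentration, the threshold is below the tested range.
    With no responsive pathways the highest tested concentration is
    returned.
    """
    if not concentrations or concentrations[0] != 0:
        raise ParameterError("concentrations must start with the control (0)")
    tested = [c for c in concentrations[1:]]
    if sorted(tested) != tested:
        raise ParameterError("concentrations must be sorted ascending")
    ids = [p.pathway_id for p in responsive]
    if not responsive or not tested:
        return ThresholdResult(responsive_pathways=ids,
                               threshold=tested[-1] if tested else 0.0)
    threshold: float | str = BELOW_LOWEST
    for c in tested:
        perturbed = any(p.degree.get(c, 0.0) > epsilon for p in responsive)
        if perturbed:
            break
        threshold = c
    return ThresholdResult(responsive_pathways=ids, threshold=threshold)


def load_reference_degrees() -> list[PathwayPerturbation]:
    """Perturbation degrees reported for the E. coli naphthenic-acid
    exposure case study (10/100/1000 mg/L), shipped as package data."""
    with resources.files("dntox.data").joinpath("nas_pathway_degrees.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        genes = {g.strip() for g in str(row.genes).split(",")}
        out.append(PathwayPerturbation(
            pathway_id=row.pathway_id, pathway_name=row.pathway_name,
            genes=genes,
            degree={10.0: float(row.low), 100.0: float(row.mid), 1000.0: float(row.high)},
        ))
    return out


def perturbation_report(perturbations: list[PathwayPerturbation],
                        concentrations: tuple[float, float, float]) -> pd.DataFrame:
    """Tabular report: pathway, degree per concentration (2 decimals in the
    formatted columns), member genes and count."""
    low, mid, high = concentrations
    rows = [{
        "pathway_id": p.pathway_id,
        "pathway_name": p.pathway_name,
        "low": round(p.degree[low], 2),
        "mid": round(p.degree[mid], 2),
        "high": round(p.degree[high], 2),
        "genes": ", ".join(sorted(p.genes)),
        "n_genes": len(p.genes),
    } for p in perturbations]
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "low", "mid",
                                       "high", "genes", "n_genes"])
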