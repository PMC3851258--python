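"""Differential edges between a treatment network and the control network.

An edge's identity is its ordered (source, target) pair; sign and
strength are ignored for presence by default (an edge that flips from
stimulatory to inhibitive is not counted as differential unless
``sign_sensitive`` is requested).  Gained edges are present in the
treatment network but absent in the control; lost edges the reverse.

Per gene, the fraction of changed incident edges is

    pct_change = (n_gained + n_lost) / (n_control + n_treatment)

where the denominator sums the gene's incident edges over both networks
(edges present in both count twice), so complete turnover gives exactly
1.0 and a disconnected gene 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import Edge, EdgeSet

__all__ = [
    "DifferentialNetwork",
    "GeneEdgeStats",
    "differential_edges",
    "gene_edge_stats",
    "all_gene_edge_stats",
    "filter_genes_by_differential_edges",
    "summarize_differential_networks",
]


@dataclass
class DifferentialNetwork:
    treatment: str
    gained: list[Edge]
    lost: list[Edge]

    def gained_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.gained}

    def lost_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.lost}

    @property
    def n_differential(self) -> int:
        return len(self.gained) + len(self.lost)


@dataclass(frozen=True)
class GeneEdgeStats:
    gene: str
    treatment: str
    n_control: int
    n_treatment: int
    n_gained: int
    n_lost: int

    @property
    def pct_change(self) -> float:
        denom = self.n_control + self.n_treatment
        return (self.n_gained + self.n_lost) / denom if denom else 0.0


def _edge_key(edge: Edge, sign_sensitive: bool):
    return (edge.source, edge.target, edge.sign) if sign_sensitive else edge.pair


def differential_edges(control: EdgeSet, treated: EdgeSet,
                       sign_sensitive: bool = False) -> DifferentialNetwork:
    """Edges gained and lost from the control network to the treated one."""
    ckeys = {_edge_key(e, sign_sensitive) for e in control}
    tkeys = {_edge_key(e, sign_sensitive) for e in treated}
    gained = [e for e in treated if _edge_key(e, sign_sensitive) not in ckeys]
    lost = [e for e in control if _edge_key(e, sign_sensitive) not in tkeys]
    return DifferentialNetwork(treatment=treated.network_label, gained=gained, lost=lost)


def _incident(gene: str, pairs: set[tuple[str, str]]) -> int:
    """Edges touching the gene; a self-edge counts once."""
    return sum(1 for s, t in pairs if s == gene or t == gene)


def gene_edge_stats(gene: str, control: EdgeSet, treated: EdgeSet,
                    diff: DifferentialNetwork) -> GeneEdgeStats:
    return GeneEdgeStats(
        gene=gene,
        treatment=treated.network_label,
        n_control=_incident(gene, control.pairs()),
        n_treatment=_incident(gene, treated.pairs()),
        n_gained=_incident(gene, diff.gained_pairs()),
        n_lost=_incident(gene, diff.lost_pairs()),
    )


def all_gene_edge_stats(genes, control: EdgeSet, treated: EdgeSet,
                        diff: DifferentialNetwork) -> dict[str, GeneEdgeStats]:
    cpairs, tpairs = control.pairs(), treated.pairs()
    gpairs, lpairs = diff.gained_pairs(), diff.lost_pairs()
    return {
        g: GeneEdgeStats(
            gene=g, treatment=treated.network_label,
            n_control=_incident(g, cpairs), n_treatment=_incident(g, tpairs),
            n_gained=_incident(g, gpairs), n_lost=_incident(g, lpairs),
        )
        for g in genes
    }


def filter_genes_by_differential_edges(stats_by_treatment: dict[str, dict[str, GeneEdgeStats]],
                                       min_edges: int = 4) -> set[str]:
    """Keep a gene if it has at least ``min_edges`` differential edges
    (gained + lost) in any one treatment's differential network."""
    if min_edges < 0:
        raise ValueError("min_edges must be >= 0")
    kept: set[str] = set()
    for stats in stats_by_treatment.values():
        kept |= {g for g, s in stats.items() if s.n_gained + s.n_lost >= min_edges}
    return kept


def summarize_differential_networks(diffs: dict[str, DifferentialNetwork],
                                    n_selected: int) -> dict[str, dict]:
    """Per treatment: differential-edge counts and the changed share of the
    ``n_selected`` retained edges, rounded to the nearest percent.

    When control and treatment networks are both cut to the same size,
    every lost edge is matched by a gained one, so the number of changed
    edge positions is ``|lost| = |gained| = (gained + lost) / 2``; the
    percentage reports that count relative to ``n_selected``.
    """
    if n_selected <= 0:
        raise ValueError("n_selected must be positive")
    return {
        t: {
            "n_gained": len(d.gained),
            "n_lost": len(d.lost),
            "n_differential": d.n_differential,
            "pct_of_selected": int(round(100.0 * d.n_differential / (2 * n_selected))),
        }
        for t, d in diffs.items()
    }
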