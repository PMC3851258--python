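"""End-to-end orchestration of the six pipeline stages.

preprocess -> DE detection -> per-treatment network reconstruction ->
differential networks -> pathway perturbation -> toxicity threshold.

:func:`run_pipeline` takes an experiment (read from disk or simulated),
a pathway map and a :class:`RunConfig`, runs every stage with seeds
derived deterministically from the master seed, and returns a
:class:`PipelineResult` whose :meth:`~PipelineResult.summary_lines`
mirror the counts a study report would state: DE genes per screen,
edges retained per network, differential-edge counts and percentages,
genes surviving the differential-edge filter, the pathway table and the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import de as de_mod
from . import diffnet as dn
from . import network as net
from . import pathways as pw
from .errors import ConfigurationError
from .io import LcaExperiment, PathwayMap, write_network
from .preprocess import PreprocessResult, preprocess_pipeline

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunable parameters with the canonical study defaults:
    3-point smoothing, a 2-sigma noise floor, a 1.5-fold type II cutoff,
    4N retained edges and a >= 4 differential-edge gene filter."""

    window: int = 3
    floor_multiplier: float = 2.0
    fold: float = 1.5
    pseudocount: float | None = None        # default: 2 x promoterless sd
    gp_restarts: int = 1
    k: int | None = None                    # None -> select from explained variance
    variance_threshold: float = 0.9
    em_restarts: int = 5                    # ensemble size for connectivity averaging
    max_iter: int = 10                      # short EM runs regularize the ensemble
    tol: float = 1e-4
    edge_multiplier: int = 4
    min_differential_edges: int = 4
    sign_sensitive: bool = False
    epsilon: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def subseed(self, stage: int) -> int:
        """Deterministic per-stage seed below 2**31."""
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    preprocessed: PreprocessResult
    de: de_mod.DeGeneList
    de_detail: dict
    edge_sets: dict[str, net.EdgeSet]             # top-4N per treatment label
    full_edge_sets: dict[str, net.EdgeSet]
    diffs: dict[str, dn.DifferentialNetwork]
    diff_summary: dict[str, dict]
    gene_stats: dict[str, dict[str, dn.GeneEdgeStats]]
    interconnected_genes: set[str]
    filtered_genes: set[str]
    perturbations: list[pw.PathwayPerturbation]
    unmapped_genes: set[str]
    responsive: list[pw.PathwayPerturbation]
    threshold: pw.ThresholdResult
    concentrations: dict[str, float] = field(default_factory=dict)

    def summary_lines(self) -> list[str]:
        lines = []
        labels = list(self.edge_sets)
        lines.append("== preprocessing ==")
        lines.append(f"treatments\t{len(self.concentrations)}")
        lines.append(f"promoterless_sd\t{self.preprocessed.noise.promoterless_sd:.6g}")
        lines.append("== de_detection ==")
        lines.append(f"type1_genes\t{len(self.de.type1)}")
        lines.append(f"type2_genes\t{len(self.de.type2)}")
        lines.append(f"overlap\t{len(self.de.overlap)}")
        lines.append(f"pooled_de_genes\t{len(self.de.pooled)}")
        lines.append("== reconstruction ==")
        for label in labels:
            lines.append(f"edges_selected[{label}]\t{len(self.edge_sets[label])}")
        lines.append("== differential_networks ==")
        for label, s in self.diff_summary.items():
            lines.append(f"differential_edges[{label}]\t{s['n_lost']} lost + "
                         f"{s['n_gained']} gained\t{s['pct_of_selected']}%")
        lines.append("== gene_filter ==")
        lines.append(f"interconnected_genes\t{len(self.interconnected_genes)}")
        lines.append(f"filtered_genes\t{len(self.filtered_genes)}")
        lines.append("== pathways ==")
        lines.append(f"mapped_pathways\t{len(self.perturbations)}")
        lines.append(f"unmapped_genes\t{len(self.unmapped_genes)}")
        lines.append(f"responsive_pathways\t{len(self.responsive)}")
        lines.append("== threshold ==")
        lines.append(f"toxicity_threshold\t{self.threshold.threshold}")
        return lines


def _interconnected(edge_sets: dict[str, net.EdgeSet]) -> set[str]:
    """Genes incident to at least one retained edge in any network."""
    genes: set[str] = set()
    for es in edge_sets.values():
        for e in es:
            genes.add(e.source)
            genes.add(e.target)
    return genes


def run_pipeline(experiment: LcaExperiment, pathway_map: PathwayMap,
                 config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    labels = experiment.treatment_labels()
    concs = {label: experiment.concentration(label) for label in labels}
    control = experiment.control_label()

    logger.info("stage 1/6: preprocessing")
    pre = preprocess_pipeline(experiment, window=config.window,
                              floor_multiplier=config.floor_multiplier)

    logger.info("stage 2/6: DE detection")
    de, detail = de_mod.identify_de_genes(
        pre, fold=config.fold, restarts=config.gp_restarts,
        seed=config.subseed(2), pseudocount=config.pseudocount)
    panel = sorted(de.pooled)
    if len(panel) < 3:
        raise ConfigurationError(
            f"only {len(panel)} DE genes detected; too few to reconstruct a network")

    logger.info("stage 3/6: network reconstruction over %d DE genes", len(panel))
    full_sets, edge_sets = {}, {}
    # one hidden dimension for all treatments, selected on the control, so
    # the four networks are directly comparable
    ctrl_m = pre.gene_matrices[control]
    ctrl_sub = ctrl_m.values[[ctrl_m.genes.index(g) for g in panel]]
    k = config.k or net.select_hidden_dimension(
        ctrl_sub, k_max=min(len(panel), ctrl_sub.shape[1]) - 1,
        variance_threshold=config.variance_threshold)
    subs = {}
    for label in labels:
        m = pre.gene_matrices[label]
        subs[label] = m.values[[m.genes.index(g) for g in panel]]
    conns = net.ensemble_connectivity(
        subs, panel, k=k, n_init=config.em_restarts, max_iter=config.max_iter,
        tol=config.tol, seed=config.subseed(3))
    for label in labels:
        ranked = net.rank_edges(conns[label], network_label=label)
        full_sets[label] = ranked
        edge_sets[label] = net.top_edges(ranked, multiplier=config.edge_multiplier)

    logger.info("stage 4/6: differential networks")
    treated_labels = [label for label in labels if label != control]
    diffs = {
        label: dn.differential_edges(edge_sets[control], edge_sets[label],
                                     sign_sensitive=config.sign_sensitive)
        for label in treated_labels
    }
    n_selected = len(edge_sets[control])
    diff_summary = dn.summarize_differential_networks(diffs, n_selected)
    gene_stats = {
        label: dn.all_gene_edge_stats(panel, edge_sets[control], edge_sets[label],
                                      diffs[label])
        for label in treated_labels
    }
    interconnected = _interconnected(edge_sets)
    filtered = dn.filter_genes_by_differential_edges(
        gene_stats, min_edges=config.min_differential_edges) & interconnected

    logger.info("stage 5/6: pathway mapping (%d filtered genes)", len(filtered))
    stats_by_conc = {concs[label]: gene_stats[label] for label in treated_labels}
    perturbations, unmapped = pw.pathway_perturbation_table(
        filtered, stats_by_conc, pathway_map)

    logger.info("stage 6/6: concentration response and threshold")
    exposure = sorted(concs[label] for label in treated_labels)
    if len(exposure) == 3:
        responsive = pw.concentration_response_pathways(
            perturbations, (exposure[0], exposure[1], exposure[2]))
    else:
        responsive = list(perturbations)
    threshold = pw.toxicity_threshold(responsive, [0.0] + exposure,
                                      epsilon=config.epsilon)

    return PipelineResult(
        preprocessed=pre, de=de, de_detail=detail,
        edge_sets=edge_sets, full_edge_sets=full_sets,
        diffs=diffs, diff_summary=diff_summary, gene_stats=gene_stats,
        interconnected_genes=interconnected, filtered_genes=filtered,
        perturbations=perturbations, unmapped_genes=unmapped,
        responsive=responsive, threshold=threshold, concentrations=concs,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every intermediate artifact as text tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    labels = list(result.edge_sets)
    control = min(result.concentrations, key=lambda k: result.concentrations[k])

    de_rows = []
    for gene in sorted(result.de.pooled | set(result.preprocessed.gene_matrices[control].genes)):
        row = {"gene": gene,
               "type1": int(gene in result.de.type1),
               "type2": int(gene in result.de.type2),
               "pooled": int(gene in result.de.pooled)}
        for label, scores in result.de_detail["gene_scores"].items():
            llr = {s.gene: s.llr for s in scores}.get(gene, float("nan"))
            row[f"llr[{label}]"] = llr
        de_rows.append(row)
    pd.DataFrame(de_rows).to_csv(outdir / "de_genes.tsv", sep="\t", index=False)

    for label in labels:
        write_network(result.edge_sets[label], outdir / f"network_{label}.sif", "sif")
        write_network(result.edge_sets[label], outdir / f"network_{label}.tsv", "tsv")
    for label, diff in result.diffs.items():
        write_network(diff, outdir / f"diffnet_{label}.sif", "sif")
        write_network(diff, outdir / f"diffnet_{label}.tsv", "tsv")

    stat_rows = [
        {"gene": g, "treatment": label, "n_control": s.n_control,
         "n_treatment": s.n_treatment, "n_gained": s.n_gained,
         "n_lost": s.n_lost, "pct_change": s.pct_change}
        for label, stats in result.gene_stats.items() for g, s in sorted(stats.items())
    ]
    pd.DataFrame(stat_rows).to_csv(outdir / "gene_edge_stats.tsv", sep="\t", index=False)

    exposure = sorted(c for c in result.concentrations.values() if c > 0)
    if len(exposure) == 3 and result.perturbations:
        pw.perturbation_report(result.perturbations, tuple(exposure)).to_csv(
            outdir / "pathway_perturbation.tsv", sep="\t", index=False)

    (outdir / "summary.txt").write_text("\n".join(result.summary_lines()) + "\n")
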