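"""Synthetic live-cell-array experiments with known ground truth.

The generator emulates the structure of a plate-based reporter study —
four treatments (control plus three exposure concentrations), 18 time
points at 10-minute intervals, promoter wells, promoterless background
wells and empty wells — while making the true gene network available for
benchmarking every pipeline stage.

Ground truth is defined at the gene level: a sparse signed directed
network ``W`` drives first-order vector-autoregressive promoter-activity
dynamics ``x_{t+1} = W x_t + drive``; the pair (i, j) indexes the
one-step-map entry ``W[i, j]`` and is identified with the directed edge
gene_i -> gene_j, the same orientation in which the reconstruction
module reads its connectivity matrix.  Exposure perturbs the network by
rewiring a concentration-dependent fraction of edges (removed edges are
the true lost edges, their replacements the true gained ones).  A subset
of genes is inactive (flat noise) to exercise activity detection.  The
plate layer multiplies activity by a per-well optical density, adds a
shared time-varying autofluorescence background and measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import LcaExperiment, PathwayMap, WellRecord
from .preprocess import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExpression",
    "simulate_truth",
    "simulate_expression",
    "wrap_as_lca",
    "simulate_lca_experiment",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated experiment.

    Defaults mirror a desk-scale version of the plate design: 18 samples
    at 10-minute spacing, exposure concentrations 0/10/100/1000 mg/L with
    a rewiring fraction that grows with dose, ~10% network density with
    edge weights of magnitude 0.3-0.6, measurement noise an order of
    magnitude below the unit-scale activity fluctuations, pre-treatment
    OD between 0.3 and 0.9, and a small autofluorescence background.
    """

    n_genes: int = 30
    k_hidden: int | None = None          # suggested reconstruction dimension
    n_timepoints: int = 18
    dt_minutes: float = 10.0
    treatments: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)
    edge_density: float = 0.1
    perturb_fraction: dict[float, float] = field(
        default_factory=lambda: {10.0: 0.1, 100.0: 0.2, 1000.0: 0.4})
    weight_range: tuple[float, float] = (0.3, 0.6)
    spectral_radius: float = 0.95
    drive_sd: float = 1.0                # state-noise sd (signal scale)
    obs_sd: float = 0.1                  # measurement noise on activity
    baseline: float = 8.0                # resting promoter activity of active genes
    background_level: float = 2.0        # autofluorescence level
    background_sd: float = 0.05          # background drift / well noise sd
    empty_sd: float = 0.01               # instrument noise of cell-free wells
    od_range: tuple[float, float] = (0.3, 0.9)
    active_fraction: float = 0.8
    pathway_size: int = 5
    n_promoterless: int = 4
    n_empty: int = 6
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.perturb_fraction[c] for c in sorted(self.perturb_fraction)]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ParameterError("perturb_fraction must be non-decreasing in concentration")
        if not 0 < self.edge_density <= 1:
            raise ParameterError("edge_density must be in (0, 1]")
        if self.treatments[0] != 0.0:
            raise ParameterError("first treatment must be the control (0)")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_minutes

    def labels(self) -> list[str]:
        return [format(c, "g") for c in self.treatments]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class GroundTruth:
    genes: list[str]
    active_genes: set[str]
    base_edges: dict[tuple[str, str], float]                  # (source, target) -> weight
    treatment_edges: dict[float, dict[tuple[str, str], float]]
    gene_pathways: PathwayMap

    def weight_matrix(self, concentration: float) -> np.ndarray:
        n = len(self.genes)
        idx = {g: i for i, g in enumerate(self.genes)}
        W = np.zeros((n, n))
        for (s, t), w in self.treatment_edges[concentration].items():
            W[idx[s], idx[t]] = w
        return W

    def differential_pairs(self, concentration: float) -> tuple[set, set]:
        base = set(self.base_edges)
        treat = set(self.treatment_edges[concentration])
        return treat - base, base - treat      # gained, lost


@dataclass
class SimulatedExpression:
    genes: list[str]
    times: np.ndarray
    observed: dict[str, np.ndarray]      # treatment label -> (N, T) noisy activity
    clean: dict[str, np.ndarray]         # noise-free activity

    def matrix(self, label: str) -> ExpressionMatrix:
        return ExpressionMatrix(genes=list(self.genes), times=self.times.copy(),
                                values=self.observed[label], treatment=label)


# ---------------------------------------------------------------------------

def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Sample the base network and its dose-dependent rewirings."""
    rng = config.rng(1)
    genes = config.gene_names()
    n_active = max(2, int(round(config.active_fraction * config.n_genes)))
    active_idx = sorted(rng.choice(config.n_genes, size=n_active, replace=False))
    active = [genes[i] for i in active_idx]

    pairs = [(s, t) for s in active for t in active]
    n_edges = int(round(config.edge_density * len(pairs)))
    if n_edges < 1:
        raise ParameterError("edge density too low: no edges to sample")
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)

    def draw_weight() -> float:
        lo, hi = config.weight_range
        return float(rng.choice([-1, 1]) * rng.uniform(lo, hi))

    base = {pairs[i]: draw_weight() for i in chosen}

    treatment_edges: dict[float, dict] = {0.0: dict(base)}
    for conc in config.treatments[1:]:
        frac = config.perturb_fraction.get(conc, 0.0)
        n_rewire = int(round(frac * len(base)))
        edges = dict(base)
        if n_rewire:
            remove = rng.choice(len(base), size=n_rewire, replace=False)
            base_keys = list(base)
            for i in remove:
                del edges[base_keys[i]]
            candidates = [p for p in pairs if p not in base]
            if len(candidates) < n_rewire:
                raise ParameterError("network too dense to rewire the requested fraction")
            add = rng.choice(len(candidates), size=n_rewire, replace=False)
            for i in add:
                edges[candidates[i]] = draw_weight()
        treatment_edges[conc] = edges

    blocks = [active[i:i + config.pathway_size]
              for i in range(0, len(active), config.pathway_size)]
    entries = [(f"path{b + 1:02d}", f"synthetic pathway {b + 1}", g)
               for b, block in enumerate(blocks) for g in block]
    return GroundTruth(genes=genes, active_genes=set(active), base_edges=base,
                       treatment_edges=treatment_edges,
                       gene_pathways=PathwayMap(entries=entries))


def _stabilized(W: np.ndarray, target: float) -> np.ndarray:
    rho = max(abs(np.linalg.eigvals(W)))
    if rho >= target and rho > 0:
        W = W * (target / rho)
    if max(abs(np.linalg.eigvals(W))) >= 1.0:
        raise ParameterError("dynamics remain unstable after spectral scaling")
    return W


def simulate_expression(truth: GroundTruth, config: SimulationConfig,
                        burn_in: int = 100) -> SimulatedExpression:
    """First-order autoregressive promoter-activity trajectories.

    Active genes fluctuate around a common baseline under the treatment's
    network; inactive genes sit at zero.  The stochastic drive is drawn
    once and shared across treatments — the same strains and starting
    cultures are split over the treatment plates, so conditions differ
    through the network perturbation rather than through independent
    stochastic histories (a paired design).  Measurement noise is drawn
    independently per treatment.
    """
    rng = config.rng(2)
    genes = truth.genes
    n, T = len(genes), config.n_timepoints
    active_mask = np.array([g in truth.active_genes for g in genes])
    drive = config.drive_sd * rng.standard_normal((burn_in + T, n)) * active_mask
    observed, clean = {}, {}
    for conc, label in zip(config.treatments, config.labels()):
        # the update matrix is W itself: the edge pair (i, j) indexes the
        # one-step-map entry W[i, j], the same orientation the network
        # reconstruction reads its connectivity matrix in
        M = _stabilized(truth.weight_matrix(conc), config.spectral_radius)
        x = np.zeros(n)
        for s in range(burn_in):
            x = M @ x + drive[s]
        traj = np.zeros((n, T))
        for t in range(T):
            traj[:, t] = x
            x = M @ x + drive[burn_in + t]
        sig = traj + np.where(active_mask, config.baseline, 0.0)[:, None]
        clean[label] = sig
        observed[label] = sig + config.obs_sd * rng.standard_normal((n, T))
    return SimulatedExpression(genes=list(genes), times=config.times(),
                               observed=observed, clean=clean)


def wrap_as_lca(expression: SimulatedExpression, config: SimulationConfig) -> LcaExperiment:
    """Dress the activity trajectories up as a raw plate experiment.

    Raw promoter signal is ``od * (activity + background(t)) + noise``;
    promoterless wells carry only the background, empty wells only a
    small instrument noise.  The background trace is shared across wells
    and treatments, so pooled promoterless subtraction can remove it.
    """
    rng = config.rng(3)
    T = config.n_timepoints
    labels = config.labels()
    background = config.background_level + np.cumsum(
        config.background_sd * rng.standard_normal(T))

    def noisy(shape):
        return config.background_sd * rng.standard_normal(shape)

    wells = []
    wid = 0
    for gene in expression.genes:
        for _rep in range(config.n_replicates):
            wid += 1
            od = float(rng.uniform(*config.od_range))
            series = {
                lab: od * (expression.observed[lab][expression.genes.index(gene)]
                           + background) + noisy(T)
                for lab in labels
            }
            wells.append(WellRecord(plate_id="p1", well_id=f"w{wid:04d}",
                                    role="promoter", gene=gene, od=od, series=series))
    for _ in range(config.n_promoterless):
        wid += 1
        od = float(rng.uniform(*config.od_range))
        series = {lab: od * background + noisy(T) for lab in labels}
        wells.append(WellRecord(plate_id="p1", well_id=f"w{wid:04d}",
                                role="promoterless", gene=None, od=od, series=series))
    for _ in range(config.n_empty):
        wid += 1
        series = {lab: config.empty_sd * rng.standard_normal(T) for lab in labels}
        wells.append(WellRecord(plate_id="p1", well_id=f"w{wid:04d}",
                                role="empty", gene=None, od=None, series=series))

    return LcaExperiment(
        wells=wells,
        treatments=list(zip(labels, config.treatments)),
        time_points=config.times(),
    )


def simulate_lca_experiment(config: SimulationConfig
                            ) -> tuple[LcaExperiment, GroundTruth, SimulatedExpression]:
    """Convenience wrapper: truth -> expression -> plate experiment."""
    truth = simulate_truth(config)
    expression = simulate_expression(truth, config)
    experiment = wrap_as_lca(expression, config)
    return experiment, truth, expression
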