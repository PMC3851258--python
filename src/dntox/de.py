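"""Differential-expression detection for reporter time courses.

Two complementary screens:

* **Type I (active genes).**  Each well's trajectory is scored with a
  one-sample Gaussian-process regression: the marginal log-likelihood of a
  smooth dynamic model (squared-exponential kernel plus white noise) minus
  that of a null model (constant mean plus white noise).  Wells with no
  cells ("empty" wells) are scored identically and their maximum score per
  treatment is the detection cutoff — a gene is active if it beats the
  empty-well maximum in at least one treatment.

* **Type II (between-treatment).**  Per gene, a least-squares linear trend
  is fitted to the control and the treated series; the gene qualifies if
  the fitted values differ by at least a 1.5-fold ratio at one or more
  time points, for at least one treated concentration.

The two gene sets are pooled (union) into the final DE list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import ConfigurationError, ParameterError
from .preprocess import ExpressionMatrix, PreprocessResult

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScore",
    "DeGeneList",
    "gp_llr_score",
    "score_matrix",
    "select_active_genes",
    "fold_change_de",
    "pool_de_genes",
    "identify_de_genes",
]


@dataclass(frozen=True)
class GeneScore:
    """Per-treatment activity score of one gene or well."""

    gene: str
    treatment: str
    llr: float
    rank: int = 0


@dataclass
class DeGeneList:
    type1: set[str]
    type2: set[str]

    @property
    def pooled(self) -> set[str]:
        return self.type1 | self.type2

    @property
    def overlap(self) -> set[str]:
        return self.type1 & self.type2


# ---------------------------------------------------------------------------
# type I: Gaussian-process activity score
# ---------------------------------------------------------------------------

def _null_loglik(y: np.ndarray) -> float:
    """Maximized log-likelihood of iid N(mean, var) with both at their MLEs."""
    n = y.size
    var = float(np.mean((y - y.mean()) ** 2))
    var = max(var, 1e-12)
    return -0.5 * n * (np.log(2 * np.pi * var) + 1.0)


def gp_llr_score(series: np.ndarray, times: np.ndarray,
                 restarts: int = 2, seed: int = 0) -> float:
    """Marginal log-likelihood ratio of a smooth GP versus a flat null.

    The dynamic model is a zero-mean GP over the centered series with
    kernel ``amplitude * RBF(lengthscale) + WhiteKernel(noise)``; the
    lengthscale is bounded below by twice the sampling interval so the
    smooth component cannot mimic point-to-point noise.  The null model is
    a constant mean with iid Gaussian noise, both at their maximum
    likelihood.  Scores are invariant to adding a constant to the series.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size != t.size or y.size < 4:
        raise ParameterError("series and times must share length >= 4")
    if not np.all(np.isfinite(y)):
        raise ParameterError("series contains non-finite values")
    yc = y - y.mean()
    if np.ptp(yc) == 0.0:
        return 0.0
    var = float(np.mean(yc ** 2))
    dt = float(np.median(np.diff(t)))
    span = float(t[-1] - t[0])
    kernel = (
        ConstantKernel(var, (var * 1e-3, var * 1e3))
        * RBF(length_scale=span / 4, length_scale_bounds=(2 * dt, 10 * span))
        + WhiteKernel(noise_level=var / 2, noise_level_bounds=(var * 1e-6, var * 10))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        optimizer="fmin_l_bfgs_b",
        n_restarts_optimizer=max(restarts - 1, 0),
        normalize_y=False,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # hyperparameters hitting their bounds is expected for noise-only
        # or near-degenerate series and is the intended regularization
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(t.reshape(-1, 1), yc)
    return float(gp.log_marginal_likelihood_value_ - _null_loglik(yc))


def score_matrix(matrix: ExpressionMatrix, restarts: int = 2, seed: int = 0) -> list[GeneScore]:
    """GP-score every row of a matrix and rank within the treatment
    (rank 1 = highest log-likelihood ratio)."""
    llrs = [
        gp_llr_score(matrix.values[i], matrix.times, restarts=restarts, seed=seed)
        for i in range(len(matrix.genes))
    ]
    order = np.argsort([-v for v in llrs], kind="stable")
    ranks = np.empty(len(llrs), dtype=int)
    ranks[order] = np.arange(1, len(llrs) + 1)
    return [
        GeneScore(gene=g, treatment=matrix.treatment, llr=llrs[i], rank=int(ranks[i]))
        for i, g in enumerate(matrix.genes)
    ]


def select_active_genes(scores: dict[str, list[GeneScore]],
                        empty_scores: dict[str, list[float]]) -> set[str]:
    """Genes whose score strictly exceeds the empty-well maximum in at
    least one treatment (ties are excluded)."""
    active: set[str] = set()
    for treatment, treat_scores in scores.items():
        if treatment not in empty_scores or not empty_scores[treatment]:
            raise ConfigurationError(f"no empty-well scores for treatment {treatment!r}")
        cutoff = max(empty_scores[treatment])
        active |= {s.gene for s in treat_scores if s.llr > cutoff}
    return active


# ---------------------------------------------------------------------------
# type II: fold-change screen
# ---------------------------------------------------------------------------

def _fitted_trend(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(times, values, 1)
    return slope * times + intercept


def fold_change_de(control: ExpressionMatrix, treated: ExpressionMatrix,
                   fold: float = 1.5, pseudocount: float = 1e-6) -> set[str]:
    """Genes whose fitted linear trends differ by >= ``fold`` (or <= 1/fold)
    at one or more time points between control and one treated condition.

    Fitted values are clipped at zero before the pseudocount is added so
    the ratio is stable when a trend dips below the noise floor.
    """
    if fold <= 1:
        raise ParameterError(f"fold cutoff must exceed 1, got {fold}")
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    if control.genes != treated.genes:
        raise ParameterError("control and treated matrices must share genes")
    selected = set()
    for i, gene in enumerate(control.genes):
        fc = np.clip(_fitted_trend(control.values[i], control.times), 0, None) + pseudocount
        ft = np.clip(_fitted_trend(treated.values[i], treated.times), 0, None) + pseudocount
        ratio = ft / fc
        if np.any(ratio >= fold) or np.any(ratio <= 1.0 / fold):
            selected.add(gene)
    return selected


def pool_de_genes(type1: set[str], type2: set[str]) -> DeGeneList:
    """Union of the two screens; sizes and overlap are logged."""
    out = DeGeneList(type1=set(type1), type2=set(type2))
    logger.info("DE pooling: %d type I, %d type II, %d overlap -> %d pooled",
                len(out.type1), len(out.type2), len(out.overlap), len(out.pooled))
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def identify_de_genes(pre: PreprocessResult, fold: float = 1.5,
                      restarts: int = 2, seed: int = 0,
                      pseudocount: float | None = None) -> tuple[DeGeneList, dict]:
    """Run both screens on a preprocessing result.

    Promoter wells are scored individually and collapsed to genes by the
    maximum score over replicate wells; empty wells provide the per
    treatment cutoffs.  Returns the pooled list and a detail dict with the
    per-treatment scores.
    """
    if pseudocount is None:
        pseudocount = max(2.0 * pre.noise.promoterless_sd, 1e-9)

    well_scores = {t: score_matrix(m, restarts=restarts, seed=seed)
                   for t, m in pre.well_matrices.items()}
    gene_scores: dict[str, list[GeneScore]] = {}
    for t, scores in well_scores.items():
        best: dict[str, float] = {}
        for s in scores:
            gene = pre.well_genes[s.gene]
            best[gene] = max(best.get(gene, -np.inf), s.llr)
        gene_scores[t] = [GeneScore(gene=g, treatment=t, llr=v)
                          for g, v in sorted(best.items())]
    empty_scores = {
        t: [gp_llr_score(m.values[i], m.times, restarts=restarts, seed=seed)
            for i in range(len(m.genes))]
        for t, m in pre.empty_matrices.items()
    }
    type1 = select_active_genes(gene_scores, empty_scores)

    control = pre.treatments[0]
    type2: set[str] = set()
    for t in pre.treatments[1:]:
        type2 |= fold_change_de(pre.gene_matrices[control], pre.gene_matrices[t],
                                fold=fold, pseudocount=pseudocount)

    de = pool_de_genes(type1, type2)
    return de, {"gene_scores": gene_scores, "empty_scores": empty_scores,
                "well_scores": well_scores}
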