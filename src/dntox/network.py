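"""Gene-interaction network reconstruction with a hidden-state linear dynamical model.

The observed gene-expression time series ``y_t`` (N genes) are modelled as a
linear projection of a low-dimensional hidden state ``x_t`` (k < N)::

    x_{t+1} = A x_t + w_t,   w_t ~ N(0, Q)
    y_t     = C x_t + v_t,   v_t ~ N(0, diag(R))
    x_1     ~ N(mu0, V0)

Parameters are estimated by expectation-maximization: the E-step runs a
Kalman filter and Rauch-Tung-Striebel smoother, the M-step uses the
closed-form updates of Shumway & Stoffer / Ghahramani & Hinton.  The fitted
model induces a one-step gene-level map ``D = C A C+`` (``C+`` the
Moore-Penrose pseudoinverse) whose entry ``D[i, j]`` is read as the signed
confidence of a directed interaction from gene ``i`` to gene ``j``:
positive entries are stimulatory, negative inhibitive, and the absolute
value is the edge strength used for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import pinv, slogdet
from scipy import linalg

from .errors import NumericalError, ParameterError
from .preprocess import ExpressionMatrix

__all__ = [
    "StateSpaceModel",
    "ConnectivityMatrix",
    "Edge",
    "EdgeSet",
    "fit_state_space",
    "initialize_state_space",
    "ensemble_connectivity",
    "select_hidden_dimension",
    "connectivity_matrix",
    "rank_edges",
    "top_edges",
]


@dataclass
class StateSpaceModel:
    """Fitted latent linear dynamical system."""

    k: int
    A: np.ndarray          # (k, k) state transition
    C: np.ndarray          # (N, k) observation loading
    Q: np.ndarray          # (k, k) state-noise covariance
    R: np.ndarray          # (N,) diagonal observation-noise variances
    mu0: np.ndarray        # (k,) initial state mean
    V0: np.ndarray         # (k, k) initial state covariance
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_genes(self) -> int:
        return self.C.shape[0]


@dataclass
class ConnectivityMatrix:
    """Signed N x N confidence matrix; rows are source genes, columns targets."""

    genes: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.genes), len(self.genes)):
            raise ValidationShapeError(self.D.shape, len(self.genes))


class ValidationShapeError(ParameterError):
    def __init__(self, shape, n):
        super().__init__(f"connectivity matrix shape {shape} does not match {n} genes")


@dataclass(frozen=True)
class Edge:
    """A directed, signed, ranked interaction between two genes."""

    source: str
    target: str
    sign: int              # +1 stimulatory, -1 inhibitive
    strength: float        # |confidence|
    rank: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class EdgeSet:
    """Ranked directed edges of one reconstructed network."""

    edges: list[Edge]
    network_label: str = ""

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}


# ---------------------------------------------------------------------------
# EM for the linear dynamical system
# ---------------------------------------------------------------------------

def _as_matrix(expr) -> np.ndarray:
    if isinstance(expr, ExpressionMatrix):
        return np.asarray(expr.values, dtype=float)
    return np.asarray(expr, dtype=float)


def _init_params(Y: np.ndarray, k: int, rng: np.random.Generator,
                 jitter_scale: float = 0.0) -> StateSpaceModel:
    """PCA-based initialization: C from the leading left singular vectors,
    A by least squares on the projected states, noise from residuals."""
    N, T = Y.shape
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    C = U[:, :k].copy()
    if jitter_scale > 0:
        C = C + jitter_scale * rng.standard_normal(C.shape)
    X = C.T @ Y                                    # (k, T) projected states
    A = X[:, 1:] @ pinv(X[:, :-1])
    rx = X[:, 1:] - A @ X[:, :-1]
    Q = rx @ rx.T / max(T - 1, 1)
    Q += 1e-6 * np.trace(Q) / k * np.eye(k) + 1e-9 * np.eye(k)
    ry = Y - C @ X
    scale = float(np.mean(Y * Y)) + 1e-12
    R = np.maximum(np.mean(ry * ry, axis=1), 1e-8 * scale)
    mu0 = X[:, 0].copy()
    V0 = Q.copy()
    return StateSpaceModel(k=k, A=A, C=C, Q=Q, R=R, mu0=mu0, V0=V0)


def _e_step(Y: np.ndarray, m: StateSpaceModel):
    """Kalman filter + RTS smoother.

    Returns the log-likelihood and the smoothed sufficient statistics:
    means ``xs`` (k, T), covariances ``Vs`` (T, k, k) and lag-one
    cross-covariances ``Vlag[t] = Cov(x_{t+1}, x_t | Y)`` (T-1, k, k).
    """
    N, T = Y.shape
    k = m.k
    A, C, Q, R = m.A, m.C, m.Q, m.R
    I_k = np.eye(k)

    xf = np.zeros((k, T))      # filtered means
    Vf = np.zeros((T, k, k))   # filtered covariances
    xp = np.zeros((k, T))      # one-step-ahead predicted means
    Vp = np.zeros((T, k, k))
    Ks = np.zeros((T, k, N))
    ll = 0.0

    for t in range(T):
        if t == 0:
            xpred = m.mu0
            Vpred = m.V0
        else:
            xpred = A @ xf[:, t - 1]
            Vpred = A @ Vf[t - 1] @ A.T + Q
        Vpred = 0.5 * (Vpred + Vpred.T)
        xp[:, t] = xpred
        Vp[t] = Vpred

        S = C @ Vpred @ C.T + np.diag(R)
        S = 0.5 * (S + S.T) + 1e-12 * np.eye(N)
        innov = Y[:, t] - C @ xpred
        try:
            cho = linalg.cho_factor(S, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalError(f"innovation covariance not PD at t={t}") from exc
        sign, logdet = slogdet(S)
        if sign <= 0 or not np.isfinite(logdet):
            raise NumericalError(f"non-finite innovation determinant at t={t}")
        alpha = linalg.cho_solve(cho, innov)
        ll += -0.5 * (N * np.log(2 * np.pi) + logdet + innov @ alpha)

        K = Vpred @ C.T @ linalg.cho_solve(cho, np.eye(N))
        Ks[t] = K
        xf[:, t] = xpred + K @ innov
        IKC = I_k - K @ C
        # Joseph form keeps the filtered covariance PSD
        Vf[t] = IKC @ Vpred @ IKC.T + K @ np.diag(R) @ K.T
        Vf[t] = 0.5 * (Vf[t] + Vf[t].T)

    if not np.isfinite(ll):
        raise NumericalError("non-finite log-likelihood in Kalman filter")

    xs = np.zeros((k, T))
    Vs = np.zeros((T, k, k))
    J = np.zeros((T, k, k))
    xs[:, -1] = xf[:, -1]
    Vs[-1] = Vf[-1]
    for t in range(T - 2, -1, -1):
        J[t] = Vf[t] @ A.T @ pinv(Vp[t + 1])
        xs[:, t] = xf[:, t] + J[t] @ (xs[:, t + 1] - xp[:, t + 1])
        Vs[t] = Vf[t] + J[t] @ (Vs[t + 1] - Vp[t + 1]) @ J[t].T
        Vs[t] = 0.5 * (Vs[t] + Vs[t].T)

    # lag-one covariance smoother (Shumway & Stoffer)
    Vlag = np.zeros((T - 1, k, k))
    if T > 1:
        Vlag[-1] = (I_k - Ks[-1] @ C) @ A @ Vf[-2]
        for t in range(T - 2, 0, -1):
            Vlag[t - 1] = Vf[t] @ J[t - 1].T + J[t] @ (Vlag[t] - A @ Vf[t]) @ J[t - 1].T

    return ll, xs, Vs, Vlag


def _m_step(Y: np.ndarray, m: StateSpaceModel, xs, Vs, Vlag) -> StateSpaceModel:
    N, T = Y.shape
    k = m.k
    # second-moment sums
    Ptt = Vs + np.einsum("it,jt->tij", xs, xs)           # E[x_t x_t'] per t
    S_all = Ptt.sum(axis=0)                              # sum over 1..T
    S00 = S_all - Ptt[-1]                                # 1..T-1
    S11 = S_all - Ptt[0]                                 # 2..T
    S10 = Vlag.sum(axis=0) + xs[:, 1:] @ xs[:, :-1].T    # sum E[x_t x_{t-1}']

    A = S10 @ pinv(S00)
    Q = (S11 - A @ S10.T) / max(T - 1, 1)
    Q = 0.5 * (Q + Q.T) + 1e-9 * np.eye(k)

    Syx = Y @ xs.T                                       # (N, k)
    C = Syx @ pinv(S_all)
    resid = np.einsum("ij,jt,it->i", C, xs, Y)           # diag(C * sum x y')
    R = (np.einsum("it,it->i", Y, Y) - resid) / T
    scale = float(np.mean(Y * Y)) + 1e-12
    R = np.maximum(R, 1e-10 * scale)

    mu0 = xs[:, 0].copy()
    V0 = 0.5 * (Vs[0] + Vs[0].T) + 1e-9 * np.eye(k)
    return StateSpaceModel(k=k, A=A, C=C, Q=Q, R=R, mu0=mu0, V0=V0)


def initialize_state_space(expr, k: int, seed: int = 0,
                           center: bool = True) -> StateSpaceModel:
    """PCA-based starting parameters for :func:`fit_state_space`.

    Computing the initialization on data pooled across conditions and
    passing it as ``init`` to every per-condition fit correlates the
    estimation errors of the fitted networks, so that differences between
    them reflect differences in the data rather than in the starting
    point.
    """
    Y = _as_matrix(expr)
    if center:
        Y = Y - Y.mean(axis=1, keepdims=True)
    return _init_params(Y, k, np.random.default_rng(seed))


def fit_state_space(expr, k: int, max_iter: int = 100, tol: float = 1e-4,
                    seed: int = 0, restarts: int = 1, center: bool = True,
                    init: StateSpaceModel | None = None) -> StateSpaceModel:
    """Fit the latent linear dynamical system by EM.

    Parameters
    ----------
    expr : ExpressionMatrix or (N, T) array
        Preprocessed expression values, one row per gene.
    k : int
        Hidden-state dimension; must satisfy ``1 <= k < min(N, T)``.
    max_iter : int
        Maximum number of EM iterations.  ``max_iter=0`` returns the
        initialization with a single-element log-likelihood trace.
    tol : float
        Stop when the log-likelihood gain drops below this value.
    seed : int
        Seeds the initialization jitter used for restarts beyond the first.
    restarts : int
        Number of EM runs; the first starts from the plain PCA
        initialization, subsequent ones from jittered versions.  The run
        with the highest final log-likelihood is returned.
    center : bool
        Subtract each gene's temporal mean before fitting (default); the
        hidden dynamics then describe fluctuations about resting levels.
    init : StateSpaceModel, optional
        Starting parameters for the first restart (additional restarts
        jitter them); defaults to the PCA initialization of the data.
    """
    Y = _as_matrix(expr)
    N, T = Y.shape
    if T < 4:
        raise ParameterError(f"need at least 4 time points, got {T}")
    if not (1 <= k < min(N, T)):
        raise ParameterError(f"hidden dimension k={k} must satisfy 1 <= k < min(N={N}, T={T})")
    if restarts < 1:
        raise ParameterError("restarts must be >= 1")
    if center:
        # model the fluctuations about each gene's temporal mean; the
        # one-step connectivity of the centered process is the quantity
        # of interest and is unbiased by resting expression levels
        Y = Y - Y.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)

    if init is not None and (init.k != k or init.C.shape[0] != N):
        raise ParameterError("init model dimensions do not match the data and k")

    best: StateSpaceModel | None = None
    for r in range(restarts):
        if init is not None:
            model = StateSpaceModel(
                k=k, A=init.A.copy(), C=init.C.copy(), Q=init.Q.copy(),
                R=init.R.copy(), mu0=init.mu0.copy(), V0=init.V0.copy())
            if r > 0:
                model.C = model.C + 0.1 * rng.standard_normal(model.C.shape)
        else:
            model = _init_params(Y, k, rng, jitter_scale=0.0 if r == 0 else 0.1)
        trace: list[float] = []
        for it in range(max_iter + 1):
            ll, xs, Vs, Vlag = _e_step(Y, model)
            trace.append(ll)
            if it == max_iter:
                break
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
            model = _m_step(Y, model, xs, Vs, Vlag)
        model.loglik_trace = np.asarray(trace)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    return best


def select_hidden_dimension(expr, k_max: int, variance_threshold: float = 0.9) -> int:
    """Smallest hidden dimension whose principal components explain at least
    ``variance_threshold`` of the variance of the N x T data, capped at
    ``k_max``."""
    Y = _as_matrix(expr)
    N, T = Y.shape
    k_max = int(min(k_max, N - 1, T - 1))
    if k_max < 1:
        raise ParameterError("k_max must allow at least one hidden dimension")
    if variance_threshold <= 0:
        return 1
    Yc = Y - Y.mean(axis=1, keepdims=True)
    s = np.linalg.svd(Yc, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    return min(k, k_max)


def connectivity_matrix(model: StateSpaceModel, genes: list[str],
                        rcond: float = 1e-10) -> ConnectivityMatrix:
    """Signed gene-level connectivity ``D = C A C+``.

    ``D[i, j]`` is the confidence of the directed edge gene_i -> gene_j in
    the one-step gene-level map induced by the hidden dynamics; the sign
    encodes the action type (positive stimulatory, negative inhibitive) and
    the magnitude the strength.  Diagonal entries are self-to-self edges.
    """
    if len(genes) != model.n_genes:
        raise ParameterError(f"{len(genes)} gene names for a {model.n_genes}-gene model")
    D = model.C @ model.A @ pinv(model.C, rcond=rcond)
    return ConnectivityMatrix(genes=list(genes), D=D)


def ensemble_connectivity(matrices: dict[str, np.ndarray], genes: list[str],
                          k: int, n_init: int = 5, max_iter: int = 10,
                          tol: float = 1e-4, seed: int = 0,
                          ) -> dict[str, ConnectivityMatrix]:
    """Per-condition connectivity averaged over a shared initialization ensemble.

    A common set of ``n_init`` starting points is drawn from the PCA of
    the pooled (per-condition centered) data; every condition is fitted
    by a short EM run from each start and the resulting gene-level maps
    are averaged.  The confidence of an edge is thus its mean coupling
    over the ensemble — edges that persist across starts keep a large
    magnitude, unstable ones shrink.  Sharing both data pooling and the
    start set across conditions correlates the estimation errors of the
    per-condition networks, so differential comparisons between them are
    driven by differences in the data.
    """
    mats = {label: _as_matrix(m) for label, m in matrices.items()}
    pooled = np.hstack([m - m.mean(axis=1, keepdims=True) for m in mats.values()])
    rng = np.random.default_rng(seed)
    inits = [_init_params(pooled, k, rng, jitter_scale=0.0 if r == 0 else 0.1)
             for r in range(n_init)]
    out = {}
    for label, Y in mats.items():
        Ds = []
        for init in inits:
            model = fit_state_space(Y, k=k, max_iter=max_iter, tol=tol,
                                    seed=seed, init=init)
            Ds.append(connectivity_matrix(model, genes).D)
        out[label] = ConnectivityMatrix(genes=list(genes), D=np.mean(Ds, axis=0))
    return out


def rank_edges(conn: ConnectivityMatrix, network_label: str = "") -> EdgeSet:
    """All N^2 ordered gene pairs (self-edges included) ranked by decreasing
    |confidence|; ties broken lexicographically by (source, target)."""
    genes = conn.genes
    n = len(genes)
    D = conn.D
    idx = [(i, j) for i in range(n) for j in range(n)]
    idx.sort(key=lambda ij: (-abs(D[ij[0], ij[1]]), genes[ij[0]], genes[ij[1]]))
    edges = [
        Edge(
            source=genes[i],
            target=genes[j],
            sign=-1 if D[i, j] < 0 else 1,
            strength=float(abs(D[i, j])),
            rank=r + 1,
        )
        for r, (i, j) in enumerate(idx)
    ]
    return EdgeSet(edges=edges, network_label=network_label)


def top_edges(ranked: EdgeSet, multiplier: int = 4) -> EdgeSet:
    """Retain the ``multiplier * N`` strongest edges (N = number of genes).

    Mirrors the empirical rule that curated gene-interaction networks rarely
    exceed four edges per node.  If the request exceeds the N^2 available
    edges, all edges are returned.
    """
    if multiplier < 1:
        raise ParameterError("multiplier must be >= 1")
    n_genes = len({e.source for e in ranked.edges} | {e.target for e in ranked.edges})
    limit = multiplier * n_genes
    if limit >= len(ranked.edges):
        return EdgeSet(edges=list(ranked.edges), network_label=ranked.network_label)
    return EdgeSet(edges=list(ranked.edges[:limit]), network_label=ranked.network_label)
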