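"""The helix-embedding optimizer.

The model projects a log-normalized genes × cells matrix X (D × N) onto a
3-dimensional embedding Z = WᵀX with an orthonormal basis W (WᵀW = I), and
asks that the embedded cells (i) lie near a circular helix

    Ẑᵢ = (v·θᵢ, a·sin θᵢ, a·cos θᵢ),       a > 0, v > 0,

whose circular cross-section captures the cyclic part of the transcriptional
program and whose axis carries progression, and (ii) form K soft clusters
(one per cell-cycle phase). The joint objective is

    Σᵢ ‖Xᵢ − WZᵢ‖² + λ Σᵢ ‖Zᵢ − Ẑᵢ‖²
        + γ [ Σₖ Σᵢ r_{i,k} ‖Zᵢ − Yₖ‖² + σ Σᵢₖ r_{i,k} log r_{i,k} ],

minimized by alternating structure optimization: with the helix fixed every
other block has a closed form (softmax responsibilities, weighted-mean
centroids, a linear solve for Z, an orthogonal-Procrustes SVD for W), and
with those fixed the helix parameters (a, v, θ) are fit by block coordinate
descent. Every update is an exact minimizer of its block, so the objective
trace is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix, Scale

logger = logging.getLogger("helixcycle")

_EPS = 1e-8  # positivity clamp for the helix radius and slope


class DegenerateInputError(ValueError):
    """Input lacks the variation the model needs (constant matrix, etc.)."""


class ConfigurationError(ValueError):
    """Invalid model configuration for the given data."""


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the helix model.

    lam (λ) weighs helix fidelity, gam (γ) the clustering term, sigma (σ)
    the entropy temperature of the soft assignments. The defaults
    {50, 50, 0.001} are the no-ground-truth operating point; K=3 clusters
    for the three cell-cycle phases; the embedding dimension is fixed at 3
    (one axis for progression, two for the circle).
    """

    lam: float = 50.0
    gam: float = 50.0
    sigma: float = 0.001
    K: int = 3
    d: int = 3
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.gam > 0 and self.sigma > 0):
            raise ConfigurationError("lam, gam and sigma must all be positive")
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if self.d != 3:
            raise ConfigurationError("the helix model requires d = 3")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")


@dataclass
class HelixFit:
    """A fitted circular helix: radius a, slope parameter v, per-cell angles."""

    a: float
    v: float
    theta: np.ndarray          # (N,)
    Zhat: np.ndarray           # (3, N), helix evaluated at theta
    residual: float            # sum of squared distances Z - Zhat


@dataclass
class ModelState:
    """Full optimizer state after (or during) a fit."""

    config: ModelConfig
    X: np.ndarray              # (D, N) gene-centered log2 expression
    gene_means: np.ndarray     # (D,) the subtracted per-gene means
    W: np.ndarray              # (D, 3) orthonormal basis
    Z: np.ndarray              # (3, N) embedding
    helix: HelixFit
    R: np.ndarray              # (N, K) responsibilities
    Y: np.ndarray              # (3, K) centroids
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# closed-form block updates
# ---------------------------------------------------------------------------

def compute_responsibilities(Z: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Soft cluster memberships r_{i,k} ∝ exp(−‖Zᵢ−Yₖ‖²/σ).

    Computed with max-subtraction so small σ cannot overflow; exact zeros
    from underflow are lifted to the smallest positive float and rows are
    renormalized, keeping every responsibility strictly positive.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    d2 = ((Z.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(axis=2)  # (N, K)
    logits = -d2 / sigma
    logits -= logits.max(axis=1, keepdims=True)
    r = np.exp(logits)
    r = np.maximum(r, np.finfo(float).tiny)
    return r / r.sum(axis=1, keepdims=True)


def update_centroids(Z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Y = ZRΓ⁻¹: each centroid is the responsibility-weighted cell mean."""
    nk = R.sum(axis=0)
    if (nk <= 0).any():
        raise DegenerateInputError("a cluster has zero total responsibility")
    return (Z @ R) / nk


class QOperator:
    """The solve Q = [(1+λ+γ)I − γRΓ⁻¹Rᵀ]⁻¹, applied without forming Q.

    The matrix inside the brackets is symmetric positive definite: RΓ⁻¹Rᵀ is
    PSD with spectral norm ≤ 1 (Γ collects its column masses), so the
    smallest eigenvalue is at least 1+λ. For small N a Cholesky factor of
    the explicit N×N matrix is used; past `woodbury_threshold` cells the
    inverse is applied through the N×K factor R instead (Woodbury identity),
    which costs O(NK²) per solve.
    """

    def __init__(self, R: np.ndarray, lam: float, gam: float,
                 woodbury_threshold: int = 2000):
        if lam <= 0 or gam < 0:
            raise ConfigurationError("lam must be positive and gam non-negative")
        n, k = R.shape
        self.n = n
        self.c = 1.0 + lam + gam
        if gam == 0:
            # the clustering term vanishes: Q is a scaled identity
            self.use_woodbury = True
            self.R = np.zeros((n, 1))
            self.inner_cf = scipy.linalg.cho_factor(np.eye(1))
            return
        nk = R.sum(axis=0)
        if (nk <= 0).any():
            raise DegenerateInputError("a cluster has zero total responsibility")
        self.use_woodbury = n > woodbury_threshold
        if self.use_woodbury:
            # (cI − USUᵀ)⁻¹ = c⁻¹I + c⁻¹U(S⁻¹ − c⁻¹UᵀU)⁻¹Uᵀc⁻¹ with U=R, S=γΓ⁻¹
            self.R = R
            inner = np.diag(nk / gam) - (R.T @ R) / self.c
            self.inner_cf = scipy.linalg.cho_factor(inner)
        else:
            M = self.c * np.eye(n) - gam * (R / nk) @ R.T
            self.cf = scipy.linalg.cho_factor(M)

    def solve(self, B: np.ndarray) -> np.ndarray:
        """Return Q @ B for B of shape (N, ...)."""
        if self.use_woodbury:
            x = B / self.c
            t = scipy.linalg.cho_solve(self.inner_cf, self.R.T @ x)
            return x + (self.R @ t) / self.c
        return scipy.linalg.cho_solve(self.cf, B)

    def rmul(self, B: np.ndarray) -> np.ndarray:
        """Return B @ Q for B of shape (..., N); Q is symmetric."""
        return self.solve(B.T).T

    def dense(self) -> np.ndarray:
        return self.solve(np.eye(self.n))


def compute_Q(R: np.ndarray, lam: float, gam: float, **kw) -> QOperator:
    """Build the Q solve for the current responsibilities."""
    return QOperator(R, lam, gam, **kw)


def update_embedding(W: np.ndarray, X: np.ndarray, C: np.ndarray,
                     Q: QOperator, lam: float) -> np.ndarray:
    """Z = (WᵀX + λC)Q — the exact minimizer over Z with Y eliminated."""
    if C.shape != (W.shape[1], X.shape[1]):
        raise ValueError(
            f"helix points have shape {C.shape}, expected {(W.shape[1], X.shape[1])}"
        )
    return Q.rmul(W.T @ X + lam * C)


def update_basis(C: np.ndarray, Q: QOperator, X: np.ndarray) -> np.ndarray:
    """Orthogonal-Procrustes step: W maximizing tr(CQXᵀW) s.t. WᵀW = I.

    With A = CQXᵀ = UΣVᵀ (thin SVD), the maximizer is W = V_thin Uᵀ and the
    attained trace is the nuclear norm of A. Under repeated singular values
    the maximizer is not unique; whichever factorization LAPACK returns is
    accepted.
    """
    A = Q.rmul(C) @ X.T                       # (d, D)
    U, s, Vt = scipy.linalg.svd(A, full_matrices=False)
    if not np.any(s > 0):
        raise DegenerateInputError("A = CQX^T is identically zero")
    return Vt.T @ U.T                         # (D, d)


# ---------------------------------------------------------------------------
# helix fitting
# ---------------------------------------------------------------------------

def _helix_points(a: float, v: float, theta: np.ndarray) -> np.ndarray:
    return np.vstack([v * theta, a * np.sin(theta), a * np.cos(theta)])


def _theta_objective(theta, x, rho, phi, a, v):
    # per-cell part of ‖Zᵢ − Ẑᵢ‖² that depends on θᵢ (constants dropped)
    return v * v * theta * theta - 2 * x * v * theta - 2 * a * rho * np.cos(theta - phi)


def _update_theta(Z: np.ndarray, a: float, v: float, theta: np.ndarray,
                  n_grid: int = 256, newton_steps: int = 20,
                  use_grid: bool = True) -> np.ndarray:
    """Per-cell 1-D minimization: coarse grid then Newton polish.

    The grid spans two turns around xᵢ/v, the unconstrained minimizer of the
    axial term; the candidate is kept only when it beats the incoming θᵢ, so
    a warm start can never worsen the fit. With ``use_grid=False`` only the
    Newton polish runs, which keeps every θᵢ on its incoming winding — used
    during initialization where turn-jumping is a degenerate escape.
    """
    x, y, z = Z
    rho = np.hypot(y, z)
    phi = np.arctan2(y, z)
    if use_grid:
        centers = x / v
        offsets = np.linspace(-2 * np.pi, 2 * np.pi, n_grid)
        grid = centers[None, :] + offsets[:, None]          # (n_grid, N)
        vals = _theta_objective(grid, x, rho, phi, a, v)
        cand = grid[np.argmin(vals, axis=0), np.arange(Z.shape[1])]
    else:
        cand = theta.copy()
    for _ in range(newton_steps):
        g = 2 * v * v * cand - 2 * x * v + 2 * a * rho * np.sin(cand - phi)
        h = 2 * v * v + 2 * a * rho * np.cos(cand - phi)
        step = np.where(h > 1e-12, g / np.maximum(h, 1e-12), 0.0)
        step = np.clip(step, -np.pi / 2, np.pi / 2)
        new = cand - step
        improve = (_theta_objective(new, x, rho, phi, a, v)
                   <= _theta_objective(cand, x, rho, phi, a, v))
        cand = np.where(improve, new, cand)
        if np.max(np.abs(step * improve)) < 1e-14:
            break
    keep_old = (_theta_objective(theta, x, rho, phi, a, v)
                < _theta_objective(cand, x, rho, phi, a, v))
    return np.where(keep_old, theta, cand)


def _helix_residual(Z: np.ndarray, a: float, v: float, theta: np.ndarray) -> float:
    return float(((Z - _helix_points(a, v, theta)) ** 2).sum())


def fit_helix(Z: np.ndarray, warm_start: HelixFit | None = None,
              max_rounds: int = 50, tol: float = 1e-10) -> HelixFit:
    """Fit (a, v, θ) minimizing Σᵢ‖Zᵢ − Ẑᵢ‖² by block coordinate descent.

    Given θ the scale parameters have closed forms
        v = Σᵢ xᵢθᵢ / Σᵢ θᵢ²,    a = Σᵢ (yᵢ sin θᵢ + zᵢ cos θᵢ) / N,
    each clamped below at 1e-8 to honor a, v > 0; given (a, v) each θᵢ is a
    smooth 1-D problem solved by grid search plus Newton refinement. A warm
    start seeds θ, a, v and the residual never increases across rounds.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[1]
    if n < 4:
        raise ConfigurationError("helix fitting needs at least 4 cells")
    x, y, z = Z
    if warm_start is not None:
        a, v, theta = warm_start.a, warm_start.v, warm_start.theta.copy()
    else:
        a = max(_EPS, float(np.hypot(y, z).mean()))
        # initialize v by unwrapping the azimuth along the axis: on a helix
        # the unwrapped angle grows linearly in x with slope 1/v
        phi = np.arctan2(y, z)
        order = np.argsort(x, kind="stable")
        phi_un = np.empty_like(phi)
        phi_un[order] = np.unwrap(phi[order])
        var = float(np.var(phi_un))
        slope = float(np.cov(x, phi_un)[0, 1]) / var if var > 0 else 0.0
        v = slope if slope > _EPS else max(
            _EPS, float(x.std()) / (2 * np.pi) or 1.0)
        theta = phi + 2 * np.pi * np.round((x / v - phi) / (2 * np.pi))
    prev = _helix_residual(Z, a, v, theta)
    best = (a, v, theta.copy(), prev)
    for _ in range(max_rounds):
        denom = float((theta ** 2).sum())
        v_new = max(_EPS, float((x * theta).sum()) / denom) if denom > 0 else _EPS
        a_new = max(_EPS, float((y * np.sin(theta) + z * np.cos(theta)).mean()))
        # accept scale step only if it does not worsen the fit (clamps can)
        if _helix_residual(Z, a_new, v_new, theta) <= prev + 1e-15:
            a, v = a_new, v_new
        theta = _update_theta(Z, a, v, theta)
        res = _helix_residual(Z, a, v, theta)
        if res < best[3]:
            best = (a, v, theta.copy(), res)
        if abs(prev - res) < tol:
            break
        prev = res
    a, v, theta, res = best
    return HelixFit(a=a, v=v, theta=theta, Zhat=_helix_points(a, v, theta),
                    residual=res)


# ---------------------------------------------------------------------------
# objective, initialization, main loop
# ---------------------------------------------------------------------------

def evaluate_objective(state: ModelState) -> float:
    """The full objective at the current state (0·log 0 ≡ 0)."""
    X, W, Z = state.X, state.W, state.Z
    cfg = state.config
    recon = float(((X - W @ Z) ** 2).sum())
    helix = float(((Z - state.helix.Zhat) ** 2).sum())
    d2 = ((Z.T[:, None, :] - state.Y.T[None, :, :]) ** 2).sum(axis=2)
    R = state.R
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(R > 0, R * np.log(R), 0.0).sum()
    cluster = float((R * d2).sum()) + cfg.sigma * float(ent)
    return recon + cfg.lam * helix + cfg.gam * cluster


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5 ** 0.5)
    return np.column_stack([np.cos(golden * i) * np.sin(phi),
                            np.sin(golden * i) * np.sin(phi),
                            np.cos(phi)])


def _fit_helix_free(Z: np.ndarray, max_rounds: int = 12
                    ) -> tuple[float, float, np.ndarray, np.ndarray, float]:
    """Helix fit with a free center: (vθ + cx, a·sinθ + cy, a·cosθ + cz).

    Initialization helper only. The center absorbs the axial intercept and
    the circle-center displacement that mean-centering introduces, so only
    the axis direction remains for the caller to search over. Returns
    (a, v, center, θ, residual).
    """
    x, y, z = Z
    cy, cz = float(y.mean()), float(z.mean())
    phi = np.arctan2(y - cy, z - cz)
    order = np.argsort(x, kind="stable")
    phi_un = np.empty_like(phi)
    phi_un[order] = np.unwrap(phi[order])
    theta = phi_un
    a, v, cx = max(_EPS, float(np.hypot(y - cy, z - cz).mean())), 1.0, 0.0
    n = x.size
    res = np.inf
    for _ in range(max_rounds):
        var = float(np.var(theta))
        if var > 0:
            v = max(_EPS, float(np.cov(x, theta)[0, 1]) / var)
        cx = float(x.mean() - v * theta.mean())
        s, c = np.sin(theta), np.cos(theta)
        # joint LS for (a, cy, cz) given theta
        lhs = np.array([[n, s.sum(), c.sum()],
                        [s.sum(), n, 0.0],
                        [c.sum(), 0.0, n]])
        rhs = np.array([(y * s + z * c).sum(), y.sum(), z.sum()])
        try:
            a_, cy, cz = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            a_, cy, cz = a, cy, cz
        a = max(_EPS, float(a_))
        theta = _update_theta(np.vstack([x - cx, y - cy, z - cz]), a, v, theta,
                              use_grid=False)
        new_res = float(((x - v * theta - cx) ** 2
                         + (y - a * np.sin(theta) - cy) ** 2
                         + (z - a * np.cos(theta) - cz) ** 2).sum())
        if abs(res - new_res) < 1e-12:
            res = new_res
            break
        res = new_res
    return a, v, np.array([cx, cy, cz]), theta, res


def _align_to_helix(Z: np.ndarray, n_candidates: int = 64
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rotation O and translation t exposing Z as an origin-centered helix.

    The helix model places the progression axis on the first embedding
    coordinate, circle centered at the origin and phase pinned to the axial
    origin; a PCA embedding is rotated arbitrarily and mean-centering
    displaces the circle center. Candidate axis directions on a Fibonacci
    sphere are scored by a short free-center helix fit, the best rotation is
    polished by alternating helix fits with Procrustes re-rotation, and the
    fitted center becomes the translation: O @ Z − t is (near) a model-form
    helix.
    """
    best = None
    for u in _fibonacci_sphere(n_candidates):
        # complete u to an orthonormal basis (rows): axis first
        h = np.eye(3)[np.argmin(np.abs(u))]
        b1 = np.cross(u, h)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(u, b1)
        base = np.vstack([u, b1, b2])
        # the model helix has fixed handedness; a reflected copy of each
        # candidate lets mirror-handed embeddings align too
        for O in (base, np.diag([1.0, -1.0, 1.0]) @ base):
            res = _fit_helix_free(O @ Z, max_rounds=8)[4]
            if best is None or res < best[0]:
                best = (res, O)
    O = best[1]
    for _ in range(50):
        a, v, cen, theta, res = _fit_helix_free(O @ Z)
        Zhat = np.vstack([v * theta + cen[0],
                          a * np.sin(theta) + cen[1],
                          a * np.cos(theta) + cen[2]])
        ZO = O @ Z
        U, _, Vt = scipy.linalg.svd((Zhat - Zhat.mean(1, keepdims=True))
                                    @ (ZO - ZO.mean(1, keepdims=True)).T)
        O_new = (U @ Vt) @ O
        if np.allclose(O_new, O, atol=1e-12):
            O = O_new
            break
        O = O_new
    a, v, cen, theta, res = _fit_helix_free(O @ Z)
    return O, cen


def _deterministic_pca(Xc: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-d principal axes/scores of a gene-centered matrix.

    Sign convention: the largest-magnitude loading of each axis is positive,
    so the result does not depend on the SVD implementation's sign choices.
    """
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    W = U[:, :d]
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W, W.T @ Xc


def initialize_state(X: ExpressionMatrix, config: ModelConfig) -> ModelState:
    """Deterministic initialization: PCA for (W, Z), seeded k-means for Y.

    The matrix is gene-centered (the linear model WZ has no intercept, so
    per-gene means are removed and remembered); Z is the top-3 PC scores, W
    the corresponding orthonormal axes, Y the k-means centroids of the
    embedded cells, and the helix is fit once on Z.
    """
    if X.scale != Scale.log2:
        raise ConfigurationError("fit expects a log2-normalized matrix")
    vals = X.values
    d_genes, n_cells = vals.shape
    if n_cells < config.K:
        raise ConfigurationError(f"need at least K={config.K} cells, got {n_cells}")
    if d_genes < config.d:
        raise ConfigurationError(f"need at least d={config.d} genes, got {d_genes}")
    gene_means = vals.mean(axis=1)
    Xc = vals - gene_means[:, None]
    if not (Xc != 0).any():
        raise DegenerateInputError("expression matrix is constant per gene")
    W, Z = _deterministic_pca(Xc, config.d)
    O, t = _align_to_helix(Z)
    Z = O @ Z - t[:, None]
    W = W @ O.T
    # fold the translation into the centering vector: with X centered on
    # means + W t the identity Z = WᵀX still holds exactly
    gene_means = gene_means + W @ t
    Xc = vals - gene_means[:, None]
    km = KMeans(n_clusters=config.K, n_init=10, random_state=config.seed)
    km.fit(Z.T)
    Y = km.cluster_centers_.T
    helix = fit_helix(Z)
    R = compute_responsibilities(Z, Y, config.sigma)
    return ModelState(config=config, X=Xc, gene_means=gene_means, W=W, Z=Z,
                      helix=helix, R=R, Y=Y,
                      gene_ids=list(X.gene_ids), cell_ids=list(X.cell_ids))


def fit(X: ExpressionMatrix, config: ModelConfig | None = None) -> ModelState:
    """Run the alternating optimization to convergence.

    Each iteration, in order: refit the helix to the current embedding
    (warm-started), recompute responsibilities, rebuild the Q solve, update
    the basis by the Procrustes step, then the embedding, then the
    centroids. Stops when the relative objective change drops below
    ``config.tol`` or after ``config.max_iter`` iterations.
    """
    cfg = config or ModelConfig()
    if X.n_cells < max(cfg.K, 4):
        raise ConfigurationError("too few cells for helix fitting and clustering")
    state = initialize_state(X, cfg)
    obj = evaluate_objective(state)
    state.objective_trace.append(obj)
    for it in range(cfg.max_iter):
        state.helix = fit_helix(state.Z, warm_start=state.helix)
        C = state.helix.Zhat
        state.R = compute_responsibilities(state.Z, state.Y, cfg.sigma)
        Q = compute_Q(state.R, cfg.lam, cfg.gam)
        state.W = update_basis(C, Q, state.X)
        state.Z = update_embedding(state.W, state.X, C, Q, cfg.lam)
        state.Y = update_centroids(state.Z, state.R)
        new_obj = evaluate_objective(state)
        if not np.isfinite(new_obj):
            raise FloatingPointError(f"objective became non-finite at iteration {it}")
        state.objective_trace.append(new_obj)
        state.n_iter = it + 1
        if abs(obj - new_obj) <= cfg.tol * max(1.0, abs(obj)):
            state.converged = True
            break
        obj = new_obj
    # final helix consistent with the final embedding
    state.helix = fit_helix(state.Z, warm_start=state.helix)
    return state


def tune_parameters(
    X: ExpressionMatrix,
    truth_labels,
    lam_grid=(10.0, 50.0, 100.0),
    gam_grid=(10.0, 50.0, 100.0),
    sigma_grid=(0.001, 0.01, 0.1),
    base: ModelConfig | None = None,
) -> tuple[ModelConfig, dict]:
    """Coordinate-wise hyperparameter search against labeled data.

    Starting from `base` (default {λ, γ, σ} = {50, 50, 0.001}), each of λ,
    γ, σ is tuned in turn over its grid while the other two stay fixed; the
    value with the best Hungarian-matched stage-call accuracy is kept before
    moving on. Returns the tuned config and the accuracy of every probe.
    """
    from . import evalmetrics, staging

    cfg = base or ModelConfig()
    truth = np.asarray(truth_labels)
    scores: dict[tuple[float, float, float], float] = {}

    def accuracy(c: ModelConfig) -> float:
        key = (c.lam, c.gam, c.sigma)
        if key not in scores:
            state = fit(X, c)
            stages = staging.assign_stages(
                staging.extract_pseudotime(state.helix), seed=c.seed)
            report = evalmetrics.classification_metrics(
                np.asarray(stages.labels), truth)
            scores[key] = report.accuracy
        return scores[key]

    for name, grid in (("lam", lam_grid), ("gam", gam_grid),
                       ("sigma", sigma_grid)):
        best_val, best_acc = getattr(cfg, name), -1.0
        for val in grid:
            probe = ModelConfig(**{**cfg.__dict__, name: float(val)})
            acc = accuracy(probe)
            if acc > best_acc:
                best_val, best_acc = float(val), acc
        cfg = ModelConfig(**{**cfg.__dict__, name: best_val})
    return cfg, {k: v for k, v in scores.items()}
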