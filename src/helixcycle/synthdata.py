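"""Synthetic scRNA-seq generators with known ground truth.

Two generators:

``simulate_cycle``
    A 3-phase cyclic process embedded linearly in gene space. Each cell has
    an angle θ on a circular helix (vθ, a·sinθ, a·cosθ); phases occupy
    consecutive arcs whose widths match the requested phase fractions, with
    cells concentrated around mid-phase (truncated-normal within each arc).
    The 3-D helix point is mapped into log2 expression through a random
    orthonormal basis scaled so a typical gene swings by ``gene_amplitude``
    log2 units over the cycle, plus per-gene baselines and Gaussian noise,
    then exponentiated and Poisson-sampled to counts.

``simulate_cidr_like``
    Three discrete cell groups (phase surrogates), each up-regulating its
    own block of marker genes over a shared lognormal baseline, sampled
    negative-binomially and thinned by a logistic dropout model whose level
    parameter v is calibrated so v ∈ {6.5, 9, 12} yields overall
    zero-fractions near 25.6%, 51.1% and 68.8% at the default 150 cells ×
    20,180 genes design.

Dropout model: an entry with underlying log-expression u = log1p(count)
survives with probability sigmoid(s·(u − u0(v))); the midpoint u0(v) rises
with the dropout level v, so higher v drowns progressively better-expressed
entries. The slope s and the u0(v) curve were frozen by
scripts/calibrate_dropout.py.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import PHASES, ExpressionMatrix, Scale

logger = logging.getLogger("helixcycle")

# logistic dropout calibration (see scripts/calibrate_dropout.py): u0(v) is
# the monotone piecewise-linear curve through the knots below, extended with
# the end-segment slopes
DROPOUT_SLOPE = 1.0          # s: logistic steepness in log-expression units
DROPOUT_U0_KNOTS_V = (6.5, 9.0, 12.0)
DROPOUT_U0_KNOTS = (0.086576, 1.937179, 3.028808)


def _dropout_u0(dropout_level_v: float) -> float:
    """The log-expression midpoint u0(v), increasing in v."""
    kv, ku = np.asarray(DROPOUT_U0_KNOTS_V), np.asarray(DROPOUT_U0_KNOTS)
    if dropout_level_v <= kv[0]:
        slope = (ku[1] - ku[0]) / (kv[1] - kv[0])
        return float(ku[0] + slope * (dropout_level_v - kv[0]))
    if dropout_level_v >= kv[-1]:
        slope = (ku[-1] - ku[-2]) / (kv[-1] - kv[-2])
        return float(ku[-1] + slope * (dropout_level_v - kv[-1]))
    return float(np.interp(dropout_level_v, kv, ku))


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix            # counts scale
    true_theta: np.ndarray
    true_phase: list[str]
    true_basis: np.ndarray | None       # (D, 3) orthonormal (cycle generator)
    dropout_mask: np.ndarray            # (D, N) bool, True where zeroed
    params: dict = field(default_factory=dict)


def _phase_counts(n_cells: int, fractions: tuple[float, float, float]) -> np.ndarray:
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("phase_fractions must be 3 non-negative reals summing to 1")
    counts = np.floor(fr * n_cells).astype(int)
    # hand out the rounding remainder to the largest fractional parts
    rem = n_cells - counts.sum()
    order = np.argsort(-(fr * n_cells - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def simulate_cycle(
    n_genes: int = 200,
    n_cells: int = 150,
    a: float = 1.0,
    v: float = 0.5,
    noise_sd: float = 0.1,
    phase_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
    gene_amplitude: float = 1.0,
    within_phase_sd_frac: float | None = 0.3,
    baseline_log2_range: tuple[float, float] = (3.0, 8.0),
    poisson: bool = True,
) -> SyntheticDataset:
    """Simulate a cyclic 3-phase expression process on a helix.

    Phase arcs split [0, 2π) proportionally to `phase_fractions`; within
    each arc θ is truncated-normal around the arc midpoint with sd
    ``within_phase_sd_frac`` × arc width (``None`` → uniform on the arc).
    With ``poisson=False`` the returned values are the noiseless/noisy log2
    expression itself (scale ``log2``), which makes the construction exactly
    invertible: true_basisᵀ(X − baseline)/(gene_amplitude·√D) is the helix.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    counts_per_phase = _phase_counts(n_cells, phase_fractions)
    edges = 2 * np.pi * np.concatenate([[0.0], np.cumsum(phase_fractions)])
    thetas, phases = [], []
    for p, (lo, hi, m) in enumerate(zip(edges[:-1], edges[1:], counts_per_phase)):
        if m == 0:
            continue
        if within_phase_sd_frac is None:
            th = rng.uniform(lo, hi, size=m)
        else:
            mid, sd = 0.5 * (lo + hi), within_phase_sd_frac * (hi - lo)
            th = np.clip(rng.normal(mid, sd, size=m), lo, hi - 1e-9)
        thetas.append(th)
        phases += [PHASES[p]] * m
    theta = np.concatenate(thetas)
    helix = np.vstack([v * theta, a * np.sin(theta), a * np.cos(theta)])  # (3, N)

    basis, _ = np.linalg.qr(rng.standard_normal((n_genes, 3)))
    scale = gene_amplitude * np.sqrt(n_genes)
    baseline = rng.uniform(*baseline_log2_range, size=n_genes)
    log2_expr = baseline[:, None] + scale * (basis @ helix)
    if noise_sd > 0:
        log2_expr = log2_expr + rng.normal(0, noise_sd, size=log2_expr.shape)

    params = dict(n_genes=n_genes, n_cells=n_cells, a=a, v=v, noise_sd=noise_sd,
                  phase_fractions=tuple(phase_fractions), seed=seed,
                  gene_amplitude=gene_amplitude, signal_scale=scale,
                  within_phase_sd_frac=within_phase_sd_frac,
                  baseline=baseline, poisson=poisson)
    if poisson:
        values = rng.poisson(np.maximum(np.exp2(log2_expr) - 1.0, 0.0)).astype(float)
        m = ExpressionMatrix(values, scale=Scale.counts)
    else:
        m = ExpressionMatrix(log2_expr, scale=Scale.log2)
    return SyntheticDataset(
        matrix=m, true_theta=theta, true_phase=phases, true_basis=basis,
        dropout_mask=np.zeros(m.values.shape, dtype=bool), params=params,
    )


# ---------------------------------------------------------------------------
# logistic dropout
# ---------------------------------------------------------------------------

def dropout_probability(values: np.ndarray, dropout_level_v: float) -> np.ndarray:
    """Per-entry dropout probability p(u; v) for u = log1p(value).

    p = sigmoid(s·(u0(v) − u)) with u0 increasing in v: higher v raises the
    log-expression below which entries are likely lost; p → 0 as u → ∞.
    v = 0 is by convention dropout-free (u0(0) = −∞).
    """
    if dropout_level_v < 0:
        raise ValueError("dropout level v must be non-negative")
    if dropout_level_v == 0:
        return np.zeros_like(np.asarray(values, dtype=float))
    u = np.log1p(np.asarray(values, dtype=float))
    u0 = _dropout_u0(dropout_level_v)
    return 1.0 / (1.0 + np.exp(DROPOUT_SLOPE * (u - u0)))


def apply_dropout(values: np.ndarray, dropout_level_v: float, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Zero entries independently with probability p(u; v); return (matrix, mask).

    The uniform draws depend only on the seed and matrix shape, so at a
    fixed seed raising v strictly grows the set of zeroed entries.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("values must be non-negative")
    p = dropout_probability(values, dropout_level_v)
    u = np.random.default_rng(seed).random(values.shape)
    mask = (values > 0) & (u < p)
    out = values.copy()
    out[mask] = 0.0
    return out, mask


def expected_zero_fraction(values: np.ndarray, dropout_level_v: float) -> float:
    """Expected overall zero-fraction of `values` after dropout at level v."""
    values = np.asarray(values, dtype=float)
    p = dropout_probability(values, dropout_level_v)
    return float(np.mean((values == 0) | False) + np.mean(p * (values > 0)))


def dropout_level_for_rate(values: np.ndarray, target_rate: float,
                           v_max: float = 60.0, tol: float = 1e-4) -> float:
    """Find the dropout level v whose expected zero-fraction hits `target_rate`."""
    base = float(np.mean(np.asarray(values) == 0))
    if target_rate <= base:
        return 0.0
    lo, hi = 0.0, v_max
    if expected_zero_fraction(values, hi) < target_rate:
        raise ValueError(f"target rate {target_rate} unreachable below v={v_max}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_zero_fraction(values, mid) < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# CIDR-style 3-group simulation
# ---------------------------------------------------------------------------

def simulate_cidr_like(
    n_groups: int = 3,
    markers_per_group: int = 50,
    n_cells: int = 150,
    n_genes: int = 20180,
    dropout_level_v: float = 6.5,
    seed: int = 0,
    baseline_meanlog: float = 2.0,
    baseline_sdlog: float = 1.5,
    lfc_meanlog: float = 1.0,
    lfc_sdlog: float = 0.4,
    nb_size: float = 2.0,
) -> SyntheticDataset:
    """Three discrete cell groups with block markers, NB counts and dropout.

    Each group up-regulates its own `markers_per_group` genes by a lognormal
    fold change over a shared lognormal baseline mean; counts are
    Gamma–Poisson (negative binomial, size `nb_size`); dropout is applied by
    `apply_dropout` at `dropout_level_v`. Group index stands in for
    cell-cycle phase in the returned ground truth.
    """
    if dropout_level_v < 0:
        raise ValueError("dropout level v must be non-negative")
    if n_groups * markers_per_group > n_genes:
        raise ValueError("more marker genes than genes")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_groups, n_cells // n_groups)
    sizes[: n_cells % n_groups] += 1
    if n_cells % n_groups:
        logger.warning("n_cells=%d not divisible by %d groups; sizes %s",
                       n_cells, n_groups, sizes.tolist())
    group = np.repeat(np.arange(n_groups), sizes)

    log_mu = rng.normal(baseline_meanlog, baseline_sdlog, size=n_genes)
    mu = np.tile(np.exp(log_mu)[:, None], (1, n_cells))
    for g in range(n_groups):
        marker_idx = np.arange(g * markers_per_group, (g + 1) * markers_per_group)
        lfc = rng.normal(lfc_meanlog, lfc_sdlog, size=markers_per_group)
        mu[np.ix_(marker_idx, group == g)] *= np.exp(lfc)[:, None]

    lam = rng.gamma(shape=nb_size, scale=mu / nb_size)
    counts = rng.poisson(lam).astype(float)
    dropped, mask = apply_dropout(counts, dropout_level_v,
                                  seed=int(rng.integers(2 ** 31)))
    phase_names = [PHASES[g % 3] if n_groups <= 3 else f"group_{g}" for g in group]
    m = ExpressionMatrix(dropped, scale=Scale.counts)
    return SyntheticDataset(
        matrix=m, true_theta=group.astype(float), true_phase=phase_names,
        true_basis=None, dropout_mask=mask,
        params=dict(n_groups=n_groups, markers_per_group=markers_per_group,
                    n_cells=n_cells, n_genes=n_genes,
                    dropout_level_v=dropout_level_v, seed=seed,
                    baseline_meanlog=baseline_meanlog,
                    baseline_sdlog=baseline_sdlog,
                    lfc_meanlog=lfc_meanlog, lfc_sdlog=lfc_sdlog,
                    nb_size=nb_size),
    )
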