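"""From fitted helix to continuous pseudotime and discrete G1/S/G2M calls.

Pseudotime is the min–max-normalized helix angle θ (equivalently the helix
axis vθ, since v > 0). Which end of the axis is G1 is not identifiable from
the geometry alone, so an optional marker-based orientation step flips the
axis so that G2/M marker expression rises with pseudotime. Discrete stages
come from a univariate 3-component Gaussian mixture fit to pseudotime by EM;
the component with the smallest mean is G1, the middle S, the largest G2M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import PHASES, ExpressionMatrix
from .helix_core import ConfigurationError, DegenerateInputError, HelixFit

logger = logging.getLogger("helixcycle")


@dataclass
class PseudotimeResult:
    theta: np.ndarray
    pseudotime: np.ndarray     # in [0, 1]
    orientation: str = "as_fitted"   # or "reversed"


@dataclass
class StageAssignment:
    labels: list[str]                 # per cell, in {"G1", "S", "G2M"}
    component_means: np.ndarray       # sorted ascending, mapped to G1/S/G2M
    component_sds: np.ndarray
    component_weights: np.ndarray
    responsibilities: np.ndarray      # (N, 3), columns in G1/S/G2M order


def extract_pseudotime(helix: HelixFit, orientation: str = "as_fitted"
                       ) -> PseudotimeResult:
    """Min–max normalize θ (optionally reversed) onto [0, 1]."""
    theta = np.asarray(helix.theta, dtype=float)
    t = -theta if orientation == "reversed" else theta
    span = t.max() - t.min()
    if span <= 0:
        raise DegenerateInputError("all cells share the same helix angle")
    return PseudotimeResult(theta=theta, pseudotime=(t - t.min()) / span,
                            orientation=orientation)


def orient_by_markers(pt: PseudotimeResult, X: ExpressionMatrix,
                      g2m_markers: list[str]) -> PseudotimeResult:
    """Flip pseudotime if mean G2/M marker expression falls along it.

    G2/M markers peak late in the cycle, so the orientation in which their
    mean expression correlates non-negatively with pseudotime is kept.
    Missing markers (or a constant marker profile) leave the orientation
    unchanged with a warning.
    """
    idx = [i for i, g in enumerate(X.gene_ids) if g in set(g2m_markers)]
    if not idx:
        logger.warning("none of the %d markers found; orientation unchanged",
                       len(g2m_markers))
        return pt
    profile = X.values[idx].mean(axis=0)
    if np.std(profile) == 0 or np.std(pt.pseudotime) == 0:
        logger.warning("marker profile is constant; orientation unchanged")
        return pt
    r = float(np.corrcoef(profile, pt.pseudotime)[0, 1])
    if r >= 0:
        return pt
    flipped = "reversed" if pt.orientation == "as_fitted" else "as_fitted"
    return PseudotimeResult(theta=pt.theta, pseudotime=1.0 - pt.pseudotime,
                            orientation=flipped)


def _em_gmm_1d(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
               weights: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
               var_floor: float = 1e-6):
    """Plain univariate EM; returns (means, sds, weights, resp, loglik trace)."""
    n, k = x.size, means.size
    trace = []
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E step in log space
        logpdf = (-0.5 * ((x[:, None] - means) / sds) ** 2
                  - np.log(sds) - 0.5 * np.log(2 * np.pi) + np.log(weights))
        m = logpdf.max(axis=1, keepdims=True)
        p = np.exp(logpdf - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((m.ravel() + np.log(tot.ravel())).sum())
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            break
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0)
        if (nk < n * 1e-10).any():
            raise FloatingPointError("empty mixture component")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
    return means, sds, weights, resp, trace


def assign_stages(pt: PseudotimeResult, seed: int = 0) -> StageAssignment:
    """Discretize pseudotime into G1/S/G2M with a 3-component 1-D GMM.

    EM is initialized deterministically at the 1/6, 3/6 and 5/6 quantiles of
    pseudotime (equal weights, equal spreads), with a 1e-6 variance floor,
    at most 500 iterations and a 1e-8 log-likelihood tolerance. Components
    are ordered by mean and mapped to (G1, S, G2M); each cell takes the
    stage with the largest responsibility. A degenerate fit (component
    weight below 1/(10N)) triggers one jittered re-initialization before
    giving up.
    """
    x = np.asarray(pt.pseudotime, dtype=float)
    n = x.size
    if n < 3:
        raise ConfigurationError("stage assignment needs at least 3 cells")
    if x.max() - x.min() <= 0:
        raise DegenerateInputError("pseudotime is constant; no mixture to fit")
    scale = max(x.std(), 1e-3)
    means0 = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    sds0 = np.full(3, scale)
    w0 = np.full(3, 1 / 3)
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        try:
            means, sds, weights, resp, trace = _em_gmm_1d(x, means0.copy(),
                                                          sds0.copy(), w0.copy())
        except FloatingPointError:
            weights = np.zeros(3)
        if (weights >= 1.0 / (10 * n)).all():
            break
        if attempt == 0:
            logger.warning("degenerate mixture fit; retrying with jitter")
            means0 = means0 + rng.normal(0, 0.05 * scale, size=3)
        else:
            raise DegenerateInputError(
                "Gaussian mixture degenerated twice; pseudotime has no "
                "3-component structure"
            )
    order = np.argsort(means)
    resp = resp[:, order]
    labels = [PHASES[j] for j in resp.argmax(axis=1)]
    return StageAssignment(
        labels=labels,
        component_means=means[order],
        component_sds=sds[order],
        component_weights=weights[order],
        responsibilities=resp,
    )
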