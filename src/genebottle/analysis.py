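"""Post-hoc structure analyses of weight matrices.

Two questions about what compression does to learned weights:

* Dimensionality — embed each hidden unit's incoming weight vector with
  metric multidimensional scaling at a range of target dimensions and track
  Kruskal stress-1. Genome-generated weights, being the output of a small
  smooth function of neuron labels, occupy fewer effective dimensions than
  weights trained without compression: they reach any given stress level at
  no more dimensions.

* Learning-rate non-interference — fine-tuning curves of genome-initialised
  versus randomly initialised networks should be horizontal translates of one
  another ("hot start"): the genome buys starting accuracy, not a faster
  learning rate. ``align_learning_curves`` finds the translation minimising
  the mean squared discrepancy and reports the residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

__all__ = ["MdsResult", "mds_stress_curve", "kruskal_stress", "align_learning_curves"]


@dataclass
class MdsResult:
    dimensions: list
    stress: list


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson classical scaling — deterministic SMACOF initialisation."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)[None, :]


def kruskal_stress(D: np.ndarray, X: np.ndarray) -> float:
    """Stress-1: sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²) over pairs i<j."""
    d = squareform(D, checks=False)
    dhat = pdist(X)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / np.sum(d ** 2)))


def mds_stress_curve(weight_matrix: np.ndarray, dims: Sequence[int],
                     seed=None) -> MdsResult:
    """Metric-MDS stress-1 of the hidden units' incoming weight vectors at
    each embedding dimension.

    ``weight_matrix`` is (n_inputs, n_hidden): column j — the incoming
    weights of hidden unit j — is one point. Embeddings are SMACOF refinements
    of a deterministic classical-scaling start, so the curve is reproducible
    and non-increasing in dimension.
    """
    W = np.asarray(weight_matrix, dtype=np.float64)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 hidden units")
    if any(d < 1 for d in dims):
        raise ValueError("embedding dimensions must be >= 1")
    points = W.T
    D = squareform(pdist(points))
    if D.max() == 0.0:
        raise ValueError("degenerate input: all points identical")
    # stress-1 is invariant to global rescaling; normalise for conditioning
    scale = D.max()
    Dn = D / scale
    stresses = []
    for dim in sorted(dims):
        init = _classical_mds(Dn, dim)
        X, _ = smacof(Dn, n_components=dim, init=init, n_init=1,
                      metric=True, random_state=0 if seed is None else seed,
                      normalized_stress=False)
        stresses.append(kruskal_stress(Dn, X))
    return MdsResult(list(sorted(dims)), stresses)


def align_learning_curves(curve_a: Sequence[float], curve_b: Sequence[float]
                          ) -> Tuple[float, float]:
    """Horizontal shift of ``curve_b`` that best overlays it on ``curve_a``.

    Both curves are sampled on the same unit-spaced grid. Returns
    (shift, residual): ``shift`` is the offset (in grid units, interpolated)
    such that b(t + shift) ≈ a(t), found by integer grid search refined with
    bounded continuous minimisation; ``residual`` is the RMS discrepancy over
    the overlapping support. Identical curves give (0, 0); a curve delayed by
    k epochs gives shift k.
    """
    a = np.asarray(curve_a, dtype=np.float64)
    b = np.asarray(curve_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("curves must be 1-D with at least 2 samples")
    t_a = np.arange(len(a))
    t_b = np.arange(len(b))

    def residual(shift: float) -> float:
        # compare a(t) with b(t + shift) on the overlap
        lo = max(0.0, -shift)
        hi = min(len(a) - 1.0, len(b) - 1.0 - shift)
        if hi - lo < 1.0:
            return np.inf
        grid = np.linspace(lo, hi, max(int(hi - lo) + 1, 8))
        av = np.interp(grid, t_a, a)
        bv = np.interp(grid + shift, t_b, b)
        return float(np.sqrt(np.mean((av - bv) ** 2)))

    max_shift = min(len(a), len(b)) - 2
    shifts = np.arange(-max_shift, max_shift + 1)
    costs = [residual(float(s)) for s in shifts]
    best = shifts[int(np.argmin(costs))]
    lo, hi = best - 1.0, best + 1.0
    res = minimize_scalar(residual, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    shift = float(res.x) if res.fun <= residual(float(best)) else float(best)
    r = residual(shift)
    if not np.isfinite(r):
        raise ValueError("curves do not overlap after shifting")
    return shift, r
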