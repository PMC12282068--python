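"""Uniform-ish sampling of the constrained flux space by hit-and-run.

The flux polytope {v : S v = 0, lb <= v <= ub} is explored inside the null
space of the equality system: fixed coordinates (lb == ub) are pinned, a
feasible interior point is built by averaging FVA vertex solutions, and the
walk picks random null-space directions, computing the feasible chord from
the box bounds and jumping to a uniform point on it.  Every iterate therefore
satisfies S v = 0 to numerical precision and the bounds exactly.

Used to contextualize objective-based flux predictions: an unbiased picture
of what the constraints alone allow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg, sparse
from scipy.optimize import linprog

from .ecmodel import ECModel, StoichiometricModel, ValidationError

__all__ = ["FluxSample", "sample_flux_space", "flux_within_sampled_range"]

logger = logging.getLogger("morp")

_FIXED_TOL = 1e-12
_DIR_TOL = 1e-12


@dataclass
class FluxSample:
    """n x r matrix of sampled flux vectors with its column ordering and seed."""

    matrix: np.ndarray
    reaction_ids: List[str]
    seed: int
    n: int

    def column(self, rid: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rid)]

    def ranges(self) -> Dict[str, Tuple[float, float]]:
        lo = self.matrix.min(axis=0)
        hi = self.matrix.max(axis=0)
        return {rid: (float(l), float(h)) for rid, l, h in zip(self.reaction_ids, lo, hi)}


def _lp_parts(model, extra_bounds):
    net = model.base if isinstance(model, ECModel) else model
    S = net.stoich_matrix()
    lb, ub = net.bounds()
    rids = net.reaction_ids
    if extra_bounds:
        pos = {rid: j for j, rid in enumerate(rids)}
        for rid, (blo, bhi) in extra_bounds.items():
            if rid not in pos:
                raise ValidationError(f"bound references unknown reaction {rid!r}")
            lb[pos[rid]], ub[pos[rid]] = blo, bhi
    return S, lb, ub, rids


def _warmup_vertices(S, lb, ub, n) -> np.ndarray:
    """Per-coordinate min/max FVA vertices (rows); all feasible by construction."""
    b = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub))
    vertices = []
    for j in range(n):
        if ub[j] - lb[j] <= _FIXED_TOL:
            continue
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=b, bounds=bounds, method="highs")
            if res.status == 2:
                raise ValidationError("sampling: model infeasible")
            if res.status != 0:
                continue
            vertices.append(res.x)
    if not vertices:
        # every coordinate fixed: the polytope is (at most) a point
        res = linprog(np.zeros(n), A_eq=S, b_eq=b, bounds=bounds, method="highs")
        if res.status != 0:
            raise ValidationError("sampling: model infeasible")
        vertices.append(res.x)
    return np.asarray(vertices)


def sample_flux_space(
    model: Union[ECModel, StoichiometricModel],
    n: int,
    seed: int,
    thinning: int = 100,
    burn_in: Optional[int] = None,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxSample:
    """Draw ``n`` hit-and-run samples from the flux polytope.

    ``thinning`` walk steps separate recorded samples and ``burn_in`` steps
    (default 100 x the polytope dimension) precede the first one.  The walk is
    fully determined by ``seed``.  A zero-dimensional (point) polytope yields
    ``n`` copies of that point with a warning.
    """
    if n <= 0:
        raise ValidationError(f"n must be > 0, got {n}")
    if thinning < 1:
        raise ValidationError("thinning must be >= 1")
    S, lb, ub, rids = _lp_parts(model, extra_bounds)
    nr = len(rids)

    free = ub - lb > _FIXED_TOL
    # equality system: S v = 0 plus pinned coordinates
    n_fixed = int(np.sum(~free))
    if n_fixed:
        pin_rows = sparse.csr_matrix(
            (np.ones(n_fixed), (np.arange(n_fixed), np.where(~free)[0])), shape=(n_fixed, nr)
        )
        A = sparse.vstack([S, pin_rows]).toarray()
        b = np.concatenate([np.zeros(S.shape[0]), 0.5 * (lb + ub)[~free]])
    else:
        A = S.toarray()
        b = np.zeros(S.shape[0])
    A_pinv = np.linalg.pinv(A)

    def project(v: np.ndarray) -> np.ndarray:
        """Exact orthogonal projection onto {v : A v = b}."""
        return v - A_pinv @ (A @ v - b)

    vertices = _warmup_vertices(S, lb, ub, nr)
    x0 = project(vertices.mean(axis=0))

    # Directions span the affine hull of the polytope, taken from differences
    # of feasible vertices rather than the raw null space of A: coordinates
    # that are structurally blocked (zero in every feasible point although
    # their box bounds are loose) would otherwise collapse every chord.
    D = vertices - x0
    norms = np.linalg.norm(D, axis=1)
    D = D[norms > 1e-10]
    dim = int(np.linalg.matrix_rank(D)) if len(D) else 0

    if dim == 0:
        warnings.warn("flux polytope has zero dimension; returning a single point")
        mat = np.tile(np.clip(x0, lb, ub), (n, 1))
        return FluxSample(matrix=mat, reaction_ids=rids, seed=seed, n=n)

    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = 100 * dim
    total = burn_in + n * thinning
    samples = np.empty((n, nr))
    x = x0.copy()
    kept = 0
    eps = 1e-11  # stay strictly inside so chords never collapse onto a face
    for it in range(total):
        for _attempt in range(20):
            d = D.T @ rng.standard_normal(len(D))
            nd = np.linalg.norm(d)
            if nd > _DIR_TOL:
                d /= nd
                break
        t_lo, t_hi = -np.inf, np.inf
        mask = np.abs(d) > _DIR_TOL
        if mask.any():
            dd = d[mask]
            room_hi = (ub[mask] - x[mask]) / dd
            room_lo = (lb[mask] - x[mask]) / dd
            hi = np.where(dd > 0, room_hi, room_lo)
            lo = np.where(dd > 0, room_lo, room_hi)
            t_hi = hi.min()
            t_lo = lo.max()
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi - t_lo <= 0:
            continue  # degenerate chord; try a new direction next iteration
        t = rng.uniform(t_lo + eps * (t_hi - t_lo), t_hi - eps * (t_hi - t_lo))
        x = x + t * d
        if it % 256 == 255:
            x = project(x)  # cancel accumulated floating-point drift
        # guard against floating-point drift past the box
        np.clip(x, lb, ub, out=x)
        if it >= burn_in and (it - burn_in) % thinning == thinning - 1:
            samples[kept] = np.clip(project(x), lb, ub)
            kept += 1
    if kept < n:
        samples[kept:] = x  # only reachable on pathological degenerate chords
    logger.debug("sampled %d points (dim %d, burn-in %d, thinning %d)", n, dim, burn_in, thinning)
    return FluxSample(matrix=samples, reaction_ids=rids, seed=seed, n=n)


def flux_within_sampled_range(
    sample: FluxSample,
    solution,
    reaction_ids: Sequence[str],
    tol: float = 1e-9,
) -> Dict[str, bool]:
    """Per-reaction flag: does the solution's flux lie within the sampled min/max?"""
    if sample.matrix.size == 0:
        raise ValidationError("empty flux sample")
    fluxes = solution.fluxes if hasattr(solution, "fluxes") else dict(solution)
    out: Dict[str, bool] = {}
    for rid in reaction_ids:
        if rid not in sample.reaction_ids:
            raise ValidationError(f"reaction {rid!r} not in sample")
        if rid not in fluxes:
            raise ValidationError(f"reaction {rid!r} not in solution")
        col = sample.column(rid)
        v = fluxes[rid]
        out[rid] = bool(col.min() - tol <= v <= col.max() + tol)
    return out
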