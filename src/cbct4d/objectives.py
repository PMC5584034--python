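"""Objective terms of the MAP reconstruction.

Data fidelity is the negative Poisson transmission log-likelihood: with
measured counts ``n_i = n0 exp(-y_i)`` and expected line integrals
``y* = A mu``, the mu-dependent part of ``-ln P(y | mu)`` is

    ``sum_i  n_i y*_i + n0 exp(-y*_i)``

(the constants ``n_i ln n_i`` and ``ln n_i!`` are dropped).  Its
gradient is ``A^T (n - n0 exp(-y*))``.

The regularizers are the smoothed total variation ``||Psi mu||_1``
(forward differences, root smoothed by a small ``epsilon`` so the
objective stays differentiable), the prior-image constraint
``||Psi(mu - mu_prior)||_1``, and the time-chain term coupling each
phase to its temporal neighbors through the TV of difference images,
with the one-sided term doubled at the first and last phases.
"""

from __future__ import annotations

import numpy as np

from .geometry import ScanGeometry
from .projector import ProjectionSet, back_project, forward_project
from .volume import VolumeImage

__all__ = [
    "tv_norm",
    "pic_term",
    "tcgm_term",
    "neg_log_likelihood",
    "PoissonDataTerm",
]


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, VolumeImage) else np.asarray(v, float)


def _diffs(m: np.ndarray):
    dx = np.zeros_like(m)
    dy = np.zeros_like(m)
    dz = np.zeros_like(m)
    dx[:-1, :, :] = m[:-1, :, :] - m[1:, :, :]
    dy[:, :-1, :] = m[:, :-1, :] - m[:, 1:, :]
    dz[:, :, :-1] = m[:, :, :-1] - m[:, :, 1:]
    return dx, dy, dz


def tv_norm(volume, epsilon: float = 1e-8, with_grad: bool = False):
    """Smoothed total variation ``sum sqrt(dx^2 + dy^2 + dz^2 + eps)``.

    Differences are forward differences; beyond-edge differences are
    zero (each boundary voxel still contributes ``sqrt(eps)`` through
    the remaining terms).  Returns the scalar, or ``(value, gradient)``.
    """
    m = _values(volume)
    dx, dy, dz = _diffs(m)
    root = np.sqrt(dx * dx + dy * dy + dz * dz + epsilon)
    value = float(root.sum())
    if not with_grad:
        return value
    g = (dx + dy + dz) / root
    g[1:, :, :] -= dx[:-1, :, :] / root[:-1, :, :]
    g[:, 1:, :] -= dy[:, :-1, :] / root[:, :-1, :]
    g[:, :, 1:] -= dz[:, :, :-1] / root[:, :, :-1]
    return value, g


def tv_local_curvature(volume, epsilon: float = 1e-8) -> np.ndarray:
    """Per-voxel diagonal curvature estimate of the smoothed TV.

    Each voxel collects ``1/root`` from every difference term it enters
    (its own three forward differences plus up to three from preceding
    neighbors).  Used as a diagonal scaling for Newton-like steps: in
    flat regions the smoothed TV is locally quadratic with curvature
    ``1/sqrt(eps)`` and this estimate reproduces it.
    """
    m = _values(volume)
    dx, dy, dz = _diffs(m)
    root = np.sqrt(dx * dx + dy * dy + dz * dz + epsilon)
    inv = 1.0 / root
    c = 3.0 * inv
    c[1:, :, :] += inv[:-1, :, :]
    c[:, 1:, :] += inv[:, :-1, :]
    c[:, :, 1:] += inv[:, :, :-1]
    return c


def pic_term(volume, prior, epsilon: float = 1e-8, with_grad: bool = False):
    """Prior-image constraint: TV of the difference to a fixed prior."""
    m = _values(volume)
    p = _values(prior)
    if m.shape != p.shape:
        raise ValueError("image and prior grids do not match")
    return tv_norm(m - p, epsilon, with_grad=with_grad)


def tcgm_term(series, t: int, epsilon: float = 1e-8, with_grad: bool = False):
    """Time-chain coupling of phase ``t`` (0-based) to its neighbors.

    Interior phases contribute ``TV(mu_t - mu_{t-1}) + TV(mu_t -
    mu_{t+1})``; the first and last phases double their single
    available one-sided term so every phase feels a comparable temporal
    pull.  The gradient is taken with respect to ``mu_t`` only.
    """
    phases = [_values(p) for p in (series.phases if hasattr(series, "phases") else series)]
    T = len(phases)
    if T < 2:
        raise ValueError("time-chain term needs at least 2 phases")
    if not 0 <= t < T:
        raise IndexError("phase index out of range")
    neighbors = []
    if t > 0:
        neighbors.append(phases[t - 1])
    if t < T - 1:
        neighbors.append(phases[t + 1])
    weight = 2.0 if len(neighbors) == 1 else 1.0
    value = 0.0
    grad = np.zeros_like(phases[t]) if with_grad else None
    for nb in neighbors:
        if with_grad:
            v, g = tv_norm(phases[t] - nb, epsilon, with_grad=True)
            grad += weight * g
        else:
            v = tv_norm(phases[t] - nb, epsilon)
        value += weight * v
    if with_grad:
        return value, grad
    return value


class PoissonDataTerm:
    """Per-phase Poisson transmission data term bound to a projection window.

    Caches the measured counts; ``value``/``gradient`` act on expected
    line integrals ``y* = A mu`` so a line search can reuse forward
    projections.
    """

    def __init__(
        self,
        projections: ProjectionSet,
        geometry: ScanGeometry,
        grid: VolumeImage,
        n0: float | None = None,
    ):
        from dataclasses import replace

        if not np.all(np.isfinite(projections.frames)):
            raise ValueError("projections contain non-finite values")
        # bind the geometry's frame schedule to this window
        self.geometry = replace(
            geometry, angles=projections.angles, timestamps=projections.timestamps
        )
        self.projections = projections
        self.grid = grid
        self.n0 = float(projections.n0 if n0 is None else n0)
        self.counts = self.n0 * np.exp(-projections.frames)

    def forward(self, mu: np.ndarray) -> np.ndarray:
        vol = self.grid.like(mu)
        return forward_project(vol, self.geometry).frames

    def value(self, y_star: np.ndarray) -> float:
        return float(np.sum(self.counts * y_star + self.n0 * np.exp(-y_star)))

    def curvature_diag(self) -> np.ndarray:
        """Diagonal majorizer of the data Hessian (separable paraboloids).

        ``D = A^T (n * A 1)`` — the classic precomputed transmission
        curvature; used as a fixed diagonal preconditioner.
        """
        ones = np.ones(self.grid.shape)
        l = forward_project(self.grid.like(ones), self.geometry).frames
        pset = ProjectionSet(
            self.counts * l, self.projections.angles, self.projections.timestamps
        )
        return back_project(pset, self.geometry, self.grid).values

    def gradient(self, y_star: np.ndarray) -> np.ndarray:
        resid = self.counts - self.n0 * np.exp(-y_star)
        pset = ProjectionSet(
            resid, self.projections.angles, self.projections.timestamps, self.n0
        )
        return back_project(pset, self.geometry, self.grid).values


def neg_log_likelihood(
    volume: VolumeImage,
    projections: ProjectionSet,
    geometry: ScanGeometry,
    n0: float | None = None,
) -> float:
    """Negative Poisson log-likelihood (mu-dependent part) of ``volume``."""
    term = PoissonDataTerm(projections, geometry, volume, n0=n0)
    return term.value(term.forward(volume.values))
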