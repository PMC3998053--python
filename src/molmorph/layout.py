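"""2D layouts of explored chemical space.

Two projections of the exploration tree are provided: PCA of the raw
fingerprint bit matrix, and a Kamada-Kawai-style stress layout in which the
pairwise layout targets d_ij are the *structural* fingerprint distances
between molecules (not graph shortest paths).  The stress energy is

    E = sum_{i<j} (1 / d_ij^2) * (||x_i - x_j|| - d_ij)^2

and is minimized by node-wise relaxation from a seeded random start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Fingerprint

__all__ = ["LayoutState", "pca_layout", "kk_layout", "stress_energy"]


@dataclass
class LayoutState:
    coords: np.ndarray          # (n, 2)
    d_matrix: np.ndarray        # (n, n) symmetric, zero diagonal
    energy: float
    energy_trace: list[float] | None = None  # energy after each accepted move


def pca_layout(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Project fingerprints onto their top-2 principal directions.

    Bits are treated as 0/1 reals and mean-centred.  The sign of each axis is
    fixed by making its largest-magnitude loading positive, so the layout is
    fully deterministic.  All-identical fingerprints collapse to the origin.
    """
    if len(fps) < 2:
        raise ValueError("PCA layout needs at least 2 molecules")
    x = np.array([fp.bits for fp in fps], dtype=float)
    x -= x.mean(axis=0)
    if not np.any(x):
        return np.zeros((len(fps), 2))
    # SVD of the centred matrix: right singular vectors are the principal axes.
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    axes = vt[:2]
    if axes.shape[0] < 2:
        axes = np.vstack([axes, np.zeros_like(axes[0])])
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return x @ axes.T


def stress_energy(coords: np.ndarray, d_matrix: np.ndarray) -> float:
    """E = sum over pairs of (1/d^2) (euclidean - d)^2."""
    n = len(coords)
    e = 0.0
    for i in range(n):
        diff = coords[i + 1:] - coords[i]
        dist = np.sqrt((diff * diff).sum(axis=1))
        d = d_matrix[i, i + 1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(d > 0, 1.0 / np.maximum(d, 1e-12) ** 2, 0.0)
        e += float((w * (dist - d) ** 2).sum())
    return e


def _node_gradient_hessian(i: int, coords: np.ndarray, d: np.ndarray):
    """Gradient and Hessian of E with respect to x_i (classical KK update)."""
    diff = coords[i] - coords          # (n, 2)
    dist = np.sqrt((diff * diff).sum(axis=1))
    mask = np.ones(len(coords), dtype=bool)
    mask[i] = False
    mask &= d[i] > 0
    diff = diff[mask]
    dist = np.maximum(dist[mask], 1e-12)
    dij = d[i][mask]
    w = 1.0 / dij**2
    grad = 2.0 * (w * (1.0 - dij / dist))[:, None] * diff
    g = grad.sum(axis=0)
    # Hessian entries
    hxx = 2.0 * (w * (1.0 - dij * diff[:, 1] ** 2 / dist**3)).sum()
    hyy = 2.0 * (w * (1.0 - dij * diff[:, 0] ** 2 / dist**3)).sum()
    hxy = 2.0 * (w * dij * diff[:, 0] * diff[:, 1] / dist**3).sum()
    h = np.array([[hxx, hxy], [hxy, hyy]])
    return g, h


def kk_layout(
    d_matrix: np.ndarray,
    max_iters: int = 1000,
    tol: float = 1e-9,
    rng: "np.random.Generator | int | None" = None,
) -> LayoutState:
    """Stress-minimizing 2D embedding of a distance matrix.

    Node-wise relaxation: repeatedly pick the node with the largest stress
    gradient and move it by a damped Newton step, accepting only moves that
    decrease the energy (so the energy sequence is non-increasing).  Stops
    after `max_iters` node updates or when the improvement of a full pass
    falls below `tol`.  Off-diagonal zero distances (duplicate molecules) are
    coalesced before layout and the duplicates placed on their
    representative.
    """
    d = np.asarray(d_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # Coalesce duplicate molecules (d_ij = 0 off-diagonal).
    rep = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == 0 and rep[j] == j:
                rep[j] = rep[i]
    uniq = np.flatnonzero(rep == np.arange(n))
    du = d[np.ix_(uniq, uniq)]
    m = len(uniq)

    scale = du.max() if du.max() > 0 else 1.0
    coords = rng.uniform(-scale, scale, size=(m, 2))
    if m == 1:
        coords = np.zeros((1, 2))
    energy = stress_energy(coords, du)
    initial_energy = energy
    trace = [energy]

    updates = 0
    while updates < max_iters and m > 1:
        pass_improvement = 0.0
        grads = np.array([
            np.linalg.norm(_node_gradient_hessian(i, coords, du)[0]) for i in range(m)
        ])
        order = np.argsort(-grads)
        for i in order:
            if updates >= max_iters:
                break
            updates += 1
            g, h = _node_gradient_hessian(int(i), coords, du)
            try:
                step = np.linalg.solve(h, -g)
            except np.linalg.LinAlgError:
                step = -g
            # Backtracking: accept only energy-decreasing moves.
            old = coords[i].copy()
            for damping in (1.0, 0.5, 0.25, 0.1, 0.01):
                coords[i] = old + damping * step
                new_energy = stress_energy(coords, du)
                if new_energy < energy:
                    pass_improvement += energy - new_energy
                    energy = new_energy
                    trace.append(energy)
                    break
            else:
                coords[i] = old
        if pass_improvement < tol:
            break

    full = np.empty((n, 2))
    pos_of = {int(k): idx for idx, k in enumerate(uniq)}
    for i in range(n):
        full[i] = coords[pos_of[int(rep[i])]]
    assert energy <= initial_energy + 1e-12
    return LayoutState(coords=full, d_matrix=d, energy=energy, energy_trace=trace)
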