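"""Analytic test potentials for elastic-band path optimization.

These surfaces stand in for a molecular force field at desk scale: the
isotropic harmonic well (convex, exactly solvable) and the Müller–Brown
surface, the standard two-dimensional benchmark whose minimum-energy path
between the two deep minima crosses two saddle points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Potential",
    "HarmonicWell",
    "MuellerBrown",
    "check_gradient",
    "grid_minimax_saddle",
]


class Potential:
    """Energy/gradient contract over flat configuration vectors."""

    dimension: int
    name: str

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class HarmonicWell(Potential):
    """V(x) = k/2 · |x − center|²."""

    center: np.ndarray
    k: float = 1.0
    name: str = "harmonic"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dimension = self.center.size

    def energy(self, x: np.ndarray) -> float:
        d = np.asarray(x, float) - self.center
        return 0.5 * self.k * float(d @ d)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(x, float) - self.center)


@dataclass
class MuellerBrown(Potential):
    """The Müller–Brown surface (sum of four anisotropic Gaussians)."""

    name: str = "mueller-brown"
    dimension: int = 2
    A: np.ndarray = field(
        default_factory=lambda: np.array([-200.0, -100.0, -170.0, 15.0])
    )
    a: np.ndarray = field(
        default_factory=lambda: np.array([-1.0, -1.0, -6.5, 0.7])
    )
    b: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 11.0, 0.6])
    )
    c: np.ndarray = field(
        default_factory=lambda: np.array([-10.0, -10.0, -6.5, 0.7])
    )
    x0: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, -0.5, -1.0])
    )
    y0: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.5, 1.5, 1.0])
    )

    #: The two deep minima (standard endpoint choice) and the shallow one.
    MINIMUM_A = np.array([-0.5582236346, 1.4417258418])
    MINIMUM_B = np.array([0.6234994049, 0.0280377585])
    MINIMUM_MID = np.array([-0.0500108233, 0.4666941049])

    def _terms(self, x: float, y: float) -> np.ndarray:
        dx = x - self.x0
        dy = y - self.y0
        return self.A * np.exp(
            self.a * dx**2 + self.b * dx * dy + self.c * dy**2
        )

    def energy(self, x: np.ndarray) -> float:
        x = np.asarray(x, float)
        return float(self._terms(x[0], x[1]).sum())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        t = self._terms(x[0], x[1])
        gx = (t * (2.0 * self.a * dx + self.b * dy)).sum()
        gy = (t * (self.b * dx + 2.0 * self.c * dy)).sum()
        return np.array([gx, gy])

    def energy_grid(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorized energies on a meshgrid, shape (len(ys), len(xs))."""
        X, Y = np.meshgrid(xs, ys)
        dx = X[..., None] - self.x0
        dy = Y[..., None] - self.y0
        return (
            self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2)
        ).sum(axis=-1)


def check_gradient(potential: Potential, points: np.ndarray,
                   h: float = 1e-6, rtol: float = 1e-5) -> None:
    """Verify the analytic gradient against central differences."""
    for x in np.atleast_2d(points):
        g = potential.gradient(x)
        num = np.zeros_like(g)
        for d in range(x.size):
            e = np.zeros(x.size)
            e[d] = h
            num[d] = (potential.energy(x + e) - potential.energy(x - e)) / (2 * h)
        scale = max(np.linalg.norm(g), 1.0)
        if np.linalg.norm(g - num) > rtol * scale:
            raise AssertionError(
                f"gradient mismatch at {x}: analytic {g}, numeric {num}"
            )


# ---------------------------------------------------------------------------
# brute-force saddle oracle

def grid_minimax_saddle(
    potential,
    point_a: np.ndarray,
    point_b: np.ndarray,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    n: int = 2000,
) -> tuple[np.ndarray, float]:
    """Saddle between two basins by brute-force grid search (2-D only).

    The saddle energy is the minimax (bottleneck) level: the lowest energy
    threshold at which the sub-level set connects the two points, found by
    bisection over connected-component labelings of an n×n energy grid. The
    saddle position is the grid cell whose inclusion joins the two basins.
    """
    (xlo, xhi), (ylo, yhi) = bounds
    xs = np.linspace(xlo, xhi, n)
    ys = np.linspace(ylo, yhi, n)
    if hasattr(potential, "energy_grid"):
        E = potential.energy_grid(xs, ys)
    else:
        E = np.array([[potential.energy(np.array([x, y])) for x in xs]
                      for y in ys])

    def _cell(p):
        j = int(np.clip(np.searchsorted(xs, p[0]), 1, n - 1))
        i = int(np.clip(np.searchsorted(ys, p[1]), 1, n - 1))
        # snap to the lowest-energy cell in a small neighbourhood
        i0, i1 = max(i - 2, 0), min(i + 3, n)
        j0, j1 = max(j - 2, 0), min(j + 3, n)
        local = E[i0:i1, j0:j1]
        di, dj = np.unravel_index(np.argmin(local), local.shape)
        return (i0 + di, j0 + dj)

    ca, cb = _cell(np.asarray(point_a)), _cell(np.asarray(point_b))

    def _connected(level: float) -> bool:
        lab, _ = ndimage.label(E <= level)
        return lab[ca] != 0 and lab[ca] == lab[cb]

    lo = max(E[ca], E[cb])
    hi = float(E.max())
    if not _connected(hi):
        raise ValueError("endpoints not connected anywhere on the grid")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _connected(mid):
            hi = mid
        else:
            lo = mid
    # Bottleneck cell: among cells just below the converged level, adjacent
    # to both basins of the just-disconnected labeling.
    lab, _ = ndimage.label(E <= lo)
    la, lb = lab[ca], lab[cb]
    cand = np.argwhere((E > lo) & (E <= hi + (hi - lo)))
    best = None
    for i, j in cand:
        neigh = set()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < n and 0 <= jj < n and lab[ii, jj] != 0:
                neigh.add(lab[ii, jj])
        if la in neigh and lb in neigh:
            if best is None or E[i, j] < E[best]:
                best = (i, j)
    if best is None:
        # fall back to the lowest candidate cell at the bottleneck level
        i, j = min(cand, key=lambda ij: E[ij[0], ij[1]])
        best = (int(i), int(j))
    pos = np.array([xs[best[1]], ys[best[0]]])
    return pos, float(E[best])
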