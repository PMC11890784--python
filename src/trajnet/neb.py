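"""Nudged-elastic-band minimum-energy-path optimization.

A band of R replicas connects two fixed endpoint configurations. Interior
replicas feel the potential force projected perpendicular to the local path
tangent plus a spring force k·(|d_{i+1}| − |d_{i−1}|) along the tangent,
using the improved (uphill-neighbour) tangent estimate that suppresses band
kinks. A partial band restricts the tangent/spring treatment to a masked
coordinate subset; unmasked coordinates feel the bare potential force and
simply relax. Optimization is deterministic damped steepest descent with
FIRE velocity quenching; an optional climbing image drives the highest
replica to the saddle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .potentials import Potential

logger = logging.getLogger(__name__)

__all__ = ["Band", "PathResult", "neb_force", "optimize_band", "path_profile"]

#: Documented default spring constant for molecular-scale coordinates
#: (kcal mol⁻¹ Å⁻²); analytic surfaces typically use much smaller k.
DEFAULT_MOLECULAR_SPRING_K = 10.0


@dataclass
class Band:
    """Ordered replicas between two fixed endpoints."""

    replicas: np.ndarray          # (R, D)
    k: float                      # spring constant, energy/length²
    mask: np.ndarray | None = None  # bool (D,), True = band coordinate

    def __post_init__(self) -> None:
        self.replicas = np.asarray(self.replicas, dtype=float)
        if self.replicas.ndim != 2 or self.replicas.shape[0] < 3:
            raise ValueError("band needs at least 3 replicas of equal dimension")
        if self.mask is None:
            self.mask = np.ones(self.replicas.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.replicas.shape[1],):
                raise ValueError("mask length must equal configuration dimension")
            if not self.mask.any():
                raise ValueError("partial-band mask must select at least one coordinate")

    @property
    def n_replicas(self) -> int:
        return int(self.replicas.shape[0])

    @classmethod
    def interpolate(cls, start: np.ndarray, end: np.ndarray, n_replicas: int,
                    k: float, mask: np.ndarray | None = None) -> "Band":
        """Linear interpolation between two endpoint configurations."""
        t = np.linspace(0.0, 1.0, n_replicas)[:, None]
        reps = (1 - t) * np.asarray(start, float) + t * np.asarray(end, float)
        return cls(reps, k, mask)


@dataclass
class PathResult:
    """Optimized band with energies and the convergence trace."""

    replicas: np.ndarray
    energies: np.ndarray
    converged: bool
    n_iterations: int
    max_displacement_trace: np.ndarray  # per iteration
    replica_rmsd_trace: np.ndarray      # mean adjacent-replica RMSD
    mask: np.ndarray

    @property
    def highest_index(self) -> int:
        return int(np.argmax(self.energies))

    def write_csv(self, path) -> None:
        arc, en = path_profile(self)[:2]
        with open(path, "w") as fh:
            fh.write("replica,arc_length,energy," + ",".join(
                f"x{d}" for d in range(self.replicas.shape[1])
            ) + "\n")
            for i in range(self.replicas.shape[0]):
                coords = ",".join(f"{v:.8g}" for v in self.replicas[i])
                fh.write(f"{i},{arc[i]:.8g},{en[i]:.8g},{coords}\n")


def _tangent(rm: np.ndarray, r0: np.ndarray, rp: np.ndarray,
             vm: float, v0: float, vp: float) -> np.ndarray:
    """Improved (uphill-neighbour) tangent of Henkelman & Jónsson."""
    dp = rp - r0
    dm = r0 - rm
    if vp > v0 > vm:
        tau = dp
    elif vp < v0 < vm:
        tau = dm
    else:
        dvmax = max(abs(vp - v0), abs(vm - v0))
        dvmin = min(abs(vp - v0), abs(vm - v0))
        if vp > vm:
            tau = dp * dvmax + dm * dvmin
        else:
            tau = dp * dvmin + dm * dvmax
    norm = np.linalg.norm(tau)
    if norm == 0.0:
        return np.zeros_like(tau)
    return tau / norm


def neb_force(band: Band, potential: Potential,
              climbing_index: int | None = None) -> np.ndarray:
    """Per-replica NEB forces; endpoint rows are zero (pinned).

    With a partial mask, the tangent and spring act on masked coordinates
    only; unmasked coordinates feel the bare potential force.
    """
    R, D = band.replicas.shape
    if getattr(potential, "dimension", D) != D:
        raise ValueError(
            f"potential dimension {potential.dimension} != band dimension {D}"
        )
    mask = band.mask
    x = band.replicas
    if np.array_equal(x[0], x[-1]):
        # Degenerate band (identical endpoints): tangent projection would
        # leave any collinear spike at equilibrium, so fall back to a plain
        # elastic band, which collapses onto the endpoint.
        forces = np.zeros_like(x)
        for i in range(1, R - 1):
            forces[i] = -potential.gradient(x[i]) + band.k * (
                x[i + 1] - 2.0 * x[i] + x[i - 1]
            )
        return forces
    V = np.array([potential.energy(x[i]) for i in range(R)])
    G = np.array([potential.gradient(x[i]) for i in range(R)])
    forces = np.zeros_like(x)
    for i in range(1, R - 1):
        g = G[i]
        gm = g[mask]
        tau = _tangent(x[i - 1][mask], x[i][mask], x[i + 1][mask],
                       V[i - 1], V[i], V[i + 1])
        if climbing_index is not None and i == climbing_index:
            f_band = -gm + 2.0 * (gm @ tau) * tau
        else:
            f_perp = -gm + (gm @ tau) * tau
            dp = np.linalg.norm((x[i + 1] - x[i])[mask])
            dm = np.linalg.norm((x[i] - x[i - 1])[mask])
            f_band = f_perp + band.k * (dp - dm) * tau
        f = np.zeros(D)
        f[mask] = f_band
        f[~mask] = -g[~mask]
        forces[i] = f
    return forces


def optimize_band(
    band: Band,
    potential: Potential,
    tol: float = 1e-6,
    max_iter: int = 20000,
    dt: float = 0.01,
    max_step: float = 0.05,
    climbing: bool = False,
) -> PathResult:
    """Relax a band by FIRE-quenched steepest descent.

    Iterates until the maximum per-replica displacement in one iteration
    stays below ``tol`` for ten consecutive iterations (a single sub-``tol``
    step right after a FIRE velocity reset is not convergence).
    With ``climbing`` the band is first relaxed
    without a climbing image, then the highest-energy replica climbs along
    the tangent to the saddle. Non-convergence at ``max_iter`` flags the
    result rather than raising.
    """
    x = band.replicas.copy()
    endpoints = (x[0].copy(), x[-1].copy())
    v = np.zeros_like(x)
    # FIRE parameters (standard values)
    dt_now, dt_max = dt, 10.0 * dt
    alpha, alpha0 = 0.1, 0.1
    n_pos = 0
    disp_trace: list[float] = []
    rmsd_trace: list[float] = []
    converged = False
    climbing_index: int | None = None
    D = x.shape[1]
    n_small = 0  # consecutive sub-tol iterations

    it = 0
    for it in range(1, max_iter + 1):
        work = Band(x, band.k, band.mask)
        F = neb_force(work, potential, climbing_index=climbing_index)
        # FIRE velocity mixing
        p = float((F * v).sum())
        if p > 0:
            fnorm = np.linalg.norm(F)
            vnorm = np.linalg.norm(v)
            if fnorm > 0:
                v = (1 - alpha) * v + alpha * vnorm * F / fnorm
            n_pos += 1
            if n_pos > 5:
                dt_now = min(dt_now * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt_now *= 0.5
            alpha = alpha0
            n_pos = 0
        v += dt_now * F
        step = dt_now * v
        norms = np.linalg.norm(step, axis=1)
        big = norms > max_step
        if big.any():
            step[big] *= (max_step / norms[big])[:, None]
        x += step
        x[0], x[-1] = endpoints
        step[0] = 0.0
        step[-1] = 0.0
        max_disp = float(np.linalg.norm(step, axis=1).max())
        disp_trace.append(max_disp)
        seg = np.linalg.norm(np.diff(x, axis=0), axis=1)
        rmsd_trace.append(float((seg / np.sqrt(D)).mean()))
        n_small = n_small + 1 if max_disp < tol else 0
        if n_small >= 10:
            if climbing and climbing_index is None:
                # plain band has relaxed; let the highest replica climb
                energies = np.array([potential.energy(r) for r in x])
                climbing_index = int(np.argmax(energies[1:-1])) + 1
                v[:] = 0.0
                dt_now = dt
                alpha = alpha0
                n_pos = 0
                n_small = 0
                continue
            converged = True
            break

    if not converged:
        logger.warning("band not converged after %d iterations", it)
    energies = np.array([potential.energy(r) for r in x])
    return PathResult(
        x, energies, converged, it,
        np.array(disp_trace), np.array(rmsd_trace), band.mask.copy(),
    )


def path_profile(result: PathResult) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative arc length, per-replica energy, and the barrier.

    The barrier is the maximum energy minus the energy of the start replica.
    """
    seg = np.linalg.norm(np.diff(result.replicas, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    barrier = float(result.energies.max() - result.energies[0])
    return arc, result.energies.copy(), barrier
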