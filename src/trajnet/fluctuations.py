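"""Per-node fluctuation statistics of superposed conformer ensembles.

Frames are rigid-body superposed (Kabsch, no scaling) onto a reference, then
per-node mean-square fluctuations, crystallographic-style B-factors
(B = 8π²/3 · MSF) and the linear dynamic cross-correlation matrix

    c_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)

are computed over the representative atoms of a NodeSet, where Δr is the
instantaneous minus mean position. The signed linear estimator is used (its
coefficient appears inside |·| when edges are weighted downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import NodeSet, TrajectoryEnsemble, select_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "FluctuationProfile",
    "superpose",
    "rmsf_bfactor",
    "correlation_matrix",
    "BFACTOR_PER_MSF",
]

#: B = (8π²/3) · MSF
BFACTOR_PER_MSF = 8.0 * np.pi**2 / 3.0


@dataclass
class CorrelationMatrix:
    """N×N node–node correlation coefficients, node order = NodeSet order."""

    c: np.ndarray
    nodes: NodeSet

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        n = len(self.nodes)
        if self.c.shape != (n, n):
            raise ValueError(f"correlation shape {self.c.shape} != ({n}, {n})")

    def validate(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.c, self.c.T, atol=atol):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.c), 1.0, atol=atol):
            raise ValueError("correlation diagonal deviates from 1")
        if np.abs(self.c).max() > 1.0 + atol:
            raise ValueError("correlation magnitude exceeds 1")

    def write_matrix(self, path) -> None:
        np.savetxt(path, self.c, fmt="%.6f", delimiter="\t")

    def write_triplets(self, path) -> None:
        labels = self.nodes.labels
        with open(path, "w") as fh:
            fh.write("i\tj\tc_ij\n")
            n = len(labels)
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{labels[i]}\t{labels[j]}\t{self.c[i, j]:.6f}\n")


@dataclass
class FluctuationProfile:
    """Per-node MSF (Å²), RMSF (Å) and B-factor (Å²)."""

    msf: np.ndarray
    nodes: NodeSet

    @property
    def rmsf(self) -> np.ndarray:
        return np.sqrt(self.msf)

    @property
    def bfactor(self) -> np.ndarray:
        return BFACTOR_PER_MSF * self.msf

    def bfactor_by_residue(self) -> dict[tuple[str, int, str], float]:
        return {
            node.residue_id: float(b)
            for node, b in zip(self.nodes, self.bfactor)
        }


# ---------------------------------------------------------------------------
# superposition

def _kabsch_apply(frame: np.ndarray, fit_idx: np.ndarray,
                  ref_fit: np.ndarray) -> np.ndarray:
    """Rigid transform of a whole frame minimizing fit-atom RMSD to ref."""
    P = frame[fit_idx]
    pc, qc = P.mean(axis=0), ref_fit.mean(axis=0)
    H = (P - pc).T @ (ref_fit - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (frame - pc) @ R.T + qc


def superpose(
    ensemble: TrajectoryEnsemble,
    fit_nodes: NodeSet | None = None,
    reference: int | str = "mean",
) -> TrajectoryEnsemble:
    """Rigid-body superpose all frames (Kabsch, no scaling).

    The RMSD of the fit nodes' representative atoms to the reference is
    minimized. ``reference`` is a frame index or ``"mean"``; the mean
    reference is iterated twice (align → recompute mean → align).
    """
    if ensemble.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    if fit_nodes is None:
        fit_nodes = select_nodes(ensemble.topology)
    if len(fit_nodes) < 1:
        raise ValueError("no fit nodes")
    fit_idx = fit_nodes.atom_indices
    sample = ensemble.frames[0][fit_idx]
    if len(fit_idx) < 3 or np.linalg.matrix_rank(
        sample - sample.mean(axis=0), tol=1e-8
    ) < 2:
        raise ValueError(
            "rotation under-determined: need at least 3 non-collinear fit atoms"
        )

    frames = ensemble.frames.copy()

    def _align_to(ref_fit: np.ndarray) -> None:
        for f in range(frames.shape[0]):
            frames[f] = _kabsch_apply(frames[f], fit_idx, ref_fit)

    if reference == "mean":
        for _ in range(2):
            ref_fit = frames[:, fit_idx, :].mean(axis=0)
            _align_to(ref_fit)
    else:
        _align_to(frames[int(reference)][fit_idx].copy())
    return TrajectoryEnsemble(ensemble.topology, frames)


# ---------------------------------------------------------------------------
# fluctuations and correlations

def rmsf_bfactor(ensemble: TrajectoryEnsemble,
                 nodes: NodeSet | None = None) -> FluctuationProfile:
    """Per-node mean-square fluctuation about the ensemble mean position."""
    if nodes is None:
        nodes = select_nodes(ensemble.topology)
    x = ensemble.frames[:, nodes.atom_indices, :]
    d = x - x.mean(axis=0)
    msf = np.einsum("fia,fia->i", d, d) / x.shape[0]
    return FluctuationProfile(msf, nodes)


def correlation_matrix(ensemble: TrajectoryEnsemble,
                       nodes: NodeSet | None = None) -> CorrelationMatrix:
    """Linear dynamic cross-correlation matrix over representative atoms.

    Zero-variance (static) nodes get zero off-diagonal entries and a unit
    diagonal, with a warning, so they cannot poison the matrix.
    """
    if ensemble.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    if nodes is None:
        nodes = select_nodes(ensemble.topology)
    x = ensemble.frames[:, nodes.atom_indices, :]
    d = x - x.mean(axis=0)
    cov = np.einsum("fia,fja->ij", d, d) / x.shape[0]
    var = np.diag(cov).copy()
    static = var <= 0.0
    if static.any():
        logger.warning(
            "%d zero-variance node(s); correlation rows zeroed", static.sum()
        )
        var[static] = 1.0
    c = cov / np.sqrt(np.outer(var, var))
    c[static, :] = 0.0
    c[:, static] = 0.0
    np.fill_diagonal(c, 1.0)
    np.clip(c, -1.0, 1.0, out=c)
    c = 0.5 * (c + c.T)
    return CorrelationMatrix(c, nodes)
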