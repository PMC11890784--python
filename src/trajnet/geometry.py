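"""Structure and ensemble geometry: distances, lysine reach, DNA kink, SASA.

These are the measures used to characterize interfaces and ubiquitination
geometry: atom-pair distances across conformers, scans for lysine residues
whose side-chain amine lies within reach of an enzyme active site, the kink
angle of a bent nucleic-acid duplex (180° = straight), Shrake–Rupley
solvent-accessible surface areas, and buried-surface fractions of a component
within a complex, with a per-partner decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import StructureModel, TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSelection",
    "ReachEntry",
    "ReachReport",
    "pair_distance",
    "lysine_reach_scan",
    "duplex_kink_angle",
    "sasa",
    "residue_sasa",
    "buried_fraction",
    "BuriedFractionResult",
    "VDW_RADII",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_SASA_POINTS",
    "DEFAULT_REACH_CUTOFF",
]

#: Van der Waals radii (Å) by element; unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
_DEFAULT_RADIUS = 1.70
DEFAULT_PROBE_RADIUS = 1.4   # Å
DEFAULT_SASA_POINTS = 960
DEFAULT_REACH_CUTOFF = 12.0  # Å, strict upper bound


@dataclass(frozen=True)
class AtomSelection:
    """A (chain, residue number[, insertion code], atom name) selector."""

    chain: str
    resseq: int
    atom_name: str
    icode: str = " "

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        """Parse 'chain:resnum:atom' (e.g. ``A:1268:CA``)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"selection {text!r} is not chain:resnum:atom")
        return cls(parts[0], int(parts[1]), parts[2])

    def resolve(self, model: StructureModel) -> int:
        """Index of the single atom matched; error if none or ambiguous."""
        hits = [
            i for i, a in enumerate(model.atoms)
            if a.chain == self.chain and a.resseq == self.resseq
            and a.name == self.atom_name
            and (self.icode == " " or a.icode == self.icode)
        ]
        if not hits:
            raise ValueError(f"selection {self} matches no atom")
        if len(hits) > 1:
            raise ValueError(f"selection {self} is ambiguous ({len(hits)} atoms)")
        return hits[0]


def pair_distance(
    structure: StructureModel | TrajectoryEnsemble,
    sel_a: AtomSelection | str,
    sel_b: AtomSelection | str,
):
    """Euclidean distance between two single-atom selections.

    For a StructureModel returns a float; for an ensemble returns
    ``(per_frame_distances, {"min": .., "mean": .., "max": ..})``.
    """
    if isinstance(sel_a, str):
        sel_a = AtomSelection.parse(sel_a)
    if isinstance(sel_b, str):
        sel_b = AtomSelection.parse(sel_b)
    if isinstance(structure, TrajectoryEnsemble):
        ia = sel_a.resolve(structure.topology)
        ib = sel_b.resolve(structure.topology)
        d = np.linalg.norm(
            structure.frames[:, ia, :] - structure.frames[:, ib, :], axis=1
        )
        return d, {
            "min": float(d.min()), "mean": float(d.mean()), "max": float(d.max())
        }
    ia, ib = sel_a.resolve(structure), sel_b.resolve(structure)
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))


# ---------------------------------------------------------------------------
# lysine reach scan

@dataclass(frozen=True)
class ReachEntry:
    residue_id: tuple[str, int, str]
    min_distance: float
    atom_used: str  # NZ, or CA fallback (flagged)


@dataclass
class ReachReport:
    """Lysines whose attacking amine comes within ``cutoff`` of a reference.

    ``per_frame`` lists, per conformer, the (residue_id, distance) pairs
    strictly inside the cutoff; ``union`` aggregates over the ensemble with
    each residue's minimum distance.
    """

    per_frame: list[list[tuple[tuple[str, int, str], float]]]
    union: list[ReachEntry]
    cutoff: float
    reference: AtomSelection

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresseq\tatom\tmin_distance\n")
            for e in self.union:
                fh.write(
                    f"{e.residue_id[0]}\t{e.residue_id[1]}\t{e.atom_used}\t"
                    f"{e.min_distance:.2f}\n"
                )


def lysine_reach_scan(
    structure: StructureModel | TrajectoryEnsemble,
    target_chains: set[str] | list[str],
    reference: AtomSelection | str,
    cutoff: float = DEFAULT_REACH_CUTOFF,
) -> ReachReport:
    """All LYS residues on target chains whose NZ atom lies strictly inside
    ``cutoff`` of the reference atom, per conformer and as an ensemble union.

    Lysines lacking an NZ atom fall back to Cα (flagged in the report).
    """
    if isinstance(reference, str):
        reference = AtomSelection.parse(reference)
    if isinstance(structure, StructureModel):
        structure = TrajectoryEnsemble(structure, structure.coords[None, :, :])
    top = structure.topology
    chains = set(target_chains)
    ref_idx = reference.resolve(top)

    lysines: list[tuple[tuple[str, int, str], int, str]] = []
    for rid, atom_idx in top.residues():
        first = top.atoms[atom_idx[0]]
        if first.resname != "LYS" or first.chain not in chains:
            continue
        names = {top.atoms[i].name: i for i in atom_idx}
        if "NZ" in names:
            lysines.append((rid, names["NZ"], "NZ"))
        elif "CA" in names:
            logger.warning("LYS %s lacks NZ; falling back to CA", rid)
            lysines.append((rid, names["CA"], "CA"))
    if not lysines:
        logger.warning("no LYS residues on target chains %s", sorted(chains))
        return ReachReport([[] for _ in range(structure.n_frames)], [],
                           cutoff, reference)

    idx = np.array([i for _, i, _ in lysines])
    d = np.linalg.norm(
        structure.frames[:, idx, :] - structure.frames[:, [ref_idx], :], axis=2
    )  # (F, L)
    per_frame = []
    for f in range(structure.n_frames):
        per_frame.append(
            [
                (lysines[k][0], float(d[f, k]))
                for k in range(len(lysines))
                if d[f, k] < cutoff
            ]
        )
    union = [
        ReachEntry(lysines[k][0], float(d[:, k].min()), lysines[k][2])
        for k in range(len(lysines))
        if (d[:, k] < cutoff).any()
    ]
    union.sort(key=lambda e: (e.residue_id[0], e.residue_id[1]))
    return ReachReport(per_frame, union, cutoff, reference)


# ---------------------------------------------------------------------------
# duplex kink angle

def _arm_axis(points: np.ndarray, junction: np.ndarray) -> np.ndarray:
    """First principal direction of arm backbone atoms, oriented to point
    away from the junction."""
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center)
    axis = vt[0]
    # Point away from the junction end of the arm.
    if np.dot(axis, center - junction) < 0:
        axis = -axis
    return axis


def duplex_kink_angle(
    model: StructureModel,
    arm_a: list[tuple[str, int]],
    arm_b: list[tuple[str, int]],
) -> float:
    """Kink angle in degrees between two duplex arms; 180° = straight.

    Each arm is the list of (chain, resseq) residues of one duplex segment;
    its axis is the first principal direction of the residues' backbone
    representative atoms (P, falling back to Cα), oriented away from the
    junction — the point where the two arms come closest.
    """
    coords = []
    for arm in (arm_a, arm_b):
        pts = []
        for chain, resseq in arm:
            names = {}
            for i, a in enumerate(model.atoms):
                if a.chain == chain and a.resseq == resseq:
                    names[a.name] = i
            idx = names.get("P", names.get("CA"))
            if idx is None:
                continue
            pts.append(model.coords[idx])
        if len(pts) < 3:
            raise ValueError("each arm needs at least 3 P/CA atoms")
        coords.append(np.array(pts))
    a_pts, b_pts = coords
    # Junction: midpoint of the closest residue pair across the arms.
    diff = a_pts[:, None, :] - b_pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    ia, ib = np.unravel_index(np.argmin(dist), dist.shape)
    junction = 0.5 * (a_pts[ia] + b_pts[ib])
    va = _arm_axis(a_pts, junction)
    vb = _arm_axis(b_pts, junction)
    cosang = np.clip(np.dot(va, vb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii(model: StructureModel) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS) for a in model.atoms]
    )


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    subset: np.ndarray | None = None,
    occluders: np.ndarray | None = None,
) -> np.ndarray:
    """Shrake–Rupley per-atom solvent-accessible surface area (Å²).

    Quasi-uniform test points are placed on each atom's probe-expanded
    sphere; the accessible fraction is the share of points not inside any
    neighbour's expanded sphere. ``subset`` limits which atoms are reported
    (others return 0); ``occluders`` limits which atoms may bury surface
    (default: all atoms of the model). Hydrogens are included when present.
    """
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    radii = _radii(model) + probe
    coords = model.coords
    sphere = _fibonacci_sphere(n_points)
    subset_idx = (
        np.arange(model.n_atoms) if subset is None else np.asarray(subset, int)
    )
    occ_idx = (
        np.arange(model.n_atoms) if occluders is None
        else np.asarray(occluders, int)
    )
    tree = cKDTree(coords[occ_idx])
    rmax = radii.max()
    out = np.zeros(model.n_atoms)
    for i in subset_idx:
        pts = coords[i] + radii[i] * sphere
        neigh = [
            occ_idx[j]
            for j in tree.query_ball_point(coords[i], radii[i] + rmax)
            if occ_idx[j] != i
        ]
        if neigh:
            nc = coords[neigh]
            nr = radii[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nr**2)[None, :] - 1e-9).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return out


def residue_sasa(model: StructureModel, per_atom: np.ndarray
                 ) -> dict[tuple[str, int, str], float]:
    """Aggregate a per-atom SASA array by residue."""
    out: dict[tuple[str, int, str], float] = {}
    for rid, idx in model.residues():
        out[rid] = float(per_atom[idx].sum())
    return out


@dataclass
class BuriedFractionResult:
    """Buried-surface fraction of a component and per-partner shares."""

    fraction: float
    sasa_alone: float
    sasa_in_complex: float
    partner_shares: dict[str, float]  # partner chain -> normalized share


def buried_fraction(
    model: StructureModel,
    component_chains: set[str] | list[str],
    partner_chains: list[str] | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> BuriedFractionResult:
    """Fraction of a component's isolated surface buried in the complex.

        fraction = (SASA_alone − SASA_in_complex) / SASA_alone

    The per-partner decomposition removes one partner chain at a time and
    measures the component surface each removal restores, normalized over
    partners.
    """
    chains = set(component_chains)
    comp_idx = np.array(
        [i for i, a in enumerate(model.atoms) if a.chain in chains], dtype=int
    )
    if len(comp_idx) == 0:
        raise ValueError(f"component chains {sorted(chains)} match no atoms")
    all_idx = np.arange(model.n_atoms)
    alone = sasa(model, probe, n_points, subset=comp_idx,
                 occluders=comp_idx)[comp_idx].sum()
    if alone <= 0:
        raise ValueError("component has zero isolated surface area")
    within = sasa(model, probe, n_points, subset=comp_idx,
                  occluders=all_idx)[comp_idx].sum()
    fraction = float((alone - within) / alone)

    if partner_chains is None:
        partner_chains = sorted(
            {a.chain for a in model.atoms} - chains
        )
    restored: dict[str, float] = {}
    for partner in partner_chains:
        keep = np.array(
            [i for i, a in enumerate(model.atoms) if a.chain != partner],
            dtype=int,
        )
        s = sasa(model, probe, n_points, subset=comp_idx,
                 occluders=keep)[comp_idx].sum()
        restored[partner] = max(float(s - within), 0.0)
    total = sum(restored.values())
    shares = {
        p: (v / total if total > 0 else 0.0) for p, v in restored.items()
    }
    return BuriedFractionResult(fraction, float(alone), float(within), shares)
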