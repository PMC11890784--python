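"""Persistence-filtered residue contacts.

A residue pair is "in contact" in a frame when the minimum distance between
their heavy atoms is at or below a cutoff (4.5 Å by default). The persistence
of a pair is the fraction of frames in contact; network edges keep pairs in
contact for at least 75% of the frames (inclusive boundary). Pairs adjacent
in sequence on the same chain (|Δresnum| ≤ 1) are excluded; inter-chain pairs
never are. Hydrogens are ignored in every distance test.

Persistent contacts are additionally classified with the tighter conventions
used for interaction reporting: any inter-residue N/O–N/O atom pair at
≤ 3.5 Å counts as a hydrogen-bond/salt-bridge event, any apolar C–C pair at
≤ 4.5 Å as a hydrophobic event, and a contact is reported persistent when its
event fraction exceeds 0.60 (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import NodeSet, StructureModel, TrajectoryEnsemble, select_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "ContactPersistence",
    "PersistentContact",
    "contact_persistence",
    "contact_edges",
    "classify_persistent_contacts",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_PERSISTENCE_THRESHOLD",
    "HBOND_CUTOFF",
    "HYDROPHOBIC_CUTOFF",
    "CLASS_MIN_FRACTION",
]

DEFAULT_CONTACT_CUTOFF = 4.5        # Å
DEFAULT_PERSISTENCE_THRESHOLD = 0.75  # inclusive ("at least 75%")
HBOND_CUTOFF = 3.5                  # Å, N/O–N/O
HYDROPHOBIC_CUTOFF = 4.5            # Å, apolar C–C
CLASS_MIN_FRACTION = 0.60           # exclusive ("more than 60%")

ADJACENCY_RULE = "same_chain_seq_adjacent"

# Carbons bonded to N/O (polar, excluded from hydrophobic events), by
# residue-specific atom name; the backbone carbonyl C is polar everywhere.
_POLAR_CARBONS: dict[str, set[str]] = {
    "ASP": {"CG"}, "ASN": {"CG"}, "GLU": {"CD"}, "GLN": {"CD"},
    "ARG": {"CZ"}, "HIS": {"CG", "CD2", "CE1"}, "HID": {"CG", "CD2", "CE1"},
    "HIE": {"CG", "CD2", "CE1"}, "HIP": {"CG", "CD2", "CE1"},
    "TRP": {"CD1", "CE2"}, "SER": {"CB"}, "THR": {"CB"}, "CYS": {"CB"},
    "MET": {"CG", "CE"}, "TYR": {"CZ"}, "LYS": {"CE"},
}
_BACKBONE_POLAR = {"C", "CA"}  # carbonyl C and Cα (bonded to N)


@dataclass
class ContactPersistence:
    """N×N fraction-of-frames contact matrix over a NodeSet."""

    p: np.ndarray
    nodes: NodeSet
    cutoff: float
    n_frames: int
    exclusion_rule: str = ADJACENCY_RULE

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.nodes)
        if self.p.shape != (n, n):
            raise ValueError(f"persistence shape {self.p.shape} != ({n}, {n})")

    def write_triplets(self, path) -> None:
        labels = self.nodes.labels
        with open(path, "w") as fh:
            fh.write("i\tj\tpersistence\n")
            n = len(labels)
            for i in range(n):
                for j in range(i + 1, n):
                    if self.p[i, j] > 0:
                        fh.write(
                            f"{labels[i]}\t{labels[j]}\t{self.p[i, j]:.4f}\n"
                        )


@dataclass(frozen=True)
class PersistentContact:
    """A classified persistent residue contact."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    contact_class: str  # "hbond_saltbridge" | "hydrophobic"
    fraction: float
    class_cutoff: float


def _adjacency_mask(nodes: NodeSet) -> np.ndarray:
    """Boolean mask of same-chain |Δresnum| ≤ 1 pairs (and the diagonal)."""
    chains = np.array([n.chain for n in nodes])
    resseq = np.array([n.resseq for n in nodes])
    same_chain = chains[:, None] == chains[None, :]
    near = np.abs(resseq[:, None] - resseq[None, :]) <= 1
    return same_chain & near


def _residue_atom_groups(model: StructureModel, nodes: NodeSet) -> list[np.ndarray]:
    """Heavy-atom index arrays per node residue."""
    by_res: dict[tuple[str, int, str], list[int]] = {}
    for i, atom in enumerate(model.atoms):
        if atom.element.upper() == "H":
            continue
        by_res.setdefault(atom.residue_id, []).append(i)
    return [np.array(by_res[n.residue_id], dtype=int) for n in nodes]


def _min_distance_matrix(frame: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-frame min heavy-atom distance between every residue pair."""
    sizes = [len(g) for g in groups]
    if all(s == 1 for s in sizes):  # bead model fast path
        pts = frame[[g[0] for g in groups]]
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt(np.einsum("ija,ija->ij", diff, diff))
    n = len(groups)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = cdist(frame[groups[i]], frame[groups[j]]).min()
            out[i, j] = out[j, i] = dij
    return out


def contact_persistence(
    ensemble: TrajectoryEnsemble,
    nodes: NodeSet | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactPersistence:
    """Fraction of frames each residue pair spends within ``cutoff``.

    Sequence-adjacent pairs on the same chain are zeroed out; the diagonal is
    stored as 0.
    """
    if nodes is None:
        nodes = select_nodes(ensemble.topology)
    groups = _residue_atom_groups(ensemble.topology, nodes)
    n = len(nodes)
    counts = np.zeros((n, n), dtype=np.int64)
    for f in range(ensemble.n_frames):
        d = _min_distance_matrix(ensemble.frames[f], groups)
        counts += d <= cutoff
    p = counts / float(ensemble.n_frames)
    p[_adjacency_mask(nodes)] = 0.0
    np.fill_diagonal(p, 0.0)
    return ContactPersistence(p, nodes, cutoff, ensemble.n_frames)


def contact_edges(
    persistence: ContactPersistence,
    threshold: float = DEFAULT_PERSISTENCE_THRESHOLD,
) -> list[tuple[int, int]]:
    """Node-index pairs with persistence ≥ threshold (inclusive), i < j."""
    ii, jj = np.where(persistence.p >= threshold)
    return sorted((int(i), int(j)) for i, j in zip(ii, jj) if i < j)


# ---------------------------------------------------------------------------
# contact classification

def _is_apolar_carbon(name: str, resname: str, element: str) -> bool:
    if element.upper() != "C":
        return False
    if name in _BACKBONE_POLAR:
        return False
    return name not in _POLAR_CARBONS.get(resname, set())


def classify_persistent_contacts(
    ensemble: TrajectoryEnsemble,
    model: StructureModel | None = None,
    hbond_cutoff: float = HBOND_CUTOFF,
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
    min_fraction: float = CLASS_MIN_FRACTION,
) -> list[PersistentContact]:
    """Classify persistent contacts on a full-atom ensemble.

    Event fractions must exceed ``min_fraction`` strictly; when both classes
    qualify the higher-fraction class wins, ties going to hbond_saltbridge.
    """
    if model is None:
        model = ensemble.topology
    if any(not a.element for a in model.atoms):
        raise ValueError("element fields are required for contact classification")
    nodes = select_nodes(model)
    groups = _residue_atom_groups(model, nodes)
    polar = {  # N/O atoms per node
        k: np.array(
            [i for i in g if model.atoms[i].element.upper() in ("N", "O")],
            dtype=int,
        )
        for k, g in enumerate(groups)
    }
    apolar = {
        k: np.array(
            [
                i for i in g
                if _is_apolar_carbon(
                    model.atoms[i].name, model.atoms[i].resname,
                    model.atoms[i].element,
                )
            ],
            dtype=int,
        )
        for k, g in enumerate(groups)
    }
    adj = _adjacency_mask(nodes)
    n = len(nodes)
    F = ensemble.n_frames
    hb = np.zeros((n, n), dtype=np.int64)
    hp = np.zeros((n, n), dtype=np.int64)
    for f in range(ensemble.n_frames):
        frame = ensemble.frames[f]
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    continue
                if len(polar[i]) and len(polar[j]):
                    if cdist(frame[polar[i]], frame[polar[j]]).min() <= hbond_cutoff:
                        hb[i, j] += 1
                if len(apolar[i]) and len(apolar[j]):
                    if (
                        cdist(frame[apolar[i]], frame[apolar[j]]).min()
                        <= hydrophobic_cutoff
                    ):
                        hp[i, j] += 1
    out: list[PersistentContact] = []
    for i in range(n):
        for j in range(i + 1, n):
            fb, fp = hb[i, j] / F, hp[i, j] / F
            if max(fb, fp) <= min_fraction:
                continue
            if fb >= fp:
                cls, frac, cut = "hbond_saltbridge", fb, hbond_cutoff
            else:
                cls, frac, cut = "hydrophobic", fp, hydrophobic_cutoff
            out.append(
                PersistentContact(
                    nodes[i].residue_id, nodes[j].residue_id, cls, frac, cut
                )
            )
    return out


def write_contact_report(contacts: list[PersistentContact], path) -> None:
    """TSV report: chainA, resA, chainB, resB, class, fraction."""
    with open(path, "w") as fh:
        fh.write("chainA\tresA\tchainB\tresB\tclass\tfraction\n")
        for c in contacts:
            fh.write(
                f"{c.residue_a[0]}\t{c.residue_a[1]}{c.residue_a[2].strip()}\t"
                f"{c.residue_b[0]}\t{c.residue_b[1]}{c.residue_b[2].strip()}\t"
                f"{c.contact_class}\t{c.fraction:.4f}\n"
            )
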