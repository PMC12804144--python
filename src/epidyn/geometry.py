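"""Superposition, RMSD, distances, and epitope-reachability.

Rigid-body superposition follows the Kabsch least-squares solution via
:func:`scipy.spatial.transform.Rotation.align_vectors`, which returns a
proper rotation (reflections corrected). Reachability of the epitopic
Gly1 amide nitrogen by a TCR carboxylate (E101) is a donor-acceptor
heavy-atom distance criterion; with no hydrogens in crystal structures
the conventional crystallographic cutoff of 3.5 A is used, with no
angular term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError, LookupAtomError
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "ContactMeasurement",
    "kabsch_superpose",
    "superpose_structures",
    "atom_distance",
    "classify_reachability",
    "measure_contact",
    "DEFAULT_HBOND_CUTOFF",
]

#: Donor-acceptor heavy-atom hydrogen-bond cutoff (angstrom).
DEFAULT_HBOND_CUTOFF = 3.5


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``."""

    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, angstrom
    rmsd: float  # angstrom, after transform
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ContactMeasurement:
    """A donor-acceptor distance with its reachability verdict."""

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float
    reachable: bool
    per_acceptor: dict[str, float] | None = None


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation.

    Minimises the RMSD of ``R @ mobile + t`` against ``reference`` over
    all proper rotations; the returned RMSD is evaluated after applying
    the transform.

    Raises
    ------
    InputError
        On length mismatch, fewer than 3 atoms, or a degenerate
        (collinear) point set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError(
            f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("expected (N, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise InputError("need at least 3 atoms for superposition")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-9) < 2:
        raise InputError("degenerate (collinear) coordinate set")
    rot, _rssd = Rotation.align_vectors(ref0, mob0)
    rotation = rot.as_matrix()
    translation = ref_c - rotation @ mob_c
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def superpose_structures(
    mobile: Structure, reference: Structure
) -> SuperpositionResult:
    """Superpose two structures pairing atoms by (chain, resSeq, name).

    Atoms present in only one structure are dropped; the dropped count
    is logged.
    """

    def keys(s: Structure):
        return {(a.chain_id, a.residue_seq, a.ins_code, a.name): a for a in s.atoms}

    mob_map, ref_map = keys(mobile), keys(reference)
    shared = [k for k in mob_map if k in ref_map]
    dropped = (len(mob_map) - len(shared)) + (len(ref_map) - len(shared))
    if dropped:
        logger.info("superposition dropped %d unpaired atom(s)", dropped)
    if len(shared) < 3:
        raise InputError(f"only {len(shared)} paired atoms; need >= 3")
    mob = np.array([mob_map[k].coords for k in shared])
    ref = np.array([ref_map[k].coords for k in shared])
    return kabsch_superpose(mob, ref)


def atom_distance(
    s: Structure, a: tuple[str, int, str], b: tuple[str, int, str]
) -> float:
    """Euclidean distance (angstrom) between two atoms given as
    (chain_id, residue_seq, atom_name)."""
    atom_a = s.atom(*a)
    atom_b = s.atom(*b)
    return float(np.linalg.norm(np.subtract(atom_a.coords, atom_b.coords)))


def classify_reachability(distance: float, cutoff: float = DEFAULT_HBOND_CUTOFF) -> bool:
    """True iff the donor-acceptor distance permits a hydrogen bond.

    The boundary is inclusive: a distance exactly at the cutoff is
    reachable.
    """
    if distance < 0:
        raise InputError("distance must be >= 0")
    return distance <= cutoff


def measure_contact(
    s: Structure,
    donor: tuple[str, int, str],
    acceptors: list[tuple[str, int, str]],
    cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> ContactMeasurement:
    """Minimum donor-acceptor distance over candidate acceptor atoms.

    Carboxylate acceptors (e.g. E101 OE1/OE2) are chemically equivalent,
    so the minimum over the listed atoms decides reachability; all
    individual distances are reported.
    """
    if not acceptors:
        raise LookupAtomError("no acceptor atoms given")
    per = {f"{c}:{r}:{n}": atom_distance(s, donor, (c, r, n)) for c, r, n in acceptors}
    best_name, best_d = min(per.items(), key=lambda kv: kv[1])
    best = next(a for a in acceptors if f"{a[0]}:{a[1]}:{a[2]}" == best_name)
    return ContactMeasurement(
        donor=donor,
        acceptor=best,
        distance=best_d,
        reachable=classify_reachability(best_d, cutoff),
        per_acceptor=per,
    )
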