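"""Trajectory -> epitope-state analysis.

A trajectory of a groove-bound lipopeptide complex is reduced to a
strided time series of the Gly1 residue's accessible surface area,
computed in the full-complex context of each frame. Each sample is
classified into one of three conformational states:

* ``exposed``    - ASA strictly greater than 50 A^2 (epitope presented),
* ``buried``     - ASA strictly less than 25 A^2 (epitope hidden),
* ``transition`` - in between (boundary values inclusive).

Occupancy fractions of these states summarise how efficiently a ligand
sustains the epitope-exposed form; ligands are ranked by exposed
fraction (ties by mean ASA, then label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, LookupAtomError, ParameterError
from .sasa import SasaParams, atom_sasa
from .structure_io import RadiiTable, Trajectory, assign_radii

__all__ = [
    "EXPOSED",
    "BURIED",
    "TRANSITION",
    "AnalysisParams",
    "StateThresholds",
    "AsaSeries",
    "OccupancySummary",
    "residue_asa_series",
    "classify_states",
    "occupancy",
    "rank_ligands",
]

EXPOSED = "exposed"
TRANSITION = "transition"
BURIED = "buried"
_STATES = (EXPOSED, TRANSITION, BURIED)


@dataclass(frozen=True)
class AnalysisParams:
    """How to sample a trajectory.

    stride:
        Frames between evaluated snapshots (default 10, i.e. a
        5000-frame run yields 500 samples).
    target_residue:
        (chain_id, residue_seq) of the residue whose ASA is monitored
        (the ligand's Gly1).
    """

    target_residue: tuple[str, int] = ("C", 1)
    stride: int = 10
    sasa_params: SasaParams = field(default_factory=SasaParams)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")


@dataclass(frozen=True)
class StateThresholds:
    """ASA bands of the three conformational states (angstrom^2)."""

    exposed_min: float = 50.0
    buried_max: float = 25.0

    def __post_init__(self) -> None:
        if not self.buried_max < self.exposed_min:
            raise ParameterError("buried_max must be < exposed_min")


@dataclass(frozen=True)
class AsaSeries:
    """Strided per-frame ASA of the target residue."""

    frame_indices: np.ndarray  # original frame numbering, strictly increasing
    values: np.ndarray  # angstrom^2
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_indices", np.asarray(self.frame_indices, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.frame_indices.shape != self.values.shape:
            raise InputError("frame indices and values differ in length")
        if self.frame_indices.size and np.any(np.diff(self.frame_indices) <= 0):
            raise InputError("frame indices must be strictly increasing")


@dataclass(frozen=True)
class OccupancySummary:
    """State occupancy of one analysed run."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_changes: int
    mean_asa: float
    label: str = ""

    @property
    def exposed_fraction(self) -> float:
        return self.fractions[EXPOSED]


def residue_asa_series(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    radii_table: RadiiTable | None = None,
    label: str = "",
) -> AsaSeries:
    """ASA of the target residue at frames 0, stride, 2*stride, ...

    Each value is the residue ASA in that frame's full-complex context
    (all atoms of the frame contribute to burial).
    """
    params = params or AnalysisParams()
    chain, resi = params.target_residue
    topo = traj.topology
    try:
        topo.residue(chain, resi)
    except LookupAtomError:
        raise LookupAtomError(
            f"target residue {chain}:{resi} absent from trajectory topology"
        ) from None
    # Topology is shared by all frames, so radii and the heavy-atom mask
    # are computed once; per frame only coordinates change.
    radii = assign_radii(topo, radii_table)
    heavy = np.array([a.element != "H" for a in topo.atoms], dtype=bool)
    target = np.array(
        [
            a.chain_id == chain and a.residue_seq == resi and a.ins_code == ""
            for a in topo.atoms
        ],
        dtype=bool,
    )[heavy]
    indices = np.arange(0, traj.frame_count, params.stride)
    values = np.empty(indices.size)
    for k, i in enumerate(indices):
        areas = atom_sasa(traj.frames[i][heavy], radii[heavy], params.sasa_params)
        values[k] = areas[target].sum()
    return AsaSeries(frame_indices=indices, values=values, label=label)


def classify_states(
    series: AsaSeries, thresholds: StateThresholds | None = None
) -> np.ndarray:
    """Per-sample conformational state.

    The inequalities are strict, so values exactly at a threshold fall
    in the transition band.
    """
    thresholds = thresholds or StateThresholds()
    if series.values.size == 0:
        raise InputError("empty ASA series")
    states = np.full(series.values.shape, TRANSITION, dtype=object)
    states[series.values > thresholds.exposed_min] = EXPOSED
    states[series.values < thresholds.buried_max] = BURIED
    return states


def occupancy(
    states: np.ndarray, asa_values: np.ndarray | None = None, label: str = ""
) -> OccupancySummary:
    """Occupancy fractions, counts, and adjacent state changes."""
    states = np.asarray(states, dtype=object)
    if states.size == 0:
        raise InputError("empty state sequence")
    unknown = set(states) - set(_STATES)
    if unknown:
        raise InputError(f"unknown state label(s): {sorted(unknown)}")
    counts = {s: int(np.sum(states == s)) for s in _STATES}
    n = states.size
    fractions = {s: counts[s] / n for s in _STATES}
    n_changes = int(np.sum(states[1:] != states[:-1]))
    mean_asa = float(np.mean(asa_values)) if asa_values is not None else float("nan")
    return OccupancySummary(
        fractions=fractions,
        counts=counts,
        n_changes=n_changes,
        mean_asa=mean_asa,
        label=label,
    )


def rank_ligands(summaries: dict[str, OccupancySummary]) -> list[str]:
    """Ligand labels ordered by decreasing epitope-exposed fraction.

    Ties break by higher mean ASA, then alphabetical label.
    """
    if len(summaries) < 2:
        raise InputError("need at least 2 ligands to rank")
    return sorted(
        summaries,
        key=lambda lab: (
            -summaries[lab].exposed_fraction,
            -summaries[lab].mean_asa if np.isfinite(summaries[lab].mean_asa) else 0.0,
            lab,
        ),
    )
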