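"""Ground-truth-labelled synthetic inputs.

Three generators emulate the study's data at desk scale:

* :func:`make_toy_complex` - a pseudo-atomic antigen-binding groove
  (two dense carbon walls flanking a floor, forming a channel) holding a
  myristoylated tetrapeptide ligand (MYR acyl chain + Gly1-X2-X3-Ile4).
  A single elevation parameter places the Gly1 residue above the groove
  rim (epitope-exposed) or down inside the channel (epitope-buried); the
  generator verifies the achieved Gly1 ASA with the SASA engine and
  nudges the elevation until it clears the requested margin.
* :func:`make_markov_trajectory` - frames that switch between the
  exposed and buried templates as a hidden two-state Markov chain, with
  i.i.d. Gaussian coordinate jitter on every atom; true state labels are
  returned for recovery experiments.
* :func:`make_sensorgram_set` - multi-concentration 1:1 Langmuir
  sensorgrams (serial dilutions) with additive Gaussian noise and
  optional linear drift, plus a zero-concentration reference trace.
  :func:`make_two_site_sensorgram_set` generates data from a two-site
  heterogeneous surface, which the 1:1 global fit should reject.

All generators are pure functions of (spec, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CongruenceError, GenerationError, InputError
from .kinetics import KineticParams, Sensorgram, model_response
from .sasa import SasaParams, compute_sasa
from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "ToyComplexSpec",
    "TwoStateMarkovSpec",
    "SensorgramSpec",
    "make_toy_complex",
    "make_markov_trajectory",
    "make_sensorgram_set",
    "make_two_site_sensorgram_set",
]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of the pseudo-atomic groove-ligand complex.

    The channel runs along x; walls are dense carbon lattices at
    y = +/- ``channel_half_width`` rising to ``wall_height`` above the
    floor (z = 0). ``exposed_target``/``buried_target`` sit inside the
    50/25 A^2 classification thresholds so that coordinate jitter rarely
    flips a constructed label.
    """

    channel_half_width: float = 2.8  # A
    channel_length: float = 19.5  # A
    wall_height: float = 6.0  # A, groove rim
    lattice_spacing: float = 1.5  # A between groove pseudo-atoms
    exposed_elevation: float = 4.0  # A of Gly1 above the rim, start value
    buried_elevation: float = -3.0  # A (below the rim), start value
    exposed_target: float = 55.0  # A^2, generation margin
    buried_target: float = 20.0  # A^2
    placement_jitter: float = 0.05  # A, seed-dependent coordinate wobble
    seed: int = 0
    sasa_params: SasaParams = field(default_factory=SasaParams)


@dataclass(frozen=True)
class TwoStateMarkovSpec:
    """Two-state (exposed/buried) Markov switching with jitter."""

    p_eb: float = 0.02  # per-frame exposed -> buried probability
    p_be: float = 0.08  # per-frame buried -> exposed probability
    jitter_sigma: float = 0.15  # A, i.i.d. per coordinate
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_eb <= 1.0 and 0.0 <= self.p_be <= 1.0):
            raise InputError("transition probabilities must lie in [0, 1]")
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")

    @property
    def stationary_exposed(self) -> float:
        """Stationary probability of the exposed state."""
        if self.p_eb + self.p_be == 0:
            return 1.0  # chain never leaves its (exposed) start state
        return self.p_be / (self.p_eb + self.p_be)


@dataclass(frozen=True)
class SensorgramSpec:
    """Serial-dilution BLI simulation settings (study defaults)."""

    params: KineticParams = field(
        default_factory=lambda: KineticParams(ka=1.0e3, kd=2.52e-2, rmax=2.5)
    )
    top_concentration: float = 40e-6  # M
    dilution_factor: float = 2.0
    n_doses: int = 6
    t_assoc: float = 60.0  # s
    t_dissoc: float = 60.0  # s
    dt: float = 0.5  # s sampling interval
    noise_sigma: float = 0.02  # nm
    drift: float = 0.0  # nm/s, added to every trace incl. reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.dt <= 0:
            raise InputError("phase durations and sampling interval must be > 0")
        if self.n_doses < 2:
            raise InputError("need at least 2 doses")

    @property
    def concentrations(self) -> np.ndarray:
        return self.top_concentration / self.dilution_factor ** np.arange(self.n_doses)


# ---------------------------------------------------------------------------
# toy complex


def _groove_atoms(spec: ToyComplexSpec) -> list[tuple[str, str, str, int, np.ndarray, bool]]:
    """(name, element, resname, resseq, xyz, hetatm) for groove pseudo-atoms."""
    s = spec.lattice_spacing
    half_len = spec.channel_length / 2.0
    xs = np.arange(-half_len, half_len + 1e-9, s)
    out = []
    # floor
    ys = np.arange(-spec.channel_half_width, spec.channel_half_width + 1e-9, s)
    for x in xs:
        for y in ys:
            out.append(np.array([x, y, 0.0]))
    # walls
    zs = np.arange(s, spec.wall_height + 1e-9, s)
    for x in xs:
        for z in zs:
            out.append(np.array([x, -spec.channel_half_width, z]))
            out.append(np.array([x, spec.channel_half_width, z]))
    return [
        ("C", "C", "GRV", i + 1, xyz, False) for i, xyz in enumerate(out)
    ]


def _ligand_atoms(
    spec: ToyComplexSpec, elevation: float
) -> list[tuple[str, str, str, int, np.ndarray, bool]]:
    """Ligand atoms as a smooth function of the Gly1 elevation.

    Chain C: MYR acyl chain (resi 0, 14 carbons, running from the Gly1
    amide down into the channel and along the floor toward the B-pocket
    end), GLY resi 1 (N, CA, C, O - the epitopic residue), then three
    pseudo-residues X2, X3 and ILE 4 descending toward the F-pocket
    anchor at the far channel end.
    """
    rim = spec.wall_height
    z_g = rim + elevation  # Gly1 backbone height
    atoms: list[tuple[str, str, str, int, np.ndarray, bool]] = []

    # Gly1 backbone around x ~ 0
    gly = {
        "N": np.array([-0.7, 0.0, z_g]),
        "CA": np.array([0.7, 0.0, z_g + 0.2]),
        "C": np.array([1.9, 0.0, z_g]),
        "O": np.array([2.3, 1.1, z_g + 0.3]),
    }
    for name, xyz in gly.items():
        atoms.append((name, name[0], "GLY", 1, xyz, False))

    # acyl chain: C1 bonded to Gly1 N, descending into the channel then
    # running along the floor in -x
    x0, z0 = -1.8, z_g - 0.6
    x_floor, z_floor = -4.5, 1.6
    n_desc = 5
    for k in range(14):
        if k < n_desc:
            f = k / (n_desc - 1)
            xyz = np.array(
                [x0 + f * (x_floor - x0), 0.35 * (-1) ** k, z0 + f * (z_floor - z0)]
            )
        else:
            xyz = np.array(
                [x_floor - 1.25 * (k - n_desc + 1), 0.35 * (-1) ** k, z_floor]
            )
        atoms.append((f"C{k + 1}", "C", "MYR", 0, xyz, True))

    # peptide residues 2..4 descending from Gly1 toward the F-pocket anchor
    x_anchor, z_anchor = 8.0, 1.8
    for ri, resname in ((2, "ALA"), (3, "ALA"), (4, "ILE")):
        f = (ri - 1) / 3.0
        x = 1.9 + f * (x_anchor - 1.9)
        z = z_g + f * (z_anchor - z_g)
        base = np.array([x, 0.0, z])
        atoms.append(("N", "N", resname, ri, base + np.array([0.5, 0.3, 0.0]), False))
        atoms.append(("CA", "C", resname, ri, base + np.array([1.3, -0.3, 0.1]), False))
        atoms.append(("C", "C", resname, ri, base + np.array([2.1, 0.2, -0.1]), False))
        atoms.append(("O", "O", resname, ri, base + np.array([2.4, 1.3, 0.0]), False))
    return atoms


def _build_complex(spec: ToyComplexSpec, elevation: float, jitter: np.ndarray) -> Structure:
    records = []
    serial = 1
    groove = _groove_atoms(spec)
    ligand = _ligand_atoms(spec, elevation)
    for (name, element, resname, resseq, xyz, het), dxyz in zip(
        groove + ligand, jitter
    ):
        chain = "A" if resname == "GRV" else "C"
        records.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
                # PDB coordinate precision, so templates round-trip exactly
                coords=tuple(np.round(xyz + dxyz, 3)),
                is_hetatm=het or resname == "GRV",
            )
        )
        serial += 1
    return Structure(records)


def make_toy_complex(
    spec: ToyComplexSpec, mode: str = "exposed"
) -> tuple[Structure, float]:
    """Build a groove-ligand complex with a verified Gly1 ASA.

    The Gly1 elevation is adjusted (up for ``exposed``, down for
    ``buried``) in 0.4 A steps until the SASA engine reports an ASA
    beyond the generation margin (> ``exposed_target`` or
    < ``buried_target``); at most 50 adjustments are attempted.

    Returns the structure and the achieved Gly1 ASA (A^2).
    """
    if mode not in ("exposed", "buried"):
        raise InputError(f"mode must be 'exposed' or 'buried', got {mode!r}")
    rng = np.random.default_rng(spec.seed)
    n_atoms = len(_groove_atoms(spec)) + len(_ligand_atoms(spec, 0.0))
    jitter = rng.normal(0.0, spec.placement_jitter, size=(n_atoms, 3))
    elevation = spec.exposed_elevation if mode == "exposed" else spec.buried_elevation
    step = 0.4 if mode == "exposed" else -0.4
    for _ in range(50):
        structure = _build_complex(spec, elevation, jitter)
        result = compute_sasa(structure, spec.sasa_params)
        asa = result.residue_areas[("C", 1, "")]
        if (mode == "exposed" and asa > spec.exposed_target) or (
            mode == "buried" and asa < spec.buried_target
        ):
            return structure, float(asa)
        elevation += step
    raise GenerationError(
        f"could not reach {mode} Gly1 ASA target within 50 adjustment steps "
        f"(last ASA {asa:.1f} A^2)"
    )


def make_markov_trajectory(
    spec: TwoStateMarkovSpec, exposed: Structure, buried: Structure
) -> tuple[Trajectory, np.ndarray]:
    """Two-state switching trajectory with per-atom Gaussian jitter.

    The hidden state starts exposed and evolves with per-frame
    transition probabilities ``p_eb`` and ``p_be``; each frame's
    coordinates are the current state's template plus i.i.d. N(0,
    jitter_sigma^2) displacements on every coordinate. Returns the
    trajectory and the true per-frame labels ("exposed"/"buried").
    """
    if len(exposed) != len(buried):
        raise CongruenceError("exposed and buried templates differ in atom count")
    for a, b in zip(exposed.atoms, buried.atoms):
        if (a.chain_id, a.residue_seq, a.name) != (b.chain_id, b.residue_seq, b.name):
            raise CongruenceError("exposed and buried templates differ in atom order")
    rng = np.random.default_rng(spec.seed)
    templates = {"exposed": exposed.coords, "buried": buried.coords}
    labels = np.empty(spec.n_frames, dtype=object)
    state = "exposed"
    u = rng.random(spec.n_frames)
    frames = np.empty((spec.n_frames, len(exposed), 3))
    for i in range(spec.n_frames):
        labels[i] = state
        frames[i] = templates[state] + rng.normal(
            0.0, spec.jitter_sigma, size=(len(exposed), 3)
        )
        if state == "exposed":
            state = "buried" if u[i] < spec.p_eb else "exposed"
        else:
            state = "exposed" if u[i] < spec.p_be else "buried"
    return Trajectory(topology=exposed, frames=frames), labels


# ---------------------------------------------------------------------------
# sensorgrams


def _time_grid(spec: SensorgramSpec) -> np.ndarray:
    return np.arange(0.0, spec.t_assoc + spec.t_dissoc + spec.dt / 2, spec.dt)


def _noisy_curve(
    spec: SensorgramSpec, clean: np.ndarray, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    return clean + spec.drift * t + rng.normal(0.0, spec.noise_sigma, size=t.size)


def make_sensorgram_set(
    spec: SensorgramSpec,
) -> tuple[list[Sensorgram], Sensorgram]:
    """Serial-dilution sensorgram set plus a zero-concentration reference.

    With ``noise_sigma`` and ``drift`` zero the curves equal
    :func:`epidyn.kinetics.model_response` exactly. Drift is shared by
    the reference trace, so reference subtraction removes it.
    """
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec)
    curves = []
    for i, conc in enumerate(spec.concentrations):
        clean = model_response(spec.params, float(conc), t, spec.t_assoc)
        curves.append(
            Sensorgram(
                time=t,
                response=_noisy_curve(spec, clean, t, rng),
                concentration=float(conc),
                t_assoc=spec.t_assoc,
                label=f"dose{i + 1}",
            )
        )
    reference = Sensorgram(
        time=t,
        response=_noisy_curve(spec, np.zeros_like(t), t, rng),
        concentration=0.0,
        t_assoc=spec.t_assoc,
        label="reference",
    )
    return curves, reference


def make_two_site_sensorgram_set(
    spec: SensorgramSpec,
    params2: KineticParams | None = None,
    fraction: float = 0.5,
) -> tuple[list[Sensorgram], Sensorgram]:
    """Sensorgrams from a heterogeneous two-site surface.

    The response is a mixture of two independent 1:1 sites:
    ``spec.params`` with weight ``1 - fraction`` and ``params2`` with
    weight ``fraction`` (each weight scaling R_max). The default second
    site binds and releases fast (k_a = 5e4 /(M s), k_d = 1 /s); paired
    with a slow first site (e.g. k_a = 200, k_d = 5e-3, the same 25 uM
    affinity) the traces are strongly biphasic - an instantaneous step
    riding on a slow ramp - which a single 1:1 model cannot track. This
    is the construction used to exercise poor-fit flagging.
    """
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie in (0, 1)")
    params2 = params2 or KineticParams(ka=5.0e4, kd=1.0, rmax=spec.params.rmax)
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec)
    p1 = replace(spec.params, rmax=spec.params.rmax * (1.0 - fraction))
    p2 = replace(params2, rmax=spec.params.rmax * fraction)
    curves = []
    for i, conc in enumerate(spec.concentrations):
        clean = model_response(p1, float(conc), t, spec.t_assoc) + model_response(
            p2, float(conc), t, spec.t_assoc
        )
        curves.append(
            Sensorgram(
                time=t,
                response=_noisy_curve(spec, clean, t, rng),
                concentration=float(conc),
                t_assoc=spec.t_assoc,
                label=f"dose{i + 1}",
            )
        )
    reference = Sensorgram(
        time=t,
        response=_noisy_curve(spec, np.zeros_like(t), t, rng),
        concentration=0.0,
        t_assoc=spec.t_assoc,
        label="reference",
    )
    return curves, reference
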