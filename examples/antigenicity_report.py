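"""End-to-end antigenic-strength report for two synthetic ligands.

Ligand "strong" switches rarely out of the epitope-exposed state
(stationary exposed fraction 0.8) and carries well-behaved 1:1
sensorgrams; ligand "weak" is buried-dominant (stationary 0.2). The
pipeline classifies each trajectory, fits the kinetics, applies the
call rule (high iff pooled exposed fraction >= 0.5 and K_D determined)
and ranks the ligands by exposed fraction.
"""

from epidyn.kinetics import reference_subtract
from epidyn.pipeline import LigandInput, run_report
from epidyn.synthetic_data import (
    SensorgramSpec,
    ToyComplexSpec,
    TwoStateMarkovSpec,
    make_markov_trajectory,
    make_sensorgram_set,
    make_toy_complex,
)

cspec = ToyComplexSpec(seed=7)
exposed, _ = make_toy_complex(cspec, "exposed")
buried, _ = make_toy_complex(cspec, "buried")

traj_strong, _ = make_markov_trajectory(
    TwoStateMarkovSpec(p_eb=0.02, p_be=0.08, n_frames=600, seed=21), exposed, buried
)
traj_weak, _ = make_markov_trajectory(
    TwoStateMarkovSpec(p_eb=0.08, p_be=0.02, n_frames=600, seed=22), exposed, buried
)
curves, ref = make_sensorgram_set(SensorgramSpec(seed=31))
sensorgrams = [reference_subtract(c, ref) for c in curves]

ligands = [
    LigandInput(label="strong", trajectories=[traj_strong], sensorgrams=sensorgrams),
    LigandInput(label="weak", trajectories=[traj_weak]),
]
reports, summary = run_report(ligands)

for r in reports:
    kd = f"{r.kD * 1e6:.1f} uM" if r.kD is not None else f"n.d. ({r.kD_reason})"
    print(
        f"{r.label:6s} exposed fraction {r.pooled_exposed_fraction:.3f}  "
        f"K_D {kd:28s} call: {r.antigenicity}"
    )
print("ranking:", " > ".join(summary["ranking_by_exposed_fraction"]))
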