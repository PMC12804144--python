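"""Epitope-state occupancy of a switching trajectory.

Generates a two-state Markov trajectory (exposed <-> buried templates,
coordinate jitter 0.15 A), samples the Gly1 ASA every 10 frames, and
summarises how much of the time each conformational state occupies.
With p(exposed->buried) = 0.02 and p(buried->exposed) = 0.08 the
stationary exposed fraction is 0.08/0.10 = 0.8 - a strongly antigenic
profile, where the epitope is presented most of the measurement time.
"""

from epidyn.synthetic_data import (
    ToyComplexSpec,
    TwoStateMarkovSpec,
    make_markov_trajectory,
    make_toy_complex,
)
from epidyn.traj_analysis import (
    AnalysisParams,
    classify_states,
    occupancy,
    residue_asa_series,
)

cspec = ToyComplexSpec(seed=7)
exposed, _ = make_toy_complex(cspec, "exposed")
buried, _ = make_toy_complex(cspec, "buried")

mspec = TwoStateMarkovSpec(p_eb=0.02, p_be=0.08, n_frames=1000, seed=11)
traj, true_labels = make_markov_trajectory(mspec, exposed, buried)

series = residue_asa_series(traj, AnalysisParams(stride=10))
states = classify_states(series)
summary = occupancy(states, series.values)

print(f"samples analysed      : {series.values.size} (every 10th of {traj.frame_count} frames)")
print(f"exposed fraction      : {summary.fractions['exposed']:.3f}  (stationary truth {mspec.stationary_exposed:.2f})")
print(f"transition fraction   : {summary.fractions['transition']:.3f}")
print(f"buried fraction       : {summary.fractions['buried']:.3f}")
print(f"state changes         : {summary.n_changes}")
print(f"mean Gly1 ASA         : {summary.mean_asa:.1f} A^2")
print(
    "\nA ligand sustaining the exposed state for most of the run ranks as "
    "antigenically strong; the fractions above recover the generating chain."
)
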