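"""Strided ASA series, three-state classification, occupancy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidyn.errors import InputError, LookupAtomError, ParameterError
from epidyn.sasa import compute_sasa
from epidyn.structure_io import Trajectory, parse_pdb
from epidyn.synthetic_data import TwoStateMarkovSpec, make_markov_trajectory
from epidyn.traj_analysis import (
    BURIED,
    EXPOSED,
    TRANSITION,
    AnalysisParams,
    AsaSeries,
    OccupancySummary,
    StateThresholds,
    classify_states,
    occupancy,
    rank_ligands,
    residue_asa_series,
)

TINY_LIGAND = (
    "ATOM      1  N   GLY C   1       0.000   0.000   0.000  1.00 20.00           N\n"
    "ATOM      2  CA  GLY C   1       1.450   0.000   0.000  1.00 20.00           C\n"
    "HETATM    3  C1  MYR C   0      -1.400   0.600   0.000  1.00 20.00           C\n"
)


def tiny_trajectory(n_frames: int) -> Trajectory:
    topo = parse_pdb(TINY_LIGAND)
    frames = np.repeat(topo.coords[np.newaxis], n_frames, axis=0)
    return Trajectory(topology=topo, frames=frames)


class TestAsaSeries:
    def test_5000_frames_stride_10_gives_500_samples(self):
        series = residue_asa_series(
            tiny_trajectory(5000), AnalysisParams(target_residue=("C", 1), stride=10)
        )
        assert series.values.size == 500
        assert series.frame_indices[0] == 0
        assert series.frame_indices[-1] == 4990

    def test_stride_1_three_frames(self):
        series = residue_asa_series(
            tiny_trajectory(3), AnalysisParams(target_residue=("C", 1), stride=1)
        )
        assert series.values.size == 3

    def test_frozen_trajectory_matches_static_sasa(self):
        traj = tiny_trajectory(4)
        series = residue_asa_series(
            traj, AnalysisParams(target_residue=("C", 1), stride=1)
        )
        static = compute_sasa(traj.topology).residue_areas[("C", 1, "")]
        np.testing.assert_allclose(series.values, static)

    def test_missing_residue_is_lookup_error(self):
        with pytest.raises(LookupAtomError):
            residue_asa_series(
                tiny_trajectory(2), AnalysisParams(target_residue=("Z", 9))
            )

    def test_stride_must_be_positive(self):
        with pytest.raises(ParameterError):
            AnalysisParams(stride=0)


class TestClassifyStates:
    def test_example_bands(self):
        series = AsaSeries(frame_indices=[0, 1, 2], values=[60.0, 30.0, 10.0])
        assert list(classify_states(series)) == [EXPOSED, TRANSITION, BURIED]

    @pytest.mark.parametrize("value, state", [(50.0, TRANSITION), (25.0, TRANSITION),
                                              (50.01, EXPOSED), (24.99, BURIED)])
    def test_boundaries_are_transition(self, value, state):
        series = AsaSeries(frame_indices=[0], values=[value])
        assert classify_states(series)[0] == state

    def test_all_zero_is_buried(self):
        series = AsaSeries(frame_indices=range(5), values=np.zeros(5))
        assert set(classify_states(series)) == {BURIED}

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            classify_states(AsaSeries(frame_indices=[], values=[]))

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ParameterError):
            StateThresholds(exposed_min=20.0, buried_max=30.0)


class TestOccupancy:
    def test_counting_example(self):
        summary = occupancy(np.array([EXPOSED, EXPOSED, BURIED], dtype=object))
        assert summary.fractions[EXPOSED] == pytest.approx(2 / 3)
        assert summary.fractions[BURIED] == pytest.approx(1 / 3)
        assert summary.n_changes == 1

    def test_constant_sequence(self):
        summary = occupancy(np.array([BURIED] * 7, dtype=object))
        assert summary.fractions[BURIED] == 1.0
        assert summary.n_changes == 0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            occupancy(np.array([], dtype=object))

    @given(st.lists(st.sampled_from([EXPOSED, TRANSITION, BURIED]), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_sum_to_one(self, states):
        summary = occupancy(np.array(states, dtype=object))
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(summary.counts.values()) == len(states)

    def test_markov_label_fraction_near_stationary(self, toy_pair):
        # generator-labelled chain: label fraction itself, no SASA involved
        exposed, _, buried, _ = toy_pair
        spec = TwoStateMarkovSpec(p_eb=0.02, p_be=0.08, n_frames=5000, seed=11)
        _, labels = make_markov_trajectory(spec, exposed, buried)
        frac = np.mean(labels == "exposed")
        # 3 binomial SEs with the chain's autocorrelation-corrected n_eff
        rho = 1.0 - spec.p_eb - spec.p_be
        n_eff = spec.n_frames * (1 - rho) / (1 + rho)
        se = np.sqrt(0.8 * 0.2 / n_eff)
        assert abs(frac - spec.stationary_exposed) < 3 * se


class TestRankLigands:
    def make(self, exposed_frac, mean_asa=40.0, label=""):
        other = 1.0 - exposed_frac
        return OccupancySummary(
            fractions={EXPOSED: exposed_frac, TRANSITION: 0.0, BURIED: other},
            counts={EXPOSED: 0, TRANSITION: 0, BURIED: 0},
            n_changes=0,
            mean_asa=mean_asa,
            label=label,
        )

    def test_descending_by_exposed_fraction(self):
        order = rank_ligands({"A": self.make(0.9), "B": self.make(0.2)})
        assert order == ["A", "B"]

    def test_tie_breaks_by_mean_asa(self):
        order = rank_ligands(
            {"lo": self.make(0.5, mean_asa=52.0), "hi": self.make(0.5, mean_asa=55.0)}
        )
        assert order == ["hi", "lo"]

    def test_three_distinct(self):
        order = rank_ligands(
            {"a": self.make(0.3), "b": self.make(0.7), "c": self.make(0.5)}
        )
        assert order == ["b", "c", "a"]

    def test_fewer_than_two_rejected(self):
        with pytest.raises(InputError):
            rank_ligands({"only": self.make(0.5)})
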