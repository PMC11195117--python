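import networkx as nx
import numpy as np
import pandas as pd
import pytest

from boutonpipe.heterogeneity import (
    aggregate_same_fraction,
    axon_heterogeneity,
    label_peak_outcome,
    match_peaks,
    outcome_peak_fractions,
    same_peak_fraction,
)


def max_matching_oracle(t_i, t_j, tol=0.670):
    """Independent maximum-cardinality bipartite matching via networkx."""
    g = nx.Graph()
    g.add_nodes_from([("i", k) for k in range(len(t_i))], bipartite=0)
    g.add_nodes_from([("j", k) for k in range(len(t_j))], bipartite=1)
    for a, ta in enumerate(t_i):
        for b, tb in enumerate(t_j):
            if abs(ta - tb) <= tol:
                g.add_edge(("i", a), ("j", b))
    top = [n for n in g.nodes if n[0] == "i"]
    return len(nx.bipartite.maximum_matching(g, top_nodes=top)) // 2


class TestMatchPeaks:
    def test_identical_trains_fully_matched(self):
        t = np.array([1.0, 3.0, 7.0])
        m = match_peaks(t, t)
        assert m.n_matched == 3
        assert m.unique_i.size == m.unique_j.size == 0

    def test_offset_beyond_tolerance_matches_nothing(self):
        t = np.array([1.0, 3.0, 7.0])
        m = match_peaks(t, t + 1.0)
        assert m.n_matched == 0
        assert m.unique_i.size == 3 and m.unique_j.size == 3

    def test_mixed_example_equals_exhaustive_matching(self):
        m = match_peaks(np.array([1.0, 5.0]), np.array([1.5, 9.0]))
        assert m.matched == [(1.0, 1.5)]
        np.testing.assert_allclose(m.unique_i, [5.0])
        np.testing.assert_allclose(m.unique_j, [9.0])
        assert m.n_matched == max_matching_oracle([1.0, 5.0], [1.5, 9.0])

    def test_symmetry_swapping_inputs(self, rng):
        t_i = np.sort(rng.uniform(0, 60, 12))
        t_j = np.sort(rng.uniform(0, 60, 15))
        m1 = match_peaks(t_i, t_j)
        m2 = match_peaks(t_j, t_i)
        assert m1.n_matched == m2.n_matched
        assert {(a, b) for a, b in m1.matched} == {
            (b, a) for a, b in m2.matched
        }

    def test_greedy_equals_optimal_on_spaced_trains(self, rng):
        # spacing > 2 tol within each train guarantees greedy optimality
        tol = 0.670
        for _ in range(200):
            n_i, n_j = rng.integers(0, 8, 2)
            t_i = np.cumsum(rng.uniform(2 * tol + 0.01, 5.0, n_i))
            t_j = np.cumsum(rng.uniform(2 * tol + 0.01, 5.0, n_j))
            m = match_peaks(t_i, t_j, tol)
            assert m.n_matched == max_matching_oracle(t_i, t_j, tol)

    def test_one_to_one_and_conservation(self, rng):
        t_i = np.sort(rng.uniform(0, 30, 10))
        t_j = np.sort(rng.uniform(0, 30, 7))
        m = match_peaks(t_i, t_j)
        assert m.n_matched <= min(10, 7)
        assert m.n_matched + m.unique_i.size == 10
        assert m.n_matched + m.unique_j.size == 7
        assert all(abs(a - b) <= 0.670 for a, b in m.matched)


class TestSamePeakFraction:
    def test_all_matched_gives_one(self):
        t = np.array([1.0, 3.0])
        assert same_peak_fraction(match_peaks(t, t)) == 1.0

    def test_no_matches_gives_zero(self):
        m = match_peaks(np.array([1.0]), np.array([10.0]))
        assert same_peak_fraction(m) == 0.0

    def test_two_of_three_matched(self):
        m = match_peaks(
            np.array([1.0, 5.0, 20.0]), np.array([1.2, 5.3, 40.0])
        )
        assert m.n_matched == 2
        assert same_peak_fraction(m) == pytest.approx(4 / 6)

    def test_empty_pair_is_an_error(self):
        with pytest.raises(ValueError, match="both trains empty"):
            same_peak_fraction(match_peaks(np.array([]), np.array([])))


class TestAggregate:
    def test_uniform_fraction_passes_through(self):
        df = pd.DataFrame(
            {
                "axon_id": [0, 0, 0, 1],
                "bouton_i": [0, 0, 1, 3],
                "bouton_j": [1, 2, 2, 4],
                "fraction": [0.5] * 4,
            }
        )
        assert aggregate_same_fraction(df) == pytest.approx(0.5)

    def test_two_homogeneous_axons_average(self):
        df = pd.DataFrame(
            {
                "axon_id": [0, 1],
                "bouton_i": [0, 2],
                "bouton_j": [1, 3],
                "fraction": [0.4, 0.8],
            }
        )
        assert aggregate_same_fraction(df) == pytest.approx(0.6)

    def test_matches_exhaustive_three_level_oracle(self, rng):
        rows = []
        for axon in range(3):
            boutons = [axon * 10 + k for k in range(4)]
            for i in range(4):
                for j in range(i + 1, 4):
                    rows.append(
                        (axon, boutons[i], boutons[j], rng.uniform())
                    )
        df = pd.DataFrame(
            rows, columns=["axon_id", "bouton_i", "bouton_j", "fraction"]
        )
        # brute force: bouton means, then axon means, then the mouse mean
        axon_vals = []
        for axon in range(3):
            sub = df[df.axon_id == axon]
            bmeans = []
            for b in set(sub.bouton_i) | set(sub.bouton_j):
                vals = sub[(sub.bouton_i == b) | (sub.bouton_j == b)][
                    "fraction"
                ]
                bmeans.append(vals.mean())
            axon_vals.append(np.mean(bmeans))
        assert aggregate_same_fraction(df) == pytest.approx(
            np.mean(axon_vals)
        )


class TestOutcomeLabels:
    onsets = np.array([10.0, 30.0])
    labels = np.array(["RM", "UM"])

    def test_peak_shortly_after_rm_onset(self):
        assert label_peak_outcome(10.2, self.onsets, self.labels) == "RM"

    def test_peak_too_early_is_none(self):
        assert label_peak_outcome(9.5, self.onsets, self.labels) == "none"

    def test_peak_late_in_um_window(self):
        assert label_peak_outcome(30.6, self.onsets, self.labels) == "UM"

    def test_overlap_resolved_to_nearest_onset(self):
        onsets = np.array([10.0, 10.8])
        labels = np.array(["RM", "UM"])
        assert label_peak_outcome(10.65, onsets, labels) == "UM"

    def test_outcome_fractions_toy_table(self):
        m = match_peaks(np.array([10.1, 30.1]), np.array([10.2, 50.0]))
        out = outcome_peak_fractions([m], self.onsets, self.labels)
        # RM peaks: one matched pair -> RM_same = 1
        assert out["RM_same"] == pytest.approx(1.0)
        assert out["RM_unique"] == pytest.approx(0.0)
        # UM peaks: the unique 30.1 event -> UM_unique = 1
        assert out["UM_unique"] == pytest.approx(1.0)

    def test_no_rm_peaks_reported_missing(self):
        m = match_peaks(np.array([100.0]), np.array([100.1]))
        out = outcome_peak_fractions(
            [m], np.array([10.0]), np.array(["RM"])
        )
        assert np.isnan(out["RM_same"])


class TestAxonHeterogeneity:
    @pytest.mark.parametrize(
        "classes, expected",
        [
            (["RM_only"] * 5, 0.0),
            (["RM_only"] * 3 + ["UM_only"] * 3, 0.5),
            (["RM_only"] * 4 + ["UM_only"], 0.2),
        ],
    )
    def test_minority_fraction(self, classes, expected):
        assert axon_heterogeneity(classes) == pytest.approx(expected)

    def test_both_and_none_excluded(self):
        classes = ["RM_only", "UM_only", "both", "none", "RM_only"]
        assert axon_heterogeneity(classes) == pytest.approx(1 / 3)

    def test_fewer_than_two_selective_is_an_error(self):
        with pytest.raises(ValueError, match="two RM/UM-selective"):
            axon_heterogeneity(["RM_only", "both", "none"])


class TestSharedFractionConvergence:
    def test_same_peak_fraction_tracks_p_shared(self):
        """Lower p_shared must strictly lower the mean same-peak fraction,
        and at each level the detected-event fraction must agree with the
        ground-truth-log prediction."""
        from boutonpipe.signals import compute_dff, detect_events, zscore_trace
        from boutonpipe.synthetic import (
            BehaviorSpec,
            SimConfig,
            simulate_behavior,
            simulate_fluorescence,
        )

        measured, predicted = [], []
        for p_shared in (0.9, 0.6, 0.3):
            cfg = SimConfig(
                n_axons=1, boutons_per_axon=2, n_frames=15000,
                noise_sd=0.0, p_shared=p_shared,
                shared_event_rate=0.12, unique_event_rate=0.03,
                frac_rm_only=0, frac_um_only=0, frac_both=0,
                min_event_spacing=1.5,
                behavior=BehaviorSpec(p_success=0, p_fail_push=0,
                                      p_iti_push=0),
            )
            session, tb = simulate_behavior(cfg, 13)
            fset, truth = simulate_fluorescence(cfg, session, tb, 13)
            dff = compute_dff(fset.raw, fset.frame_rate)
            z = zscore_trace(dff)
            trains = [
                detect_events(dff[b], z[b], fset.frame_rate).times
                for b in range(2)
            ]
            m = match_peaks(trains[0], trains[1])
            measured.append(same_peak_fraction(m))
            gt = [
                truth.events.query("bouton_id == @b")["time_s"].to_numpy()
                for b in range(2)
            ]
            m_gt = match_peaks(gt[0], gt[1])
            predicted.append(same_peak_fraction(m_gt))
        for got, exp in zip(measured, predicted):
            assert got == pytest.approx(exp, abs=0.05)
        assert measured[0] > measured[1] > measured[2]
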