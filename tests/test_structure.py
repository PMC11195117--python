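import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boutonpipe.structure import (
    BoutonTrack,
    annotate_dynamics,
    density_day_correlation,
    density_timecourse,
    ecdf,
    function_structure_join,
    new_bouton_pair_distances,
    survival_curve,
    turnover_rates,
)
from boutonpipe.synthetic import SimConfig, StructureSpec, simulate_structure


def make_track(presence_rows, positions=None, length=50.0):
    n = len(presence_rows)
    days = list(range(0, 2 * len(presence_rows[0]), 2))
    boutons = pd.DataFrame(
        {
            "bouton_id": range(n),
            "axon_id": [0] * n,
            "position_um": positions if positions is not None
            else np.linspace(1, length - 1, n),
        }
    )
    presence = pd.DataFrame(
        presence_rows, columns=days,
        index=pd.Index(range(n), name="bouton_id"),
    ).astype(bool)
    return BoutonTrack(
        boutons=boutons,
        presence=presence,
        axon_length_um=pd.Series([length], index=pd.Index([0],
                                 name="axon_id")),
    )


class TestAnnotateDynamics:
    def test_always_present_is_persistent(self):
        track = make_track([[1, 1, 1]])
        ann = annotate_dynamics(track)
        assert (ann.state == "persistent").all()

    def test_formation_on_first_pair(self):
        track = make_track([[0, 1, 1], [1, 1, 1]])
        ann = annotate_dynamics(track)
        first = ann[(ann.bouton_id == 0) & (ann.day_from == 0)]
        assert first.state.iloc[0] == "formed"

    def test_reappearance_is_elimination_then_formation(self):
        track = make_track([[1, 0, 1]])
        states = annotate_dynamics(track).state.tolist()
        assert states == ["eliminated", "formed"]

    def test_every_transition_has_exactly_one_state(self):
        cfg = SimConfig(n_axons=10)
        track, _ = simulate_structure(cfg, 3)
        ann = annotate_dynamics(track)
        n_pairs = len(track.days) - 1
        assert len(ann) == len(track.boutons) * n_pairs

    def test_annotations_equal_simulator_event_log(self):
        cfg = SimConfig(n_axons=15)
        track, truth = simulate_structure(cfg, 9)
        ann = annotate_dynamics(track)
        got = ann[ann.state.isin(["formed", "eliminated"])]
        got = set(zip(got.bouton_id, got.day_to, got.state))
        exp = set(
            zip(truth.structural_events.bouton_id,
                truth.structural_events.day,
                truth.structural_events.kind)
        )
        assert got == exp


class TestDensity:
    def test_ten_boutons_on_fifty_um(self):
        track = make_track([[1, 1, 1]] * 10, length=50.0)
        dens = density_timecourse(track)
        assert dens[("density", 0)].iloc[0] == pytest.approx(0.2)

    def test_no_turnover_normalized_is_one(self):
        track = make_track([[1, 1, 1]] * 5)
        dens = density_timecourse(track)
        for d in (0, 2, 4):
            assert dens[("normalized", d)].iloc[0] == pytest.approx(1.0)

    def test_net_formation_increases_mean_normalized_density(self):
        cfg = SimConfig(
            n_axons=40,
            structure=StructureSpec(formation_rate=0.25,
                                    elimination_rate=0.02),
        )
        track, _ = simulate_structure(cfg, 5)
        dens = density_timecourse(track)
        means = [dens[("normalized", d)].mean() for d in track.days]
        assert all(b > a for a, b in zip(means[:-1], means[1:]))

    def test_bookkeeping_identity_exact(self):
        cfg = SimConfig(n_axons=25)
        track, _ = simulate_structure(cfg, 17)
        ann = annotate_dynamics(track)
        for d0, d1 in zip(track.days[:-1], track.days[1:]):
            sub = ann[ann.day_from == d0]
            present0 = int(track.presence[d0].sum())
            present1 = int(track.presence[d1].sum())
            formed = int((sub.state == "formed").sum())
            eliminated = int((sub.state == "eliminated").sum())
            assert present1 == present0 - eliminated + formed


class TestTurnover:
    def test_no_changes_zero_rates(self):
        track = make_track([[1, 1, 1]] * 8)
        rates = turnover_rates(track)
        assert (rates.formation_pct == 0).all()
        assert (rates.elimination_pct == 0).all()

    def test_two_formed_from_twenty(self):
        rows = [[1, 1]] * 20 + [[0, 1]] * 2
        track = make_track(rows)
        rates = turnover_rates(track)
        assert rates.formation_pct.iloc[0] == pytest.approx(10.0)

    def test_programmed_rates_within_binomial_ci(self):
        cfg = SimConfig(
            n_axons=50,
            structure=StructureSpec(formation_rate=0.08,
                                    elimination_rate=0.06),
        )
        track, _ = simulate_structure(cfg, 23)
        rates = turnover_rates(track)
        n = rates.present_before.sum()
        f = rates.formed.sum() / n
        e = rates.eliminated.sum() / n
        assert abs(f - 0.08) < 1.96 * np.sqrt(0.08 * 0.92 / n) + 1e-9
        assert abs(e - 0.06) < 1.96 * np.sqrt(0.06 * 0.94 / n) + 1e-9


class TestSurvival:
    def test_all_persist(self):
        track = make_track([[0, 0, 1, 1, 1, 1]] * 4)
        surv = survival_curve(track)
        assert surv.tolist() == [1.0, 1.0, 1.0]

    def test_all_eliminated_by_day6(self):
        track = make_track([[0, 0, 1, 0, 0, 0]] * 4)
        assert survival_curve(track).tolist() == [0.0, 0.0, 0.0]

    def test_no_formed_boutons_is_an_error(self):
        track = make_track([[1, 1, 1, 1, 1, 1]] * 4)
        with pytest.raises(ValueError, match="no boutons formed"):
            survival_curve(track)

    def test_geometric_decay_within_ci(self):
        # per-interval survival 0.8 -> curve ~ (0.8, 0.64, 0.512)
        rng = np.random.default_rng(31)
        n = 600
        rows = []
        for _ in range(n):
            alive = True
            row = [0, 0, 1]  # formed on day 4
            for _ in range(3):
                alive = alive and rng.random() < 0.8
                row.append(int(alive))
            rows.append(row)
        track = make_track(rows)
        surv = survival_curve(track)
        for frac, expect in zip(surv, (0.8, 0.64, 0.512)):
            half = 1.96 * np.sqrt(expect * (1 - expect) / n)
            assert abs(frac - expect) < half + 1e-9


class TestPairDistances:
    def test_two_formed_boutons_distance(self):
        track = make_track(
            [[1, 1], [0, 1], [0, 1]], positions=[30.0, 10.0, 14.0]
        )
        d = new_bouton_pair_distances(track, day=2)
        np.testing.assert_allclose(d, [4.0])

    def test_single_formed_bouton_no_pairs(self):
        track = make_track([[1, 1], [0, 1]], positions=[30.0, 10.0])
        assert new_bouton_pair_distances(track, day=2).size == 0

    def test_clustered_simulator_detected_by_ecdf_comparison(self):
        base = SimConfig(
            n_axons=40,
            structure=StructureSpec(formation_rate=0.25,
                                    elimination_rate=0.0,
                                    cluster_scale_um=5.0),
        )
        clustered, _ = simulate_structure(base, 41)
        uniform_cfg = SimConfig(
            n_axons=40,
            structure=StructureSpec(formation_rate=0.25,
                                    elimination_rate=0.0,
                                    cluster_scale_um=None),
        )
        uniform, _ = simulate_structure(uniform_cfg, 41)
        d_c = np.concatenate(
            [new_bouton_pair_distances(clustered, d)
             for d in clustered.days[1:]]
        )
        d_u = np.concatenate(
            [new_bouton_pair_distances(uniform, d)
             for d in uniform.days[1:]]
        )
        assert d_c.size >= 50 and d_u.size >= 50
        assert d_c.mean() < d_u.mean()
        assert stats.ks_2samp(d_c, d_u).pvalue < 0.05
        x, f = ecdf(d_c)
        assert f[0] > 0 and f[-1] == 1.0 and np.all(np.diff(x) >= 0)


class TestDensityCorrelation:
    def test_identical_columns_give_one(self):
        track = make_track([[1, 1, 1]] * 6)
        # build multi-axon densities manually
        dens = pd.DataFrame(
            {("density", 4): [0.1, 0.2, 0.3], ("density", 10): [0.1, 0.2, 0.3]}
        )
        r, _ = density_day_correlation(dens, 4, 10)
        assert r == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        dens = pd.DataFrame(
            {
                ("density", 4): rng.uniform(size=200),
                ("density", 10): rng.uniform(size=200),
            }
        )
        r, _ = density_day_correlation(dens, 4, 10)
        assert abs(r) < 0.2

    def test_axon_specific_rates_induce_positive_correlation(self):
        rng = np.random.default_rng(8)
        n_axons = 60
        cfg = SimConfig(n_axons=n_axons)
        form = rng.uniform(0.0, 0.3, n_axons)  # axon random effects
        track, _ = simulate_structure(
            cfg, 51, formation_rate_per_axon=form,
            elimination_rate_per_axon=np.full(n_axons, 0.05),
        )
        dens = density_timecourse(track)
        r, p = density_day_correlation(dens, 4, 10)
        assert r > 0
        assert p < 0.05


class TestFunctionStructureJoin:
    def test_single_class_equals_pooled(self):
        cfg = SimConfig(n_axons=10)
        track, _ = simulate_structure(cfg, 61)
        classes = pd.DataFrame(
            {
                "axon_id": range(10),
                "early_class": ["RM"] * 10,
                "late_class": ["RM"] * 10,
            }
        )
        join = function_structure_join(track, classes)
        pooled = turnover_rates(track, per_axon=True).groupby("axon_id")[
            "formation_pct"
        ].mean().mean()
        got = join["formation_by_late_class"]
        assert len(got) == 1
        assert got["mean"].iloc[0] == pytest.approx(pooled)

    def test_programmed_coupling_recovers_rm_gt_um(self):
        n_axons = 40
        cfg = SimConfig(n_axons=n_axons)
        late = np.array(["RM"] * 20 + ["UM"] * 20)
        form = np.where(late == "RM", 0.25, 0.05)
        track, _ = simulate_structure(
            cfg, 71, formation_rate_per_axon=form
        )
        classes = pd.DataFrame(
            {"axon_id": range(n_axons), "early_class": late,
             "late_class": late}
        )
        join = function_structure_join(track, classes)
        f = join["formation_by_late_class"].set_index("late_class")["mean"]
        assert f["RM"] > f["UM"]

    def test_unmatched_axons_excluded(self):
        cfg = SimConfig(n_axons=5)
        track, _ = simulate_structure(cfg, 81)
        classes = pd.DataFrame(
            {
                "axon_id": [0, 1, 99],
                "early_class": ["RM", "UM", "RM"],
                "late_class": ["RM", "UM", "RM"],
            }
        )
        join = function_structure_join(track, classes)
        assert join["formation_by_late_class"]["count"].sum() == 2
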