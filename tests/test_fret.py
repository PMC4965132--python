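"""Orientation factor, acceptor selection, Foerster radius, efficiency,
ensemble analysis, and cluster summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretensemble import (PhotophysicsConfig, SelectionSet, TransitionRecord,
                          analyze_ensemble, donor_acceptor_distance,
                          forster_radius, fret_efficiency, orientation_factor,
                          relative_rate, select_acceptor_transition,
                          summarize_clusters)

from conftest import hexagon, make_trajectory

X, Y, Z = np.eye(3)

vec3 = st.tuples(*[st.floats(-5, 5) for _ in range(3)]).filter(
    lambda v: np.linalg.norm(v) > 1e-3)


class TestOrientationFactor:
    @pytest.mark.parametrize("mu_d,mu_a,sep,expected", [
        (Z, Z, X, 1.0),   # parallel dipoles, transverse to the axis
        (X, X, X, 4.0),   # collinear parallel
        (Z, Y, X, 0.0),   # mutually orthogonal
    ])
    def test_limiting_geometries_exact(self, mu_d, mu_a, sep, expected):
        kappa2, _ = orientation_factor(mu_d, mu_a, sep)
        assert kappa2 == expected

    def test_angles_reported(self):
        kappa2, (t_t, t_d, t_a) = orientation_factor(Z, Z, X)
        assert (t_t, t_d, t_a) == (0.0, 90.0, 90.0)

    @given(mu_d=vec3, mu_a=vec3, sep=vec3,
           scale=st.floats(0.01, 100), signs=st.tuples(
               st.sampled_from([-1, 1]), st.sampled_from([-1, 1]),
               st.sampled_from([-1, 1])))
    @settings(max_examples=100, deadline=None)
    def test_range_and_invariance_under_scaling_and_sign(
            self, mu_d, mu_a, sep, scale, signs):
        base, _ = orientation_factor(mu_d, mu_a, sep)
        assert 0.0 <= base <= 4.0
        altered, _ = orientation_factor(
            np.multiply(mu_d, signs[0] * scale),
            np.multiply(mu_a, signs[1]),
            np.multiply(sep, signs[2] * scale))
        assert altered == pytest.approx(base, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            orientation_factor((0, 0, 0), Z, X)


class TestDistance:
    def test_two_points(self):
        traj = make_trajectory(np.array([[[0, 0, 0], [0, 0, 30.0],
                                          [1, 1, 1]]]))
        sel = SelectionSet(donor_ring=[0], acceptor_ring=[1],
                           backbone_fit=[2])
        r, u = donor_acceptor_distance(traj.coords[0], sel)
        assert r == 30.0
        np.testing.assert_allclose(u, [0, 0, 1])

    def test_translation_invariant(self):
        coords = np.random.default_rng(0).normal(size=(12, 3))
        sel = SelectionSet(donor_ring=list(range(6)),
                           acceptor_ring=list(range(6, 12)))
        r1, _ = donor_acceptor_distance(coords, sel)
        r2, _ = donor_acceptor_distance(coords + [3.0, -4.0, 5.0], sel)
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_hexagon_pair_centroid_gap(self):
        frame = np.vstack([hexagon([0, 0, 0]), hexagon([0, 10.0, 0])])
        sel = SelectionSet(donor_ring=list(range(6)),
                           acceptor_ring=list(range(6, 12)))
        r, _ = donor_acceptor_distance(frame, sel)
        assert r == pytest.approx(10.0, abs=1e-9)


class TestAcceptorSelection:
    donor = TransitionRecord(0, "donor", "emission", "S1", 2.4, 0.0,
                             (1.0, 0, 0))

    @staticmethod
    def acceptor(energy, f, state="S1"):
        return TransitionRecord(0, "acceptor", "absorption", state,
                                energy, f, (1.0, 0, 0))

    def test_soret_above_donor_is_skipped_q_band_selected(self):
        candidates = [self.acceptor(3.0, 1.0, "S2"),
                      self.acceptor(1.9, 0.1, "S1")]
        chosen = select_acceptor_transition(self.donor, candidates, 0.75)
        assert chosen is candidates[1]

    def test_tight_cutoff_excludes_all(self):
        candidates = [self.acceptor(3.0, 1.0), self.acceptor(1.9, 0.1)]
        assert select_acceptor_transition(self.donor, candidates, 0.3) is None

    def test_resonant_boundary_excluded_by_strict_inequality(self):
        assert select_acceptor_transition(
            self.donor, [self.acceptor(2.4, 1.0)], 0.75) is None

    def test_most_intense_wins_ties_to_lowest_energy(self):
        candidates = [self.acceptor(2.3, 0.5), self.acceptor(2.1, 0.9),
                      self.acceptor(2.0, 0.9)]
        chosen = select_acceptor_transition(self.donor, candidates, 0.75)
        assert chosen.energy_ev == 2.0


class TestScalarFormulas:
    def test_relative_rate_values(self):
        assert relative_rate(1.0, 1.0) == 1.0
        assert relative_rate(2 / 3, 10.0) == pytest.approx(6.667e-7, rel=1e-3)
        assert relative_rate(1.0, 2.0) == pytest.approx(relative_rate(1.0, 1.0) / 64)

    def test_forster_radius_reference_value(self):
        # independent high-precision evaluation: R0(2/3, n=1.333,
        # Q_D=0.099, J=1.044e15) = 35.25 A in the sixth-power mode
        r0 = forster_radius(2 / 3, PhotophysicsConfig())
        assert r0 == pytest.approx(35.25, abs=0.01)

    def test_forster_radius_scaling_and_zero(self):
        cfg = PhotophysicsConfig()
        assert forster_radius(0.0, cfg) == 0.0
        assert forster_radius(4 * 0.5, cfg) == pytest.approx(
            4 ** (1 / 6) * forster_radius(0.5, cfg), rel=1e-12)

    def test_constant_modes_agree_within_0p2_percent(self):
        r0_a = forster_radius(1.0, PhotophysicsConfig(forster_constant_mode="eq3"))
        r0_b = forster_radius(1.0, PhotophysicsConfig(forster_constant_mode="eq4"))
        assert abs(r0_a - r0_b) / r0_b < 0.002

    def test_efficiency_anchors(self):
        assert fret_efficiency(25.0, 25.0) == 0.5
        assert fret_efficiency(25.0, 50.0) == pytest.approx(1 / 65)
        assert fret_efficiency(0.0, 10.0) == 0.0

    @given(r=st.floats(1.0, 100.0), r2=st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_efficiency_strictly_decreasing_in_r(self, r, r2):
        lo, hi = sorted([r, r2])
        if lo < hi:
            assert fret_efficiency(30.0, lo) > fret_efficiency(30.0, hi)


class TestAnalyzeEnsemble:
    def _single_frame_setup(self):
        frame = np.vstack([hexagon([0, 0, 0]), hexagon([20.0, 0, 0])])
        traj = make_trajectory(frame[None])
        sel = SelectionSet(donor_ring=list(range(6)),
                           acceptor_ring=list(range(6, 12)))
        donor = TransitionRecord(0, "donor", "emission", "S1", 2.4, 0.0,
                                 (0.0, 0.0, 3.0))
        acceptor = TransitionRecord(0, "acceptor", "absorption", "S1",
                                    1.9, 0.1, (0.0, 0.0, 1.0))
        return traj, sel, [donor, acceptor]

    def test_single_frame_reproduces_scalar_formulas(self):
        traj, sel, records = self._single_frame_setup()
        cfg = PhotophysicsConfig()
        (res,) = analyze_ensemble(traj, records, sel, cfg)
        assert res.r == pytest.approx(20.0)
        assert res.kappa2 == pytest.approx(1.0)  # parallel, transverse
        assert res.R0 == pytest.approx(forster_radius(1.0, cfg))
        assert res.efficiency == pytest.approx(fret_efficiency(res.R0, 20.0))
        assert res.k_T_rel == pytest.approx(1.0 / 20.0 ** 6)
        assert res.selected_acceptor_state == "S1"

    def test_frame_without_resonant_acceptor_kept_with_nan(self):
        traj, sel, records = self._single_frame_setup()
        records[1] = TransitionRecord(0, "acceptor", "absorption", "S2",
                                      3.0, 1.0, (0.0, 0.0, 1.0))
        (res,) = analyze_ensemble(traj, records, sel)
        assert np.isnan(res.kappa2) and res.selected_acceptor_state is None
        assert res.r == pytest.approx(20.0)
        assert np.isfinite(res.k_r)

    def test_output_length_equals_frame_count(self, two_mode_ensemble,
                                              two_mode_transitions):
        _, traj, sel, _ = two_mode_ensemble
        results = analyze_ensemble(traj, two_mode_transitions, sel)
        assert len(results) == traj.n_frames

    def test_isotropic_ensemble_mean_efficiency_matches_oracle(self):
        """Ensemble-mean E equals the direct average of
        R0^6/(R0^6 + r^6) over the same kappa^2 samples."""
        from fretensemble import gen_isotropic_pairs
        cfg = PhotophysicsConfig()
        r_fix = forster_radius(2 / 3, cfg)  # operate near R0
        traj, mu_d, mu_a = gen_isotropic_pairs(4000, r_fix, seed=21)
        sel = SelectionSet(donor_ring=[0], acceptor_ring=[1])
        records = []
        for i in range(traj.n_frames):
            records.append(TransitionRecord(i, "donor", "emission", "S1",
                                            2.4, 0.0, tuple(3.0 * mu_d[i])))
            records.append(TransitionRecord(i, "acceptor", "absorption", "S1",
                                            1.9, 0.1, tuple(mu_a[i])))
        results = analyze_ensemble(traj, records, sel, cfg)
        mean_e = np.mean([res.efficiency for res in results])
        kappa2, _ = orientation_factor(mu_d, mu_a, np.array([[1.0, 0, 0]]))
        r0_oracle = (cfg.forster_prefactor * kappa2 *
                     cfg.refractive_index ** -4 * cfg.q_d *
                     cfg.j_overlap) ** (1 / 6)
        oracle = np.mean(r0_oracle ** 6 / (r0_oracle ** 6 + r_fix ** 6))
        assert mean_e == pytest.approx(oracle, abs=1e-12)


class TestSummaries:
    def test_two_mode_cluster_means_recover_generating_means(
            self, two_mode_ensemble, two_mode_transitions):
        from fretensemble import average_linkage, pairwise_rmsd_matrix
        params, traj, sel, labels = two_mode_ensemble
        results = analyze_ensemble(traj, two_mode_transitions, sel)
        summaries = summarize_clusters(results, labels)
        by_id = {s.cluster_id: s for s in summaries}
        for mode, (mean_r, sd_r, w) in enumerate(params.r_modes):
            s = by_id[str(mode)]
            se = sd_r / np.sqrt(s.n_snapshots)
            assert abs(s.mean["r"] - mean_r) < 3 * se

    def test_counts_and_fractions_bookkeeping(self):
        results = []
        labels = []
        from fretensemble import FRETSnapshotResult
        for i in range(10):
            lab = 0 if i < 8 else 1
            r = 10.0 if lab == 0 else 30.0
            results.append(FRETSnapshotResult(
                frame_index=i, r=r, kappa2=0.5, R0=28.0, efficiency=0.9,
                k_T_rel=0.5 / r ** 6, k_r=1e8, selected_acceptor_state="S1"))
            labels.append(lab)
        summaries = summarize_clusters(results, labels, distance_threshold=20.0)
        by_id = {s.cluster_id: s for s in summaries}
        assert by_id["0"].n_snapshots == 8
        assert by_id["0"].fraction == pytest.approx(0.8)
        assert by_id["all"].n_snapshots == 10
        assert by_id["1"].mean["r"] == 30.0
        # a single far cluster does not get a redundant pooled row
        assert all(s.cluster_id in ("0", "1", "all") for s in summaries)

    def test_population_sd_convention(self):
        from fretensemble import FRETSnapshotResult
        rs = [8.0, 12.0]
        results = [FRETSnapshotResult(
            frame_index=i, r=r, kappa2=1.0, R0=30.0, efficiency=0.9,
            k_T_rel=1.0, k_r=1e8, selected_acceptor_state="S1")
            for i, r in enumerate(rs)]
        summaries = summarize_clusters(results, [0, 0])
        s = summaries[0]
        assert s.sd["r"] == pytest.approx(np.std(rs))  # divide-by-N

    def test_misaligned_labels_rejected(self):
        from fretensemble import FRETSnapshotResult
        results = [FRETSnapshotResult(frame_index=0, r=10.0)]
        with pytest.raises(ValueError, match="align"):
            summarize_clusters(results, [0, 1])
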