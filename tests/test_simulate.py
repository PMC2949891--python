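"""Trajectory integration and dataset generation."""

import numpy as np
import pytest

import grncompare as g


class TestIntegrate:
    def test_pure_decay_matches_closed_form(self):
        # zero production, k = 0.3: X(t) = 0.8 * exp(-0.3 t)
        p = g.SSParams(alpha=[0.0], beta=[0.3], g=[[0.0]], h=[[1.0]])
        model = g.GRNModel("SS", g.GRNTopology(1), p)
        s = g.IntegrationSettings(t_end=20.0, n_points=200)
        tr = g.integrate(model, np.array([0.8]), s)
        assert tr.success
        expected = 0.8 * np.exp(-0.3 * tr.t)
        assert np.max(np.abs(tr.x[:, 0] - expected)) < 1e-5

    def test_ann_steady_state(self):
        # single unregulated gene: X* = v * f(-theta) / k
        p = g.ANNParams(v=[1.0], w=[[0.0]], theta=[4.0], k=[0.3])
        model = g.GRNModel("ANN", g.GRNTopology(1), p)
        s = g.IntegrationSettings(t_end=60.0, n_points=100)
        tr = g.integrate(model, np.array([0.9]), s)
        star = 1.0 * float(g.logistic(np.array(-4.0))) / 0.3
        assert abs(tr.x[-1, 0] - star) < 1e-4

    def test_blowup_flagged_not_raised(self):
        # strong positive self-amplification in a power law diverges
        p = g.SSParams(alpha=[5.0], beta=[0.1], g=[[2.0]], h=[[1.0]])
        model = g.GRNModel(
            "SS", g.GRNTopology.from_tuples(1, [(1, 1, "activating")]), p)
        tr = g.integrate(model, np.array([5.0]),
                         g.IntegrationSettings(t_end=50.0, n_points=50))
        assert not tr.success
        assert np.all(np.isfinite(tr.x))

    def test_singular_inhibition_flagged(self, case_models):
        # drive the case C S-system toward X5 = 0 with the negative
        # kinetic order active: integration must flag, not crash
        m = case_models[("C", "SS")]
        d = m.to_dict()
        d["params"]["g"][1][4] = -3.0      # much stronger inhibition
        d["params"]["beta"] = [0.3, 0.3, 0.3, 0.3, 15.0]  # X5 -> 0 fast
        model = g.GRNModel.from_dict(d)
        tr = g.integrate(model, np.array([0.8, 0.1, 0.1, 0.1, 1e-6]),
                         g.IntegrationSettings(t_end=20.0, n_points=50))
        assert np.all(np.isfinite(tr.x))
        assert not tr.success

    def test_wrong_x0_shape(self, case_models):
        with pytest.raises(ValueError):
            g.integrate(case_models[("A", "ANN")], np.ones(3))


class TestDatasets:
    def test_sparse_shape_and_initial_row(self, sparse_case_a_ann):
        assert len(sparse_case_a_ann.trajectories) == 1
        tr = sparse_case_a_ann.trajectories[0]
        assert tr.x.shape == (200, 5)
        assert np.allclose(tr.x[0], [0.8, 0.1, 0.1, 0.1, 0.1])

    def test_sparse_deterministic(self, case_models):
        m = case_models[("B", "GRLOT")]
        a = g.generate_sparse(m)
        b = g.generate_sparse(m)
        assert np.array_equal(a.trajectories[0].x, b.trajectories[0].x)

    def test_detailed_five_starting_sets(self, case_models, quick_settings):
        data = g.generate_detailed(case_models[("B", "GRLOT")],
                                   quick_settings)
        assert [tr.label for tr in data.trajectories] == [1, 2, 3, 4, 5]
        assert np.allclose(data.trajectories[4].x[0],
                           [0.5, 0.2, 0.8, 0.8, 0.2])

    def test_detailed_first_trajectory_equals_sparse(self, case_models,
                                                     quick_settings):
        m = case_models[("A", "SS")]
        sparse = g.generate_sparse(m, quick_settings)
        detailed = g.generate_detailed(m, quick_settings)
        assert np.array_equal(sparse.trajectories[0].x,
                              detailed.trajectories[0].x)

    def test_tolerance_convergence(self, case_models):
        # halving tolerances moves sampled concentrations by < 1e-5
        x0 = np.array([0.8, .1, .1, .1, .1])
        for key in [("C", "ANN"), ("B", "SS"), ("A", "GRLOT")]:
            m = case_models[key]
            coarse = g.integrate(m, x0, g.IntegrationSettings())
            fine = g.integrate(
                m, x0, g.IntegrationSettings(rtol=5e-8, atol=5e-10))
            assert np.max(np.abs(coarse.x - fine.x)) < 1e-5

    def test_nonnegative_trajectories(self, case_models, quick_settings):
        for method in ("ANN", "GRLOT"):
            data = g.generate_detailed(case_models[("B", method)],
                                       quick_settings)
            for tr in data.trajectories:
                assert np.all(tr.x >= -1e-8)

    def test_csv_roundtrip(self, tmp_path, case_models, quick_settings):
        data = g.generate_detailed(case_models[("A", "ANN")], quick_settings)
        path = tmp_path / "data.csv"
        data.to_csv(path)
        again = g.TimeSeriesSet.from_csv(path)
        assert len(again.trajectories) == 5
        for a, b in zip(data.trajectories, again.trajectories):
            assert np.allclose(a.x, b.x)
            assert np.allclose(a.t, b.t)


class TestPerturbations:
    def test_input_perturbation_values(self, case_models):
        inc, dec = g.perturb_input(case_models[("A", "ANN")])
        assert inc.params.k[0] == 0.1
        assert dec.params.k[0] == 0.5
        assert np.all(inc.params.k[1:] == 0.3)

    def test_ss_variant_modifies_beta(self, case_models):
        inc, dec = g.perturb_input(case_models[("A", "SS")])
        assert inc.params.beta[0] == 0.1
        assert dec.params.beta[0] == 0.5

    def test_idempotent_on_perturbed_values(self, case_models):
        inc, dec = g.perturb_input(case_models[("A", "GRLOT")])
        inc2, dec2 = g.perturb_input(inc)
        assert inc2.params.k[0] == 0.1 and dec2.params.k[0] == 0.5

    def test_initial_value_perturbation(self):
        x0 = np.array([0.0045, 0.03, 0.01, 0.02, 0.01])
        assert g.perturb_initial(x0, 1, 3)[0] == pytest.approx(0.0135)
        assert g.perturb_initial(x0, 1, 48)[0] == pytest.approx(0.216)
        assert np.array_equal(g.perturb_initial(x0, 2, 1), x0)
        # untouched entries stay put
        assert np.array_equal(g.perturb_initial(x0, 1, 3)[1:], x0[1:])

    def test_gene_index_out_of_range(self):
        with pytest.raises(IndexError):
            g.perturb_initial(np.ones(5), 6, 3)


class TestPlotting:
    def test_plot_helpers_return_axes(self, sparse_case_a_ann):
        import matplotlib
        matplotlib.use("Agg")
        ax = g.plot_trajectories(sparse_case_a_ann)
        assert ax.get_xlabel() == "time"
        ax2 = g.plot_fit(sparse_case_a_ann, sparse_case_a_ann)
        assert ax2 is not None


class TestNoiseHook:
    def test_off_by_default_and_seedable(self, sparse_case_a_ann):
        a = g.add_noise(sparse_case_a_ann, 0.05, rng=9)
        b = g.add_noise(sparse_case_a_ann, 0.05, rng=9)
        assert np.array_equal(a.trajectories[0].x, b.trajectories[0].x)
        # the source set is untouched and differs from the noisy copy
        assert not np.array_equal(a.trajectories[0].x,
                                  sparse_case_a_ann.trajectories[0].x)
        assert a.meta["noise_sigma"] == 0.05
        assert np.all(a.trajectories[0].x >= 0)

    def test_zero_sigma_identity(self, sparse_case_a_ann):
        a = g.add_noise(sparse_case_a_ann, 0.0, rng=1)
        assert np.array_equal(a.trajectories[0].x,
                              sparse_case_a_ann.trajectories[0].x)
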