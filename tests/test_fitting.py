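"""Two-phase reverse-engineering machinery (fast, reduced-scale checks)."""

import numpy as np
import pytest

import grncompare as g
from grncompare.codec import NetworkCodec, NodeCodec
from grncompare.ea import WORST_FITNESS
from grncompare.fitting import network_objective, node_objective

TINY = g.EAConfig(population=60, generations=60, repeats=2)


@pytest.fixture(scope="module")
def two_gene_ss():
    """A 2-gene S-system cascade with known parameters."""
    topo = g.GRNTopology.from_tuples(2, [(1, 2, "activating")])
    params = g.SSParams(alpha=[0.0, 1.2], beta=[0.4, 0.3],
                        g=[[0.0, 0.0], [1.6, 0.0]], h=np.eye(2))
    return g.GRNModel("SS", topo, params)


class TestCodec:
    def test_canonical_roundtrip(self, case_models):
        for m in case_models.values():
            codec = NetworkCodec(m.method, m.topology)
            rebuilt = codec.build_model(codec.encode(m))
            assert np.allclose(codec.encode(rebuilt), codec.encode(m))

    def test_free_parameter_counts(self, case_models):
        # cascade case A: ANN 3N + 4 weights; SS 3N + 4 orders;
        # GRLOT 2N + 2 per regulator
        assert NetworkCodec("ANN", case_models[("A", "ANN")].topology
                            ).dim == 19
        assert NetworkCodec("SS", case_models[("A", "SS")].topology
                            ).dim == 19
        assert NetworkCodec("GRLOT", case_models[("A", "GRLOT")].topology
                            ).dim == 18

    def test_bounds_shapes_and_defaults(self, case_models):
        codec = NetworkCodec("ANN", case_models[("A", "ANN")].topology)
        assert codec.lower.shape == (codec.dim,)
        w_cols = [i for i, nm in enumerate(codec.names)
                  if nm.startswith("w[")]
        assert all(codec.lower[i] == -15.0 and codec.upper[i] == 15.0
                   for i in w_cols)

    def test_grlot_role_dependent_exponent_bounds(self, case_models):
        codec = NetworkCodec("GRLOT", case_models[("C", "GRLOT")].topology)
        idx = {nm: i for i, nm in enumerate(codec.names)}
        # X3 -> X2 activator: [0, 7]; X5 -| X2 inhibitor: [-5, 5]
        assert codec.lower[idx["n[2,3]"]] == 0.0
        assert codec.upper[idx["n[2,3]"]] == 7.0
        assert codec.lower[idx["n[2,5]"]] == -5.0
        assert codec.upper[idx["n[2,5]"]] == 5.0


class TestObjectives:
    def test_generator_parameters_near_zero_objective(self, case_models,
                                                      sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        codec = NetworkCodec("ANN", m.topology)
        obj = network_objective(codec, sparse_case_a_ann)
        assert obj(codec.encode(m)[None, :])[0] < 1e-4

    def test_node_objective_of_generator_near_zero(self, case_models,
                                                   sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        for gene in range(1, 6):
            codec = NodeCodec("ANN", m.topology, gene)
            obj = node_objective(codec, sparse_case_a_ann)
            assert obj(codec.encode(m)[None, :])[0] < 1e-3

    def test_failure_containment_fuzz(self, case_models):
        # thousands of random S-system candidates on the feedback
        # topology: no crash, failures map to the worst-fitness sentinel
        m = case_models[("C", "SS")]
        data = g.generate_sparse(m, g.IntegrationSettings(n_points=50))
        codec = NetworkCodec("SS", m.topology)
        rng = np.random.default_rng(0)
        V = rng.uniform(codec.lower, codec.upper, (10_000, codec.dim))
        f = network_objective(codec, data)(V)
        assert f.shape == (10_000,)
        assert np.all(np.isfinite(f))
        assert np.all(f <= WORST_FITNESS)
        assert np.any(f >= WORST_FITNESS)  # some candidates do blow up


class TestNodePhase:
    def test_unregulated_gene_recovers_decay(self, case_models,
                                             sparse_case_a_ann):
        # gene X1 has no regulators: fitting reduces to matching pure
        # decay from X1(0); the fitted trajectory must match the data
        m = case_models[("A", "ANN")]
        res = g.fit_node_model(sparse_case_a_ann, m.topology, "ANN", 1,
                               config=TINY, rng=4)
        assert res.objective < 1e-3

    def test_two_gene_parameter_recovery(self, two_gene_ss):
        # detailed-style data from several starting points pins down
        # the generator parameters
        data = g.TimeSeriesSet([
            g.integrate(two_gene_ss, np.array(x0),
                        g.IntegrationSettings(t_end=15.0, n_points=100),
                        label=i)
            for i, x0 in enumerate([(0.8, 0.1), (0.3, 0.6), (0.6, 0.9)])
        ])
        cfg = g.EAConfig(population=150, generations=150, repeats=3)
        fit = g.two_phase_fit(data, two_gene_ss.topology, "SS",
                              config=cfg, rng=8)
        recovered = fit.model()
        assert g.p_inf_models(two_gene_ss, recovered) > 0.95
        codec = NetworkCodec("SS", two_gene_ss.topology)
        ref = codec.encode(two_gene_ss)
        est = codec.encode(recovered)
        # the regulated gene's kinetic order and rate constants
        idx = {nm: i for i, nm in enumerate(codec.names)}
        assert abs(est[idx["g[2,1]"]] - ref[idx["g[2,1]"]]) < 0.15


class TestAssembly:
    def test_assembled_parameter_count(self, case_models,
                                       sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        nodes = [g.fit_node_model(sparse_case_a_ann, m.topology, "ANN",
                                  gene, config=g.EAConfig(population=20,
                                                          generations=5,
                                                          repeats=1),
                                  rng=gene)
                 for gene in range(1, 6)]
        assembled = g.assemble_network(nodes)
        codec = NetworkCodec("ANN", m.topology)
        assert codec.encode(assembled).shape == (codec.dim,)
        assert sum(len(n.vector) for n in nodes) == codec.dim

    def test_mixed_methods_rejected(self, case_models, sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        cfg = g.EAConfig(population=10, generations=2, repeats=1)
        a = g.fit_node_model(sparse_case_a_ann, m.topology, "ANN", 1,
                             config=cfg, rng=1)
        b = g.fit_node_model(sparse_case_a_ann, m.topology, "SS", 2,
                             config=cfg, rng=1)
        with pytest.raises(ValueError):
            g.assemble_network([a, b])

    def test_missing_gene_rejected(self, case_models, sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        cfg = g.EAConfig(population=10, generations=2, repeats=1)
        nodes = [g.fit_node_model(sparse_case_a_ann, m.topology, "ANN",
                                  gene, config=cfg, rng=1)
                 for gene in (1, 2, 3)]
        with pytest.raises(ValueError):
            g.assemble_network(nodes)


class TestNetworkPhase:
    def test_seeding_with_generator_is_preserved(self, case_models,
                                                 sparse_case_a_ann):
        # the generator model seeded into the population scores ~0 at
        # generation 0 and elitist bookkeeping keeps it
        m = case_models[("A", "ANN")]
        cfg = g.EAConfig(population=40, generations=10, repeats=1)
        fit = g.fit_network_model(sparse_case_a_ann, m.topology, "ANN",
                                  config=cfg, rng=2, seeds=[m])
        assert fit.objective < 1e-4
        assert fit.history[0] < 1e-4

    def test_same_seed_reproducible(self, case_models, sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        cfg = g.EAConfig(population=20, generations=5, repeats=2)
        a = g.fit_network_model(sparse_case_a_ann, m.topology, "ANN",
                                config=cfg, rng=3)
        b = g.fit_network_model(sparse_case_a_ann, m.topology, "ANN",
                                config=cfg, rng=3)
        assert np.array_equal(a.vector, b.vector)
        assert a.objective == b.objective

    def test_fit_result_serialization(self, case_models,
                                      sparse_case_a_ann, tmp_path):
        m = case_models[("A", "ANN")]
        cfg = g.EAConfig(population=10, generations=2, repeats=1)
        fit = g.fit_network_model(sparse_case_a_ann, m.topology, "ANN",
                                  config=cfg, rng=1)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["scope"] == "network"
        assert len(payload["vector"]) == NetworkCodec(
            "ANN", m.topology).dim
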