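"""Energy model: fitting, potentials, total energy and its decomposition."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulcalfcd.energy import (
    EPSILON_FLOOR,
    ControlModel,
    edge_potential,
    fit_control_model,
    local_energy_decomposition,
    node_features,
    node_potential,
    relation_key,
    total_energy,
)
from sulcalfcd.graph import SulcalGraph
from sulcalfcd.nomenclature import BACKGROUND, CENTRAL_REGION_LABELS
from sulcalfcd.synthetic import default_template, sample_control_graph, template_mean_graph


def brute_force_total_energy(graph, labeling, model):
    """Independent term-by-term recomputation of the labeling objective.

    Deliberately naive: enumerates every node, every edge and every model
    relation from scratch, sharing no code path with ``total_energy``.
    """
    acc = 0.0
    for n in graph.nodes:
        lab = labeling[n.node_id]
        if lab == BACKGROUND:
            acc += model.lambda_background
        else:
            s = model.node_stats[lab]
            x = node_features(n, graph.hemisphere)
            d = x - s.mean
            acc += 0.5 * d @ np.linalg.solve(s.cov, d)
            m = -1.0 if graph.hemisphere == "right" else 1.0
            o = np.array([m * n.orientation[0], n.orientation[1], n.orientation[2]])
            theta = math.acos(min(abs(float(o @ s.mean_direction)), 1.0))
            acc += 0.5 * (theta / s.sigma_theta) ** 2
    realized = set()
    for e in graph.edges:
        la, lb = labeling[e.endpoints[0]], labeling[e.endpoints[1]]
        if BACKGROUND in (la, lb):
            continue
        key = relation_key(la, lb, e.relation_type)
        if key not in model.relation_stats:
            acc += model.lambda_spurious
            continue
        realized.add(key)
        s = model.relation_stats[key]
        if e.relation_type == "buried_gyrus_split":
            x = np.array([e.relation_volume, e.min_distance, e.buried_gyrus_depth])
        else:
            x = np.array([e.relation_volume, e.min_distance])
        d = x - s.mean
        acc += 0.5 * d @ np.linalg.solve(s.cov, d)
        m = -1.0 if graph.hemisphere == "right" else 1.0
        cd = np.array([m * e.contact_direction[0], *e.contact_direction[1:]])
        theta = math.acos(min(abs(float(cd @ s.mean_direction)), 1.0))
        acc += 0.5 * (theta / s.sigma_theta) ** 2
        acc += max(-math.log(model.relation_freq[key]), 0.0)
    assigned = {lab for lab in labeling.values() if lab != BACKGROUND}
    for lo, hi, t in model.relation_stats:
        if (lo in assigned or hi in assigned) and (lo, hi, t) not in realized:
            acc += model.lambda_missing
    return acc


class TestFitControlModel:
    def test_identical_graphs_give_epsilon_identity_covariance(self, template):
        g = template_mean_graph(template)
        model = fit_control_model([g, dataclasses.replace(g, subject_id="b")])
        cov = model.node_stats["S.C."].cov
        assert np.allclose(cov, EPSILON_FLOOR * np.eye(6))

    def test_mean_recovery_within_3_standard_errors(self, template):
        rng = np.random.default_rng(0)
        graphs = [sample_control_graph(template, rng, f"t{i}") for i in range(200)]
        model = fit_control_model(graphs)
        mu_hat = model.node_stats["S.C."].mean[1]
        mu = template.scalar_means["S.C."][1]
        se = template.scalar_sds("S.C.")[1] / math.sqrt(200)
        assert abs(mu_hat - mu) < 3 * se

    def test_relation_frequency_one_for_always_present_junction(self, model):
        key = relation_key("S.C.", "S.Pe.C.sup", "geodesic_neighbor")
        assert model.relation_freq[key] == 1.0

    def test_unobserved_label_raises(self, template):
        graphs = [template_mean_graph(template, f"g{i}") for i in range(3)]
        pruned = [
            SulcalGraph(g.subject_id, g.hemisphere,
                        [n for n in g.nodes if n.true_label != "S.p.C"],
                        [e for e in g.edges]) for g in graphs
        ]
        pruned = [
            SulcalGraph(g.subject_id, g.hemisphere, g.nodes,
                        [e for e in g.edges
                         if all(any(n.node_id == x for n in g.nodes) for x in e.endpoints)])
            for g in pruned
        ]
        with pytest.raises(ValueError, match="S.p.C"):
            fit_control_model(pruned)


class TestPotentials:
    def test_node_at_model_mean_has_zero_energy(self, template):
        g = template_mean_graph(template)
        model = fit_control_model([g, dataclasses.replace(g, subject_id="b")])
        node = next(n for n in g.nodes if n.true_label == "S.C.")
        assert node_potential(node, "S.C.", model) == pytest.approx(0.0, abs=1e-9)

    def test_scalar_two_sigma_deviation_costs_two(self):
        """1-D check of the quadratic form: a - mu = 2 sigma -> energy 2."""
        from sulcalfcd.energy import GaussianStats

        s = GaussianStats(
            mean=np.array([10.0]), cov=np.array([[4.0]]),
            mean_direction=np.array([0.0, 0.0, 1.0]), sigma_theta=1.0, n=10,
        )
        e = s.quad(np.array([14.0]), np.array([0.0, 0.0, 1.0]))
        assert e == pytest.approx(2.0)

    def test_true_label_beats_wrong_labels_on_template_means(self, template, model):
        g = template_mean_graph(template)
        for n in g.nodes:
            e_true = node_potential(n, n.true_label, model)
            for other in CENTRAL_REGION_LABELS:
                if other != n.true_label:
                    assert node_potential(n, other, model) >= e_true

    def test_background_costs_lambda_background(self, template, model):
        node = template_mean_graph(template).nodes[0]
        assert node_potential(node, BACKGROUND, model) == model.lambda_background

    def test_edge_at_mean_with_f_one_is_cheap(self, template):
        g = template_mean_graph(template)
        model = fit_control_model([g, dataclasses.replace(g, subject_id="b")])
        e = g.edges[0]
        labels = {n.node_id: n.true_label for n in g.nodes}
        pot = edge_potential(e, labels[e.endpoints[0]], labels[e.endpoints[1]], model)
        assert pot == pytest.approx(0.0, abs=1e-9)

    def test_halved_frequency_costs_log_two(self, model):
        key = relation_key("S.C.", "S.Po.C.sup", "geodesic_neighbor")
        tweaked = dataclasses.replace(model)
        tweaked.relation_freq = dict(model.relation_freq)
        tweaked.relation_freq[key] = 0.5
        g = template_mean_graph(default_template())
        labels = {n.node_id: n.true_label for n in g.nodes}
        edge = next(
            e for e in g.edges
            if relation_key(labels[e.endpoints[0]], labels[e.endpoints[1]], e.relation_type) == key
        )
        base = edge_potential(edge, "S.C.", "S.Po.C.sup", model)
        bumped = edge_potential(edge, "S.C.", "S.Po.C.sup", tweaked)
        assert bumped - base == pytest.approx(
            math.log(2) - max(-math.log(model.relation_freq[key]), 0.0)
        )

    def test_spurious_relation_costs_lambda_spurious(self, model):
        g = template_mean_graph(default_template())
        # a junction between two sulci that never share one in controls
        edge = dataclasses.replace(g.edges[0], relation_type="junction",
                                   endpoints=g.edges[0].endpoints)
        pot = edge_potential(edge, "S.F.median", "F.I.P.Po.C.inf", model)
        assert pot == model.lambda_spurious


class TestTotalEnergyAndDecomposition:
    def test_zero_noise_graph_with_true_labels_has_zero_energy(self, template):
        graphs = [template_mean_graph(template, f"g{i}") for i in range(3)]
        model = fit_control_model(graphs)
        g = graphs[0]
        assert total_energy(g, g.true_labeling(), model) == pytest.approx(0.0, abs=1e-6)

    def test_single_attribute_deviation_increases_energy(self, template):
        graphs = [template_mean_graph(template, f"g{i}") for i in range(3)]
        model = fit_control_model(graphs)
        g = graphs[0]
        base = total_energy(g, g.true_labeling(), model)
        bumped_nodes = [
            dataclasses.replace(n, max_depth=n.max_depth + 1.0) if n.true_label == "S.C." else n
            for n in g.nodes
        ]
        g2 = SulcalGraph(g.subject_id, g.hemisphere, bumped_nodes, g.edges)
        assert total_energy(g2, g2.true_labeling(), model) > base

    def test_missing_expected_relation_charges_lambda_missing(self, template, model):
        g = template_mean_graph(template)
        labeling = g.true_labeling()
        base = total_energy(g, labeling, model)
        dropped = SulcalGraph(g.subject_id, g.hemisphere, g.nodes, g.edges[1:])
        e0 = g.edges[0]
        pot0 = edge_potential(e0, labeling[e0.endpoints[0]], labeling[e0.endpoints[1]], model)
        assert total_energy(dropped, labeling, model) == pytest.approx(
            base - pot0 + model.lambda_missing
        )

    def test_matches_independent_brute_force_sum(self, template, model):
        rng = np.random.default_rng(4)
        for i in range(25):
            g = sample_control_graph(template, rng, f"s{i}", "left" if i % 2 else "right")
            labeling = g.true_labeling()
            if i % 3 == 0 and g.nodes:  # also exercise background assignments
                labeling[g.nodes[0].node_id] = BACKGROUND
            assert total_energy(g, labeling, model) == pytest.approx(
                brute_force_total_energy(g, labeling, model)
            )

    def test_decomposition_conserves_total_on_many_random_graphs(self, template, model):
        rng = np.random.default_rng(5)
        for i in range(100):
            g = sample_control_graph(template, rng, f"s{i}")
            labeling = g.true_labeling()
            emap = local_energy_decomposition(g, labeling, model)
            assert emap.total == pytest.approx(total_energy(g, labeling, model), rel=1e-9)
            assert emap.total == pytest.approx(sum(emap.local.values()), rel=1e-9)
            assert all(v >= 0 for v in emap.local.values())

    def test_single_node_graph_energy_is_node_potential_plus_breaks(self, template, model):
        g = template_mean_graph(template)
        sc = next(n for n in g.nodes if n.true_label == "S.C.")
        solo = SulcalGraph("solo", "left", [sc], [])
        emap = local_energy_decomposition(solo, {sc.node_id: "S.C."}, model)
        n_expected = sum(1 for key in model.relation_stats if "S.C." in key[:2])
        want = node_potential(sc, "S.C.", model) + n_expected * model.lambda_missing
        assert emap.local["S.C."] == pytest.approx(want)
        assert emap.total == pytest.approx(want)

    def test_two_node_graph_splits_edge_term_evenly(self, template):
        g = template_mean_graph(template)
        labels = {n.node_id: n.true_label for n in g.nodes}
        e = g.edges[0]
        keep = set(e.endpoints)
        sub = SulcalGraph("duo", "left", [n for n in g.nodes if n.node_id in keep], [e])
        model = fit_control_model([g, dataclasses.replace(g, subject_id="b")])
        sub_labeling = {nid: labels[nid] for nid in keep}
        emap = local_energy_decomposition(sub, sub_labeling, model)
        la, lb = sub_labeling[e.endpoints[0]], sub_labeling[e.endpoints[1]]
        pot = edge_potential(e, la, lb, model)
        na = node_potential(sub.node(e.endpoints[0]), la, model)
        breaks_a = sum(
            1 for key in model.relation_stats
            if la in key[:2] and not (set(key[:2]) <= {la, lb} and key[2] == e.relation_type)
        )
        assert emap.local[la] == pytest.approx(
            na + 0.5 * pot + breaks_a * model.lambda_missing
        )

    def test_unlabeled_node_rejected(self, template, model):
        g = template_mean_graph(template)
        with pytest.raises(ValueError, match="unlabeled"):
            total_energy(g, {}, model)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariance_to_node_order_and_orientation_sign(self, seed):
        template = default_template()
        rng = np.random.default_rng(123)
        model = fit_control_model(
            [sample_control_graph(template, rng, f"t{i}") for i in range(30)]
        )
        g = sample_control_graph(template, seed)
        labeling = g.true_labeling()
        e1 = total_energy(g, labeling, model)
        perm = np.random.default_rng(seed).permutation(len(g.nodes))
        flipped = [
            dataclasses.replace(
                g.nodes[i],
                orientation=tuple(-c for c in g.nodes[i].orientation),
            )
            for i in perm
        ]
        g2 = SulcalGraph(g.subject_id, g.hemisphere, flipped, list(g.edges))
        assert total_energy(g2, labeling, model) == pytest.approx(e1, rel=1e-9)


def test_model_serialization_round_trip(model, tmp_path, template):
    path = tmp_path / "model.json"
    model.save(path)
    loaded = ControlModel.load(path)
    g = sample_control_graph(template, 77)
    labeling = g.true_labeling()
    assert total_energy(g, labeling, loaded) == pytest.approx(
        total_energy(g, labeling, model), rel=1e-12
    )
    assert loaded.labels == model.labels
    assert loaded.n_train == model.n_train
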