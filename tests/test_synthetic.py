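"""Synthetic cohort generator: template, sampling, perturbation, manifests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sulcalfcd.manifest import validate_manifest
from sulcalfcd.nomenclature import CENTRAL_REGION_LABELS
from sulcalfcd.synthetic import (
    PerturbationSpec,
    apply_fcd_perturbation,
    default_template,
    generate_cohort,
    sample_control_graph,
    template_mean_graph,
)


class TestDefaultTemplate:
    def test_thirteen_labels_and_central_sulcus_always_present(self, template):
        assert len(template.labels) == 13
        assert template.presence["S.C."] == 1.0

    def test_variability_increases_from_central_to_sylvian(self, template):
        ranked = [template.variability[lab] for lab in CENTRAL_REGION_LABELS]
        assert all(a < b for a, b in zip(ranked, ranked[1:]))
        sd_sc = template.scalar_sds("S.C.")[1] / template.scalar_means["S.C."][1]
        sd_syl = template.scalar_sds("S.C.sylvian")[1] / template.scalar_means["S.C.sylvian"][1]
        assert sd_sc < sd_syl  # relative depth SD ordering

    def test_edges_reference_template_labels(self, template):
        for e in template.edges:
            assert set(e.labels) <= set(template.labels)
        # S.C. is the hub: neighbours + the three ramifications as junctions
        junctions = {e.labels[1] for e in template.edges
                     if e.labels[0] == "S.C." and e.relation_type == "junction"}
        assert junctions == {"S.C.sylvian", "S.C.LPC", "S.p.C"}


class TestSampling:
    def test_same_seed_gives_identical_graph(self, template):
        g1 = sample_control_graph(template, 42, "s", "left")
        g2 = sample_control_graph(template, 42, "s", "left")
        assert g1 == g2

    def test_full_presence_gives_13_nodes(self, template):
        import dataclasses

        full = dataclasses.replace(
            template, presence={lab: 1.0 for lab in template.labels}, _cache={}
        )
        for seed in range(20):
            assert len(sample_control_graph(full, seed).nodes) == 13

    def test_empirical_mean_depth_matches_template(self, template):
        depths = []
        rng = np.random.default_rng(7)
        for _ in range(1000):
            g = sample_control_graph(template, rng)
            node = next(n for n in g.nodes if n.true_label == "S.C.")
            depths.append(node.max_depth)
        mu = template.scalar_means["S.C."][1]
        sd = template.scalar_sds("S.C.")[1]
        se = sd / math.sqrt(len(depths))
        assert abs(np.mean(depths) - mu) < 3 * se

    def test_minor_sulci_occasionally_absent(self, template):
        rng = np.random.default_rng(11)
        n_sylvian = sum(
            any(n.true_label == "S.C.sylvian" for n in sample_control_graph(template, rng).nodes)
            for _ in range(300)
        )
        # presence 0.9: a 3-sigma binomial band around 270/300
        assert 254 <= n_sylvian <= 286

    def test_mirrored_hemispheres(self, template):
        gl = template_mean_graph(template, hemisphere="left")
        gr = template_mean_graph(template, hemisphere="right")
        for nl, nr in zip(gl.nodes, gr.nodes):
            assert nr.centroid[0] == -nl.centroid[0]
            assert nr.centroid[1:] == nl.centroid[1:]


class TestPerturbation:
    def test_zero_effect_is_identity(self, template):
        g = sample_control_graph(template, 3)
        spec = PerturbationSpec(targets=("S.C.",), delta_depth=0, delta_area=0,
                                delta_theta_deg=0, relation_disruption=0)
        assert apply_fcd_perturbation(g, spec, 0, template) == g

    def test_depth_shift_is_exactly_delta_sd(self, template):
        g = sample_control_graph(template, 3)
        spec = PerturbationSpec(targets=("S.C.",), delta_depth=2.0, delta_area=0,
                                delta_theta_deg=0, relation_disruption=0)
        out = apply_fcd_perturbation(g, spec, 0, template)
        before = next(n for n in g.nodes if n.true_label == "S.C.")
        after = next(n for n in out.nodes if n.true_label == "S.C.")
        assert after.max_depth == pytest.approx(
            before.max_depth + 2.0 * template.scalar_sds("S.C.")[1]
        )
        assert after.area == before.area

    def test_orientation_rotated_by_requested_angle(self, template):
        g = sample_control_graph(template, 3)
        spec = PerturbationSpec(targets=("S.C.",), delta_depth=0, delta_area=0,
                                delta_theta_deg=30.0, relation_disruption=0)
        out = apply_fcd_perturbation(g, spec, 5, template)
        before = np.array(next(n for n in g.nodes if n.true_label == "S.C.").orientation)
        after = np.array(next(n for n in out.nodes if n.true_label == "S.C.").orientation)
        angle = math.degrees(math.acos(np.clip(abs(before @ after), 0, 1)))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_full_disruption_leaves_no_target_relation_untouched(self, template):
        g = sample_control_graph(template, 3)
        spec = PerturbationSpec(targets=("S.C.",), delta_depth=0, delta_area=0,
                                delta_theta_deg=0, relation_disruption=1.0)
        out = apply_fcd_perturbation(g, spec, 0, template)
        sc_id = next(n.node_id for n in g.nodes if n.true_label == "S.C.")
        original = {(e.endpoints, e.relation_type) for e in g.edges if sc_id in e.endpoints}
        surviving = {(e.endpoints, e.relation_type) for e in out.edges if sc_id in e.endpoints}
        assert original.isdisjoint(surviving)

    def test_absent_target_raises(self, template):
        g = sample_control_graph(template, 3)
        g2 = type(g)(g.subject_id, g.hemisphere,
                     [n for n in g.nodes if n.true_label != "S.C.sylvian"], [])
        spec = PerturbationSpec(targets=("S.C.sylvian",))
        with pytest.raises(ValueError, match="S.C.sylvian"):
            apply_fcd_perturbation(g2, spec, 0, template)

    def test_non_target_attributes_unchanged(self, template):
        g = sample_control_graph(template, 3)
        out = apply_fcd_perturbation(g, PerturbationSpec(targets=("S.C.",)), 0, template)
        for before, after in zip(g.nodes, out.nodes):
            if before.true_label != "S.C.":
                assert before == after


class TestGenerateCohort:
    def test_reproducible_and_valid_manifest(self, template):
        _, man1 = generate_cohort(4, 3, template=template, seed=9)
        _, man2 = generate_cohort(4, 3, template=template, seed=9)
        assert man1.equals(man2)
        assert validate_manifest(man1) == []

    def test_no_patients_means_no_fcd_sulci(self, template):
        _, man = generate_cohort(3, 0, template=template, seed=1)
        assert all(len(s) == 0 for s in man["fcd_sulci"])

    def test_fcd_sulcus_counts_between_1_and_3(self, template):
        _, man = generate_cohort(0, 40, template=template, seed=2)
        counts = man.loc[man["group"] == "patient", "fcd_sulci"].map(len)
        assert set(counts.unique()) <= {1, 2, 3}
        assert counts.min() >= 1

    def test_contralateral_hemisphere_never_perturbed(self, template):
        """Contralateral FCD-sulcus depths stay at the control distribution
        (standardized depths ~ N(0,1)) while ipsilateral ones are shifted."""
        graphs, man = generate_cohort(0, 60, template=template, seed=3)
        by_key = {(g.subject_id, g.hemisphere): g for g in graphs}
        contra_z, ipsi_z = [], []
        for _, row in man.iterrows():
            contra = "right" if row["lesion_side"] == "left" else "left"
            for hemi, store in ((contra, contra_z), (row["lesion_side"], ipsi_z)):
                g = by_key[(row["subject_id"], hemi)]
                for n in g.nodes:
                    if n.true_label in row["fcd_sulci"]:
                        mu = template.scalar_means[n.true_label][1]
                        sd = template.scalar_sds(n.true_label)[1]
                        store.append((n.max_depth - mu) / sd)
        assert abs(np.mean(contra_z)) < 3 / math.sqrt(len(contra_z))
        assert np.mean(ipsi_z) > 1.5  # default shift is +2 SD

    def test_nontarget_labels_distributed_as_controls(self, template):
        """Perturbation is localized: non-FCD sulci of patients match controls."""
        graphs, man = generate_cohort(60, 60, template=template, seed=17)
        fcd = {r["subject_id"]: set(r["fcd_sulci"]) for _, r in man.iterrows()}
        side = dict(zip(man["subject_id"], man["lesion_side"]))
        grp = dict(zip(man["subject_id"], man["group"]))
        ctl_depths, pat_depths = [], []
        for g in graphs:
            for n in g.nodes:
                if n.true_label != "S.Po.C.sup":
                    continue
                if grp[g.subject_id] == "control":
                    ctl_depths.append(n.max_depth)
                elif g.hemisphere == side[g.subject_id] and n.true_label not in fcd[g.subject_id]:
                    pat_depths.append(n.max_depth)
        p = sps.ks_2samp(ctl_depths, pat_depths).pvalue
        assert p > 0.01
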