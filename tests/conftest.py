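"""Shared fixtures: a fitted control model and cohort-simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from sulcalfcd.energy import fit_control_model, local_energy_decomposition
from sulcalfcd.graph import SulcalGraph
from sulcalfcd.stats import records_from_zscore_maps
from sulcalfcd.synthetic import (
    PerturbationSpec,
    default_template,
    sample_control_graph,
)
from sulcalfcd.zscore import cohort_energy_stats, zscore_map

NULL_PERTURBATION = PerturbationSpec(
    targets=("S.C.",), delta_depth=0.0, delta_area=0.0,
    delta_theta_deg=0.0, relation_disruption=0.0,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def training_graphs(template):
    rng = np.random.default_rng(12345)
    return [
        sample_control_graph(template, rng, f"train{i:03d}", hemi)
        for i in range(60)
        for hemi in ("left", "right")
    ]


@pytest.fixture(scope="session")
def model(training_graphs):
    return fit_control_model(training_graphs)


@pytest.fixture(scope="session")
def true_label_maps(model):
    """graph -> energy map under ground-truth labels."""

    def compute(graphs):
        return [local_energy_decomposition(g, g.true_labeling(), model) for g in graphs]

    return compute


def induced_subgraph(graph: SulcalGraph, keep_ids) -> SulcalGraph:
    keep = set(keep_ids)
    return SulcalGraph(
        graph.subject_id,
        graph.hemisphere,
        [n for n in graph.nodes if n.node_id in keep],
        [e for e in graph.edges if e.endpoints[0] in keep and e.endpoints[1] in keep],
    )


@pytest.fixture(scope="session")
def small_graph_factory(template):
    """Random 3-5 node induced subgraphs of sampled hemispheres."""

    def make(seed: int) -> SulcalGraph:
        g = sample_control_graph(template, 900_000 + seed)
        rng = np.random.default_rng(seed)
        size = int(rng.integers(3, 6))
        keep = rng.choice([n.node_id for n in g.nodes], size=size, replace=False)
        return induced_subgraph(g, keep)

    return make


@pytest.fixture(scope="session")
def simulated_cohort_analysis(template, model):
    """Generate a cohort, compute true-label energies, z-score the patients
    ipsilaterally and build localization records — the statistical core of
    the pipeline without the annealer in the loop."""
    from sulcalfcd.synthetic import generate_cohort

    def run(n_controls, n_patients, perturbation, seed):
        graphs, manifest = generate_cohort(
            n_controls, n_patients, template=template, perturbation=perturbation, seed=seed
        )
        maps = [local_energy_decomposition(g, g.true_labeling(), model) for g in graphs]
        controls = set(manifest.loc[manifest["group"] == "control", "subject_id"])
        stats = cohort_energy_stats([m for m in maps if m.subject_id in controls])
        side = dict(zip(manifest["subject_id"], manifest["lesion_side"]))
        ipsi = {
            m.subject_id: zscore_map(m, stats)
            for m in maps
            if m.subject_id not in controls and m.hemisphere == side[m.subject_id]
        }
        records = records_from_zscore_maps(ipsi, manifest)
        return {
            "graphs": graphs,
            "manifest": manifest,
            "maps": maps,
            "stats": stats,
            "ipsi_zmaps": ipsi,
            "records": records,
        }

    return run
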