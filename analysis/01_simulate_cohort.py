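#!/usr/bin/env python
"""Simulate the study cohorts: 29 controls, 29 FCD patients, two hemispheres
each, plus a separate 50-control training cohort for the normative model.

Patients carry 1-3 FCD sulci on one hemisphere with the default lesion
signature (depth/area +2 control SD, orientation rotated 30 degrees, 25%
relation disruption); the contralateral hemisphere is untouched.

Graphs land under scratch/cohort/ (bulk intermediates); the cohort manifest
and a summary table go under results/.
"""

import argparse
from pathlib import Path

from sulcalfcd.graph import write_graph
from sulcalfcd.manifest import write_manifest
from sulcalfcd.pipeline import _stage_seed
from sulcalfcd.synthetic import default_template, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    template = default_template()
    study_dir = ROOT / "scratch" / "cohort" / "study"
    train_dir = ROOT / "scratch" / "cohort" / "training"
    results = ROOT / "results"
    for d in (study_dir, train_dir, results):
        d.mkdir(parents=True, exist_ok=True)

    graphs, manifest = generate_cohort(
        29, 29, template=template, seed=_stage_seed(args.seed, "cohort")
    )
    for g in graphs:
        write_graph(g, study_dir / f"{g.subject_id}_{g.hemisphere}.json")
    write_manifest(manifest, results / "cohort_manifest.csv")

    train_graphs, _ = generate_cohort(
        50, 0, template=template, seed=_stage_seed(args.seed, "fit")
    )
    for g in train_graphs:
        write_graph(g, train_dir / f"{g.subject_id}_{g.hemisphere}.json")

    pat = manifest[manifest["group"] == "patient"]
    counts = pat["fcd_sulci"].map(len).value_counts().sort_index()
    print(f"study cohort: {len(graphs)} hemisphere graphs "
          f"({len(manifest)} subjects) -> {study_dir}")
    print(f"training cohort: {len(train_graphs)} hemisphere graphs -> {train_dir}")
    print("patients per FCD-sulcus count:", dict(counts))
    print("lesion side split:", dict(pat["lesion_side"].value_counts()))


if __name__ == "__main__":
    main()
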