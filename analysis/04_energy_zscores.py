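#!/usr/bin/env python
"""Sulcus energy maps and normative z-scores for the study cohort.

Local energies are computed under the generator's ground-truth labels (the
recognition stage is profiled separately in 03; using true labels keeps the
statistical results free of labeling noise).  Control maps define the
per-sulcus mean/SD; each patient's ipsilateral hemisphere is standardized
sulcus-by-sulcus.  A leave-one-out pass over the controls checks that the
z-scores are calibrated (mean ~0, SD ~1).
"""

from pathlib import Path

from sulcalfcd.energy import ControlModel, local_energy_decomposition
from sulcalfcd.graph import read_graph
from sulcalfcd.manifest import read_manifest
from sulcalfcd.zscore import (
    cohort_energy_stats,
    leave_one_out_zscores,
    zscore_map,
    zscore_maps_to_frame,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    model = ControlModel.load(ROOT / "scratch" / "control_model.json")
    manifest = read_manifest(ROOT / "results" / "cohort_manifest.csv")
    graphs = [read_graph(p) for p in sorted((ROOT / "scratch" / "cohort" / "study").glob("*.json"))]
    maps = [local_energy_decomposition(g, g.true_labeling(), model) for g in graphs]

    controls = set(manifest.loc[manifest["group"] == "control", "subject_id"])
    control_maps = [m for m in maps if m.subject_id in controls]
    stats = cohort_energy_stats(control_maps)
    stats.to_frame().to_csv(ROOT / "results" / "control_energy_stats.csv", index=False)

    patient_maps = [m for m in maps if m.subject_id not in controls]
    zmaps = [zscore_map(m, stats) for m in patient_maps]
    zscore_maps_to_frame(zmaps).to_csv(ROOT / "results" / "patient_zscore_maps.csv", index=False)

    loo = leave_one_out_zscores(control_maps)
    calib = loo.groupby("label")["z"].agg(["mean", "std", "count"]).round(3)
    calib.to_csv(ROOT / "results" / "zscore_calibration.csv")

    print("control energy stats (left hemisphere):")
    f = stats.to_frame()
    print(f[f["hemisphere"] == "left"].round(2).to_string(index=False))
    print("\nleave-one-out z calibration per sulcus:")
    print(calib.to_string())


if __name__ == "__main__":
    main()
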