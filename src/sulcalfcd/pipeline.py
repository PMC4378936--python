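"""End-to-end orchestration: cohort -> model -> recognition -> energies ->
z-scores -> statistics, with full seed/config provenance.

Every stage writes its outputs under the run directory and can be re-run
from the serialized intermediates; a run manifest records the master seed,
per-stage derived seeds, the configuration hash and the package version.
Reruns with the same seed reproduce every output bit-for-bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .energy import energy_maps_to_frame, fit_control_model, local_energy_decomposition
from .graph import write_graph
from .manifest import load_reference_cohort, write_manifest
from .recognition import AnnealSchedule, run_k_recognitions, select_recognition
from .stats import (
    bilateral_group_comparison,
    central_sulcus_energy_table,
    ipsilateral_group_comparison,
    localization_permutation_test,
    poisson_binomial_tail,
    pool_sulcus_scores,
    records_from_reference_cohort,
    records_from_zscore_maps,
    roc_curve,
)
from .synthetic import CovariateModel, PerturbationSpec, default_template, generate_cohort
from .zscore import cohort_energy_stats, zscore_map, zscore_maps_to_frame

log = logging.getLogger("sulcalfcd")

DEFAULT_CONFIG: dict = {
    "cohort": {"n_controls": 29, "n_patients": 29},
    "training": {"n_controls": 50},
    "perturbation": {
        "delta_depth": 2.0,
        "delta_area": 2.0,
        "delta_theta_deg": 30.0,
        "relation_disruption": 0.25,
    },
    "recognition": {
        "enabled": True,
        "k": 10,
        "schedule": {"t0": 5.0, "gamma": 0.95, "sweeps": 20, "t_min": 0.01},
    },
    "zscore": {"sd_floor": 1e-6},
    "stats": {"n_perm": 10_000},
}

# Printed per-group totals of patients whose maximum-z sulcus was an FCD
# sulcus, in the published reference cohort (all / MR-negative / MR-positive).
REFERENCE_OBSERVED_HITS = {"all": 9, "MR-": 4, "MR+": 5}


def merge_config(overrides: Optional[dict]) -> dict:
    """Deep-merge user overrides onto the default configuration."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                merge(dst[key], val)
            else:
                dst[key] = val

    if overrides:
        merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence(entropy=master, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def localize_reference_cohort(n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Permutation + exact localization p-values on the published cohort.

    Uses 13 candidate sulci per patient, the per-patient FCD-sulcus counts
    of the reference table and the printed observed hit totals; returns one
    row per group (all, MR-, MR+) with the 10 000-permutation p-value and
    the exact Poisson-binomial upper tail.
    """
    ref = load_reference_cohort()
    rows = []
    for i, (group, status) in enumerate([("all", None), ("MR-", "MR-"), ("MR+", "MR+")]):
        observed = REFERENCE_OBSERVED_HITS[group]
        records, _ = records_from_reference_cohort(ref, observed, mr_status=status)
        res = localization_permutation_test(
            records, n_perm=n_perm, seed=_stage_seed(seed, f"reference-{group}")
        )
        probs = [r.k_fcd / r.n_candidates for r in records]
        rows.append(
            {
                "group": group,
                "n_patients": len(records),
                "observed_hits": observed,
                "n_perm": n_perm,
                "p_perm": res["p_value"],
                "p_exact": poisson_binomial_tail(probs, observed),
            }
        )
    return pd.DataFrame(rows)


def _energy_maps(graphs, model, cfg, seed):
    """Per-graph energy maps under both selection scopes.

    With recognition enabled, the same k annealings per graph are selected
    by central-sulcus energy (group analyses) and central-region energy
    (individual analyses); otherwise the generator's true labels are used
    directly and the two scopes coincide.
    """
    rec_cfg = cfg["recognition"]
    group_maps, indiv_maps = [], []
    for i, g in enumerate(graphs):
        if rec_cfg["enabled"]:
            sched = AnnealSchedule(seed=0, **rec_cfg["schedule"])
            runs = run_k_recognitions(
                g, model, k=rec_cfg["k"], schedule=sched,
                seed=_stage_seed(seed, f"recognize-{i}"),
            )
            _, emap_g = select_recognition(runs, "central_sulcus")
            _, emap_i = select_recognition(runs, "central_region")
        else:
            labeling = g.true_labeling()
            emap_g = emap_i = local_energy_decomposition(g, labeling, model)
        group_maps.append(emap_g)
        indiv_maps.append(emap_i)
    return group_maps, indiv_maps


def run_pipeline(config: Optional[dict] = None, seed: int = 0, out_dir="run") -> dict:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Returns a summary dict (group-comparison p-values, localization test,
    ROC AUC, output paths).  Raises with the failing stage named.
    """
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_sha256": config_hash(cfg), "seed": seed, "version": __version__}
    stage_seeds: dict[str, int] = {}
    timings: dict[str, float] = {}

    current_stage = "init"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()
        log.info("stage %s ...", name)

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])

        return done

    try:
        done = stage("cohort")
        stage_seeds["cohort"] = _stage_seed(seed, "cohort")
        template = default_template()
        pert = PerturbationSpec(targets=("S.C.",), **cfg["perturbation"])
        graphs, manifest = generate_cohort(
            cfg["cohort"]["n_controls"],
            cfg["cohort"]["n_patients"],
            template=template,
            perturbation=pert,
            covariates=CovariateModel(),
            seed=stage_seeds["cohort"],
        )
        graph_dir = out / "graphs"
        graph_dir.mkdir(exist_ok=True)
        for g in graphs:
            write_graph(g, graph_dir / f"{g.subject_id}_{g.hemisphere}.json")
        write_manifest(manifest, out / "manifest.csv")
        done()

        done = stage("fit")
        stage_seeds["fit"] = _stage_seed(seed, "fit")
        train_graphs, _ = generate_cohort(
            cfg["training"]["n_controls"], 0, template=template, seed=stage_seeds["fit"]
        )
        model = fit_control_model(train_graphs)
        model.save(out / "control_model.json")
        done()

        done = stage("energy")
        group_maps, indiv_maps = _energy_maps(graphs, model, cfg, seed)
        energy_maps_to_frame(group_maps).to_csv(out / "energies_group.csv", index=False)
        energy_maps_to_frame(indiv_maps).to_csv(out / "energies_individual.csv", index=False)
        done()

        done = stage("zscore")
        controls = set(manifest.loc[manifest["group"] == "control", "subject_id"])
        control_maps = [m for m in indiv_maps if m.subject_id in controls]
        stats = cohort_energy_stats(control_maps)
        stats.to_frame().to_csv(out / "control_energy_stats.csv", index=False)
        patient_maps = [m for m in indiv_maps if m.subject_id not in controls]
        zmaps = [zscore_map(m, stats, cfg["zscore"]["sd_floor"]) for m in patient_maps]
        zscore_maps_to_frame(zmaps).to_csv(out / "zscore_maps.csv", index=False)
        side = dict(zip(manifest["subject_id"], manifest["lesion_side"]))
        ipsi = {
            zm.subject_id: zm
            for zm in zmaps
            if zm.hemisphere == side.get(zm.subject_id) and zm.z
        }
        done()

        done = stage("stats")
        stage_seeds["stats"] = _stage_seed(seed, "stats")
        n_pat = cfg["cohort"]["n_patients"]
        summary["group_comparison"] = None
        summary["localization"] = None
        summary["roc_auc"] = None
        if n_pat >= 2 and cfg["cohort"]["n_controls"] >= 2:
            table = central_sulcus_energy_table(group_maps, manifest)
            bilateral = bilateral_group_comparison(table)
            group_doc = {
                name: {"effect": r.effect, "F": r.f_stat, "p": r.p_value, "n": r.n}
                for name, r in bilateral.items()
            }
            for name, contra in (("ipsilateral", False), ("contralateral", True)):
                r = ipsilateral_group_comparison(table, contralateral=contra)
                group_doc[name] = {"effect": r.effect, "F": r.f_stat, "p": r.p_value, "n": r.n}
            _write_json(group_doc, out / "group_comparison.json")
            summary["group_comparison"] = group_doc
        if n_pat >= 1 and ipsi:
            records = records_from_zscore_maps(ipsi, manifest)
            if records:
                loc = localization_permutation_test(
                    records, n_perm=cfg["stats"]["n_perm"], seed=stage_seeds["stats"]
                )
                loc["p_exact"] = poisson_binomial_tail(
                    loc.pop("hit_probabilities"), loc["observed_hits"]
                )
                _write_json(loc, out / "localization.json")
                summary["localization"] = loc
            pooled = pool_sulcus_scores(ipsi, manifest)
            if pooled["is_fcd"].nunique() == 2:
                points, auc = roc_curve(pooled["z"], pooled["is_fcd"])
                pd.DataFrame([p.__dict__ for p in points]).to_csv(out / "roc.csv", index=False)
                summary["roc_auc"] = auc
        done()

        run_doc = {
            "seed": seed,
            "stage_seeds": stage_seeds,
            "config": cfg,
            "config_sha256": summary["config_sha256"],
            "version": __version__,
        }
        _write_json(run_doc, out / "run_manifest.json")
        _write_json({"timings_s": timings}, out / "timings.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc
    return summary
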