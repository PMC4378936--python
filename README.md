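# sulcalfcd

Sulcus-based anomaly analysis of focal cortical dysplasia (FCD) in the
central region. FCD is a developmental cortical malformation causing
refractory focal epilepsy; up to a third of lesions are invisible on
conventional MRI reading. Because the malformation arises during sulcal
morphogenesis, it perturbs the folds themselves — broadening, increased
depth, altered orientation, disrupted relations with neighbours. This
package quantifies that signature on attributed sulcal graphs and asks
whether the most anomalous sulcus points at the lesion.

The method, end to end:

1. **Recognition** — the 13 sulci of the central region are labeled on an
   attributed graph (nodes = folds with area/depth/length/centroid/
   orientation; edges = junction, geodesic-neighbourhood or buried-gyrus
   relations) by minimizing an energy
   `E = Σ node terms + Σ relation terms + structural penalties`
   against a normative control model, via simulated annealing; ten runs
   are performed and the one with the lowest central-sulcus (group
   analyses) or central-region (individual analyses) energy is kept.
2. **Sulcus energy map** — `E` splits exactly into per-sulcus local
   energies `E_s` (own potential + half of each incident relation term);
   low `E_s` means the sulcal pattern matches the control population.
3. **Z-score map** — `z_s = (E_s − mean_controls) / sd_controls`, sulcus
   by sulcus, normalizing for each sulcus's own variability.
4. **Localization statistics** — the maximum-z sulcus of the ipsilateral
   hemisphere is compared with the expert-annotated FCD sulci; the hit
   count over patients is tested against the within-patient permutation
   null (hit probability `k/13` per patient, 10 000 permutations, exact
   Poisson-binomial oracle), alongside a covariate-adjusted group
   comparison of central-sulcus energies and a sulcus-wise ROC.

MRI processing is out of scope: a synthetic generator produces control and
patient cohorts with the statistical structure the analysis assumes, and a
packaged annotation table of a published 28-patient surgical cohort
(11 MR-negative, 17 MR-positive; per-patient FCD sulci) drives the
localization test on real printed data. See `docs/methods.md` for the
model, defaults and calibration properties.

## Worked example

```python
>>> import sulcalfcd as sf
>>> # normative model from 40 true-labeled control hemispheres
>>> tpl = sf.default_template()
>>> import numpy as np; rng = np.random.default_rng(5)
>>> train = [sf.sample_control_graph(tpl, rng, f"t{i}", h)
...          for i in range(20) for h in ("left", "right")]
>>> model = sf.fit_control_model(train)
>>> # recognize a fresh hemisphere, best of 10 annealings
>>> g = sf.sample_control_graph(tpl, 7, "probe", "left")
>>> labeling, emap = sf.best_of_k_recognitions(g, model, k=10, seed=1)
>>> round(emap.local["S.C."], 2), round(emap.total, 2)
(6.58, 60.6)
```

`emap.local["S.C."]` is the central sulcus's share of the labeling energy
(dimensionless; 0 = exactly the control template). Z-scoring a patient
against controls and locating the anomaly:

```python
>>> controls = [sf.local_energy_decomposition(x, x.true_labeling(), model)
...             for x in (sf.sample_control_graph(tpl, 100 + i, f"c{i}")
...                       for i in range(29))]
>>> stats = sf.cohort_energy_stats(controls)
>>> pat = sf.apply_fcd_perturbation(
...     sf.sample_control_graph(tpl, 999, "pat", "left"),
...     sf.PerturbationSpec(targets=("S.Pe.C.marginal",)), seed=4)
>>> zmap = sf.zscore_map(
...     sf.local_energy_decomposition(pat, pat.true_labeling(), model), stats)
>>> sf.max_zscore_sulcus(zmap)[:2]
('S.Pe.C.marginal', 3.6258569149349)
```

The perturbed sulcus (depth/area +2 control SD, orientation rotated 30°,
relations disrupted) stands out at z ≈ 3.6: the maximum-z call localizes
the simulated lesion.

The numbered drivers under `analysis/` run the full study on the default
29 + 29 cohort (`01` simulate → `02` fit → `03` recognition quality →
`04` energies and z-maps → `05` statistics), writing tables to `results/`
and bulk intermediates to `scratch/`. The same pipeline is available as
`sulcalfcd run --seed 0 --out run/` and stagewise subcommands
(`cohort`, `fit`, `recognize`, `stats localize`).

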