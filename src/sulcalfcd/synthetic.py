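"""Synthetic sulcal-graph cohorts with controlled FCD perturbations.

The generator emulates, at the graph level, what a fold-extraction pipeline
would produce for the central region of one hemisphere: 13 sulci with
label-specific interindividual variability (the central sulcus is the most
stable fold across individuals, the central sylvian sulcus the most
variable), three relation types between neighbouring folds, occasional
absence of the minor ramifications, and — for patients — the sulcal
signature of focal cortical dysplasia: broadening (area), increased depth,
altered orientation, and disrupted relations with neighbours.

Attribute noise is Gaussian (truncated to positivity for areas, depths and
lengths); orientation noise is a small-angle rotation about a random axis
perpendicular to the mean direction, so that the angular deviation equals
the drawn angle exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .graph import RelationEdge, SulcalGraph, SulcusNode
from .manifest import MANIFEST_COLUMNS
from .nomenclature import CENTRAL_REGION_LABELS

N_LABELS = len(CENTRAL_REGION_LABELS)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotate(vectors: np.ndarray, axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of each row of ``vectors`` about the matching axis."""
    c = np.cos(angles)[:, None]
    s = np.sin(angles)[:, None]
    cross = np.cross(axes, vectors)
    dot = np.sum(axes * vectors, axis=1, keepdims=True)
    return vectors * c + cross * s + axes * dot * (1.0 - c)


def _perpendicular_axes(directions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit axes perpendicular to each row of ``directions``."""
    raw = rng.standard_normal(directions.shape)
    raw -= directions * np.sum(raw * directions, axis=1, keepdims=True)
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    # degenerate draws are measure-zero; fall back to any perpendicular
    bad = norms[:, 0] < 1e-12
    if np.any(bad):
        fallback = np.cross(directions[bad], np.array([1.0, 0.0, 0.0]))
        fallback_norm = np.linalg.norm(fallback, axis=1, keepdims=True)
        small = fallback_norm[:, 0] < 1e-12
        fallback[small] = np.cross(directions[bad][small], np.array([0.0, 1.0, 0.0]))
        raw[bad] = fallback
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
    return raw / norms


@dataclass(frozen=True)
class TemplateEdge:
    labels: tuple[str, str]
    relation_type: str
    relation_volume: float      # mm^3, mean
    min_distance: float         # mm, mean
    buried_gyrus_depth: Optional[float] = None  # mm, mean (split type only)


@dataclass
class TemplateSpec:
    """Population template: per-label attribute distributions and topology.

    ``variability[label]`` is a dimensionless scale multiplying every SD of
    that label; it increases strictly from the central sulcus to the central
    sylvian sulcus, encoding the anatomical variability ranking.
    """

    labels: tuple[str, ...]
    scalar_means: dict[str, tuple[float, float, float]]   # area, depth, length
    centroid_means: dict[str, tuple[float, float, float]]  # mm, left hemisphere
    orientation_means: dict[str, tuple[float, float, float]]
    variability: dict[str, float]
    presence: dict[str, float]
    edges: list[TemplateEdge]
    # base SDs at variability factor 1.0
    scalar_rel_sd: tuple[float, float, float] = (0.10, 0.08, 0.10)
    centroid_sd_mm: float = 3.0
    orientation_sd_deg: float = 8.0
    edge_volume_rel_sd: float = 0.20
    edge_distance_rel_sd: float = 0.30
    edge_direction_sd_deg: float = 10.0
    buried_depth_rel_sd: float = 0.15
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def scalar_sds(self, label: str) -> np.ndarray:
        v = self.variability[label]
        means = np.asarray(self.scalar_means[label])
        return means * np.asarray(self.scalar_rel_sd) * v

    def arrays(self) -> dict:
        """Vectorised template arrays (cached) used by the sampler."""
        if self._cache:
            return self._cache
        L = list(self.labels)
        var = np.array([self.variability[l] for l in L])
        sm = np.array([self.scalar_means[l] for l in L])
        a = {
            "labels": L,
            "var": var,
            "scalar_means": sm,
            "scalar_sds": sm * np.asarray(self.scalar_rel_sd)[None, :] * var[:, None],
            "centroid_means": np.array([self.centroid_means[l] for l in L]),
            "centroid_sds": (self.centroid_sd_mm * var)[:, None] * np.ones((1, 3)),
            "orientation_means": np.array([_unit(self.orientation_means[l]) for l in L]),
            "orientation_sds": np.radians(self.orientation_sd_deg) * var,
            "presence": np.array([self.presence[l] for l in L]),
        }
        # per-edge arrays; contact direction mean points between centroids
        dirs, vols, dists, bdepths, evar = [], [], [], [], []
        for e in self.edges:
            c0 = np.asarray(self.centroid_means[e.labels[0]])
            c1 = np.asarray(self.centroid_means[e.labels[1]])
            dirs.append(_unit(c1 - c0))
            vols.append(e.relation_volume)
            dists.append(e.min_distance)
            bdepths.append(e.buried_gyrus_depth if e.buried_gyrus_depth else 0.0)
            evar.append(max(self.variability[e.labels[0]], self.variability[e.labels[1]]))
        a["edge_dirs"] = np.array(dirs).reshape(-1, 3)
        a["edge_vols"] = np.array(vols)
        a["edge_dists"] = np.array(dists)
        a["edge_bdepths"] = np.array(bdepths)
        a["edge_var"] = np.array(evar)
        self._cache.update(a)
        return self._cache


def default_template() -> TemplateSpec:
    """The 13-sulcus central-region template.

    Topology: the central sulcus (S.C.) is geodesic neighbour of the nine
    surrounding postcentral/precentral/frontal sulci and forms junctions
    with its three ramifications (S.C.sylvian, S.C.LPC, S.p.C); the
    precentral branches chain together, with one buried-gyrus split between
    the superior and median precentral branches.  Attribute means are
    typical adult magnitudes (mm / mm^2); SD scale increases strictly along
    the variability ranking, from 0.6 (S.C.) to 1.8 (S.C.sylvian).
    """
    scalar_means = {
        "S.C.":              (1300.0, 25.0, 95.0),
        "S.Po.C.sup":        (500.0, 18.0, 55.0),
        "S.Pe.C.sup":        (450.0, 17.0, 50.0),
        "S.Pe.C.inf":        (420.0, 16.0, 45.0),
        "S.Pe.C.median":     (250.0, 12.0, 30.0),
        "S.Pe.C.marginal":   (260.0, 13.0, 32.0),
        "S.Pe.C.inter":      (220.0, 11.0, 28.0),
        "S.F.median":        (300.0, 10.0, 45.0),
        "F.I.P.Po.C.inf":    (280.0, 14.0, 35.0),
        "F.C.L.r.retroC.tr": (180.0, 10.0, 25.0),
        "S.p.C":             (200.0, 10.0, 28.0),
        "S.C.LPC":           (160.0, 8.0, 22.0),
        "S.C.sylvian":       (120.0, 7.0, 18.0),
    }
    centroid_means = {
        "S.C.":              (0.0, 0.0, 35.0),
        "S.Po.C.sup":        (-5.0, -25.0, 45.0),
        "S.Pe.C.sup":        (-3.0, 25.0, 50.0),
        "S.Pe.C.inf":        (-10.0, 30.0, 5.0),
        "S.Pe.C.median":     (8.0, 22.0, 60.0),
        "S.Pe.C.marginal":   (-8.0, 28.0, 30.0),
        "S.Pe.C.inter":      (-6.0, 27.0, 20.0),
        "S.F.median":        (10.0, 35.0, 55.0),
        "F.I.P.Po.C.inf":    (-12.0, -30.0, 20.0),
        "F.C.L.r.retroC.tr": (-18.0, -15.0, -5.0),
        "S.p.C":             (12.0, 10.0, 65.0),
        "S.C.LPC":           (14.0, -5.0, 60.0),
        "S.C.sylvian":       (-20.0, 5.0, -10.0),
    }
    orientation_means = {
        "S.C.":              (0.20, -0.30, 0.93),
        "S.Po.C.sup":        (0.10, -0.40, 0.91),
        "S.Pe.C.sup":        (0.15, 0.35, 0.92),
        "S.Pe.C.inf":        (0.30, 0.50, 0.81),
        "S.Pe.C.median":     (0.05, 0.70, 0.71),
        "S.Pe.C.marginal":   (0.25, 0.60, 0.76),
        "S.Pe.C.inter":      (0.35, 0.55, 0.76),
        "S.F.median":        (0.10, 0.95, 0.30),
        "F.I.P.Po.C.inf":    (0.20, -0.70, 0.68),
        "F.C.L.r.retroC.tr": (0.40, -0.60, 0.69),
        "S.p.C":             (0.15, 0.80, 0.58),
        "S.C.LPC":           (0.30, -0.20, 0.93),
        "S.C.sylvian":       (0.60, 0.30, 0.74),
    }
    # strictly increasing along the CENTRAL_REGION_LABELS ranking
    variability = {
        lab: 0.6 + 0.1 * rank for rank, lab in enumerate(CENTRAL_REGION_LABELS)
    }
    presence = {lab: 1.0 for lab in CENTRAL_REGION_LABELS}
    for minor in ("S.C.sylvian", "S.C.LPC", "S.p.C"):
        presence[minor] = 0.9

    g, j, b = "geodesic_neighbor", "junction", "buried_gyrus_split"
    edges = [
        TemplateEdge(("S.C.", "S.Po.C.sup"), g, 150.0, 6.0),
        TemplateEdge(("S.C.", "F.C.L.r.retroC.tr"), g, 120.0, 8.0),
        TemplateEdge(("S.C.", "F.I.P.Po.C.inf"), g, 130.0, 7.0),
        TemplateEdge(("S.C.", "S.F.median"), g, 110.0, 9.0),
        TemplateEdge(("S.C.", "S.Pe.C.median"), g, 140.0, 6.5),
        TemplateEdge(("S.C.", "S.Pe.C.marginal"), g, 150.0, 6.0),
        TemplateEdge(("S.C.", "S.Pe.C.sup"), g, 160.0, 5.5),
        TemplateEdge(("S.C.", "S.Pe.C.inter"), g, 140.0, 6.5),
        TemplateEdge(("S.C.", "S.Pe.C.inf"), g, 150.0, 6.0),
        TemplateEdge(("S.C.", "S.C.sylvian"), j, 300.0, 0.5),
        TemplateEdge(("S.C.", "S.C.LPC"), j, 280.0, 0.5),
        TemplateEdge(("S.C.", "S.p.C"), j, 260.0, 0.5),
        TemplateEdge(("S.Pe.C.sup", "S.Pe.C.inter"), j, 250.0, 0.8),
        TemplateEdge(("S.Pe.C.inter", "S.Pe.C.inf"), j, 240.0, 0.8),
        TemplateEdge(("S.Pe.C.sup", "S.Pe.C.median"), b, 200.0, 2.0, 8.0),
        TemplateEdge(("S.Pe.C.sup", "S.Pe.C.marginal"), g, 130.0, 5.0),
        TemplateEdge(("S.Po.C.sup", "F.I.P.Po.C.inf"), j, 260.0, 0.8),
        TemplateEdge(("S.p.C", "S.C.LPC"), g, 100.0, 5.0),
        TemplateEdge(("F.C.L.r.retroC.tr", "S.C.sylvian"), g, 90.0, 6.0),
    ]
    return TemplateSpec(
        labels=CENTRAL_REGION_LABELS,
        scalar_means=scalar_means,
        centroid_means=centroid_means,
        orientation_means=orientation_means,
        variability=variability,
        presence=presence,
        edges=edges,
    )


def template_mean_graph(
    template: TemplateSpec, subject_id: str = "template", hemisphere: str = "left"
) -> SulcalGraph:
    """The noise-free graph sitting exactly at the template means.

    All 13 sulci present, every expected relation instantiated at its mean
    attributes — the idealized 'perfectly average' hemisphere used to probe
    identity properties of the energy model and the recognizer.
    """
    a = template.arrays()
    mirror = -1.0 if hemisphere == "right" else 1.0
    prefix = "L" if hemisphere == "left" else "R"
    nodes, id_of = [], {}
    for i, lab in enumerate(a["labels"]):
        nid = f"{prefix}f{i:02d}"
        id_of[lab] = nid
        cx, cy, cz = a["centroid_means"][i]
        ox, oy, oz = a["orientation_means"][i]
        nodes.append(
            SulcusNode(
                node_id=nid,
                area=float(a["scalar_means"][i, 0]),
                max_depth=float(a["scalar_means"][i, 1]),
                length=float(a["scalar_means"][i, 2]),
                centroid=(mirror * float(cx), float(cy), float(cz)),
                orientation=(mirror * float(ox), float(oy), float(oz)),
                true_label=lab,
            )
        )
    edges = []
    for k, te in enumerate(template.edges):
        dx, dy, dz = a["edge_dirs"][k]
        edges.append(
            RelationEdge(
                endpoints=(id_of[te.labels[0]], id_of[te.labels[1]]),
                relation_type=te.relation_type,
                contact_direction=(mirror * float(dx), float(dy), float(dz)),
                relation_volume=te.relation_volume,
                min_distance=te.min_distance,
                buried_gyrus_depth=te.buried_gyrus_depth,
            )
        )
    return SulcalGraph(subject_id=subject_id, hemisphere=hemisphere, nodes=nodes, edges=edges)


@dataclass(frozen=True)
class PerturbationSpec:
    """FCD-like perturbation of target sulci, in control-SD units.

    ``delta_depth`` and ``delta_area`` shift the target's depth/area by that
    many template SDs; ``delta_theta_deg`` rotates its orientation by
    exactly that angle about a random perpendicular axis; each relation of a
    target is independently dropped or retyped with probability
    ``relation_disruption``.
    """

    targets: tuple[str, ...]
    delta_depth: float = 2.0
    delta_area: float = 2.0
    delta_theta_deg: float = 30.0
    relation_disruption: float = 0.25

    def __post_init__(self):
        for t in self.targets:
            if t not in CENTRAL_REGION_LABELS:
                raise ValueError(f"perturbation target outside nomenclature: {t!r}")
        if min(self.delta_depth, self.delta_area, self.delta_theta_deg) < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0.0 <= self.relation_disruption <= 1.0:
            raise ValueError("relation_disruption must be in [0, 1]")


def sample_control_graph(
    template: TemplateSpec,
    seed,
    subject_id: str = "subject",
    hemisphere: str = "left",
) -> SulcalGraph:
    """Draw one hemisphere's graph from the template distributions.

    Minor labels are dropped with probability 1 - presence; an expected
    relation is instantiated (with attribute noise) iff both endpoints are
    present.  The right hemisphere is the mirror image (x negated) of the
    left-hemisphere template.  Deterministic given the seed (or Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = template.arrays()
    mirror = -1.0 if hemisphere == "right" else 1.0

    present = rng.random(N_LABELS) < a["presence"]
    scalars = a["scalar_means"] + rng.standard_normal((N_LABELS, 3)) * a["scalar_sds"]
    scalars = np.maximum(scalars, 1e-6)  # positivity guard; ~never binds at defaults
    centroids = a["centroid_means"] + rng.standard_normal((N_LABELS, 3)) * a["centroid_sds"]
    axes = _perpendicular_axes(a["orientation_means"], rng)
    angles = rng.standard_normal(N_LABELS) * a["orientation_sds"]
    orients = _rotate(a["orientation_means"], axes, angles)
    orients /= np.linalg.norm(orients, axis=1, keepdims=True)

    prefix = "L" if hemisphere == "left" else "R"
    nodes = []
    id_of: dict[str, str] = {}
    for i, lab in enumerate(a["labels"]):
        if not present[i]:
            continue
        nid = f"{prefix}f{i:02d}"
        id_of[lab] = nid
        cx, cy, cz = centroids[i]
        ox, oy, oz = orients[i]
        nodes.append(
            SulcusNode(
                node_id=nid,
                area=float(scalars[i, 0]),
                max_depth=float(scalars[i, 1]),
                length=float(scalars[i, 2]),
                centroid=(mirror * float(cx), float(cy), float(cz)),
                orientation=(mirror * float(ox), float(oy), float(oz)),
                true_label=lab,
            )
        )

    n_e = len(template.edges)
    evols = a["edge_vols"] * (1.0 + rng.standard_normal(n_e) * template.edge_volume_rel_sd * a["edge_var"])
    edists = a["edge_dists"] * (1.0 + rng.standard_normal(n_e) * template.edge_distance_rel_sd * a["edge_var"])
    ebd = a["edge_bdepths"] * (1.0 + rng.standard_normal(n_e) * template.buried_depth_rel_sd * a["edge_var"])
    eaxes = _perpendicular_axes(a["edge_dirs"], rng)
    eangles = rng.standard_normal(n_e) * np.radians(template.edge_direction_sd_deg) * a["edge_var"]
    edirs = _rotate(a["edge_dirs"], eaxes, eangles)
    edirs /= np.linalg.norm(edirs, axis=1, keepdims=True)

    edges = []
    for k, te in enumerate(template.edges):
        l0, l1 = te.labels
        if l0 not in id_of or l1 not in id_of:
            continue
        dx, dy, dz = edirs[k]
        edges.append(
            RelationEdge(
                endpoints=(id_of[l0], id_of[l1]),
                relation_type=te.relation_type,
                contact_direction=(mirror * float(dx), float(dy), float(dz)),
                relation_volume=float(max(evols[k], 1e-6)),
                min_distance=float(max(edists[k], 0.0)),
                buried_gyrus_depth=(
                    float(max(ebd[k], 1e-6))
                    if te.relation_type == "buried_gyrus_split"
                    else None
                ),
            )
        )
    return SulcalGraph(subject_id=subject_id, hemisphere=hemisphere, nodes=nodes, edges=edges)


def apply_fcd_perturbation(
    graph: SulcalGraph,
    spec: PerturbationSpec,
    seed,
    template: Optional[TemplateSpec] = None,
) -> SulcalGraph:
    """Apply an FCD-like lesion signature to the target sulci of a graph.

    Depth and area increase by exactly delta * template SD, the orientation
    rotates by exactly delta_theta about a random perpendicular axis, and
    each relation touching a target is dropped or retyped with the
    disruption probability.  Non-target nodes are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = template or default_template()
    by_label = {n.true_label: n for n in graph.nodes if n.true_label is not None}
    missing = [t for t in spec.targets if t not in by_label]
    if missing:
        raise ValueError(f"perturbation targets absent from graph: {missing}")

    target_ids = set()
    new_nodes = []
    for n in graph.nodes:
        if n.true_label not in spec.targets:
            new_nodes.append(n)
            continue
        target_ids.add(n.node_id)
        sds = template.scalar_sds(n.true_label)
        orient = np.asarray(n.orientation)
        if spec.delta_theta_deg > 0:
            axis = _perpendicular_axes(orient[None, :], rng)[0]
            orient = _rotate(
                orient[None, :], axis[None, :], np.array([math.radians(spec.delta_theta_deg)])
            )[0]
            orient = orient / np.linalg.norm(orient)
        new_nodes.append(
            replace(
                n,
                area=n.area + spec.delta_area * float(sds[0]),
                max_depth=n.max_depth + spec.delta_depth * float(sds[1]),
                orientation=(float(orient[0]), float(orient[1]), float(orient[2])),
            )
        )

    other_types = {t: [u for u in ("junction", "geodesic_neighbor", "buried_gyrus_split") if u != t]
                   for t in ("junction", "geodesic_neighbor", "buried_gyrus_split")}
    new_edges = []
    for e in graph.edges:
        touches = e.endpoints[0] in target_ids or e.endpoints[1] in target_ids
        if not touches or rng.random() >= spec.relation_disruption:
            new_edges.append(e)
            continue
        if rng.random() < 0.5:
            continue  # relation destroyed by the lesion
        # retype: the relation survives but with a different topology class
        new_type = other_types[e.relation_type][int(rng.integers(2))]
        depth = (
            float(max(rng.normal(8.0, 1.5), 1e-3))
            if new_type == "buried_gyrus_split"
            else None
        )
        new_edges.append(
            replace(e, relation_type=new_type, buried_gyrus_depth=depth)
        )
    return SulcalGraph(graph.subject_id, graph.hemisphere, new_nodes, new_edges)


@dataclass(frozen=True)
class CovariateModel:
    """Distribution of subject covariates; morphological effects default to 0.

    Nonzero effects (depth shift in mm per unit covariate) enable power
    studies of covariate confounding; the study conditions use zero effects.
    """

    age_low: float = 18.0
    age_high: float = 45.0
    p_male: float = 0.5
    p_3t: float = 0.3
    age_depth_slope: float = 0.0    # mm per year of age above 30
    sex_depth_effect: float = 0.0   # mm added for males
    field_depth_effect: float = 0.0  # mm added at 3 T


# empirical distribution of FCD-sulcus counts in the reference cohort
FCD_COUNT_PROBS = {1: 16 / 28, 2: 7 / 28, 3: 5 / 28}


def _neighbors(template: TemplateSpec) -> dict[str, list[str]]:
    nb: dict[str, list[str]] = {lab: [] for lab in template.labels}
    for e in template.edges:
        nb[e.labels[0]].append(e.labels[1])
        nb[e.labels[1]].append(e.labels[0])
    return nb


def _pick_fcd_sulci(present: list[str], template: TemplateSpec, rng) -> list[str]:
    """1-3 FCD sulci: a seed sulcus plus neighbouring sulci (lesions sit in
    the vicinity of several adjacent folds)."""
    counts = np.array(list(FCD_COUNT_PROBS.keys()))
    probs = np.array(list(FCD_COUNT_PROBS.values()))
    c = int(rng.choice(counts, p=probs))
    nb = _neighbors(template)
    chosen = [present[int(rng.integers(len(present)))]]
    while len(chosen) < c:
        frontier = sorted(
            {m for lab in chosen for m in nb[lab] if m in present and m not in chosen}
        )
        if not frontier:
            frontier = [lab for lab in present if lab not in chosen]
            if not frontier:
                break
        chosen.append(frontier[int(rng.integers(len(frontier)))])
    return chosen


def _apply_covariate_effects(
    graph: SulcalGraph, cov: CovariateModel, age: float, male: bool, at_3t: bool
) -> SulcalGraph:
    shift = (
        cov.age_depth_slope * (age - 30.0)
        + (cov.sex_depth_effect if male else 0.0)
        + (cov.field_depth_effect if at_3t else 0.0)
    )
    if shift == 0.0:
        return graph
    nodes = [replace(n, max_depth=max(n.max_depth + shift, 1e-6)) for n in graph.nodes]
    return SulcalGraph(graph.subject_id, graph.hemisphere, nodes, list(graph.edges))


def generate_cohort(
    n_controls: int,
    n_patients: int,
    template: Optional[TemplateSpec] = None,
    perturbation: Optional[PerturbationSpec] = None,
    covariates: Optional[CovariateModel] = None,
    seed: int = 0,
) -> tuple[list[SulcalGraph], pd.DataFrame]:
    """Generate a two-hemisphere cohort and its manifest.

    Controls are unperturbed draws from the template; each patient carries
    1-3 FCD sulci (neighbour-contiguous where possible) on one hemisphere,
    perturbed with the given effect sizes; the contralateral hemisphere is
    never perturbed.  ``perturbation.targets`` is ignored — targets are
    drawn per patient; the effect sizes and disruption probability apply.
    Fully reproducible from the seed.
    """
    template = template or default_template()
    base = perturbation or PerturbationSpec(targets=("S.C.",))
    cov = covariates or CovariateModel()
    rng = np.random.default_rng(seed)

    graphs: list[SulcalGraph] = []
    rows = []
    groups = [("control", i) for i in range(n_controls)] + [
        ("patient", i) for i in range(n_patients)
    ]
    for group, i in groups:
        sid = f"{'ctl' if group == 'control' else 'pat'}{i:03d}"
        age = float(np.round(rng.uniform(cov.age_low, cov.age_high), 1))
        male = bool(rng.random() < cov.p_male)
        at_3t = bool(rng.random() < cov.p_3t)
        side = "n/a"
        fcd: list[str] = []
        mr_status = "n/a"
        pair = {}
        for hemi in ("left", "right"):
            g = sample_control_graph(template, rng, subject_id=sid, hemisphere=hemi)
            pair[hemi] = _apply_covariate_effects(g, cov, age, male, at_3t)
        if group == "patient":
            side = "left" if rng.random() < 0.5 else "right"
            mr_status = "MR+" if rng.random() < 17 / 28 else "MR-"
            present = [n.true_label for n in pair[side].nodes if n.true_label]
            fcd = _pick_fcd_sulci(present, template, rng)
            spec = replace(base, targets=tuple(fcd))
            pair[side] = apply_fcd_perturbation(pair[side], spec, rng, template)
        graphs.extend([pair["left"], pair["right"]])
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "mr_status": mr_status,
                "age": age,
                "sex": "M" if male else "F",
                "field_T": 3.0 if at_3t else 1.5,
                "lesion_side": side,
                "fcd_sulci": fcd,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return graphs, manifest
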