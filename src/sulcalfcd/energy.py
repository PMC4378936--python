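"""Sulcus energy: normative Gaussian potentials over labeled sulcal graphs.

The labeling objective ("energy") quantifies how far a labeled graph lies
from a normative control population.  It is a sum of non-negative local
terms:

* a node potential per labeled fold — half the squared Mahalanobis distance
  of its morphological descriptors from the control distribution of that
  label, plus a quadratic angular term for its (sign-ambiguous) orientation;
* an edge potential per relation between two labeled folds — the analogous
  Mahalanobis/angular term for the relation attributes plus ``-log f``
  where ``f`` is the control frequency of that relation;
* fixed penalties for structural anomalies: an expected relation that is
  absent (``lambda_missing``), a relation the controls never exhibit
  (``lambda_spurious``), and a fold left unlabeled (``lambda_background``).

Energy 0 therefore means a perfect match to the control template.  The
total energy decomposes exactly into per-sulcus local energies ("sulcus
energy map"): each node keeps its own potential and half of every incident
pairwise term, so the local energies sum to the total.

Right-hemisphere graphs are mapped to the left-hemisphere frame (x
mirrored) before any statistic is computed, so a single model serves both
hemispheres, mirroring the shared nomenclature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .graph import RelationEdge, SulcalGraph, SulcusNode
from .nomenclature import BACKGROUND, CENTRAL_REGION_LABELS

# floor on angular SDs (radians) — guards degenerate (zero-variance) cohorts
SIGMA_THETA_FLOOR = 1e-3
# floor on the covariance regularizer for zero-variance training sets
EPSILON_FLOOR = 1e-6

RelationKey = tuple[str, str, str]  # (label_lo, label_hi, relation_type)


def relation_key(label_a: str, label_b: str, relation_type: str) -> RelationKey:
    lo, hi = sorted((label_a, label_b))
    return (lo, hi, relation_type)


def _mirror_sign(hemisphere: str) -> float:
    return -1.0 if hemisphere == "right" else 1.0


def node_features(node: SulcusNode, hemisphere: str) -> np.ndarray:
    """Scalar descriptor vector in the canonical (left) frame."""
    m = _mirror_sign(hemisphere)
    return np.array(
        [
            node.area,
            node.max_depth,
            node.length,
            m * node.centroid[0],
            node.centroid[1],
            node.centroid[2],
        ]
    )


def node_orientation(node: SulcusNode, hemisphere: str) -> np.ndarray:
    m = _mirror_sign(hemisphere)
    o = node.orientation
    return np.array([m * o[0], o[1], o[2]])


def edge_features(edge: RelationEdge) -> np.ndarray:
    if edge.relation_type == "buried_gyrus_split":
        return np.array([edge.relation_volume, edge.min_distance, edge.buried_gyrus_depth])
    return np.array([edge.relation_volume, edge.min_distance])


def edge_direction(edge: RelationEdge, hemisphere: str) -> np.ndarray:
    m = _mirror_sign(hemisphere)
    d = edge.contact_direction
    return np.array([m * d[0], d[1], d[2]])


def _angle(direction: np.ndarray, mean_dir: np.ndarray) -> float:
    c = abs(float(np.dot(direction, mean_dir)))
    return math.acos(min(c, 1.0))


def _mean_direction(vectors: np.ndarray) -> np.ndarray:
    """Sign-invariant mean direction: principal axis of the scatter matrix."""
    scatter = vectors.T @ vectors
    w, v = np.linalg.eigh(scatter)
    return v[:, -1]


def _regularized_cov(samples: np.ndarray, epsilon_rel: float) -> np.ndarray:
    n, d = samples.shape
    cov = np.cov(samples, rowvar=False, ddof=1).reshape(d, d)
    eps = max(epsilon_rel * float(np.mean(np.diag(cov))), EPSILON_FLOOR)
    return cov + eps * np.eye(d)


@dataclass
class GaussianStats:
    """Mean/covariance of a descriptor block plus its angular statistics."""

    mean: np.ndarray
    cov: np.ndarray
    mean_direction: np.ndarray
    sigma_theta: float  # radians
    n: int
    _inv: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def inv(self) -> np.ndarray:
        if self._inv is None:
            self._inv = np.linalg.inv(self.cov)
        return self._inv

    def quad(self, x: np.ndarray, direction: np.ndarray) -> float:
        d = x - self.mean
        theta = _angle(direction, self.mean_direction)
        return 0.5 * float(d @ self.inv @ d) + 0.5 * (theta / self.sigma_theta) ** 2


@dataclass
class ControlModel:
    """Normative statistics learned from control graphs with true labels."""

    labels: tuple[str, ...]
    node_stats: dict[str, GaussianStats]
    relation_stats: dict[RelationKey, GaussianStats]
    relation_freq: dict[RelationKey, float]
    lambda_missing: float = 3.0
    lambda_spurious: float = 3.0
    lambda_background: float = 10.0
    n_train: int = 0

    def expected_relations(self) -> Iterable[RelationKey]:
        return self.relation_stats.keys()

    # -- serialization ------------------------------------------------------

    def to_doc(self) -> dict:
        def stats_doc(s: GaussianStats) -> dict:
            return {
                "mean": s.mean.tolist(),
                "cov": s.cov.tolist(),
                "mean_direction": s.mean_direction.tolist(),
                "sigma_theta": s.sigma_theta,
                "n": s.n,
            }

        return {
            "schema_version": "1",
            "labels": list(self.labels),
            "node_stats": {lab: stats_doc(s) for lab, s in self.node_stats.items()},
            "relation_stats": {
                "|".join(k): stats_doc(s) for k, s in self.relation_stats.items()
            },
            "relation_freq": {"|".join(k): f for k, f in self.relation_freq.items()},
            "penalties": {
                "lambda_missing": self.lambda_missing,
                "lambda_spurious": self.lambda_spurious,
                "lambda_background": self.lambda_background,
            },
            "n_train": self.n_train,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "ControlModel":
        def stats(d: dict) -> GaussianStats:
            return GaussianStats(
                mean=np.asarray(d["mean"], dtype=float),
                cov=np.asarray(d["cov"], dtype=float),
                mean_direction=np.asarray(d["mean_direction"], dtype=float),
                sigma_theta=float(d["sigma_theta"]),
                n=int(d["n"]),
            )

        pen = doc["penalties"]
        return cls(
            labels=tuple(doc["labels"]),
            node_stats={lab: stats(s) for lab, s in doc["node_stats"].items()},
            relation_stats={
                tuple(k.split("|")): stats(s) for k, s in doc["relation_stats"].items()
            },
            relation_freq={tuple(k.split("|")): float(f) for k, f in doc["relation_freq"].items()},
            lambda_missing=float(pen["lambda_missing"]),
            lambda_spurious=float(pen["lambda_spurious"]),
            lambda_background=float(pen["lambda_background"]),
            n_train=int(doc["n_train"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_doc(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ControlModel":
        with open(path) as fh:
            return cls.from_doc(json.load(fh))


def fit_control_model(
    graphs: Iterable[SulcalGraph],
    epsilon_rel: float = 1e-3,
    lambda_missing: float = 3.0,
    lambda_spurious: float = 3.0,
    lambda_background: float = 10.0,
) -> ControlModel:
    """Estimate normative statistics from true-labeled control graphs.

    Sample means/covariances per label (regularized by adding
    ``epsilon_rel * mean(diag(cov))`` to the covariance diagonal) and per
    (label-pair, relation-type); the relation frequency ``f`` is the
    fraction of training graphs exhibiting the relation.  Every label must
    be observed at least twice.
    """
    graphs = list(graphs)
    n_train = len(graphs)
    if n_train < 2:
        raise ValueError("need at least 2 training graphs")

    node_samples: dict[str, list[np.ndarray]] = {lab: [] for lab in CENTRAL_REGION_LABELS}
    node_orients: dict[str, list[np.ndarray]] = {lab: [] for lab in CENTRAL_REGION_LABELS}
    rel_samples: dict[RelationKey, list[np.ndarray]] = {}
    rel_dirs: dict[RelationKey, list[np.ndarray]] = {}
    rel_graph_count: dict[RelationKey, int] = {}

    for g in graphs:
        by_id = {n.node_id: n for n in g.nodes}
        seen_rel: set[RelationKey] = set()
        for n in g.nodes:
            if n.true_label is None or n.true_label == BACKGROUND:
                continue
            node_samples[n.true_label].append(node_features(n, g.hemisphere))
            node_orients[n.true_label].append(node_orientation(n, g.hemisphere))
        for e in g.edges:
            la = by_id[e.endpoints[0]].true_label
            lb = by_id[e.endpoints[1]].true_label
            if la in (None, BACKGROUND) or lb in (None, BACKGROUND):
                continue
            key = relation_key(la, lb, e.relation_type)
            rel_samples.setdefault(key, []).append(edge_features(e))
            rel_dirs.setdefault(key, []).append(edge_direction(e, g.hemisphere))
            seen_rel.add(key)
        for key in seen_rel:
            rel_graph_count[key] = rel_graph_count.get(key, 0) + 1

    under = [lab for lab, s in node_samples.items() if len(s) < 2]
    if under:
        raise ValueError(f"labels observed fewer than 2 times in training: {under}")

    def build_stats(samples: list[np.ndarray], dirs: list[np.ndarray]) -> GaussianStats:
        X = np.asarray(samples)
        D = np.asarray(dirs)
        mean_dir = _mean_direction(D)
        cosines = np.clip(np.abs(D @ mean_dir), 0.0, 1.0)
        thetas = np.arccos(cosines)
        sigma = max(float(np.sqrt(np.mean(thetas**2))), SIGMA_THETA_FLOOR)
        return GaussianStats(
            mean=X.mean(axis=0),
            cov=_regularized_cov(X, epsilon_rel),
            mean_direction=mean_dir,
            sigma_theta=sigma,
            n=len(samples),
        )

    node_stats = {
        lab: build_stats(node_samples[lab], node_orients[lab])
        for lab in CENTRAL_REGION_LABELS
    }
    relation_stats = {}
    relation_freq = {}
    for key, samples in rel_samples.items():
        if len(samples) < 2:
            continue  # a relation seen once carries no usable covariance
        relation_stats[key] = build_stats(samples, rel_dirs[key])
        relation_freq[key] = rel_graph_count[key] / n_train

    return ControlModel(
        labels=CENTRAL_REGION_LABELS,
        node_stats=node_stats,
        relation_stats=relation_stats,
        relation_freq=relation_freq,
        lambda_missing=lambda_missing,
        lambda_spurious=lambda_spurious,
        lambda_background=lambda_background,
        n_train=n_train,
    )


# ---------------------------------------------------------------------------
# Potentials

def node_potential(
    node: SulcusNode, label: str, model: ControlModel, hemisphere: str = "left"
) -> float:
    if label == BACKGROUND:
        return model.lambda_background
    stats = model.node_stats[label]
    return stats.quad(node_features(node, hemisphere), node_orientation(node, hemisphere))


def edge_potential(
    edge: RelationEdge,
    label_a: str,
    label_b: str,
    model: ControlModel,
    hemisphere: str = "left",
) -> float:
    """Energy of a *present* relation given its endpoint labels.

    Relations with a background endpoint carry no normative information and
    contribute zero; a relation the controls never exhibit between these
    labels costs ``lambda_spurious``.
    """
    if label_a == BACKGROUND or label_b == BACKGROUND:
        return 0.0
    key = relation_key(label_a, label_b, edge.relation_type)
    stats = model.relation_stats.get(key)
    if stats is None:
        return model.lambda_spurious
    f = model.relation_freq[key]
    return stats.quad(edge_features(edge), edge_direction(edge, hemisphere)) + max(
        -math.log(f), 0.0
    )


def _check_labeling(graph: SulcalGraph, labeling: Mapping[str, str]) -> None:
    unlabeled = [n.node_id for n in graph.nodes if n.node_id not in labeling]
    if unlabeled:
        raise ValueError(f"unlabeled nodes: {unlabeled}")


def _missing_expected(
    graph: SulcalGraph, labeling: Mapping[str, str], model: ControlModel
) -> list[tuple[RelationKey, tuple[str, ...]]]:
    """Expected relations not realised by the labeling.

    A model relation is charged whenever at least one of its endpoint
    labels is assigned and no present edge realises it (with one endpoint
    unassigned the relation cannot be realised at all).  Returns
    ``(key, charged_labels)`` pairs, where ``charged_labels`` are the
    assigned endpoint labels that share the penalty.  Charging one-sided
    breaks is what makes unlabeling a well-connected sulcus expensive: its
    relation terms do not silently vanish.
    """
    assigned = {lab: nid for nid, lab in labeling.items() if lab != BACKGROUND}
    present: set[RelationKey] = set()
    for e in graph.edges:
        la, lb = labeling[e.endpoints[0]], labeling[e.endpoints[1]]
        if la == BACKGROUND or lb == BACKGROUND:
            continue
        present.add(relation_key(la, lb, e.relation_type))
    out = []
    for key in model.expected_relations():
        lo, hi, _ = key
        charged = tuple(lab for lab in (lo, hi) if lab in assigned)
        if charged and key not in present:
            out.append((key, charged))
    return out


def total_energy(
    graph: SulcalGraph, labeling: Mapping[str, str], model: ControlModel
) -> float:
    """Total labeling energy: node + edge potentials + missing-relation terms."""
    _check_labeling(graph, labeling)
    e_total = 0.0
    for n in graph.nodes:
        e_total += node_potential(n, labeling[n.node_id], model, graph.hemisphere)
    for e in graph.edges:
        e_total += edge_potential(
            e, labeling[e.endpoints[0]], labeling[e.endpoints[1]], model, graph.hemisphere
        )
    e_total += model.lambda_missing * len(_missing_expected(graph, labeling, model))
    return e_total


@dataclass
class EnergyMap:
    """Per-sulcus local energies of one labeled hemisphere.

    ``local`` maps each assigned label (plus a pooled ``background`` entry
    when unlabeled folds exist) to its share of the total energy; the
    shares sum to ``total`` exactly.
    """

    subject_id: str
    hemisphere: str
    local: dict[str, float]
    total: float

    def get(self, label: str) -> Optional[float]:
        return self.local.get(label)


def local_energy_decomposition(
    graph: SulcalGraph, labeling: Mapping[str, str], model: ControlModel
) -> EnergyMap:
    """Split the total energy into per-sulcus local energies.

    Each node keeps its own potential; every pairwise term (edge potential
    or missing-relation penalty) is shared half-and-half between its two
    endpoint labels, making the decomposition exactly conservative.
    """
    _check_labeling(graph, labeling)
    local: dict[str, float] = {}

    def add(label: str, value: float) -> None:
        local[label] = local.get(label, 0.0) + value

    for n in graph.nodes:
        lab = labeling[n.node_id]
        add(lab if lab != BACKGROUND else BACKGROUND,
            node_potential(n, lab, model, graph.hemisphere))
    for e in graph.edges:
        la, lb = labeling[e.endpoints[0]], labeling[e.endpoints[1]]
        pot = edge_potential(e, la, lb, model, graph.hemisphere)
        if pot != 0.0:
            add(la, 0.5 * pot)
            add(lb, 0.5 * pot)
    for _key, charged in _missing_expected(graph, labeling, model):
        share = model.lambda_missing / len(charged)
        for lab in charged:
            add(lab, share)

    return EnergyMap(
        subject_id=graph.subject_id,
        hemisphere=graph.hemisphere,
        local=local,
        total=sum(local.values()),
    )


def energy_maps_to_frame(maps: Iterable[EnergyMap]):
    """Long-format table (subject_id, hemisphere, label, local_energy)."""
    import pandas as pd

    rows = [
        {
            "subject_id": m.subject_id,
            "hemisphere": m.hemisphere,
            "label": lab,
            "local_energy": val,
        }
        for m in maps
        for lab, val in sorted(m.local.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "hemisphere", "label", "local_energy"])
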