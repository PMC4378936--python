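"""Statistics for group comparison and lesion localization.

Three layers:

* covariate-adjusted OLS comparison of central-sulcus energies between
  patients and controls (per hemisphere, on subject means, or on the
  hemisphere ipsilateral to the lesion), with the group effect tested by a
  nested-model F test;
* the within-patient permutation test for lesion localization: under the
  null that the most abnormal sulcus is unrelated to the lesion, each
  patient's maximum-z sulcus hits one of its ``k`` FCD sulci among ``n``
  candidates with probability ``k/n``; the observed hit count is compared
  with 10 000 within-patient permutations of the FCD indicator, and the
  exact null (a Poisson-binomial upper tail) is available as an oracle;
* sulcus-wise ROC of the z-score as an FCD-sulcus classifier, pooled over
  patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .energy import EnergyMap
from .nomenclature import CENTRAL_REGION_LABELS
from .zscore import ZScoreMap, max_zscore_sulcus


# ---------------------------------------------------------------------------
# Group-level comparison

@dataclass(frozen=True)
class GroupComparison:
    effect: float     # group (patient - control) coefficient, energy units
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    n: int


def _design(df: pd.DataFrame, columns: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(df))], ["intercept"]
    for c in columns:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.astype(str).unique())
            # one indicator per non-reference level
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        running = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([running, X[:, j]])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                bad.append(names[j])
            else:
                running = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def group_energy_comparison(
    table: pd.DataFrame,
    energy_col: str = "energy",
    group_col: str = "group",
    covariate_cols: Sequence[str] = (),
) -> GroupComparison:
    """OLS of energy on group + covariates; F test of the group term.

    ``group`` must have exactly the levels control/patient.  The p-value
    comes from the nested-model residual-sum-of-squares comparison between
    the covariate-only model and the full model.
    """
    counts = table[group_col].value_counts()
    if set(counts.index) != {"control", "patient"} or counts.min() < 2:
        raise ValueError("need >= 2 subjects in each of groups control/patient")
    y = table[energy_col].to_numpy(dtype=float)
    g = (table[group_col] == "patient").to_numpy(dtype=float)
    X_red, names = _design(table, covariate_cols)
    X_full = np.column_stack([X_red, g])
    names.append(group_col)
    _check_full_rank(X_full, names)
    if len(y) - X_full.shape[1] < 1:
        raise ValueError(
            f"too few observations ({len(y)}) for {X_full.shape[1]} design columns"
        )

    beta_full, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta_full) ** 2))
    beta_red, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))

    df_num = 1
    df_den = len(y) - X_full.shape[1]
    f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return GroupComparison(
        effect=float(beta_full[-1]),
        f_stat=float(f_stat),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
        n=len(y),
    )


def central_sulcus_energy_table(
    energy_maps: Iterable[EnergyMap],
    manifest: pd.DataFrame,
    label: str = "S.C.",
) -> pd.DataFrame:
    """One row per (subject, hemisphere) with the central-sulcus energy and
    the subject covariates, ready for the group comparisons."""
    emap_rows = [
        {"subject_id": m.subject_id, "hemisphere": m.hemisphere, "energy": m.local[label]}
        for m in energy_maps
        if label in m.local
    ]
    energies = pd.DataFrame(emap_rows)
    meta = manifest[["subject_id", "group", "mr_status", "age", "sex", "field_T", "lesion_side"]]
    return energies.merge(meta, on="subject_id", how="inner")


def bilateral_group_comparison(
    table: pd.DataFrame,
    covariate_cols: Sequence[str] = ("age", "sex", "field_T"),
) -> dict[str, GroupComparison]:
    """Per-hemisphere comparisons plus a subject-mean comparison."""
    out = {}
    for hemi in ("left", "right"):
        sub = table[table["hemisphere"] == hemi]
        out[hemi] = group_energy_comparison(sub, covariate_cols=covariate_cols)
    mean_tab = (
        table.groupby("subject_id")
        .agg(
            energy=("energy", "mean"),
            group=("group", "first"),
            age=("age", "first"),
            sex=("sex", "first"),
            field_T=("field_T", "first"),
        )
        .reset_index()
    )
    out["subject_mean"] = group_energy_comparison(mean_tab, covariate_cols=covariate_cols)
    return out


def ipsilateral_group_comparison(
    table: pd.DataFrame,
    covariate_cols: Sequence[str] = ("age", "sex", "field_T", "hemisphere"),
    contralateral: bool = False,
) -> GroupComparison:
    """Patients' lesion-side (or contralateral) central-sulcus energy versus
    controls' central-sulcus energies (both hemispheres), with hemisphere as
    an additional cofactor."""
    is_pat = table["group"] == "patient"
    if contralateral:
        keep_pat = is_pat & (table["hemisphere"] != table["lesion_side"])
    else:
        keep_pat = is_pat & (table["hemisphere"] == table["lesion_side"])
    sub = table[keep_pat | ~is_pat]
    return group_energy_comparison(sub, covariate_cols=covariate_cols)


# ---------------------------------------------------------------------------
# Within-patient permutation test

@dataclass(frozen=True)
class LocalizationRecord:
    """One patient's localization outcome.

    ``n_candidates`` scored central-region sulci on the ipsilateral
    hemisphere, of which ``k_fcd`` are FCD sulci; ``hit`` says whether the
    maximum-z sulcus is one of them.
    """

    subject_id: str
    n_candidates: int
    k_fcd: int
    hit: bool
    mr_status: str = "n/a"

    def __post_init__(self):
        if not 1 <= self.k_fcd <= self.n_candidates:
            raise ValueError(
                f"{self.subject_id}: need 1 <= k_fcd <= n_candidates, "
                f"got k={self.k_fcd}, n={self.n_candidates}"
            )


def records_from_zscore_maps(
    ipsilateral_zmaps: dict[str, ZScoreMap],
    manifest: pd.DataFrame,
) -> list[LocalizationRecord]:
    """Build localization records for patients from their ipsilateral maps.

    Patients whose FCD sulci are all unscored (e.g. mislabeled outside the
    central region) cannot contribute and are dropped.
    """
    records = []
    for _, row in manifest[manifest["group"] == "patient"].iterrows():
        zm = ipsilateral_zmaps.get(row["subject_id"])
        if zm is None:
            continue
        candidates = [lab for lab in zm.z if lab in CENTRAL_REGION_LABELS]
        k = sum(1 for lab in row["fcd_sulci"] if lab in candidates)
        if not candidates or k == 0:
            continue
        best_label, _, _ = max_zscore_sulcus(zm)
        records.append(
            LocalizationRecord(
                subject_id=row["subject_id"],
                n_candidates=len(candidates),
                k_fcd=k,
                hit=best_label in row["fcd_sulci"],
                mr_status=row["mr_status"],
            )
        )
    return records


def records_from_reference_cohort(
    reference: pd.DataFrame,
    observed_hits: int,
    n_candidates: int = 13,
    mr_status: Optional[str] = None,
) -> tuple[list[LocalizationRecord], int]:
    """Records for the published patient table, where only the per-group hit
    totals (not per-patient hits) are printed.

    Individual ``hit`` flags are set arbitrarily to reproduce the printed
    total; the permutation test depends on hits only through their sum.
    Returns (records, observed_hits).
    """
    rows = reference if mr_status is None else reference[reference["mr_status"] == mr_status]
    records = []
    for i, (_, row) in enumerate(rows.iterrows()):
        records.append(
            LocalizationRecord(
                subject_id=str(row["patient_id"]),
                n_candidates=n_candidates,
                k_fcd=int(row["n_fcd_sulci"]),
                hit=i < observed_hits,
                mr_status=row["mr_status"],
            )
        )
    if observed_hits > len(records):
        raise ValueError("observed_hits exceeds number of patients")
    return records, observed_hits


def localization_permutation_test(
    records: Sequence[LocalizationRecord],
    n_perm: int = 10_000,
    seed: int = 0,
    observed_hits: Optional[int] = None,
) -> dict:
    """Within-patient permutation test of the hit count.

    For each patient independently, the FCD indicator is permuted over its
    candidate sulci; since the maximum-z sulcus is fixed, a permuted hit
    occurs with probability ``k_fcd / n_candidates``.  One-sided p-value
    ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if not records:
        raise ValueError("no localization records")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = observed_hits if observed_hits is not None else sum(r.hit for r in records)
    probs = np.array([r.k_fcd / r.n_candidates for r in records])
    rng = np.random.default_rng(seed)
    # sorted probabilities: the statistic only depends on the multiset, and
    # sorting makes the Monte-Carlo p invariant to patient ordering
    perm_hits = (rng.random((n_perm, len(records))) < np.sort(probs)[None, :]).sum(axis=1)
    p = (1 + int(np.sum(perm_hits >= obs))) / (1 + n_perm)
    return {
        "observed_hits": int(obs),
        "n_patients": len(records),
        "n_perm": n_perm,
        "p_value": float(p),
        "hit_probabilities": probs.tolist(),
    }


def poisson_binomial_tail(probs: Sequence[float], m: int) -> float:
    """Exact P(X >= m) for X a sum of independent Bernoulli(p_i).

    Dynamic programming over the count distribution — the exact null of the
    localization permutation test.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    if m <= 0:
        return 1.0
    n = len(probs)
    if m > n:
        return 0.0
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, p in enumerate(probs):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - p) + pmf[: i + 1] * p
        pmf[0] *= 1 - p
    return float(np.sum(pmf[m:]))


def randomized_null_pvalue(probs: Sequence[float], observed: int, u: float) -> float:
    """Uniformized exact p-value P(X > obs) + u * P(X = obs).

    For a discrete test statistic this quantity is exactly U(0,1) under the
    null (u ~ U(0,1)), which is the appropriate target for calibration
    checks of the localization test.
    """
    upper = poisson_binomial_tail(probs, observed + 1)
    point = poisson_binomial_tail(probs, observed) - upper
    return upper + u * point


# ---------------------------------------------------------------------------
# Sulcus-wise ROC

@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def pool_sulcus_scores(
    ipsilateral_zmaps: dict[str, ZScoreMap],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Pool all scored ipsilateral central-region sulci over patients into a
    (subject_id, label, z, is_fcd) table."""
    rows = []
    for _, row in manifest[manifest["group"] == "patient"].iterrows():
        zm = ipsilateral_zmaps.get(row["subject_id"])
        if zm is None:
            continue
        for lab, z in zm.z.items():
            rows.append(
                {
                    "subject_id": row["subject_id"],
                    "label": lab,
                    "z": z,
                    "is_fcd": lab in row["fcd_sulci"],
                    "mr_status": row["mr_status"],
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "label", "z", "is_fcd", "mr_status"])


def roc_curve(
    z_values: Sequence[float],
    is_fcd: Sequence[bool],
    thresholds: Optional[Sequence[float]] = None,
) -> tuple[list[RocPoint], float]:
    """Sulcus-wise ROC of the z-score as an FCD classifier.

    A sulcus is called positive when its z-score is >= the threshold; TP/FN
    count FCD sulci above/below threshold, FP/TN count non-FCD sulci.  AUC
    by trapezoidal integration over (1 - specificity, sensitivity).
    """
    z = np.asarray(z_values, dtype=float)
    y = np.asarray(is_fcd, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one FCD and one non-FCD sulcus")
    if thresholds is None:
        uniq = np.unique(z)
        thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    points = []
    for t in thresholds:
        pos = z >= t
        tp = int(np.sum(pos & y))
        fp = int(np.sum(pos & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        points.append(
            RocPoint(
                threshold=float(t),
                sensitivity=tp / n_pos,
                specificity=tn / n_neg,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
            )
        )
    pts = sorted(points, key=lambda p: (1 - p.specificity, p.sensitivity))
    xs = np.array([1 - p.specificity for p in pts])
    ys = np.array([p.sensitivity for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return points, auc
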