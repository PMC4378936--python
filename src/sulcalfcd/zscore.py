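"""Normative z-score maps of sulcus energy.

Patient sulcus energies are standardized sulcus-by-sulcus against the
control cohort: ``z = (E - mean_controls) / sd_controls``.  Controls only
ever enter the normative statistics; a patient is never normalized against
a cohort containing itself.  The most abnormal sulcus of the hemisphere
ipsilateral to the suspected lesion (maximum z) is the localization call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import EnergyMap
from .nomenclature import CENTRAL_REGION_LABELS

SD_FLOOR = 1e-6


@dataclass
class CohortEnergyStats:
    """Control mean/SD of local energy per (hemisphere, label)."""

    mean: dict[tuple[str, str], float]
    sd: dict[tuple[str, str], float]
    n: dict[tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "hemisphere": h,
                "label": lab,
                "mean_energy": self.mean[(h, lab)],
                "sd_energy": self.sd[(h, lab)],
                "n": self.n[(h, lab)],
            }
            for (h, lab) in sorted(self.mean)
        ]
        return pd.DataFrame(rows, columns=["hemisphere", "label", "mean_energy", "sd_energy", "n"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortEnergyStats":
        mean, sd, n = {}, {}, {}
        for _, r in df.iterrows():
            key = (r["hemisphere"], r["label"])
            mean[key] = float(r["mean_energy"])
            sd[key] = float(r["sd_energy"])
            n[key] = int(r["n"])
        return cls(mean, sd, n)


def cohort_energy_stats(control_maps: Iterable[EnergyMap]) -> CohortEnergyStats:
    """Sample mean and SD (n-1 denominator) of control local energies.

    Only central-region labels are summarized; (hemisphere, label) cells
    with fewer than 2 contributing controls are omitted.
    """
    control_maps = list(control_maps)
    if not control_maps:
        raise ValueError("no control energy maps given")
    values: dict[tuple[str, str], list[float]] = {}
    for m in control_maps:
        for lab, e in m.local.items():
            if lab in CENTRAL_REGION_LABELS:
                values.setdefault((m.hemisphere, lab), []).append(e)
    mean, sd, n = {}, {}, {}
    for key, vals in values.items():
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        mean[key] = float(arr.mean())
        sd[key] = float(arr.std(ddof=1))
        n[key] = len(vals)
    return CohortEnergyStats(mean, sd, n)


@dataclass
class ZScoreMap:
    """Per-sulcus z-scores of one hemisphere against control statistics."""

    subject_id: str
    hemisphere: str
    z: dict[str, float]
    absent_in_subject: list[str] = field(default_factory=list)
    absent_in_stats: list[str] = field(default_factory=list)


def zscore_map(
    patient_map: EnergyMap,
    stats: CohortEnergyStats,
    sd_floor: float = SD_FLOOR,
) -> ZScoreMap:
    """Standardize one subject's energy map sulcus-by-sulcus.

    Labels missing from the subject or from the control statistics are
    flagged rather than scored; the SD is floored to guard degenerate
    (zero-variance) cohorts.
    """
    if not stats.mean:
        raise ValueError("empty control statistics")
    h = patient_map.hemisphere
    z: dict[str, float] = {}
    absent_subject, absent_stats = [], []
    for lab in CENTRAL_REGION_LABELS:
        e = patient_map.local.get(lab)
        key = (h, lab)
        if e is None:
            absent_subject.append(lab)
            continue
        if key not in stats.mean:
            absent_stats.append(lab)
            continue
        z[lab] = (e - stats.mean[key]) / max(stats.sd[key], sd_floor)
    return ZScoreMap(patient_map.subject_id, h, z, absent_subject, absent_stats)


def max_zscore_sulcus(
    zmap: ZScoreMap,
    region_labels: Sequence[str] = CENTRAL_REGION_LABELS,
) -> tuple[str, float, bool]:
    """The most abnormal scored sulcus of the map: (label, z, tie_flag).

    Exact ties are broken alphabetically and flagged.
    """
    scored = {lab: z for lab, z in zmap.z.items() if lab in region_labels}
    if not scored:
        raise ValueError(f"no scored labels in region for subject {zmap.subject_id}")
    zmax = max(scored.values())
    winners = sorted(lab for lab, z in scored.items() if z == zmax)
    return winners[0], zmax, len(winners) > 1


def leave_one_out_zscores(control_maps: Sequence[EnergyMap]) -> pd.DataFrame:
    """Each control standardized against the remaining controls.

    Calibration diagnostic of the normative model: under a well-specified
    model the per-label z-scores have mean ~0 and SD ~1.  Returns a long
    table (subject_id, hemisphere, label, z).
    """
    rows = []
    for i, m in enumerate(control_maps):
        others = [x for j, x in enumerate(control_maps) if j != i]
        stats = cohort_energy_stats(others)
        zm = zscore_map(m, stats)
        rows.extend(
            {"subject_id": m.subject_id, "hemisphere": m.hemisphere, "label": lab, "z": z}
            for lab, z in zm.z.items()
        )
    return pd.DataFrame(rows, columns=["subject_id", "hemisphere", "label", "z"])


def zscore_maps_to_frame(zmaps: Iterable[ZScoreMap]) -> pd.DataFrame:
    rows = []
    for zm in zmaps:
        for lab, z in sorted(zm.z.items()):
            rows.append(
                {
                    "subject_id": zm.subject_id,
                    "hemisphere": zm.hemisphere,
                    "label": lab,
                    "z": z,
                    "flag": "",
                }
            )
        for lab in zm.absent_in_subject:
            rows.append(
                {
                    "subject_id": zm.subject_id,
                    "hemisphere": zm.hemisphere,
                    "label": lab,
                    "z": np.nan,
                    "flag": "absent_in_subject",
                }
            )
        for lab in zm.absent_in_stats:
            rows.append(
                {
                    "subject_id": zm.subject_id,
                    "hemisphere": zm.hemisphere,
                    "label": lab,
                    "z": np.nan,
                    "flag": "absent_in_stats",
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "hemisphere", "label", "z", "flag"])
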