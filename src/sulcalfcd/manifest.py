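"""Cohort manifests: subject metadata and FCD-sulcus annotations.

Two tables live here.  The *cohort manifest* describes a (synthetic or real)
study cohort: one row per subject with group, MR status, demographics,
scanner field strength, lesion side and the list of FCD sulci.  The
*reference cohort* is the published annotation table of 28 right-handed,
surgically evaluated patients with focal cortical dysplasia of the central
region (11 MR-negative, 17 MR-positive), giving for each patient the lesion
side and the expert-adjudicated FCD sulci; it ships with the package and
drives the lesion-localization statistics on printed data.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .nomenclature import CENTRAL_REGION_LABELS, canonical_label

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "mr_status",
    "age",
    "sex",
    "field_T",
    "lesion_side",
    "fcd_sulci",
]


def parse_sulcus_list(cell) -> list[str]:
    """Parse a semicolon-separated FCD-sulcus cell into canonical labels."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [canonical_label(tok) for tok in str(cell).split(";") if tok.strip()]


def format_sulcus_list(labels) -> str:
    return ";".join(labels)


def validate_manifest(df: pd.DataFrame) -> list[str]:
    """Return invariant violations of a cohort manifest (empty = valid)."""
    problems = []
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        return [f"manifest: missing columns {missing}"]
    for _, row in df.iterrows():
        sid = row["subject_id"]
        sulci = row["fcd_sulci"]
        if not isinstance(sulci, list):
            sulci = parse_sulcus_list(sulci)
        if row["group"] == "control":
            if sulci:
                problems.append(f"subject {sid}: control with nonempty fcd_sulci")
            if row["lesion_side"] not in (None, "", "n/a"):
                problems.append(f"subject {sid}: control with lesion_side set")
        elif row["group"] == "patient":
            if not sulci:
                problems.append(f"subject {sid}: patient with empty fcd_sulci")
            if row["lesion_side"] not in ("left", "right"):
                problems.append(f"subject {sid}: patient without lesion_side")
        else:
            problems.append(f"subject {sid}: unknown group {row['group']!r}")
        for lab in sulci:
            if lab not in CENTRAL_REGION_LABELS:
                problems.append(f"subject {sid}: fcd sulcus {lab!r} outside nomenclature")
    return problems


def write_manifest(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["fcd_sulci"] = out["fcd_sulci"].map(
        lambda v: format_sulcus_list(v) if isinstance(v, list) else v
    )
    out.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    # "n/a" is a meaningful level (controls have no MR status / lesion side)
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False, na_values=[])
    df["fcd_sulci"] = df["fcd_sulci"].map(parse_sulcus_list)
    return df


def load_reference_cohort() -> pd.DataFrame:
    """Load the packaged 28-patient FCD-sulcus annotation table.

    Columns: patient_id, mr_status (MR+/MR-), lesion_side, n_fcd_sulci, and
    fcd_sulci parsed into canonical label lists.  The printed per-patient
    counts are checked against the parsed lists at load time.
    """
    ref = importlib.resources.files("sulcalfcd").joinpath("data/fcd_reference_cohort.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["fcd_sulci"] = df["fcd_sulci"].map(parse_sulcus_list)
    bad = df[df["fcd_sulci"].map(len) != df["n_fcd_sulci"]]
    if len(bad):
        raise ValueError(
            f"reference cohort rows with inconsistent counts: {bad['patient_id'].tolist()}"
        )
    return df
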