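"""Readers, writers, packaged cohort fixtures, and the end-to-end report.

Volumes travel as NIfTI (PET as float, anatomy as one integer label
volume with a JSON sidecar giving the label map and the common-iliac
bifurcation plane).  Tables travel as UTF-8 comma CSV with the literal
``NA`` for missing.  The two packaged fixtures are verbatim
transcriptions of the study's printed per-patient tables — the
clinicopathologic table (30 patients, disease sites, imaging interval,
% PSA reduction) and the response table (signed percent change per
compartment and composite plus the signed PSA change) — and are
checksum-verified on load because every real-data result flows from
them.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .correlate import CorrelationResult, correlate_table
from .grid import Lesion, OrganMaskSet, VoxelGrid
from .response import CohortTable, PatientRecord, PCT_COLUMNS, summarize_cohort
from .scoring import CompartmentScores

_DATA = importlib.resources.files("psmascore") / "data"


# --------------------------------------------------------------------------
# NIfTI volumes
# --------------------------------------------------------------------------

def write_pet_nifti(grid: VoxelGrid, path: str | Path) -> None:
    affine = np.diag([*grid.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), str(path))


def read_pet_nifti(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(np.asarray(img.dataobj, dtype=float), spacing)


def mask_labels() -> dict[str, int]:
    """The packaged organ label map for label-volume masks."""
    return json.loads((_DATA / "mask_labels.json").read_text())


def write_masks_nifti(
    masks: OrganMaskSet, grid: VoxelGrid, path: str | Path
) -> None:
    """Write masks as one labeled volume plus a JSON sidecar (<path>.json)."""
    labels = mask_labels()
    affine = np.diag([*grid.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(masks.as_label_volume(labels), affine), str(path))
    sidecar = {"labels": labels, "bifurcation_z_mm": masks.bifurcation_z_mm}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_masks_nifti(path: str | Path) -> OrganMaskSet:
    img = nib.load(str(path))
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return OrganMaskSet.from_label_volume(
        np.asarray(img.dataobj), sidecar["labels"], sidecar["bifurcation_z_mm"]
    )


# --------------------------------------------------------------------------
# Lesion and score tables
# --------------------------------------------------------------------------

def lesions_to_frame(lesions: list[Lesion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lesion_id": [l.lesion_id for l in lesions],
            "compartment": [
                l.compartment.value if l.compartment else "unclassified"
                for l in lesions
            ],
            "volume_ml": [l.volume_ml for l in lesions],
            "suv_mean": [l.suv_mean for l in lesions],
            "suv_max": [l.suv_max for l in lesions],
            "psma_score": [l.psma_score for l in lesions],
            "accepted": [l.accepted for l in lesions],
        }
    )


def write_scores_csv(
    scores: dict[str, CompartmentScores], path: str | Path, timepoint: str = "baseline"
) -> None:
    """One row per patient: prostate_bed, nodal, osseous, composite."""
    rows = []
    for pid, sc in scores.items():
        d = sc.as_dict()
        rows.append({"patient_id": pid, "timepoint": timepoint, **d})
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_scores_csv(path: str | Path) -> dict[str, CompartmentScores]:
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=["NA"], keep_default_na=False,
        float_precision="round_trip")
    out: dict[str, CompartmentScores] = {}
    for _, row in df.iterrows():
        out[row["patient_id"]] = CompartmentScores(
            prostate_bed=None if pd.isna(row["prostate_bed"]) else float(row["prostate_bed"]),
            nodal=None if pd.isna(row["nodal"]) else float(row["nodal"]),
            osseous=None if pd.isna(row["osseous"]) else float(row["osseous"]),
        )
    return out


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Long-format cohort CSV: one row per patient x compartment."""
    rows = []
    for rec in records:
        b, f = rec.baseline.as_dict(), rec.followup.as_dict()
        for comp in ("prostate_bed", "nodal", "osseous"):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "compartment": comp,
                    "score_baseline": b[comp],
                    "score_followup": f[comp],
                    "psa_baseline": rec.psa_baseline,
                    "psa_followup": rec.psa_followup,
                    "interval_months": rec.interval_months,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=["NA"], keep_default_na=False,
        float_precision="round_trip")
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        vals: dict[str, dict[str, float | None]] = {"baseline": {}, "followup": {}}
        for _, row in grp.iterrows():
            comp = row["compartment"]
            for tp, col in (("baseline", "score_baseline"), ("followup", "score_followup")):
                vals[tp][comp] = None if pd.isna(row[col]) else float(row[col])
        first = grp.iloc[0]
        records.append(
            PatientRecord(
                patient_id=pid,
                baseline=CompartmentScores(**vals["baseline"]),
                followup=CompartmentScores(**vals["followup"]),
                psa_baseline=None if pd.isna(first["psa_baseline"]) else float(first["psa_baseline"]),
                psa_followup=None if pd.isna(first["psa_followup"]) else float(first["psa_followup"]),
                interval_months=None
                if pd.isna(first["interval_months"])
                else int(first["interval_months"]),
            )
        )
    return records


def write_cohort_table_csv(table: CohortTable, path: str | Path) -> None:
    cols = ["patient_id", *PCT_COLUMNS, "psa_pct"]
    flags = [c.replace("_pct", "_new") for c in PCT_COLUMNS]
    table.df[cols + flags].to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_cohort_table_csv(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=["NA"], keep_default_na=False,
        float_precision="round_trip")
    return CohortTable(df)


# --------------------------------------------------------------------------
# Packaged fixtures (printed per-patient tables)
# --------------------------------------------------------------------------

def _verified_text(name: str) -> str:
    text = (_DATA / name).read_text()
    checksums = json.loads((_DATA / "checksums.json").read_text())
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != checksums[name]:
        raise ValueError(f"fixture {name} failed checksum verification")
    return text


def load_patient_table() -> pd.DataFrame:
    """The 30-patient clinicopathologic fixture (disease sites, interval, PSA)."""
    from io import StringIO

    df = pd.read_csv(
        StringIO(_verified_text("table1_patients.csv")),
        dtype={"patient_id": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    return df


def load_response_table() -> CohortTable:
    """The per-patient response fixture as a CohortTable.

    Percent cells are the printed (integer-rounded) values; the PSA
    column is the signed change (negative = decline); the imaging
    interval is joined in from the patient table.
    """
    from io import StringIO

    df = pd.read_csv(
        StringIO(_verified_text("table2_response.csv")),
        dtype={"patient_id": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    # The two positive cells (new uptake on a scored baseline) are genuine
    # percent changes, not new disease; flags stay False.
    interval = load_patient_table().set_index("patient_id")["interval_months"]
    df["interval_months"] = df["patient_id"].map(interval)
    return CohortTable(df)


def load_paper_fixtures() -> tuple[pd.DataFrame, CohortTable]:
    """Both packaged fixtures: (patient table, response table)."""
    return load_patient_table(), load_response_table()


def load_printed_statistics() -> dict:
    """Published summary statistics used as expected values in reports."""
    return json.loads((_DATA / "printed_statistics.json").read_text())


# --------------------------------------------------------------------------
# End-to-end reproduction report
# --------------------------------------------------------------------------

def run_reproduction(config: PipelineConfig | None = None) -> dict:
    """Fixtures -> response summaries -> correlations, checked against the
    published summary row.

    Returns a report dict with per-compartment correlations, cohort
    summaries, and an ``ok`` flag that is False if any correlation
    deviates from the published value by more than the stated tolerance
    or a summary median disagrees.
    """
    config = config or PipelineConfig()
    patients, table = load_paper_fixtures()
    results = correlate_table(table)
    summary = summarize_cohort(table)
    printed = load_printed_statistics()

    ok = len(patients) == printed["n_patients"]
    tol = printed["pearson_tolerance"]
    corr_report = {}
    for res in results:
        expected = printed["pearson_row"][res.compartment]
        within = res.r is not None and abs(res.r - expected) <= tol
        ok &= within
        corr_report[res.compartment] = {**res.as_dict(), "published_r": expected, "within_tol": within}
    for comp, med in printed["median_decline_pct"].items():
        got = summary[comp]
        ok &= got is not None and got["median_decline_pct"] == med
    ok &= summary["psa"]["median_decrease_pct"] == printed["median_psa_decrease_pct"]

    n_suppressed_or_flagged = sum(r.suppressed or r.low_variance for r in results)
    return {
        "n_patients": int(len(patients)),
        "correlations": corr_report,
        "summary": summary,
        "n_flagged_correlations": n_suppressed_or_flagged,
        "ok": bool(ok),
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of a run_reproduction report."""
    lines = [f"patients: {report['n_patients']}"]
    lines.append("correlation of % change in PSMA score vs % change in PSA:")
    for comp, c in report["correlations"].items():
        flag = " [low-variance]" if c["low_variance"] else ""
        lines.append(
            f"  {comp:<13} r={c['r']:+.3f} (published {c['published_r']:+.2f})"
            f" n={c['n']} p={c['p_two_tailed']:.2g}{flag}"
        )
    s = report["summary"]
    for comp in ("prostate_bed", "nodal", "osseous", "composite"):
        if s[comp]:
            lo, hi = s[comp]["range_decline_pct"]
            lines.append(
                f"median {comp} decline: {s[comp]['median_decline_pct']:.0f}%"
                f" (range {lo:.0f} to {hi:.0f}, n={s[comp]['n']})"
            )
    lines.append(
        f"median PSA decrease: {s['psa']['median_decrease_pct']:.0f}% (n={s['psa']['n']})"
    )
    lines.append(f"all checks passed: {report['ok']}")
    return "\n".join(lines)
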