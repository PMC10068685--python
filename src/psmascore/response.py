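"""Baseline -> follow-up response: percent changes, N/A and new-disease
conventions, and cohort-level summaries.

Signed percent change is 100 * (after - before) / before, so a decline
is negative; PSA response is carried as the same signed change (a
complete PSA response is -100).  A compartment percent change is
missing when the patient had no baseline disease in that compartment
("N/A" — nothing to score a change against); baseline-zero / follow-up
positive is flagged as *new disease*, which has no defined percent and
never contributes to percent-change statistics.  A compartment scored
at baseline but absent at follow-up resolved completely: its follow-up
score is 0 and the change is -100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import CompartmentScores

#: CohortTable percent-change columns, paired with the pooled compartment name.
PCT_COLUMNS = {
    "nodal_pct": "nodal",
    "osseous_pct": "osseous",
    "prostate_pct": "prostate_bed",
    "composite_pct": "composite",
}


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 * (after - before) / before; requires before > 0."""
    if before <= 0:
        raise ValueError(f"percent_change requires before > 0, got {before}")
    return 100.0 * (after - before) / before


def psa_percent_decrease(psa0: float, psa1: float) -> float:
    """Percent *decrease* in PSA, 100 * (psa0 - psa1) / psa0; requires psa0 > 0."""
    if psa0 <= 0:
        raise ValueError(f"baseline PSA must be positive, got {psa0}")
    return 100.0 * (psa0 - psa1) / psa0


@dataclass(frozen=True)
class ChangeOutcome:
    """Result of comparing one compartment across timepoints."""

    value: float | None = None
    new_disease: bool = False

    @property
    def missing(self) -> bool:
        return self.value is None and not self.new_disease


def change_outcome(before: float | None, after: float | None) -> ChangeOutcome:
    """Percent-change outcome under the N/A / new-disease conventions.

    - baseline missing or zero, follow-up absent or zero  -> missing
    - baseline missing or zero, follow-up positive        -> new disease
    - baseline positive                                   -> signed percent
      (a missing follow-up compartment counts as 0: disease resolved)
    """
    b = 0.0 if before is None else before
    a = 0.0 if after is None else after
    if b <= 0:
        return ChangeOutcome(new_disease=True) if a > 0 else ChangeOutcome()
    return ChangeOutcome(value=percent_change(b, a))


@dataclass
class PatientRecord:
    """One patient's paired scans: scores at both timepoints plus PSA."""

    patient_id: str
    baseline: CompartmentScores
    followup: CompartmentScores
    psa_baseline: float | None = None
    psa_followup: float | None = None
    psa_pct_decrease: float | None = None
    interval_months: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psa_baseline is not None and self.psa_followup is not None:
            derived = psa_percent_decrease(self.psa_baseline, self.psa_followup)
            if self.psa_pct_decrease is None:
                self.psa_pct_decrease = derived
            elif abs(self.psa_pct_decrease - derived) > 0.5:
                raise ValueError(
                    f"patient {self.patient_id}: stated PSA decrease "
                    f"{self.psa_pct_decrease} inconsistent with values ({derived:.1f})"
                )

    @property
    def psa_pct_change(self) -> float | None:
        """Signed PSA change (negative = decline), or None if unknown."""
        if self.psa_pct_decrease is None:
            return None
        return -self.psa_pct_decrease


@dataclass
class CohortTable:
    """Per-patient signed percent changes, one row per patient.

    ``df`` columns: patient_id, nodal_pct, osseous_pct, prostate_pct,
    composite_pct, psa_pct (all signed; NaN = missing), the matching
    ``*_new`` new-disease flags, and interval_months when known.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("patient_id", "psa_pct", *PCT_COLUMNS) if c not in self.df]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        for col in PCT_COLUMNS:
            flag = col.replace("_pct", "_new")
            if flag not in self.df:
                self.df[flag] = False

    def __len__(self) -> int:
        return len(self.df)

    def column_pairs(self, col: str) -> pd.DataFrame:
        """Pairwise-complete (col, psa_pct) rows, excluding new-disease rows."""
        flag = col.replace("_pct", "_new")
        keep = self.df[col].notna() & self.df["psa_pct"].notna() & ~self.df[flag]
        return self.df.loc[keep, [col, "psa_pct"]]


def build_cohort_table(records: list[PatientRecord]) -> CohortTable:
    """Assemble the per-patient response table from paired-scan records."""
    if not records:
        raise ValueError("need at least one patient record")
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id}
        before = rec.baseline.as_dict()
        after = rec.followup.as_dict()
        for col, comp in PCT_COLUMNS.items():
            out = change_outcome(before[comp], after[comp])
            row[col] = np.nan if out.value is None else out.value
            row[col.replace("_pct", "_new")] = out.new_disease
        psa = rec.psa_pct_change
        row["psa_pct"] = np.nan if psa is None else psa
        row["interval_months"] = (
            np.nan if rec.interval_months is None else rec.interval_months
        )
        rows.append(row)
    return CohortTable(pd.DataFrame(rows))


def summarize_cohort(table: CohortTable) -> dict:
    """Median and range of declines per compartment, PSA, and interval.

    Declines are the negated signed changes, so a median decline of 100
    means the typical patient's score dropped to zero.  New-disease rows
    are excluded; an all-missing column yields ``None`` entries.
    """
    out: dict = {}
    for col, comp in PCT_COLUMNS.items():
        flag = col.replace("_pct", "_new")
        vals = table.df.loc[~table.df[flag], col].dropna()
        decl = -vals
        out[comp] = (
            {
                "median_decline_pct": float(decl.median()),
                "range_decline_pct": (float(decl.min()), float(decl.max())),
                "n": int(len(decl)),
            }
            if len(decl)
            else None
        )
    psa = -table.df["psa_pct"].dropna()
    out["psa"] = (
        {
            "median_decrease_pct": float(psa.median()),
            "range_decrease_pct": (float(psa.min()), float(psa.max())),
            "n": int(len(psa)),
        }
        if len(psa)
        else None
    )
    if "interval_months" in table.df:
        iv = table.df["interval_months"].dropna()
        out["median_interval_months"] = float(iv.median()) if len(iv) else None
    return out
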