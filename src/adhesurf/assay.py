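"""Adhesion-assay condition bookkeeping, tables and treatment contrasts.

An assay condition is the factorial key material x strain x pH x ionic
strength x treatment (optionally with suspension OD and settling time as
metadata).  Records pair a condition with a replicate coverage summary;
operations assemble wide condition tables, compute before/after protease
contrasts, and inspect coverage as a function of ionic strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import ReplicateSummary

__all__ = [
    "AssayCondition",
    "AdhesionRecord",
    "TreatmentContrast",
    "assemble_table",
    "treatment_contrast",
    "ionic_strength_profile",
    "records_to_frame",
    "records_from_frame",
]

FACTORS = ("material", "strain", "pH", "ionic_strength", "treatment")


@dataclass(frozen=True)
class AssayCondition:
    """One cell of the assay factorial."""

    material: str
    strain: str
    pH: float
    ionic_strength: float  # molar
    treatment: str = "none"  # "none" | "pronase"
    od570: float = 0.70
    settle_hours: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH {self.pH} outside [0, 14]")
        if self.ionic_strength <= 0:
            raise ValueError("ionic_strength must be > 0 (molar)")
        if self.treatment not in ("none", "pronase"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    def key(self) -> tuple:
        return (self.material, self.strain, self.pH, self.ionic_strength, self.treatment)


@dataclass(frozen=True)
class AdhesionRecord:
    condition: AssayCondition
    summary: ReplicateSummary


@dataclass(frozen=True)
class TreatmentContrast:
    """After-minus-before coverage contrast for a protease treatment."""

    difference: float
    pooled_sd: float
    ratio: float
    strong_reduction: bool


def _factor_value(record: AdhesionRecord, factor: str):
    return getattr(record.condition, factor)


def assemble_table(
    records: list[AdhesionRecord], rows: str, columns: str | list[str]
) -> pd.DataFrame:
    """Pivot records into a wide mean-coverage table.

    ``rows`` and ``columns`` name assay factors; ``columns`` may be a list,
    producing a hierarchical column index (e.g. material x strain).  Cells
    absent from the records are NaN.  Duplicate conditions are rejected.
    """
    if not records:
        raise ValueError("no records")
    col_factors = [columns] if isinstance(columns, str) else list(columns)
    for f in [rows, *col_factors]:
        if f not in FACTORS:
            raise ValueError(f"{f!r} is not an assay factor {FACTORS}")

    keys = [r.condition.key() for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate conditions: {dupes}")

    df = pd.DataFrame(
        {
            "row": [_factor_value(r, rows) for r in records],
            **{
                f: [_factor_value(r, f) for r in records] for f in col_factors
            },
            "mean_coverage": [r.summary.mean_coverage for r in records],
        }
    )
    table = df.pivot_table(
        index="row", columns=col_factors, values="mean_coverage", aggfunc="first"
    )
    table.index.name = rows
    return table


def treatment_contrast(
    before: AdhesionRecord, after: AdhesionRecord
) -> TreatmentContrast:
    """Contrast coverage after vs before a treatment on one condition.

    The difference is after-minus-before; the pooled sd is the
    root-sum-of-squares of the two replicate sds; the contrast is flagged a
    strong reduction when the drop exceeds twice the pooled sd.
    """
    kb = before.condition.key()[:-1]
    ka = after.condition.key()[:-1]
    if kb != ka:
        raise ValueError(
            f"records differ in non-treatment factors: {kb} vs {ka}"
        )
    diff = after.summary.mean_coverage - before.summary.mean_coverage
    pooled = float(np.hypot(before.summary.sd_coverage, after.summary.sd_coverage))
    if before.summary.mean_coverage == 0:
        raise ValueError("before-treatment coverage is zero; ratio undefined")
    ratio = after.summary.mean_coverage / before.summary.mean_coverage
    strong = diff < 0 and abs(diff) > 2.0 * pooled
    return TreatmentContrast(
        difference=diff, pooled_sd=pooled, ratio=ratio, strong_reduction=strong
    )


def ionic_strength_profile(
    records: list[AdhesionRecord],
) -> tuple[list[tuple[float, float]], bool]:
    """Coverage vs ionic strength for one material/strain/pH/treatment.

    Returns the series sorted by ascending ionic strength and a flag that
    is True when coverage at the highest strength falls below the mean of
    the remaining strengths — the screening-driven adhesion drop seen at
    0.1 M.
    """
    if len(records) < 2:
        raise ValueError("need records at >= 2 ionic strengths")
    other = {
        (r.condition.material, r.condition.strain, r.condition.pH, r.condition.treatment)
        for r in records
    }
    if len(other) != 1:
        raise ValueError(f"records differ in non-strength factors: {sorted(other)}")
    series = sorted(
        (r.condition.ionic_strength, r.summary.mean_coverage) for r in records
    )
    top = series[-1][1]
    rest = [c for _, c in series[:-1]]
    drop = top < float(np.mean(rest))
    return series, drop


def records_to_frame(records: list[AdhesionRecord]) -> pd.DataFrame:
    """Long-format DataFrame with one row per record (lossless CSV dialect)."""
    return pd.DataFrame(
        {
            "material": [r.condition.material for r in records],
            "strain": [r.condition.strain for r in records],
            "pH": [r.condition.pH for r in records],
            "ionic_strength": [r.condition.ionic_strength for r in records],
            "treatment": [r.condition.treatment for r in records],
            "mean_coverage": [r.summary.mean_coverage for r in records],
            "sd_coverage": [r.summary.sd_coverage for r in records],
            "n_images": [r.summary.n_images for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[AdhesionRecord]:
    """Inverse of :func:`records_to_frame`; NaN sd ingests as sd-unknown (0)."""
    out = []
    for _, row in df.iterrows():
        sd = row.get("sd_coverage", np.nan)
        n = int(row.get("n_images", 1))
        out.append(
            AdhesionRecord(
                condition=AssayCondition(
                    material=str(row["material"]),
                    strain=str(row["strain"]),
                    pH=float(row["pH"]),
                    ionic_strength=float(row["ionic_strength"]),
                    treatment=str(row["treatment"]),
                ),
                summary=ReplicateSummary(
                    mean_coverage=float(row["mean_coverage"]),
                    sd_coverage=0.0 if pd.isna(sd) else float(sd),
                    n_images=n,
                    condition_id="|".join(
                        str(row[f]) for f in FACTORS
                    ),
                    single_image=(n == 1),
                ),
            )
        )
    return out
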