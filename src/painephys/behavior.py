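"""Behavioral table ingestion and screening.

The behavioral battery per animal comprises three depression-like assays --
splash-test grooming (5 min session), tail-suspension immobility and
forced-swim immobility (6 min sessions each) -- plus electronic von Frey
mechanical sensitivity, six paw-withdrawal threshold (PWT) measures per paw
per timepoint.  Screening applies the von Frey inclusion rule: an unpaired
t-test of ipsilateral vs contralateral thresholds; nerve-injured (SNI)
animals must show a significant ipsilateral deficit, sham animals must not
differ between paws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SPLASH_MAX_S",
    "IMMOBILITY_MAX_S",
    "SURGERIES",
    "HOUSINGS",
    "AnimalRecord",
    "summarize_pwt",
    "vonfrey_inclusion",
    "load_behavior_table",
    "records_from_frame",
    "screen_behavior",
]

SPLASH_MAX_S = 300.0      #: splash test session length (5 min)
IMMOBILITY_MAX_S = 360.0  #: TST / FST session length (6 min)
SURGERIES = ("SNI", "sham")
HOUSINGS = ("SH", "EEE", "ExEE")

PWT_COLS_IPSI = [f"pwt_ipsi_{i}_g" for i in range(1, 7)]
PWT_COLS_CONTRA = [f"pwt_contra_{i}_g" for i in range(1, 7)]
REQUIRED_COLUMNS = (
    ["animal_id", "surgery", "housing", "splash_s", "tst_s", "fst_s"]
    + PWT_COLS_IPSI
    + PWT_COLS_CONTRA
    + ["timepoint_day"]
)


@dataclass
class AnimalRecord:
    """One animal at one timepoint: group labels, assay scores, PWT measures."""

    animal_id: str
    surgery: str
    housing: str
    splash_s: Optional[float]
    tst_s: Optional[float]
    fst_s: Optional[float]
    pwt_ipsi_g: tuple[float, ...]
    pwt_contra_g: tuple[float, ...]
    timepoint_day: float
    included: Optional[bool] = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.surgery not in SURGERIES:
            raise ValueError(f"unknown surgery label {self.surgery!r}")
        if self.housing not in HOUSINGS:
            raise ValueError(f"unknown housing label {self.housing!r}")
        for name, val, cap in (
            ("splash_s", self.splash_s, SPLASH_MAX_S),
            ("tst_s", self.tst_s, IMMOBILITY_MAX_S),
            ("fst_s", self.fst_s, IMMOBILITY_MAX_S),
        ):
            if val is not None and not (0.0 <= val <= cap):
                raise ValueError(
                    f"{self.animal_id}: {name}={val} outside [0, {cap}] s"
                )
        for name, paw in (("ipsi", self.pwt_ipsi_g), ("contra", self.pwt_contra_g)):
            if len(paw) != 6:
                raise ValueError(
                    f"{self.animal_id}: expected 6 {name} PWT measures, got {len(paw)}"
                )
            if any((not np.isfinite(x)) or x <= 0 for x in paw):
                raise ValueError(f"{self.animal_id}: non-positive {name} PWT measure")

    @property
    def group(self) -> str:
        return f"{self.surgery}-{self.housing}"


def summarize_pwt(measures: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (g) of the six PWT measures of one paw."""
    x = np.asarray(measures, dtype=float)
    if x.size != 6:
        raise ValueError(f"expected exactly 6 PWT measures, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("PWT measures must be finite and positive")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def vonfrey_inclusion(
    animal: AnimalRecord, alpha: float = 0.05, equal_var: bool = False
) -> tuple[bool, str]:
    """Von Frey inclusion decision for one animal (Welch t-test by default).

    Two-sided unpaired t-test, ipsilateral vs contralateral thresholds.  An
    SNI animal is included iff p < alpha AND the ipsilateral mean is below the
    contralateral mean (injury must hurt on the operated side); a sham animal
    is included iff p >= alpha (surgery alone must not change sensitivity).
    Zero variance in both paws with equal means counts as "no difference".
    """
    ipsi = np.asarray(animal.pwt_ipsi_g, dtype=float)
    contra = np.asarray(animal.pwt_contra_g, dtype=float)
    mean_i, mean_c = float(np.mean(ipsi)), float(np.mean(contra))
    if np.var(ipsi, ddof=1) == 0 and np.var(contra, ddof=1) == 0:
        p = 1.0 if mean_i == mean_c else 0.0
    else:
        p = float(sps.ttest_ind(ipsi, contra, equal_var=equal_var).pvalue)
    if animal.surgery == "SNI":
        included = bool(p < alpha and mean_i < mean_c)
        why = (
            f"SNI: ipsi {mean_i:.2f} g vs contra {mean_c:.2f} g, p={p:.4g}; "
            + ("significant ipsilateral deficit" if included else "no ipsilateral deficit")
        )
    else:
        included = bool(p >= alpha)
        why = (
            f"sham: ipsi {mean_i:.2f} g vs contra {mean_c:.2f} g, p={p:.4g}; "
            + ("paws indistinguishable" if included else "unexpected paw asymmetry")
        )
    return included, why


def _row_to_record(row: pd.Series, row_no: int) -> AnimalRecord:
    def _opt(col: str) -> Optional[float]:
        v = row[col]
        return None if pd.isna(v) else float(v)

    try:
        return AnimalRecord(
            animal_id=str(row["animal_id"]),
            surgery=str(row["surgery"]),
            housing=str(row["housing"]),
            splash_s=_opt("splash_s"),
            tst_s=_opt("tst_s"),
            fst_s=_opt("fst_s"),
            pwt_ipsi_g=tuple(float(row[c]) for c in PWT_COLS_IPSI),
            pwt_contra_g=tuple(float(row[c]) for c in PWT_COLS_CONTRA),
            timepoint_day=float(row["timepoint_day"]),
        )
    except (ValueError, TypeError) as err:
        raise ValueError(f"row {row_no}: {err}") from None


def records_from_frame(df: pd.DataFrame) -> list[AnimalRecord]:
    """Validate a behavior table and convert it to :class:`AnimalRecord` objects.

    All schema violations are collected and reported together with their row
    numbers (2-based, counting the header as row 1, as in the CSV file).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table is missing columns: {missing}")
    records: list[AnimalRecord] = []
    errors: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_row_to_record(row, pos + 2))
        except ValueError as err:
            errors.append(str(err))
    if errors:
        raise ValueError("invalid behavior table:\n  " + "\n  ".join(errors))
    return records


def load_behavior_table(path) -> list[AnimalRecord]:
    """Read and validate a behavior CSV (schema documented in the cohort writer)."""
    return records_from_frame(pd.read_csv(path))


def screen_behavior(
    df: pd.DataFrame, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Append ``included``/``reason`` columns from the von Frey criterion.

    The decision is made per row (animal x timepoint); callers wanting a
    per-animal verdict typically use the last timepoint.
    """
    records = records_from_frame(df)
    out = df.copy()
    decisions = [vonfrey_inclusion(r, alpha=alpha, equal_var=equal_var) for r in records]
    out["included"] = [d[0] for d in decisions]
    out["reason"] = [d[1] for d in decisions]
    return out
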