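"""Limb volumetry: the lower-extremity lymphedema index (LELI) and its change.

The LELI normalizes a circumference-based volume surrogate for body size:

    LELI = (sum of c_i^2 for the five predefined sites) / BMI

with circumferences in cm at (1) the superior edge of the patella,
(2) 10 cm above and (3) 10 cm below the patella, (4) the lateral
malleolus and (5) the dorsum of the foot, and BMI in kg/m^2.

Postoperative outcome is the percentage change from baseline,

    %dLELI = 100 * (LELI_pre - LELI_post) / LELI_pre,

so a positive value is a volume *reduction*.  Disease burden before
surgery is summarized as the affected-minus-contralateral LELI excess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .scoring import ValidationError

__all__ = [
    "SITE_NAMES",
    "TIMEPOINTS",
    "CircumferenceSet",
    "VolumeSeries",
    "leli",
    "pct_delta_leli",
    "excess",
    "volumetry_from_csv",
    "volumetry_to_csv",
]

SITE_NAMES = (
    "patella_superior_edge",
    "10cm_above_patella",
    "10cm_below_patella",
    "lateral_malleolus",
    "foot_dorsum",
)

TIMEPOINTS = ("pre", "1m", "3m", "6m")


@dataclass(frozen=True)
class CircumferenceSet:
    """Five-site limb circumference measurement (cm) with the patient's BMI."""

    circumferences: tuple  # 5 floats, cm, ordered as SITE_NAMES
    bmi: float             # kg/m^2

    def __post_init__(self):
        c = tuple(float(x) for x in self.circumferences)
        if len(c) != 5:
            raise ValidationError(f"expected 5 circumferences, got {len(c)}")
        if any(x <= 0 for x in c):
            raise ValidationError(f"circumferences must be positive, got {c}")
        if not self.bmi > 0:
            raise ValidationError(f"bmi must be positive, got {self.bmi}")
        object.__setattr__(self, "circumferences", c)


@dataclass(frozen=True)
class VolumeSeries:
    """LELI of one limb at baseline and (optionally) 1/3/6 months post-op."""

    leli_pre: float
    leli_1m: Optional[float] = None
    leli_3m: Optional[float] = None
    leli_6m: Optional[float] = None

    def __post_init__(self):
        for name in ("leli_pre", "leli_1m", "leli_3m", "leli_6m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")

    def at(self, timepoint: str) -> Optional[float]:
        return {"pre": self.leli_pre, "1m": self.leli_1m, "3m": self.leli_3m, "6m": self.leli_6m}[timepoint]

    def pct_delta(self, timepoint: str) -> Optional[float]:
        """%dLELI at a post-op timepoint, or None if that visit is missing."""
        post = self.at(timepoint)
        return None if post is None else pct_delta_leli(self.leli_pre, post)


def leli(c: CircumferenceSet) -> float:
    """Lower-extremity lymphedema index: sum of squared circumferences over BMI."""
    return sum(x * x for x in c.circumferences) / c.bmi


def pct_delta_leli(pre: float, post: float) -> float:
    """Percentage LELI change from baseline; positive means volume reduction."""
    if not pre > 0:
        raise ValidationError(f"baseline LELI must be positive, got {pre}")
    if not post > 0:
        raise ValidationError(f"post-op LELI must be positive, got {post}")
    return 100.0 * (pre - post) / pre


def excess(affected: float, contralateral: float) -> float:
    """Affected-minus-contralateral LELI difference (pre-op volume excess)."""
    if not (affected > 0 and contralateral > 0):
        raise ValidationError("LELI values must be positive")
    return affected - contralateral


# ---------------------------------------------------------------------------
# CSV I/O — schema: patient_id, side, timepoint, c1..c5, bmi
# ---------------------------------------------------------------------------

VOLUMETRY_COLUMNS = ["patient_id", "side", "timepoint", "c1", "c2", "c3", "c4", "c5", "bmi"]


def volumetry_from_csv(path) -> dict:
    """Load volumetry.csv into {(patient_id, side, timepoint): CircumferenceSet}."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in VOLUMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"volumetry file {path} is missing columns {missing}")
    out: dict = {}
    for idx, row in df.iterrows():
        if row["timepoint"] not in TIMEPOINTS:
            raise ValidationError(
                f"volumetry row {idx}: timepoint must be one of {TIMEPOINTS}, got {row['timepoint']!r}"
            )
        key = (row["patient_id"], row["side"], row["timepoint"])
        if key in out:
            raise ValidationError(f"volumetry row {idx}: duplicate (patient, side, timepoint) {key}")
        try:
            out[key] = CircumferenceSet(
                circumferences=tuple(float(row[f"c{i}"]) for i in range(1, 6)),
                bmi=float(row["bmi"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"volumetry row {idx} (patient {row['patient_id']}): {exc}") from exc
    return out


def volumetry_to_csv(measurements: dict, path) -> None:
    """Write {(patient_id, side, timepoint): CircumferenceSet} as volumetry.csv."""
    rows = []
    for (pid, side, tp), cs in measurements.items():
        row = {"patient_id": pid, "side": side, "timepoint": tp, "bmi": cs.bmi}
        for i, c in enumerate(cs.circumferences, start=1):
            row[f"c{i}"] = c
        rows.append(row)
    pd.DataFrame(rows, columns=VOLUMETRY_COLUMNS).to_csv(path, index=False)
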