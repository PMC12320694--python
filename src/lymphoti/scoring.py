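"""Transport-index (TI) scoring of qualitative lymphoscintigraphy reads.

A lymphoscintigraphy study is read as five ordinal components, each graded
on the scale {0, 3, 5, 9} (higher = worse):

* ``K`` — lymphatic transport kinetics (no delay / mild / marked / missing),
* ``D`` — dermal backflow pattern (normal / partial / diffuse / transport stop),
* ``N`` — visualization of the ilio-inguinal lymph nodes,
* ``V`` — visualization of the main lymphatic vessel,

plus the time ``T`` (minutes) at which the ilio-inguinal nodes first appear
on the serial images, and a binary collateral-flow flag ``C``.  The
composite severity score is

    TI = K + D + 0.04*T + N + V

where the time term is 9 when the nodes are never visualized, and is capped
at 9 so that the achievable range is exactly [0.6, 45].  The collateral
flag does not enter the sum.

The full acquisition protocol images at 15, 30, 60, 120, 180 and 240 min
(``TI_240``).  A shortened two-hour read (``TI_120``) uses only the 15-,
60- and 120-min images; :func:`censor_read` restricts a full read to such a
frame subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "NOT_VISUALIZED",
    "ORDINAL_SCORES",
    "DEFAULT_FRAMES",
    "TI120_FRAMES",
    "ValidationError",
    "QualitativeRead",
    "TransportIndex",
    "BinaryProfile",
    "time_term",
    "transport_index",
    "censor_read",
    "binarize",
    "enumerate_reads",
    "reads_from_csv",
    "reads_to_csv",
]


class ValidationError(ValueError):
    """An input violates a domain invariant (bad score, inconsistent read...)."""


class _NotVisualized:
    """Sentinel for 'lymph nodes never appeared on any image'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_VISUALIZED"


#: Node-appearance sentinel. Compare with ``is``.
NOT_VISUALIZED = _NotVisualized()

#: The four ordinal grades shared by K, D, N and V.
ORDINAL_SCORES = (0, 3, 5, 9)

#: Acquisition times (min) of the full imaging protocol.
DEFAULT_FRAMES = (15, 30, 60, 120, 180, 240)

#: Frames retained for the shortened two-hour read.
TI120_FRAMES = (15, 60, 120)

#: Time-term score assigned when nodes are never seen; also the cap on 0.04*T.
_NO_VISUALIZATION_TIME_SCORE = 9.0

# Label <-> score maps for CSV / report I/O (scores are stored as integers).
KINETICS_LABELS = {0: "no_delay", 3: "mild_delay", 5: "marked_delay", 9: "missing_transport"}
DBF_LABELS = {0: "normal", 3: "partial", 5: "diffuse", 9: "transport_stop"}
VISIBILITY_LABELS = {0: "clearly_visible", 3: "mildly_visible", 5: "hardly_visible", 9: "not_visualized"}


def _check_ordinal(value, name: str) -> int:
    if value not in ORDINAL_SCORES:
        raise ValidationError(f"{name} must be one of {ORDINAL_SCORES}, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class QualitativeRead:
    """One limb's ordinal lymphoscintigraphy assessment.

    Parameters
    ----------
    kinetics_score, dbf_score, node_score, vessel_score : int
        Ordinal grades in {0, 3, 5, 9}.
    node_time : int or NOT_VISUALIZED
        Minutes to first appearance of the ilio-inguinal nodes; must be a
        member of ``frame_set``.  ``NOT_VISUALIZED`` if and only if
        ``node_score == 9`` (a node that is never seen cannot be graded
        visible, and vice versa).
    collateral : bool
        Collateral lymphatic flow seen anywhere on the study.
    frame_set : tuple of int
        Ordered acquisition times at which images exist.
    """

    kinetics_score: int
    dbf_score: int
    node_time: object
    node_score: int
    vessel_score: int
    collateral: bool = False
    frame_set: tuple = DEFAULT_FRAMES

    def __post_init__(self):
        _check_ordinal(self.kinetics_score, "kinetics_score (K)")
        _check_ordinal(self.dbf_score, "dbf_score (D)")
        _check_ordinal(self.node_score, "node_score (N)")
        _check_ordinal(self.vessel_score, "vessel_score (V)")
        frames = tuple(sorted(int(f) for f in self.frame_set))
        if not frames or any(f <= 0 for f in frames):
            raise ValidationError(f"frame_set must be positive minutes, got {self.frame_set!r}")
        object.__setattr__(self, "frame_set", frames)
        t = self.node_time
        if t is NOT_VISUALIZED:
            if self.node_score != 9:
                raise ValidationError(
                    "node_time NOT_VISUALIZED requires node_score 9 "
                    f"(got N={self.node_score}); nodes that never appear cannot be visible"
                )
        else:
            try:
                t = int(t)
            except (TypeError, ValueError):
                raise ValidationError(f"node_time must be minutes or NOT_VISUALIZED, got {t!r}") from None
            if t not in frames:
                raise ValidationError(f"node_time {t} min is not an acquired frame {frames}")
            if self.node_score == 9:
                raise ValidationError(
                    f"node_score 9 (not visualized) is inconsistent with node_time {t} min"
                )
            object.__setattr__(self, "node_time", t)

    @property
    def nodes_visualized(self) -> bool:
        return self.node_time is not NOT_VISUALIZED


@dataclass(frozen=True)
class TransportIndex:
    """A computed TI value together with its imaging window (120 or 240 min)."""

    value: float
    window_minutes: int

    def __post_init__(self):
        if not 0.6 <= self.value <= 45.0:
            raise ValidationError(f"TI {self.value} outside the achievable range [0.6, 45]")
        if self.window_minutes not in (120, 240):
            raise ValidationError(f"window_minutes must be 120 or 240, got {self.window_minutes}")


@dataclass(frozen=True)
class BinaryProfile:
    """Dichotomized read: the six binary criteria used for group comparisons."""

    kinetics_delayed: bool        # marked delay or missing transport (K in {5, 9})
    dbf_present: bool             # any dermal backflow or transport stop (D > 0)
    node_time_late: bool          # first node appearance after 60 min, or never
    nodes_not_visualized: bool    # N == 9
    vessel_not_visualized: bool   # V == 9
    collateral_present: bool

    def as_dict(self) -> dict:
        return {
            "kinetics_delayed": self.kinetics_delayed,
            "dbf_present": self.dbf_present,
            "node_time_late": self.node_time_late,
            "nodes_not_visualized": self.nodes_not_visualized,
            "vessel_not_visualized": self.vessel_not_visualized,
            "collateral_present": self.collateral_present,
        }


def time_term(node_time, frame_set: Iterable[int] = DEFAULT_FRAMES) -> float:
    """Time component of the TI: 0.04 x minutes, capped at 9; 9 if never seen.

    The cap keeps the latest frame (240 min, nominally 9.6) from exceeding
    the no-visualization score, so the TI maximum is exactly 45.
    """
    if node_time is NOT_VISUALIZED:
        return _NO_VISUALIZATION_TIME_SCORE
    t = int(node_time)
    if t <= 0:
        raise ValidationError(f"node_time must be positive minutes, got {node_time!r}")
    if t not in tuple(frame_set):
        raise ValidationError(f"node_time {t} min is not an acquired frame {tuple(frame_set)}")
    # t*4/100 rather than t*0.04: exact decimals for the tabulated frames.
    return min(t * 4.0 / 100.0, _NO_VISUALIZATION_TIME_SCORE)


def transport_index(read: QualitativeRead, window_minutes: int = 240) -> TransportIndex:
    """Compute TI = K + D + 0.04*T + N + V for a read.

    ``window_minutes=240`` scores the read as acquired.  ``window_minutes=120``
    first censors the read to the 15/60/120-min frames (see
    :func:`censor_read`); a read already restricted to those frames is
    unchanged by the censoring, so passing either a full or a pre-censored
    read is valid.  The collateral flag never enters the sum.
    """
    if window_minutes == 240:
        r = read
    elif window_minutes == 120:
        r = censor_read(read, TI120_FRAMES)
    else:
        raise ValidationError(f"window_minutes must be 120 or 240, got {window_minutes}")
    value = (
        r.kinetics_score
        + r.dbf_score
        + time_term(r.node_time, r.frame_set)
        + r.node_score
        + r.vessel_score
    )
    return TransportIndex(value=value, window_minutes=window_minutes)


def censor_read(read: QualitativeRead, retained_frames: Iterable[int] = TI120_FRAMES) -> QualitativeRead:
    """Restrict a read to a subset of imaging frames.

    Only the node-appearance information is re-derived; the kinetics, dermal
    backflow and vessel grades are carried over unchanged (the weakest
    assumption about what a reader of the shortened study would conclude):

    * a node time on a retained frame is unchanged;
    * a node time on an omitted frame that is still within the shortened
      window is snapped forward to the next retained frame (the first image
      on which the shortened study shows the nodes);
    * a node first seen after the last retained frame — or never —
      becomes NOT_VISUALIZED with node score 9.
    """
    retained = tuple(sorted(int(f) for f in retained_frames))
    if not retained:
        raise ValidationError("retained_frames must not be empty")
    if not set(retained) <= set(read.frame_set):
        raise ValidationError(
            f"retained frames {retained} are not a subset of the acquired frames {read.frame_set}"
        )
    t = read.node_time
    if t is NOT_VISUALIZED or t > retained[-1]:
        new_time, new_score = NOT_VISUALIZED, 9
    elif t in retained:
        new_time, new_score = t, read.node_score
    else:
        new_time = min(f for f in retained if f > t)
        new_score = read.node_score
    return replace(read, node_time=new_time, node_score=new_score, frame_set=retained)


def binarize(read: QualitativeRead) -> BinaryProfile:
    """Dichotomize a read into the six binary assessment criteria."""
    return BinaryProfile(
        kinetics_delayed=read.kinetics_score in (5, 9),
        dbf_present=read.dbf_score in (3, 5, 9),
        node_time_late=(read.node_time is NOT_VISUALIZED) or read.node_time > 60,
        nodes_not_visualized=read.node_score == 9,
        vessel_not_visualized=read.vessel_score == 9,
        collateral_present=bool(read.collateral),
    )


def enumerate_reads(
    frame_set: Iterable[int] = DEFAULT_FRAMES, collateral: bool = False
) -> Iterator[QualitativeRead]:
    """Yield every valid read over ``frame_set``.

    K, D, V range over {0,3,5,9}; the (node_time, N) pair ranges over the
    valid combinations: every acquired frame paired with N in {0,3,5}, plus
    the single NOT_VISUALIZED/N=9 state.  With the default six frames this
    is 4^3 x (6*3 + 1) = 1216 reads.
    """
    frames = tuple(sorted(int(f) for f in frame_set))
    node_states = [(t, n) for t in frames for n in (0, 3, 5)]
    node_states.append((NOT_VISUALIZED, 9))
    for k, d, v in itertools.product(ORDINAL_SCORES, repeat=3):
        for t, n in node_states:
            yield QualitativeRead(
                kinetics_score=k,
                dbf_score=d,
                node_time=t,
                node_score=n,
                vessel_score=v,
                collateral=collateral,
                frame_set=frames,
            )


# ---------------------------------------------------------------------------
# CSV I/O — schema: patient_id, side, K, D, node_time_min, N, V, collateral
# ---------------------------------------------------------------------------

READS_COLUMNS = ["patient_id", "side", "K", "D", "node_time_min", "N", "V", "collateral"]


def _read_from_row(row) -> QualitativeRead:
    t_raw = row["node_time_min"]
    t = NOT_VISUALIZED if pd.isna(t_raw) or str(t_raw).strip() == "" else int(float(t_raw))
    return QualitativeRead(
        kinetics_score=int(row["K"]),
        dbf_score=int(row["D"]),
        node_time=t,
        node_score=int(row["N"]),
        vessel_score=int(row["V"]),
        collateral=bool(int(row["collateral"])),
    )


def reads_from_csv(path) -> dict:
    """Load ``reads.csv`` into a {(patient_id, side): QualitativeRead} mapping.

    Rows are validated individually; the first invalid row raises a
    :class:`ValidationError` naming the row and offending field.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in READS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"reads file {path} is missing columns {missing}")
    out: dict = {}
    for idx, row in df.iterrows():
        key = (row["patient_id"], row["side"])
        if key in out:
            raise ValidationError(f"reads row {idx}: duplicate (patient_id, side) {key}")
        try:
            out[key] = _read_from_row(row)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"reads row {idx} (patient {row['patient_id']}): {exc}") from exc
    return out


def reads_to_csv(reads: dict, path) -> None:
    """Write a {(patient_id, side): QualitativeRead} mapping as reads.csv."""
    rows = []
    for (pid, side), r in reads.items():
        rows.append(
            {
                "patient_id": pid,
                "side": side,
                "K": r.kinetics_score,
                "D": r.dbf_score,
                "node_time_min": "" if r.node_time is NOT_VISUALIZED else r.node_time,
                "N": r.node_score,
                "V": r.vessel_score,
                "collateral": int(r.collateral),
            }
        )
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, index=False)
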