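"""End-to-end study reproduction: load a cohort, score it, analyse it, report.

The pipeline mirrors the study design: per-limb transport indices at the
full (240-min) and shortened (120-min) imaging windows, limb volumetry
(LELI) before and 1/3/6 months after lymphovenous anastomosis, and a
battery of nonparametric association analyses — TI versus clinical stage,
versus pre-operative volume excess, and versus the postoperative %dLELI
outcome, plus binary-parameter group comparisons and an optional
intra-rater ICC.  Results are collected into a :class:`StudyReport`
(a JSON-serializable nested mapping) and written as JSON plus per-table
CSVs with a rounded human-readable summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .scoring import (
    NOT_VISUALIZED,
    QualitativeRead,
    ValidationError,
    _read_from_row,
    binarize,
    transport_index,
)
from .volumetrics import (
    TIMEPOINTS,
    CircumferenceSet,
    VolumeSeries,
    excess,
    leli,
)

__all__ = [
    "PatientRecord",
    "StudyOptions",
    "StudyReport",
    "CohortValidationError",
    "load_cohort",
    "run_study",
    "write_report",
]

logger = logging.getLogger("lymphoti")

POSTOP_TIMEPOINTS = ("1m", "3m", "6m")
BINARY_FLAGS = (
    "kinetics_delayed",
    "dbf_present",
    "node_time_late",
    "nodes_not_visualized",
    "vessel_not_visualized",
    "collateral_present",
)


class CohortValidationError(ValidationError):
    """One or more cohort rows failed validation; ``errors`` lists them all."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... and {len(self.errors) - 20} more"
        super().__init__(f"cohort validation failed ({len(self.errors)} problems):\n  {preview}{more}")


@dataclass
class PatientRecord:
    """One patient: bilateral reads, serial volumetry and covariates."""

    patient_id: str
    age: float
    stage: int
    duration_years: float
    bmi: float
    affected_side: str
    affected_read: QualitativeRead
    affected_volumes: VolumeSeries
    contralateral_read: Optional[QualitativeRead] = None
    contralateral_volumes: Optional[VolumeSeries] = None
    affected_read_second: Optional[QualitativeRead] = None
    bilateral: bool = False
    circumferences: dict = field(default_factory=dict)  # (side, timepoint) -> CircumferenceSet

    def __post_init__(self):
        if self.affected_side not in ("left", "right"):
            raise ValidationError(f"affected_side must be left or right, got {self.affected_side!r}")
        if self.stage not in (1, 2, 3, 4, 5):
            raise ValidationError(f"stage must be a clinical stage 1-5, got {self.stage!r}")

    def has_followup(self) -> bool:
        return any(self.affected_volumes.at(tp) is not None for tp in POSTOP_TIMEPOINTS)


@dataclass(frozen=True)
class StudyOptions:
    """Analysis switches.

    exclude_bilateral
        Drop patients flagged bilateral from outcome analyses (study rule).
    drop_patients_without_followup
        Remove patients with no post-op volumetry from the whole analysis
        (the study's enrolment rule); off by default so descriptive blocks
        keep them, with outcome analyses excluding them implicitly.
    subgroup_stage3
        Additionally rerun the association battery on the stage-3 subset.
    holm
        Apply a Holm step-down adjustment within each timepoint's
        binary-parameter p-value family (off by default, as in the study).
    """

    exclude_bilateral: bool = True
    drop_patients_without_followup: bool = False
    subgroup_stage3: bool = False
    holm: bool = False


@dataclass
class StudyReport:
    """Computed study summaries as a JSON-serializable nested mapping."""

    data: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True, allow_nan=False) + "\n")

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        return cls(data=json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

PATIENTS_COLUMNS = ["patient_id", "age", "stage", "duration_years", "bmi", "affected_side"]


def load_cohort(reads_path, volumetry_path, patients_path) -> list:
    """Join and validate the three cohort CSVs into patient records.

    Every malformed row is reported (file, row index, field) in a single
    :class:`CohortValidationError`; orphan limb rows and duplicate keys are
    errors.  Patients missing post-op timepoints are retained, with the
    gaps left as ``None`` in their volume series.
    """
    errors: list = []

    patients_df = pd.read_csv(patients_path, dtype={"patient_id": str})
    missing = [c for c in PATIENTS_COLUMNS if c not in patients_df.columns]
    if missing:
        raise CohortValidationError([f"patients file is missing columns {missing}"])

    patient_rows: dict = {}
    for idx, row in patients_df.iterrows():
        pid = row["patient_id"]
        if pid in patient_rows:
            errors.append(f"patients row {idx}: duplicate patient_id {pid!r}")
            continue
        patient_rows[pid] = row

    # reads.csv — optional `reading` column distinguishes two reader passes
    reads_df = pd.read_csv(reads_path, dtype={"patient_id": str})
    reads: dict = {}
    for idx, row in reads_df.iterrows():
        pid, side = row["patient_id"], row["side"]
        if side not in ("affected", "contralateral"):
            errors.append(f"reads row {idx}: side must be affected|contralateral, got {side!r}")
            continue
        passno = int(row["reading"]) if "reading" in reads_df.columns and not pd.isna(row.get("reading")) else 1
        if passno not in (1, 2):
            errors.append(f"reads row {idx}: reading pass must be 1 or 2, got {passno}")
            continue
        if pid not in patient_rows:
            errors.append(f"reads row {idx}: orphan limb row, unknown patient_id {pid!r}")
            continue
        key = (pid, side, passno)
        if key in reads:
            errors.append(f"reads row {idx}: duplicate (patient, side, reading) {key}")
            continue
        try:
            reads[key] = _read_from_row(row)
        except (ValidationError, ValueError) as exc:
            errors.append(f"reads row {idx} (patient {pid}): {exc}")

    # volumetry.csv
    vol_df = pd.read_csv(volumetry_path, dtype={"patient_id": str})
    circs: dict = {}
    for idx, row in vol_df.iterrows():
        pid, side, tp = row["patient_id"], row["side"], row["timepoint"]
        if side not in ("affected", "contralateral"):
            errors.append(f"volumetry row {idx}: side must be affected|contralateral, got {side!r}")
            continue
        if tp not in TIMEPOINTS:
            errors.append(f"volumetry row {idx}: timepoint must be one of {TIMEPOINTS}, got {tp!r}")
            continue
        if pid not in patient_rows:
            errors.append(f"volumetry row {idx}: orphan limb row, unknown patient_id {pid!r}")
            continue
        key = (pid, side, tp)
        if key in circs:
            errors.append(f"volumetry row {idx}: duplicate (patient, side, timepoint) {key}")
            continue
        try:
            circs[key] = CircumferenceSet(
                circumferences=tuple(float(row[f"c{i}"]) for i in range(1, 6)),
                bmi=float(row["bmi"]),
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"volumetry row {idx} (patient {pid}): {exc}")

    records: list = []
    for pid, prow in patient_rows.items():
        try:
            affected_read = reads.get((pid, "affected", 1))
            if affected_read is None:
                errors.append(f"patient {pid}: no affected-limb read")
                continue
            if (pid, "affected", "pre") not in circs:
                errors.append(f"patient {pid}: no pre-operative affected-limb volumetry")
                continue

            def series(side: str) -> Optional[VolumeSeries]:
                values = {tp: circs.get((pid, side, tp)) for tp in TIMEPOINTS}
                if values["pre"] is None:
                    return None
                return VolumeSeries(
                    leli_pre=leli(values["pre"]),
                    leli_1m=None if values["1m"] is None else leli(values["1m"]),
                    leli_3m=None if values["3m"] is None else leli(values["3m"]),
                    leli_6m=None if values["6m"] is None else leli(values["6m"]),
                )

            records.append(
                PatientRecord(
                    patient_id=pid,
                    age=float(prow["age"]),
                    stage=int(prow["stage"]),
                    duration_years=float(prow["duration_years"]),
                    bmi=float(prow["bmi"]),
                    affected_side=str(prow["affected_side"]),
                    bilateral=bool(int(prow["bilateral"])) if "bilateral" in prow.index and not pd.isna(prow.get("bilateral")) else False,
                    affected_read=affected_read,
                    affected_read_second=reads.get((pid, "affected", 2)),
                    contralateral_read=reads.get((pid, "contralateral", 1)),
                    affected_volumes=series("affected"),
                    contralateral_volumes=series("contralateral"),
                    circumferences={(s, tp): cs for (p, s, tp), cs in circs.items() if p == pid},
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"patient {pid}: {exc}")

    if errors:
        raise CohortValidationError(errors)
    logger.info("loaded cohort: %d patients, %d reads, %d volumetry rows", len(records), len(reads), len(circs))
    return records


# ---------------------------------------------------------------------------
# Analysis helpers
# ---------------------------------------------------------------------------

def _summary(values) -> dict:
    a = np.asarray(list(values), dtype=float)
    if a.size == 0:
        return {"n": 0, "mean": None, "sd": None, "min": None, "max": None}
    return {
        "n": int(a.size),
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "min": float(a.min()),
        "max": float(a.max()),
    }


def _corr_block(x, y) -> dict:
    """Spearman correlation block with a degenerate-input guard."""
    x = list(x)
    y = list(y)
    if len(x) < 3:
        return {"computed": False, "reason": f"insufficient n ({len(x)})", "n": len(x)}
    try:
        r = stats.spearman(x, y)
    except stats.ConstantInputError as exc:
        return {"computed": False, "reason": str(exc), "n": len(x)}
    return {"computed": True, "rho": r.rho, "p": r.p_value, "n": r.n}


def _mw_block(a, b) -> dict:
    a, b = list(a), list(b)
    if min(len(a), len(b)) < 1 or len(a) + len(b) < 3:
        return {"computed": False, "reason": "a group is empty or combined n < 3", "n": [len(a), len(b)]}
    r = stats.mann_whitney(a, b)
    return {"computed": True, "statistic": r.statistic, "p": r.p_value, "n": list(r.n)}


# ---------------------------------------------------------------------------
# Study analysis
# ---------------------------------------------------------------------------

def run_study(cohort: Sequence[PatientRecord], options: StudyOptions = StudyOptions()) -> StudyReport:
    """Run the full association battery on a loaded cohort.

    Requires at least 3 patients with pre-operative data.  Analyses that
    cannot be computed on the given data (constant inputs, empty groups,
    insufficient n) are marked ``computed: false`` with a reason and the
    run continues.
    """
    cohort = list(cohort)
    if options.drop_patients_without_followup:
        before = len(cohort)
        cohort = [p for p in cohort if p.has_followup()]
        logger.info("dropped %d patients without any post-op volumetry", before - len(cohort))
    if len(cohort) < 3:
        raise ValidationError(f"need at least 3 patients with pre-op data, got {len(cohort)}")

    n_bilateral = sum(p.bilateral for p in cohort)
    outcome_cohort = [p for p in cohort if not (options.exclude_bilateral and p.bilateral)]
    logger.info("cohort n=%d; outcome analyses n=%d (bilateral excluded: %d)",
                len(cohort), len(outcome_cohort), len(cohort) - len(outcome_cohort))

    # --- per-limb transport indices -------------------------------------
    ti240 = {p.patient_id: transport_index(p.affected_read, 240).value for p in cohort}
    ti120 = {p.patient_id: transport_index(p.affected_read, 120).value for p in cohort}
    ti_by_window = {"240": ti240, "120": ti120}
    contra_ti = {
        p.patient_id: transport_index(p.contralateral_read, 240).value
        for p in cohort
        if p.contralateral_read is not None
    }

    diffs = np.array([ti120[p.patient_id] - ti240[p.patient_id] for p in cohort])
    positive = diffs[diffs > 1e-9]
    ti_block = {
        "ti240": _summary(ti240.values()),
        "ti120": _summary(ti120.values()),
        "ti120_vs_ti240": {
            "n_identical": int(np.sum(np.abs(diffs) <= 1e-9)),
            "n_higher_ti120": int(positive.size),
            "difference": _summary(positive),
        },
        "contralateral": {
            "n_with_read": len(contra_ti),
            "elevated_values": sorted(round(v, 10) for v in contra_ti.values() if v > 0.6 + 1e-9),
        },
    }

    # --- descriptives (Table 3 analogue) --------------------------------
    pre_aff = {p.patient_id: p.affected_volumes.leli_pre for p in cohort}
    pre_con = {
        p.patient_id: p.contralateral_volumes.leli_pre
        for p in cohort
        if p.contralateral_volumes is not None
    }
    stage_counts = {}
    for p in cohort:
        stage_counts[str(p.stage)] = stage_counts.get(str(p.stage), 0) + 1
    descriptives = {
        "n_patients": len(cohort),
        "age_years": _summary(p.age for p in cohort),
        "bmi": _summary(p.bmi for p in cohort),
        "duration_years": _summary(p.duration_years for p in cohort),
        "affected_side_counts": {
            "left": sum(p.affected_side == "left" for p in cohort),
            "right": sum(p.affected_side == "right" for p in cohort),
        },
        "stage_counts": stage_counts,
        "leli_affected_pre": _summary(pre_aff.values()),
        "leli_contralateral_pre": _summary(pre_con.values()),
    }

    # --- component counts (Table 4 analogue) ----------------------------
    def _count(getter) -> dict:
        counts = {"0": 0, "3": 0, "5": 0, "9": 0}
        for p in cohort:
            counts[str(getter(p.affected_read))] += 1
        return counts

    time_counts: dict = {}
    for p in cohort:
        t = p.affected_read.node_time
        key = "not_visualized" if t is NOT_VISUALIZED else f"{t}min"
        time_counts[key] = time_counts.get(key, 0) + 1
    component_counts = {
        "kinetics_K": _count(lambda r: r.kinetics_score),
        "dbf_D": _count(lambda r: r.dbf_score),
        "node_time_T": time_counts,
        "nodes_N": _count(lambda r: r.node_score),
        "vessel_V": _count(lambda r: r.vessel_score),
        "collateral_C": {
            "present": sum(p.affected_read.collateral for p in cohort),
            "absent": sum(not p.affected_read.collateral for p in cohort),
        },
    }

    # --- stage-wise TI comparison ---------------------------------------
    stage_comparison = {}
    for window, ti in ti_by_window.items():
        groups: dict = {}
        for p in cohort:
            groups.setdefault(p.stage, []).append(ti[p.patient_id])
        block = {"per_stage": {str(s): _summary(v) for s, v in sorted(groups.items())}}
        if len(groups) >= 2:
            kw = stats.kruskal_wallis([groups[s] for s in sorted(groups)])
            block.update({"computed": True, "statistic": kw.statistic, "p": kw.p_value, "n": list(kw.n)})
        else:
            block.update({"computed": False, "reason": "fewer than 2 stage groups"})
        stage_comparison[window] = block

    # --- TI vs pre-op volume excess -------------------------------------
    excess_by_pid = {
        pid: excess(pre_aff[pid], pre_con[pid]) for pid in pre_aff if pid in pre_con
    }
    ti_vs_excess = {
        window: _corr_block(
            [ti[pid] for pid in excess_by_pid], list(excess_by_pid.values())
        )
        for window, ti in ti_by_window.items()
    }

    # --- affected vs contralateral pre-op LELI --------------------------
    paired = [(pre_aff[pid], pre_con[pid]) for pid in pre_aff if pid in pre_con]
    if len(paired) >= 3:
        try:
            w = stats.wilcoxon_signed_rank([a for a, _ in paired], [c for _, c in paired])
            affected_vs_contralateral = {
                "computed": True, "statistic": w.statistic, "p": w.p_value, "n": len(paired),
            }
        except stats.ConstantInputError as exc:
            affected_vs_contralateral = {"computed": False, "reason": str(exc), "n": len(paired)}
    else:
        affected_vs_contralateral = {"computed": False, "reason": "fewer than 3 limb pairs", "n": len(paired)}

    # --- postoperative outcomes -----------------------------------------
    pct: dict = {tp: {} for tp in POSTOP_TIMEPOINTS}
    for p in outcome_cohort:
        for tp in POSTOP_TIMEPOINTS:
            v = p.affected_volumes.pct_delta(tp)
            if v is not None:
                pct[tp][p.patient_id] = v
    pct_delta_block = {tp: _summary(pct[tp].values()) for tp in POSTOP_TIMEPOINTS}

    # --- binary-parameter associations (Table 5 analogue) ---------------
    profiles = {p.patient_id: binarize(p.affected_read).as_dict() for p in outcome_cohort}
    binary_associations: dict = {}
    for flag in BINARY_FLAGS:
        binary_associations[flag] = {}
        for tp in POSTOP_TIMEPOINTS:
            yes = [v for pid, v in pct[tp].items() if profiles[pid][flag]]
            no = [v for pid, v in pct[tp].items() if not profiles[pid][flag]]
            binary_associations[flag][tp] = _mw_block(yes, no)
    if options.holm:
        for tp in POSTOP_TIMEPOINTS:
            cells = [binary_associations[f][tp] for f in BINARY_FLAGS]
            live = [c for c in cells if c.get("computed")]
            if live:
                adjusted = stats.holm_adjust([c["p"] for c in live])
                for c, padj in zip(live, adjusted):
                    c["p_holm"] = padj

    # --- TI vs outcome correlations (Figure 2 analogue) -----------------
    ti_vs_outcome = {
        window: {
            tp: _corr_block([ti[pid] for pid in pct[tp]], list(pct[tp].values()))
            for tp in POSTOP_TIMEPOINTS
        }
        for window, ti in ti_by_window.items()
    }

    # --- inter-timepoint outcome correlations ---------------------------
    outcome_intercorrelations = {}
    for tp_a, tp_b in (("1m", "3m"), ("3m", "6m"), ("1m", "6m")):
        shared = [pid for pid in pct[tp_a] if pid in pct[tp_b]]
        outcome_intercorrelations[f"{tp_a}_vs_{tp_b}"] = _corr_block(
            [pct[tp_a][pid] for pid in shared], [pct[tp_b][pid] for pid in shared]
        )

    # --- optional intra-rater ICC ----------------------------------------
    dual = [(transport_index(p.affected_read, 240).value,
             transport_index(p.affected_read_second, 240).value)
            for p in cohort if p.affected_read_second is not None]
    if len(dual) >= 3:
        try:
            icc_block = {
                "computed": True,
                "icc": stats.icc_intrarater([a for a, _ in dual], [b for _, b in dual]),
                "n": len(dual),
            }
        except stats.ConstantInputError as exc:
            icc_block = {"computed": False, "reason": str(exc), "n": len(dual)}
    else:
        icc_block = {"computed": False, "reason": "fewer than 3 dual-read limbs", "n": len(dual)}

    # --- per-patient pairs (for the outcome scatter CSV) -----------------
    pairs = [
        {
            "patient_id": p.patient_id,
            "stage": p.stage,
            "ti240": ti240[p.patient_id],
            "ti120": ti120[p.patient_id],
            "pct_delta_1m": pct["1m"].get(p.patient_id),
            "pct_delta_3m": pct["3m"].get(p.patient_id),
            "pct_delta_6m": pct["6m"].get(p.patient_id),
        }
        for p in outcome_cohort
    ]

    data = {
        "descriptives": descriptives,
        "component_counts": component_counts,
        "ti": ti_block,
        "stage_comparison": stage_comparison,
        "ti_vs_excess": ti_vs_excess,
        "affected_vs_contralateral_leli": affected_vs_contralateral,
        "pct_delta_leli": pct_delta_block,
        "binary_associations": binary_associations,
        "ti_vs_outcome": ti_vs_outcome,
        "outcome_intercorrelations": outcome_intercorrelations,
        "intrarater_icc": icc_block,
        "pairs": pairs,
        "provenance": {
            "n_input_patients": len(cohort),
            "n_bilateral": n_bilateral,
            "n_outcome_patients": len(outcome_cohort),
            "n_with_contralateral_volumetry": len(pre_con),
            "n_outcome": {tp: len(pct[tp]) for tp in POSTOP_TIMEPOINTS},
            "options": {
                "exclude_bilateral": options.exclude_bilateral,
                "drop_patients_without_followup": options.drop_patients_without_followup,
                "holm": options.holm,
            },
        },
    }

    if options.subgroup_stage3:
        stage3 = [p for p in cohort if p.stage == 3]
        if len(stage3) >= 3:
            sub = run_study(
                stage3,
                StudyOptions(
                    exclude_bilateral=options.exclude_bilateral,
                    drop_patients_without_followup=False,
                    subgroup_stage3=False,
                    holm=options.holm,
                ),
            )
            data["subgroup_stage3"] = {
                "n": len(stage3),
                "ti_vs_outcome": sub.data["ti_vs_outcome"],
                "ti_vs_excess": sub.data["ti_vs_excess"],
                "pct_delta_leli": sub.data["pct_delta_leli"],
            }
        else:
            data["subgroup_stage3"] = {"computed": False, "reason": "fewer than 3 stage-3 patients", "n": len(stage3)}

    return StudyReport(data=data)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _fmt(x, nd: int) -> str:
    return "" if x is None else f"{x:.{nd}f}"


def write_report(report: StudyReport, out_dir) -> list:
    """Write report.json, per-table CSVs and a rounded text summary.

    JSON and CSV carry full precision; only ``summary.txt`` rounds for
    display (TI to 1 decimal, rho to 3, p to 3).  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    report.to_json(json_path)
    written.append(json_path)

    d = report.data

    cc_rows = []
    for comp, counts in d["component_counts"].items():
        for category, n in counts.items():
            cc_rows.append({"component": comp, "category": category, "n": n})
    pd.DataFrame(cc_rows).to_csv(out / "component_counts.csv", index=False)
    written.append(out / "component_counts.csv")

    ba_rows = []
    for flag in BINARY_FLAGS:
        row = {"parameter": flag}
        for tp in POSTOP_TIMEPOINTS:
            cell = d["binary_associations"][flag][tp]
            row[f"p_{tp}"] = cell.get("p")
        ba_rows.append(row)
    pd.DataFrame(ba_rows).to_csv(out / "binary_associations.csv", index=False)
    written.append(out / "binary_associations.csv")

    corr_rows = []
    for window in ("240", "120"):
        blk = d["ti_vs_excess"][window]
        corr_rows.append({"analysis": "ti_vs_excess", "window": window, "timepoint": "pre",
                          "rho": blk.get("rho"), "p": blk.get("p"), "n": blk.get("n")})
        for tp in POSTOP_TIMEPOINTS:
            blk = d["ti_vs_outcome"][window][tp]
            corr_rows.append({"analysis": "ti_vs_pct_delta_leli", "window": window, "timepoint": tp,
                              "rho": blk.get("rho"), "p": blk.get("p"), "n": blk.get("n")})
    for key, blk in d["outcome_intercorrelations"].items():
        corr_rows.append({"analysis": f"pct_delta_{key}", "window": "", "timepoint": "",
                          "rho": blk.get("rho"), "p": blk.get("p"), "n": blk.get("n")})
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
    written.append(out / "correlations.csv")

    ti_rows = []
    for window in ("240", "120"):
        s = d["ti"][f"ti{window}"]
        ti_rows.append({"window": window, **s})
    pd.DataFrame(ti_rows).to_csv(out / "ti_summary.csv", index=False)
    written.append(out / "ti_summary.csv")

    oc_rows = [{"timepoint": tp, **d["pct_delta_leli"][tp]} for tp in POSTOP_TIMEPOINTS]
    pd.DataFrame(oc_rows).to_csv(out / "outcomes.csv", index=False)
    written.append(out / "outcomes.csv")

    pd.DataFrame(d["pairs"]).to_csv(out / "ti_outcome_pairs.csv", index=False)
    written.append(out / "ti_outcome_pairs.csv")

    lines = ["Lymphoscintigraphy TI / LVA outcome study report", "=" * 48, ""]
    lines.append(f"Patients: {d['descriptives']['n_patients']} "
                 f"(stages: {d['descriptives']['stage_counts']})")
    for window in ("240", "120"):
        s = d["ti"][f"ti{window}"]
        lines.append(f"TI_{window}: mean {_fmt(s['mean'], 1)} +/- {_fmt(s['sd'], 1)} "
                     f"(range {_fmt(s['min'], 1)}-{_fmt(s['max'], 1)}, n={s['n']})")
    tv = d["ti"]["ti120_vs_ti240"]
    dsum = tv["difference"]
    lines.append(f"TI_120 vs TI_240: identical {tv['n_identical']}, higher {tv['n_higher_ti120']} "
                 f"(diff mean {_fmt(dsum['mean'], 1)}, range {_fmt(dsum['min'], 1)}-{_fmt(dsum['max'], 1)})")
    for window in ("240", "120"):
        sc = d["stage_comparison"][window]
        if sc.get("computed"):
            per = ", ".join(f"stage {s}: {_fmt(v['mean'], 1)}" for s, v in sc["per_stage"].items())
            lines.append(f"Stage-wise TI_{window}: {per}; p={_fmt(sc['p'], 3)}")
    for window in ("240", "120"):
        blk = d["ti_vs_excess"][window]
        if blk.get("computed"):
            lines.append(f"TI_{window} vs pre-op excess: rho={_fmt(blk['rho'], 3)}, "
                         f"p={_fmt(blk['p'], 3)} (n={blk['n']})")
    for tp in POSTOP_TIMEPOINTS:
        s = d["pct_delta_leli"][tp]
        lines.append(f"%dLELI at {tp}: mean {_fmt(s['mean'], 1)} +/- {_fmt(s['sd'], 1)} "
                     f"(range {_fmt(s['min'], 1)}-{_fmt(s['max'], 1)}, n={s['n']})")
    for window in ("240", "120"):
        for tp in POSTOP_TIMEPOINTS:
            blk = d["ti_vs_outcome"][window][tp]
            if blk.get("computed"):
                lines.append(f"TI_{window} vs %dLELI at {tp}: rho={_fmt(blk['rho'], 3)}, "
                             f"p={_fmt(blk['p'], 3)} (n={blk['n']})")
    if d["intrarater_icc"].get("computed"):
        lines.append(f"Intra-rater ICC (TI_240): {_fmt(d['intrarater_icc']['icc'], 3)} "
                     f"(n={d['intrarater_icc']['n']})")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    logger.info("wrote report: %s", ", ".join(p.name for p in written))
    return written
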