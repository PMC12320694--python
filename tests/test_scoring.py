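"""Transport-index scoring: formula, censoring rule, dichotomization."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lymphoti.scoring import (
    DEFAULT_FRAMES,
    NOT_VISUALIZED,
    ORDINAL_SCORES,
    TI120_FRAMES,
    BinaryProfile,
    QualitativeRead,
    TransportIndex,
    ValidationError,
    binarize,
    censor_read,
    enumerate_reads,
    reads_from_csv,
    reads_to_csv,
    time_term,
    transport_index,
)

ALL_READS = list(enumerate_reads())


def make_read(k=0, d=0, t=15, n=0, v=0, c=False):
    return QualitativeRead(k, d, t, n, v, c)


# ---------------------------------------------------------------------------
# time term
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "node_time, expected",
    [
        (15, 0.6),
        (30, 1.2),
        (60, 2.4),
        (120, 4.8),
        (180, 7.2),
        (240, 9.0),  # 0.04*240 = 9.6 is capped at the no-visualization score
        (NOT_VISUALIZED, 9.0),
    ],
)
def test_time_term(node_time, expected):
    assert time_term(node_time) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [-15, 0, 45, 90])
def test_time_term_rejects_non_frame_times(bad):
    with pytest.raises(ValidationError):
        time_term(bad)


# ---------------------------------------------------------------------------
# transport index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "read, expected",
    [
        (make_read(0, 0, 15, 0, 0), 0.6),                      # best possible study
        (make_read(9, 9, NOT_VISUALIZED, 9, 9), 45.0),         # worst possible study
        (make_read(3, 0, 60, 3, 0), 8.4),                      # worked example, left leg
        (make_read(3, 5, 60, 0, 5), 15.4),                     # worked example, right leg
    ],
)
def test_transport_index_values(read, expected):
    assert transport_index(read, 240).value == pytest.approx(expected)


def test_ti_bounds_by_exhaustive_enumeration():
    values = [transport_index(r, 240).value for r in ALL_READS]
    assert min(values) == pytest.approx(0.6)
    assert max(values) == pytest.approx(45.0)
    assert len(ALL_READS) == 4 * 4 * 4 * (6 * 3 + 1)


def test_ti_invariant_to_collateral_flag():
    for r in ALL_READS[::37]:
        flipped = dataclasses.replace(r, collateral=not r.collateral)
        assert transport_index(flipped, 240).value == transport_index(r, 240).value
        assert transport_index(flipped, 120).value == transport_index(r, 120).value


def test_transport_index_is_pure():
    r = make_read(5, 3, 120, 5, 9, True)
    assert transport_index(r, 120) == transport_index(r, 120)
    assert transport_index(r, 240).value == transport_index(r, 240).value


def test_ti_out_of_range_rejected():
    with pytest.raises(ValidationError):
        TransportIndex(value=0.5, window_minutes=240)
    with pytest.raises(ValidationError):
        TransportIndex(value=46.0, window_minutes=120)


# ---------------------------------------------------------------------------
# read validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(kinetics_score=4),                       # not an allowed ordinal
        dict(dbf_score=1),
        dict(node_time=45),                           # not an acquired frame
        dict(node_time=NOT_VISUALIZED, node_score=5), # invisible nodes must score 9
        dict(node_time=60, node_score=9),             # visible nodes cannot score 9
    ],
)
def test_invalid_reads_rejected(kwargs):
    base = dict(kinetics_score=0, dbf_score=0, node_time=15, node_score=0, vessel_score=0)
    base.update(kwargs)
    with pytest.raises(ValidationError):
        QualitativeRead(**base)


# ---------------------------------------------------------------------------
# censoring to the 120-min window
# ---------------------------------------------------------------------------

def test_censor_snaps_omitted_frame_forward():
    r = make_read(0, 0, 30, 3, 0)
    c = censor_read(r, TI120_FRAMES)
    assert c.node_time == 60 and c.node_score == 3
    diff = transport_index(r, 120).value - transport_index(r, 240).value
    assert diff == pytest.approx(1.2)


def test_censor_late_node_becomes_not_visualized():
    r = make_read(0, 0, 180, 5, 0)
    c = censor_read(r, TI120_FRAMES)
    assert c.node_time is NOT_VISUALIZED and c.node_score == 9
    diff = transport_index(r, 120).value - transport_index(r, 240).value
    assert diff == pytest.approx(5.8)


def test_censor_retained_frame_unchanged():
    r = make_read(5, 3, 120, 3, 5)
    assert transport_index(r, 120).value == pytest.approx(transport_index(r, 240).value)


def test_censor_preserves_other_components():
    r = make_read(5, 9, 180, 3, 5, True)
    c = censor_read(r)
    assert (c.kinetics_score, c.dbf_score, c.vessel_score, c.collateral) == (5, 9, 5, True)


def test_censoring_monotone_and_min_positive_difference():
    diffs = [
        transport_index(r, 120).value - transport_index(r, 240).value for r in ALL_READS
    ]
    assert all(d >= -1e-12 for d in diffs)
    positive = [d for d in diffs if d > 1e-9]
    assert min(positive) == pytest.approx(1.2)


def test_censor_rejects_empty_or_foreign_frames():
    r = make_read()
    with pytest.raises(ValidationError):
        censor_read(r, ())
    with pytest.raises(ValidationError):
        censor_read(r, (15, 90))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "read, expected",
    [
        (make_read(3, 0, 60, 3, 0, False), dict.fromkeys(
            ["kinetics_delayed", "dbf_present", "node_time_late",
             "nodes_not_visualized", "vessel_not_visualized", "collateral_present"], False)),
        (make_read(5, 5, NOT_VISUALIZED, 9, 9, True), dict.fromkeys(
            ["kinetics_delayed", "dbf_present", "node_time_late",
             "nodes_not_visualized", "vessel_not_visualized", "collateral_present"], True)),
        (make_read(9, 0, 120, 0, 0, False),
         {"kinetics_delayed": True, "dbf_present": False, "node_time_late": True,
          "nodes_not_visualized": False, "vessel_not_visualized": False,
          "collateral_present": False}),
    ],
)
def test_binarize(read, expected):
    assert binarize(read).as_dict() == expected


@given(st.sampled_from(ALL_READS))
def test_binarize_consistent_with_scores(read):
    p = binarize(read)
    assert p.kinetics_delayed == (read.kinetics_score >= 5)
    assert p.dbf_present == (read.dbf_score > 0)
    assert p.nodes_not_visualized == (read.node_score == 9)
    late = read.node_time is NOT_VISUALIZED or read.node_time > 60
    assert p.node_time_late == late


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_reads_csv_round_trip(tmp_path):
    reads = {
        ("P1", "affected"): make_read(5, 5, NOT_VISUALIZED, 9, 9, True),
        ("P1", "contralateral"): make_read(),
        ("P2", "affected"): make_read(3, 3, 120, 5, 3, False),
    }
    path = tmp_path / "reads.csv"
    reads_to_csv(reads, path)
    assert reads_from_csv(path) == reads


def test_reads_csv_rejects_bad_score(tmp_path):
    path = tmp_path / "reads.csv"
    path.write_text(
        "patient_id,side,K,D,node_time_min,N,V,collateral\nP1,affected,4,0,15,0,0,0\n"
    )
    with pytest.raises(ValidationError, match="K"):
        reads_from_csv(path)
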