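"""Peak-table parsing, pass/fail calling, status aggregation and redo planning."""

import pytest
from hypothesis import given, settings, strategies as st

from plasmidcad import (
    CampaignConfig,
    PcrReaction,
    PeakTable,
    WellLocation,
    call_reaction,
    feasible_constructs,
    fragment_status,
    parse_peak_table,
    redo_plan,
    write_peak_table,
)
from plasmidcad.pcr_qc import PcrCall
from plasmidcad.errors import FormatError

from helpers_oracles import oracle_feasible


def _rxn(rid="rx1", expected=1000, round_no=1, fragment="f1", well=None):
    return PcrReaction(rid, fragment, "t", "o1", "o2", expected, 60.0, round_no,
                       layout=well and WellLocation("p1", well))


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def test_parse_groups_by_well_and_sorts(tmp_path, config):
    p = tmp_path / "zag.csv"
    p.write_text(
        "Well,Size (bp),Conc. (ng/ul)\n"
        "A1,1500,4.0\nA1,300,2.0\nA1,900,8.0\n"
    )
    table = parse_peak_table(p, config)
    assert list(table.wells) == ["A1"]
    assert table.peaks("A1") == [(300, 2.0), (900, 8.0), (1500, 4.0)]
    assert table.peaks("A01") == table.peaks("A1")  # padded addressing


def test_marker_peaks_removed_by_config(tmp_path):
    cfg = CampaignConfig(marker_sizes_bp=(1, 6000))
    p = tmp_path / "zag.csv"
    p.write_text(
        "Well,Size (bp),Conc. (ng/ul)\nB2,1,9.9\nB2,1000,5.0\nB2,6000,9.9\n"
    )
    table = parse_peak_table(p, cfg)
    assert table.peaks("B2") == [(1000, 5.0)]


def test_unparseable_rows_collected_not_dropped(tmp_path, config):
    p = tmp_path / "zag.csv"
    p.write_text(
        "Well,Size (bp),Conc. (ng/ul)\nA1,1000,5.0\nZZ,800,1.0\nA2,-5,1.0\nA3,nan?,x\n"
    )
    table = parse_peak_table(p, config)
    assert table.peaks("A1") == [(1000, 5.0)]
    assert len(table.parse_errors) == 3


def test_missing_columns_is_format_error(tmp_path, config):
    p = tmp_path / "zag.csv"
    p.write_text("wellname,bp\nA1,100\n")
    with pytest.raises(FormatError):
        parse_peak_table(p, config)
    # but a column map adapts the export
    p2 = tmp_path / "zag2.csv"
    p2.write_text("wellname,bp,ng\nA1,100,2.0\n")
    table = parse_peak_table(
        p2, config, column_map={"well": "wellname", "size": "bp", "conc": "ng"}
    )
    assert table.peaks("A1") == [(100, 2.0)]


def test_peak_table_roundtrip(tmp_path, config):
    table = PeakTable(wells={"A1": [(500, 2.5)], "H12": [(900, 1.0), (1200, 3.0)]})
    path = tmp_path / "out.csv"
    write_peak_table(table, path)
    back = parse_peak_table(path, config)
    assert back.wells == table.wells


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_call_pass_fail_empty():
    r = _rxn()
    ok = call_reaction(r, [(995, 5.0)], 0.10, 1.0)
    assert ok.verdict == "pass"
    assert ok.relative_error == pytest.approx(0.005)
    assert ok.matched_peak == (995, 5.0)

    assert call_reaction(r, [(1500, 5.0), (400, 5.0)], 0.10, 1.0).verdict == "fail"
    assert call_reaction(r, [], 0.10, 1.0).verdict == "empty_lane"
    # in-tolerance size but below the concentration floor does not pass
    assert call_reaction(r, [(1000, 0.5)], 0.10, 1.0).verdict == "fail"


def test_tie_breaks_toward_higher_concentration():
    r = _rxn(expected=1000)
    call = call_reaction(r, [(990, 2.0), (1010, 9.0)], 0.10, 1.0)
    assert call.matched_peak == (1010, 9.0)


@settings(max_examples=50, deadline=None)
@given(
    peaks=st.lists(
        st.tuples(st.integers(50, 3000), st.floats(0.0, 50.0)), max_size=5
    ),
    tol1=st.floats(0.01, 0.5),
    tol2=st.floats(0.01, 0.5),
)
def test_call_monotone_in_tolerance(peaks, tol1, tol2):
    """Passing at a tight tolerance implies passing at any looser one."""
    lo, hi = sorted((tol1, tol2))
    r = _rxn(expected=1000)
    if call_reaction(r, peaks, lo, 1.0).passed:
        assert call_reaction(r, peaks, hi, 1.0).passed


# ---------------------------------------------------------------------------
# status aggregation and redo rounds
# ---------------------------------------------------------------------------

def _call(rid, verdict, round_no=1, fragment="f1"):
    return PcrCall(rid, verdict, round_no=round_no, fragment_id=fragment)


def test_fragment_status_rules():
    demand = {"f1": 2, "f2": 1, "f3": 1}
    calls = [
        _call("f1.r1.1", "pass"), _call("f1.r1.2", "fail"),
        _call("f2.r1.1", "fail", fragment="f2"),
        _call("f3.r1.1", "fail", round_no=6, fragment="f3"),
    ]
    status = fragment_status(calls, demand, max_rounds=6)
    assert status == {"f1": "verified", "f2": "pending", "f3": "exhausted"}


def test_redo_partition_property(config):
    reactions = {}
    calls = []
    for i in range(10):
        rid = f"f{i}.r1.1"
        reactions[rid] = _rxn(rid, fragment=f"f{i}", well="A1")
        calls.append(_call(rid, "pass" if i >= 3 else "fail", fragment=f"f{i}"))
    redos = redo_plan(calls, reactions, 1, config)
    redo_bases = {r.fragment_id for r in redos}
    passed = {c.fragment_id for c in calls if c.passed}
    failed = {c.fragment_id for c in calls if not c.passed}
    assert redo_bases == failed            # redo ∪ passed = original
    assert redo_bases.isdisjoint(passed)   # redo ∩ passed = ∅
    assert all(r.round_no == 2 for r in redos)
    assert all(r.layout is not None for r in redos)


def test_no_failures_means_empty_redo(config):
    rid = "f1.r1.1"
    reactions = {rid: _rxn(rid, well="A1")}
    assert redo_plan([_call(rid, "pass")], reactions, 1, config) == []


def test_redo_stops_at_max_rounds():
    cfg = CampaignConfig(max_pcr_rounds=3)
    rid = "f1.r3.1"
    reactions = {rid: _rxn(rid, round_no=3, well="A1")}
    assert redo_plan([_call(rid, "fail", round_no=3)], reactions, 3, cfg) == []


def test_gradient_strategy_perturbs_annealing(config):
    reactions, calls = {}, []
    for i in range(4):
        rid = f"f{i}.r1.1"
        reactions[rid] = _rxn(rid, fragment=f"f{i}", well="A1")
        calls.append(_call(rid, "fail", fragment=f"f{i}"))
    redos = redo_plan(calls, reactions, 1, config, strategy="gradient")
    deltas = sorted(r.annealing_c - 60.0 for r in redos)
    assert deltas == [-2.0, -2.0, 2.0, 2.0]


# ---------------------------------------------------------------------------
# feasibility
# ---------------------------------------------------------------------------

def test_feasible_all_or_nothing(small_design):
    all_ok = {fid: "verified" for fid in small_design.fragments}
    assert feasible_constructs(small_design, all_ok) == set(small_design.constructs)
    # the vector bin fragment appears in half the constructs; kill one vector
    dead = next(iter(small_design.fragments))
    some = dict(all_ok, **{dead: "exhausted"})
    feas = feasible_constructs(small_design, some)
    assert feas == oracle_feasible(small_design, some)
    assert all(
        dead not in small_design.constructs[cid].fragment_ids for cid in feas
    )
    # a fragment in every construct fails → nothing feasible
    shared = {fid: "pending" for fid in small_design.fragments}
    assert feasible_constructs(small_design, shared) == set()


def test_feasible_monotone_in_verified_set(small_design):
    """Adding a verified fragment never shrinks the feasible set."""
    fids = sorted(small_design.fragments)
    status = {fid: "pending" for fid in fids}
    prev: set[str] = set()
    for fid in fids:
        status[fid] = "verified"
        cur = feasible_constructs(small_design, status)
        assert prev <= cur
        assert cur == oracle_feasible(small_design, status)
        prev = cur
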