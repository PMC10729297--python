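"""Capillary-electrophoresis QC: peak tables, pass/fail calls, redo planning.

A capillary instrument reports, per well, the sizes (bp) and concentrations
(ng/µL) of every DNA species it resolves, bracketed by alignment-marker peaks.
A PCR passes when some non-marker peak sits within a relative size tolerance
of the expected product at sufficient concentration.  Fragments are *verified*
once any replicate passes in any round; reactions that keep failing are re-run
for a bounded number of rounds and then abandoned as *exhausted*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .compiler import PcrReaction
from .config import CampaignConfig
from .design_io import Design
from .errors import FormatError
from .plate_model import allocate, format_address, parse_address


@dataclass
class PeakTable:
    """Per-well peak lists: well address → [(size_bp, concentration ng/µL)]."""

    wells: dict[str, list[tuple[int, float]]]
    plate_id: str = ""
    parse_errors: tuple[str, ...] = ()

    def peaks(self, address: str) -> list[tuple[int, float]]:
        r, c = parse_address(address)
        return self.wells.get(format_address(r, c), [])


@dataclass(frozen=True)
class PcrCall:
    """Verdict for one reaction against one peak table."""

    reaction_id: str
    verdict: str  # pass | fail | empty_lane
    matched_peak: tuple[int, float] | None = None
    relative_error: float | None = None  # set only on a pass
    round_no: int = 1
    fragment_id: str = ""

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


DEFAULT_PEAK_COLUMNS = {"well": "Well", "size": "Size (bp)", "conc": "Conc. (ng/ul)"}


def parse_peak_table(
    path: str | Path,
    config: CampaignConfig | None = None,
    column_map: Mapping[str, str] | None = None,
    plate_id: str = "",
) -> PeakTable:
    """Parse an instrument peak-table CSV into a :class:`PeakTable`.

    ``column_map`` names the well/size/concentration columns (instrument export
    formats vary).  Configured marker sizes are stripped.  Unparseable rows are
    collected on ``parse_errors`` rather than silently dropped.
    """
    config = config or CampaignConfig()
    cols = dict(DEFAULT_PEAK_COLUMNS)
    if column_map:
        cols.update(column_map)
    markers = set(config.marker_sizes_bp)
    wells: dict[str, list[tuple[int, float]]] = {}
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(cols.values()) <= set(reader.fieldnames):
            missing = sorted(set(cols.values()) - set(reader.fieldnames or []))
            raise FormatError(f"peak table missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                r, c = parse_address(row[cols["well"]])
                size = int(round(float(row[cols["size"]])))
                conc = float(row[cols["conc"]])
                if size <= 0 or conc < 0:
                    raise ValueError("non-positive size or negative concentration")
            except Exception as exc:  # noqa: BLE001 - row-level fault isolation
                errors.append(f"line {lineno}: {exc}")
                continue
            if size in markers:
                continue
            wells.setdefault(format_address(r, c), []).append((size, conc))
    for peaks in wells.values():
        peaks.sort()
    return PeakTable(wells=wells, plate_id=plate_id, parse_errors=tuple(errors))


def write_peak_table(table: PeakTable, path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> None:
    cols = dict(DEFAULT_PEAK_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([cols["well"], cols["size"], cols["conc"]])
        for well in sorted(table.wells):
            for size, conc in table.wells[well]:
                w.writerow([well, size, f"{conc:g}"])


def call_reaction(
    reaction: PcrReaction,
    peaks: Sequence[tuple[int, float]],
    tolerance: float = 0.10,
    min_concentration_ng_ul: float = 1.0,
) -> PcrCall:
    """Pass/fail one reaction against the peaks in its lane.

    Pass iff some peak has relative size error ≤ ``tolerance`` *and*
    concentration ≥ the floor.  The matched peak minimizes relative error,
    ties broken toward higher concentration (deterministic).
    An empty lane is its own verdict, distinct from a wrong-size failure.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if not peaks:
        return PcrCall(reaction.reaction_id, "empty_lane",
                       round_no=reaction.round_no, fragment_id=reaction.fragment_id)
    candidates = [
        (abs(size - reaction.expected_size_bp) / reaction.expected_size_bp, -conc, size, conc)
        for size, conc in peaks
        if conc >= min_concentration_ng_ul
    ]
    candidates = [c for c in candidates if c[0] <= tolerance]
    if not candidates:
        return PcrCall(reaction.reaction_id, "fail",
                       round_no=reaction.round_no, fragment_id=reaction.fragment_id)
    rel, _negconc, size, conc = min(candidates)
    return PcrCall(
        reaction.reaction_id, "pass", matched_peak=(size, conc),
        relative_error=rel, round_no=reaction.round_no,
        fragment_id=reaction.fragment_id,
    )


def call_plate(
    reactions: Sequence[PcrReaction],
    table: PeakTable,
    config: CampaignConfig | None = None,
) -> list[PcrCall]:
    """Call every laid-out reaction against its well of one peak table."""
    config = config or CampaignConfig()
    calls = []
    for r in reactions:
        if r.layout is None:
            raise ValueError(f"reaction {r.reaction_id} has no layout")
        calls.append(
            call_reaction(
                r, table.peaks(r.layout.address),
                config.size_tolerance, config.min_concentration_ng_ul,
            )
        )
    return calls


def fragment_status(
    calls: Iterable[PcrCall],
    demand: Mapping[str, int],
    max_rounds: int = 6,
) -> dict[str, str]:
    """Aggregate calls into per-fragment status: verified | pending | exhausted.

    Verified: ≥ 1 replicate passed in any round.  Exhausted: every allowed
    round consumed without a pass.  Otherwise pending.
    """
    status = {fid: "pending" for fid in demand}
    deepest_round: dict[str, int] = {fid: 0 for fid in demand}
    for call in calls:
        fid = call.fragment_id
        if fid not in status:
            continue
        deepest_round[fid] = max(deepest_round[fid], call.round_no)
        if call.passed:
            status[fid] = "verified"
    for fid, st in status.items():
        if st != "verified" and deepest_round[fid] >= max_rounds:
            status[fid] = "exhausted"
    return status


def redo_plan(
    calls: Sequence[PcrCall],
    reactions: Mapping[str, PcrReaction],
    round_no: int,
    config: CampaignConfig | None = None,
    strategy: str = "repeat",
) -> list[PcrReaction]:
    """Plan the next PCR round: exactly the non-passing reactions reappear.

    Redo reactions carry ``round_no + 1`` and a fresh consolidated layout.
    Strategy ``repeat`` copies conditions verbatim; ``gradient`` perturbs the
    annealing temperature ±2 °C, alternating by replicate, to probe failures
    caused by mis-estimated annealing.
    """
    if round_no < 1:
        raise ValueError("round_no must be >= 1")
    config = config or CampaignConfig()
    if round_no >= config.max_pcr_rounds:
        return []
    failed = [c for c in calls if not c.passed and c.round_no == round_no]
    redos = []
    for i, call in enumerate(sorted(failed, key=lambda c: c.reaction_id)):
        old = reactions[call.reaction_id]
        replicate = old.reaction_id.rsplit(".", 1)[-1]
        temp = old.annealing_c
        if strategy == "gradient":
            temp = round(temp + (2.0 if i % 2 == 0 else -2.0), 1)
        redos.append(
            PcrReaction(
                reaction_id=f"{old.fragment_id}.r{round_no + 1}.{replicate}",
                fragment_id=old.fragment_id,
                template_id=old.template_id,
                forward_oligo_id=old.forward_oligo_id,
                reverse_oligo_id=old.reverse_oligo_id,
                expected_size_bp=old.expected_size_bp,
                annealing_c=temp,
                round_no=round_no + 1,
            )
        )
    layout = allocate(
        [r.reaction_id for r in redos], config.labware["pcr96"],
        config.fill_order, plate_prefix=f"pcr_r{round_no + 1}_",
    )
    return [replace(r, layout=layout[r.reaction_id]) for r in redos]


def feasible_constructs(
    design: Design, status: Mapping[str, str]
) -> set[str]:
    """Constructs whose every fragment is verified. Pure and monotone."""
    return {
        c.construct_id
        for c in design.constructs.values()
        if all(status.get(fid) == "verified" for fid in c.fragment_ids)
    }


def calls_to_frame(calls: Sequence[PcrCall]) -> pd.DataFrame:
    """Tabular view of calls for CSV persistence."""
    return pd.DataFrame(
        [
            {
                "reaction_id": c.reaction_id,
                "fragment_id": c.fragment_id,
                "round": c.round_no,
                "verdict": c.verdict,
                "matched_size_bp": c.matched_peak[0] if c.matched_peak else "",
                "matched_conc_ng_ul": c.matched_peak[1] if c.matched_peak else "",
                "relative_error": c.relative_error if c.passed else "",
            }
            for c in calls
        ]
    )
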