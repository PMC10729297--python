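"""Campaign state machine: colonies, sequencing verdicts, consolidation, funnel.

The tracker is the ledger of one build campaign.  Records flow forward only —
a colony must belong to a construct that was plated, a sequencing verdict must
name a registered colony — and the whole state serializes losslessly to a JSON
snapshot so a campaign can be resumed, diffed and audited without a database.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .compiler import PcrReaction
from .config import CampaignConfig
from .design_io import Design, export_expected_sequences
from .errors import IntegrityError
from .pcr_qc import PcrCall
from .plate_model import TransferInstruction, WellLocation, address_to_index, allocate


@dataclass(frozen=True)
class ColonyRecord:
    """One picked colony: agar position → overnight-culture well."""

    colony_id: str
    construct_id: str
    source_plate: str
    source_well: str
    culture_plate: str
    culture_well: str
    picked_at: int = 0


@dataclass(frozen=True)
class NgsVerdict:
    """Per-colony sequencing outcome from the NGS service."""

    colony_id: str
    coverage_full: bool
    mutation_count: int

    def __post_init__(self) -> None:
        if self.mutation_count < 0:
            raise ValueError("mutation count must be >= 0")


@dataclass
class BuildState:
    """The campaign ledger across every stage of the build funnel."""

    design_id: str = ""
    n_designed: int = 0
    demand: dict[str, int] = field(default_factory=dict)
    reactions: dict[str, PcrReaction] = field(default_factory=dict)
    calls: list[PcrCall] = field(default_factory=list)
    fragment_status: dict[str, str] = field(default_factory=dict)
    feasible: list[str] = field(default_factory=list)
    assembly_attempted: list[str] = field(default_factory=list)
    yeast_growth: list[str] = field(default_factory=list)
    coli_growth: list[str] = field(default_factory=list)
    plating_layout: dict[str, WellLocation] = field(default_factory=dict)
    colonies: dict[str, ColonyRecord] = field(default_factory=dict)
    verdicts: dict[str, NgsVerdict] = field(default_factory=dict)
    verified_constructs: list[str] = field(default_factory=list)
    consolidation: list[dict] = field(default_factory=list)

    # -- forward-only provenance -------------------------------------------
    def check_provenance(self) -> None:
        """Every stage-k record must reference an entity present at stage k−1."""
        bad = []
        feasible = set(self.feasible)
        if self.feasible and self.demand:
            pass  # feasibility is derived from fragment_status; checked there
        for cid in self.assembly_attempted:
            if feasible and cid not in feasible:
                bad.append(f"assembly:{cid}")
        attempted = set(self.assembly_attempted) or feasible
        for cid in self.yeast_growth:
            if attempted and cid not in attempted:
                bad.append(f"yeast:{cid}")
        grew = set(self.yeast_growth)
        for cid in self.coli_growth:
            if cid not in grew:
                bad.append(f"coli:{cid}")
        plated = set(self.coli_growth)
        for col in self.colonies.values():
            if plated and col.construct_id not in plated:
                bad.append(f"colony:{col.colony_id}")
        for vid in self.verdicts:
            if vid not in self.colonies:
                bad.append(f"verdict:{vid}")
        if bad:
            raise IntegrityError(
                "forward-only provenance violated: " + ", ".join(sorted(bad)), bad
            )

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["reactions"] = {k: _reaction_dict(r) for k, r in self.reactions.items()}
        d["plating_layout"] = {
            k: [v.plate_id, v.address] for k, v in self.plating_layout.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BuildState":
        state = cls(design_id=d["design_id"], n_designed=d["n_designed"])
        state.demand = dict(d["demand"])
        state.reactions = {
            k: _reaction_from_dict(v) for k, v in d["reactions"].items()
        }
        state.calls = [
            PcrCall(
                c["reaction_id"], c["verdict"],
                tuple(c["matched_peak"]) if c["matched_peak"] else None,
                c["relative_error"], c["round_no"], c["fragment_id"],
            )
            for c in d["calls"]
        ]
        state.fragment_status = dict(d["fragment_status"])
        state.feasible = list(d["feasible"])
        state.assembly_attempted = list(d["assembly_attempted"])
        state.yeast_growth = list(d["yeast_growth"])
        state.coli_growth = list(d["coli_growth"])
        state.plating_layout = {
            k: WellLocation(*v) for k, v in d["plating_layout"].items()
        }
        state.colonies = {k: ColonyRecord(**v) for k, v in d["colonies"].items()}
        state.verdicts = {k: NgsVerdict(**v) for k, v in d["verdicts"].items()}
        state.verified_constructs = list(d["verified_constructs"])
        state.consolidation = list(d["consolidation"])
        return state

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BuildState":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _reaction_dict(r: PcrReaction) -> dict:
    d = asdict(r)
    d["layout"] = [r.layout.plate_id, r.layout.address] if r.layout else None
    return d


def _reaction_from_dict(d: dict) -> PcrReaction:
    layout = WellLocation(*d["layout"]) if d["layout"] else None
    return PcrReaction(
        d["reaction_id"], d["fragment_id"], d["template_id"],
        d["forward_oligo_id"], d["reverse_oligo_id"], d["expected_size_bp"],
        d["annealing_c"], d["round_no"], layout,
    )


# ---------------------------------------------------------------------------
# colony registration
# ---------------------------------------------------------------------------

def register_colonies(
    picker_rows: Iterable[Mapping[str, str]] | pd.DataFrame,
    plating_layout: Mapping[str, WellLocation],
    picks_per_construct: int = 3,
) -> tuple[dict[str, ColonyRecord], list[str]]:
    """Build the colony registry from colony-picker output.

    ``picker_rows`` carry source (agar) plate/well and destination (culture)
    plate/well.  Source wells resolve to constructs through the plating
    layout; unknown source wells are reported, not raised.  Rows beyond
    ``picks_per_construct`` for one construct are tolerated with a warning and
    skipped.  A culture-well collision is a hard integrity error.
    """
    if isinstance(picker_rows, pd.DataFrame):
        picker_rows = picker_rows.to_dict("records")
    by_source = {
        (loc.plate_id, loc.address): cid for cid, loc in plating_layout.items()
    }
    registry: dict[str, ColonyRecord] = {}
    unknown: list[str] = []
    used_culture: set[tuple[str, str]] = set()
    per_construct: dict[str, int] = {}
    for i, row in enumerate(picker_rows):
        src = (row["source_plate"], row["source_well"])
        dst = (row["dest_plate"], row["dest_well"])
        cid = by_source.get(src)
        if cid is None:
            unknown.append(f"{src[0]}:{src[1]}")
            continue
        if dst in used_culture:
            raise IntegrityError(
                f"culture well collision at {dst[0]}:{dst[1]}", [f"{dst[0]}:{dst[1]}"]
            )
        n = per_construct.get(cid, 0)
        if n >= picks_per_construct:
            warnings.warn(
                f"construct {cid}: more than {picks_per_construct} colonies "
                "picked; extra row skipped",
                stacklevel=2,
            )
            continue
        used_culture.add(dst)
        per_construct[cid] = n + 1
        colony_id = f"{cid}.c{n + 1}"
        registry[colony_id] = ColonyRecord(
            colony_id, cid, src[0], src[1], dst[0], dst[1], picked_at=i
        )
    return registry, unknown


# ---------------------------------------------------------------------------
# sequencing submission and ingestion
# ---------------------------------------------------------------------------

def ngs_submission(
    registry: Mapping[str, ColonyRecord],
    design: Design,
    sheet_path: str | Path | None = None,
    sequences_path: str | Path | None = None,
    fmt: str = "fasta",
) -> pd.DataFrame:
    """Sample sheet for an NGS service plus an expected-sequence sidecar.

    One row per colony; the ``expected_sequence_id`` column references the
    construct record in the sidecar file (one record per distinct construct).
    """
    rows = [
        {
            "sample_id": col.colony_id,
            "plate": col.culture_plate,
            "well": col.culture_well,
            "construct_id": col.construct_id,
            "expected_sequence_id": col.construct_id,
        }
        for col in sorted(registry.values(), key=lambda c: c.picked_at)
    ]
    sheet = pd.DataFrame(
        rows,
        columns=["sample_id", "plate", "well", "construct_id", "expected_sequence_id"],
    )
    if sheet_path is not None:
        sheet.to_csv(sheet_path, index=False)
    if sequences_path is not None:
        unique = sorted({r["construct_id"] for r in rows})
        export_expected_sequences(design, sequences_path, fmt, unique)
    return sheet


def ingest_ngs(
    verdicts: Iterable[NgsVerdict],
    registry: Mapping[str, ColonyRecord],
    config: CampaignConfig | None = None,
) -> dict[str, bool]:
    """Fold per-colony verdicts into per-construct verification.

    Default policy: a construct is verified iff some colony has full reference
    coverage and zero mutations; both thresholds come from the config.
    """
    config = config or CampaignConfig()
    result: dict[str, bool] = {}
    for col in registry.values():
        result.setdefault(col.construct_id, False)
    for v in verdicts:
        if v.colony_id not in registry:
            raise IntegrityError(f"verdict for unknown colony {v.colony_id!r}")
        ok = v.mutation_count <= config.max_mutations and (
            v.coverage_full or not config.require_full_coverage
        )
        if ok:
            result[registry[v.colony_id].construct_id] = True
    return result


def colony_qualifies(v: NgsVerdict, config: CampaignConfig) -> bool:
    return v.mutation_count <= config.max_mutations and (
        v.coverage_full or not config.require_full_coverage
    )


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def consolidate(
    verdicts: Mapping[str, NgsVerdict],
    registry: Mapping[str, ColonyRecord],
    config: CampaignConfig | None = None,
    volume_ul: float = 50.0,
    verified: Iterable[str] | None = None,
) -> tuple[list[TransferInstruction], pd.DataFrame, list[str]]:
    """Cherry-pick exactly one qualifying colony per verified construct.

    The chosen colony is the lowest (culture plate, well index) among
    qualifiers — deterministic and idempotent.  Verified constructs with no
    qualifying colony are returned in the third element, never silently
    skipped.  Destinations fill ``ceil(n / 96)`` archive plates.
    """
    config = config or CampaignConfig()
    qualifying: dict[str, list[ColonyRecord]] = {}
    for colony_id, v in verdicts.items():
        if colony_id not in registry:
            raise IntegrityError(f"verdict for unknown colony {colony_id!r}")
        if colony_qualifies(v, config):
            col = registry[colony_id]
            qualifying.setdefault(col.construct_id, []).append(col)

    verified_set = (
        sorted(set(verified)) if verified is not None else sorted(qualifying)
    )
    missing = [cid for cid in verified_set if cid not in qualifying]
    chosen: dict[str, ColonyRecord] = {}
    for cid in verified_set:
        if cid in qualifying:
            chosen[cid] = min(
                qualifying[cid],
                key=lambda c: (c.culture_plate,
                               address_to_index(c.culture_well, (8, 12))),
            )

    archive = config.labware["archive96"]
    dest = allocate(list(chosen), archive, config.fill_order, plate_prefix="archive")
    transfers = [
        TransferInstruction(
            chosen[cid].culture_plate, chosen[cid].culture_well,
            dest[cid].plate_id, dest[cid].address, volume_ul,
        )
        for cid in chosen
    ]
    manifest = pd.DataFrame(
        [
            {
                "construct_id": cid,
                "colony_id": chosen[cid].colony_id,
                "source_plate": chosen[cid].culture_plate,
                "source_well": chosen[cid].culture_well,
                "archive_plate": dest[cid].plate_id,
                "archive_well": dest[cid].address,
            }
            for cid in chosen
        ],
        columns=["construct_id", "colony_id", "source_plate", "source_well",
                 "archive_plate", "archive_well"],
    )
    return transfers, manifest, missing


# ---------------------------------------------------------------------------
# funnel report
# ---------------------------------------------------------------------------

#: stage → the stage whose count is its natural denominator (None = absolute)
FUNNEL_STAGES: list[tuple[str, str | None]] = [
    ("designed", None),
    ("fragments_demanded", None),
    ("reactions_run", None),
    ("fragments_verified", "fragments_demanded"),
    ("feasible", "designed"),
    ("assembly_growth", "feasible"),
    ("transformation_growth", "assembly_growth"),
    ("colonies_picked", None),
    ("colony_pcr_pass", "colonies_picked"),
    ("sequenced", "colony_pcr_pass"),
    ("fully_covered", "sequenced"),
    ("zero_mutation", "fully_covered"),
    ("unique_verified", "designed"),
]


def funnel_counts(state: BuildState, config: CampaignConfig | None = None) -> dict[str, int]:
    config = config or CampaignConfig()
    passed_colony_pcr = len(state.verdicts)  # verdicts exist for sequenced colonies
    return {
        "designed": state.n_designed,
        "fragments_demanded": len(state.demand),
        "reactions_run": len({c.reaction_id for c in state.calls}),
        "fragments_verified": sum(
            1 for s in state.fragment_status.values() if s == "verified"
        ),
        "feasible": len(state.feasible),
        "assembly_growth": len(state.yeast_growth),
        "transformation_growth": len(state.coli_growth),
        "colonies_picked": len(state.colonies),
        "colony_pcr_pass": passed_colony_pcr,
        "sequenced": passed_colony_pcr,
        "fully_covered": sum(1 for v in state.verdicts.values() if v.coverage_full),
        "zero_mutation": sum(
            1 for v in state.verdicts.values()
            if v.coverage_full and v.mutation_count == 0
        ),
        "unique_verified": len(set(state.verified_constructs)),
    }


def funnel_report(
    state: BuildState, config: CampaignConfig | None = None
) -> pd.DataFrame:
    """Per-stage counts and survival rates of the build funnel.

    Each stage's rate is its count over its natural denominator stage (empty
    for absolute stages).  ``overall_success`` = unique verified / designed is
    appended as the final row.
    """
    counts = funnel_counts(state, config)
    rows = []
    for stage, denom in FUNNEL_STAGES:
        rate = None
        if denom is not None:
            rate = counts[stage] / counts[denom] if counts[denom] else None
        rows.append({"stage": stage, "count": counts[stage], "rate": rate})
    overall = counts["unique_verified"] / counts["designed"] if counts["designed"] else None
    rows.append(
        {"stage": "overall_success", "count": counts["unique_verified"], "rate": overall}
    )
    return pd.DataFrame(rows, columns=["stage", "count", "rate"])
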