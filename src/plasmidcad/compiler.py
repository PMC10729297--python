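"""Compile a design plus build state into orders, worklists and picklists.

The compiler owns all stoichiometry: how many PCR replicates each fragment
needs given its usage across constructs, which transfers set up each reaction,
how reactions share thermocycler blocks, and how much of each purified
fragment goes into an assembly mix (equivolume or equimolar).

Equimolar dosing uses the average double-stranded DNA molecular weight

    MW(L) = 617.96·L + 36.04  g/mol

so the volume delivering ``m`` fmol of an ``L``-bp fragment at ``c`` ng/µL is
``v = m · MW(L) · 1e-6 / c`` µL, rounded *up* to the acoustic droplet quantum
(the mix never under-delivers moles).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .config import CampaignConfig
from .design_io import Design
from .errors import AddressError, CompileError, VolumeOverflowError
from .plate_model import (
    TransferInstruction,
    WellLocation,
    address_to_index,
    allocate,
    index_to_address,
    parse_address,
    quantize_down,
    quantize_up,
)


@dataclass(frozen=True)
class PcrReaction:
    """One amplification attempt of one fragment in one round."""

    reaction_id: str
    fragment_id: str
    template_id: str
    forward_oligo_id: str
    reverse_oligo_id: str
    expected_size_bp: int
    annealing_c: float
    round_no: int = 1
    layout: WellLocation | None = None

    def __post_init__(self) -> None:
        if self.expected_size_bp <= 0:
            raise ValueError(f"{self.reaction_id}: expected size must be > 0")
        if self.round_no < 1:
            raise ValueError(f"{self.reaction_id}: round must be >= 1")


@dataclass(frozen=True)
class ReagentStock:
    """A stocked reagent: oligo (µM) or purified fragment (ng/µL)."""

    sample_id: str
    location: WellLocation
    concentration: float
    volume_ul: float
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"{self.sample_id}: concentration must be > 0")
        if self.volume_ul < 0:
            raise ValueError(f"{self.sample_id}: volume must be >= 0")


@dataclass(frozen=True)
class MixSpec:
    """How to dose fragments into one assembly reaction."""

    mode: str = "equimolar"  # equimolar | equivolume
    target_total_volume_ul: float = 10.0
    target_fmol_per_part: float = 10.0
    vector_excess_ratio: float = 1.0
    droplet_quantum_nl: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("equimolar", "equivolume"):
            raise ValueError(f"mix mode must be equimolar|equivolume, got {self.mode!r}")
        if self.target_total_volume_ul <= 0:
            raise ValueError("target total volume must be > 0")
        if self.vector_excess_ratio < 0:
            raise ValueError("vector excess ratio must be >= 0")


def ds_molecular_weight(length_bp: int) -> float:
    """Average dsDNA molecular weight in g/mol: 617.96·L + 36.04."""
    return 617.96 * length_bp + 36.04


# ---------------------------------------------------------------------------
# demand and ordering
# ---------------------------------------------------------------------------

def fragment_usage(design: Design) -> dict[str, int]:
    """Number of constructs each fragment appears in."""
    uses = {fid: 0 for fid in design.fragments}
    for c in design.constructs.values():
        for fid in c.fragment_ids:
            uses[fid] += 1
    return uses


def demand_plan(design: Design, capacity_uses_per_reaction: int = 4) -> dict[str, int]:
    """Replicate PCRs per fragment: ``ceil(uses / capacity)``, min 1 if used.

    One PCR product feeds at most ``capacity_uses_per_reaction`` assembly
    reactions; high-use parts in a combinatorial design need replicates.
    Unused fragments get zero reactions.
    """
    if capacity_uses_per_reaction < 1:
        raise ValueError("capacity must be >= 1")
    return {
        fid: math.ceil(n / capacity_uses_per_reaction)
        for fid, n in fragment_usage(design).items()
        if n > 0
    }


def purchase_order(
    design: Design,
    config: CampaignConfig | None = None,
    collapse_duplicates: bool = False,
) -> pd.DataFrame:
    """Vendor 96-well order sheet: one row per unique oligo (Plate, Well, Name, Sequence).

    Distinct oligo ids sharing a sequence trigger a warning; with
    ``collapse_duplicates`` only the first id is ordered.
    """
    config = config or CampaignConfig()
    oligos = list(design.oligos.values())
    seen: dict[str, str] = {}
    rows = []
    for o in oligos:
        if o.sequence in seen:
            warnings.warn(
                f"oligo {o.oligo_id} duplicates sequence of {seen[o.sequence]}",
                stacklevel=2,
            )
            if collapse_duplicates:
                continue
        else:
            seen[o.sequence] = o.oligo_id
        rows.append(o)
    layout = allocate(
        [o.oligo_id for o in rows], config.labware["pcr96"],
        config.fill_order, plate_prefix="order",
    )
    return pd.DataFrame(
        [
            {
                "Plate": layout[o.oligo_id].plate_id,
                "Well": layout[o.oligo_id].address,
                "Name": o.name or o.oligo_id,
                "Sequence": o.sequence,
            }
            for o in rows
        ],
        columns=["Plate", "Well", "Name", "Sequence"],
    )


# ---------------------------------------------------------------------------
# PCR planning and setup
# ---------------------------------------------------------------------------

def annealing_temperature(design: Design, fragment_id: str) -> float:
    """Annealing temperature for a fragment's PCR: min primer Tm (nearest 0.1 °C)."""
    f = design.fragments[fragment_id]
    tms = []
    for oid in (f.forward_oligo_id, f.reverse_oligo_id):
        o = design.oligos.get(oid)
        if o is None:
            return 60.0  # no primer record; fall back to a routine default
        tms.append(MeltingTemp.Tm_NN(o.sequence))
    return round(min(tms), 1)


def plan_reactions(
    design: Design,
    config: CampaignConfig | None = None,
    round_no: int = 1,
) -> list[PcrReaction]:
    """Expand the demand plan into laid-out first-round reactions."""
    config = config or CampaignConfig()
    demand = demand_plan(design, config.capacity_uses_per_reaction)
    reactions = []
    for fid in sorted(demand):
        f = design.fragments[fid]
        temp = annealing_temperature(design, fid)
        for rep in range(1, demand[fid] + 1):
            reactions.append(
                PcrReaction(
                    reaction_id=f"{fid}.r{round_no}.{rep}",
                    fragment_id=fid,
                    template_id=f.template_id,
                    forward_oligo_id=f.forward_oligo_id,
                    reverse_oligo_id=f.reverse_oligo_id,
                    expected_size_bp=f.length_bp,
                    annealing_c=temp,
                    round_no=round_no,
                )
            )
    layout = allocate(
        [r.reaction_id for r in reactions], config.labware["pcr96"],
        config.fill_order, plate_prefix=f"pcr_r{round_no}_",
    )
    return [replace(r, layout=layout[r.reaction_id]) for r in reactions]


def pcr_setup(
    reactions: Sequence[PcrReaction],
    oligo_stocks: Mapping[str, ReagentStock],
    template_stocks: Mapping[str, ReagentStock],
    config: CampaignConfig | None = None,
) -> list[TransferInstruction]:
    """Acoustic picklist dispensing primers and template for each reaction.

    Three transfers per reaction (forward, reverse, template) at the recipe
    volumes, quantized up to the droplet quantum. All stocks are checked
    before any transfer is emitted; missing reagents raise a
    :class:`CompileError` listing every blocked reaction.
    """
    config = config or CampaignConfig()
    blocked = []
    for r in reactions:
        missing = [
            oid for oid in (r.forward_oligo_id, r.reverse_oligo_id)
            if oid not in oligo_stocks
        ]
        if r.template_id not in template_stocks:
            missing.append(r.template_id)
        if missing:
            blocked.append(f"{r.reaction_id} (missing {', '.join(missing)})")
    if blocked:
        raise CompileError(
            f"{len(blocked)} reaction(s) blocked by missing stocks", blocked
        )

    v_primer = quantize_up(config.primer_volume_ul, config.droplet_quantum_nl)
    v_template = quantize_up(config.template_volume_ul, config.droplet_quantum_nl)
    transfers = []
    for r in reactions:
        if r.layout is None:
            raise CompileError(f"reaction {r.reaction_id} has no plate layout")
        for stock, vol in (
            (oligo_stocks[r.forward_oligo_id], v_primer),
            (oligo_stocks[r.reverse_oligo_id], v_primer),
            (template_stocks[r.template_id], v_template),
        ):
            transfers.append(
                TransferInstruction(
                    stock.location.plate_id, stock.location.address,
                    r.layout.plate_id, r.layout.address, vol,
                )
            )
    return transfers


@dataclass(frozen=True)
class ThermocyclerGroup:
    reaction_ids: tuple[str, ...]
    annealing_c: float
    extension_s: int


def thermocycler_groups(
    reactions: Sequence[PcrReaction],
    max_groups: int = 8,
    config: CampaignConfig | None = None,
) -> list[ThermocyclerGroup]:
    """Partition reactions into thermocycler blocks by annealing temperature.

    Greedy span-limited clustering on the sorted temperatures (default span
    2 °C).  If that yields more than ``max_groups`` blocks, the smallest span
    meeting the cap is found by bisection over the pairwise temperature gaps —
    optimal for contiguous partitions of 1-D data.  Each group runs at its
    coolest member's annealing temperature (permissive for every member) with
    extension time sized for its largest product.
    """
    if max_groups < 1:
        raise ValueError("max_groups must be >= 1")
    if not reactions:
        return []
    config = config or CampaignConfig()
    rs = sorted(reactions, key=lambda r: (r.annealing_c, r.reaction_id))
    temps = [r.annealing_c for r in rs]

    def greedy_count(span: float) -> int:
        groups, start = 1, temps[0]
        for t in temps[1:]:
            if t - start > span + 1e-9:
                groups += 1
                start = t
        return groups

    span = config.annealing_span_c
    if greedy_count(span) > max_groups:
        candidates = sorted({tj - ti for ti in temps for tj in temps if tj > ti})
        lo, hi = 0, len(candidates) - 1
        span = candidates[-1]
        while lo <= hi:
            mid = (lo + hi) // 2
            if greedy_count(candidates[mid]) <= max_groups:
                span = candidates[mid]
                hi = mid - 1
            else:
                lo = mid + 1

    groups: list[list[PcrReaction]] = [[rs[0]]]
    start = temps[0]
    for r in rs[1:]:
        if r.annealing_c - start > span + 1e-9:
            groups.append([])
            start = r.annealing_c
        groups[-1].append(r)

    rate_bp_per_s = 1000.0 / config.extension_s_per_kb
    return [
        ThermocyclerGroup(
            reaction_ids=tuple(r.reaction_id for r in g),
            annealing_c=min(r.annealing_c for r in g),
            extension_s=math.ceil(max(r.expected_size_bp for r in g) / rate_bp_per_s),
        )
        for g in groups
    ]


# ---------------------------------------------------------------------------
# assembly mixing
# ---------------------------------------------------------------------------

def equimolar_volumes(
    parts: Sequence[ReagentStock],
    spec: MixSpec,
    vector_ids: frozenset[str] | set[str] = frozenset(),
) -> dict[str, float]:
    """Per-part volumes (µL) delivering equal moles of every part.

    Vector parts are scaled by ``spec.vector_excess_ratio``.  Raises
    :class:`VolumeOverflowError` if the doses exceed the target total volume —
    the mix is never silently rescaled.
    """
    volumes: dict[str, float] = {}
    for p in parts:
        if p.length_bp is None:
            raise CompileError(f"equimolar mode: {p.sample_id} has no length")
        fmol = spec.target_fmol_per_part
        if p.sample_id in vector_ids:
            fmol *= spec.vector_excess_ratio
        mass_ng = fmol * ds_molecular_weight(p.length_bp) * 1e-6
        volumes[p.sample_id] = quantize_up(
            mass_ng / p.concentration, spec.droplet_quantum_nl
        )
    total = sum(volumes.values())
    if total > spec.target_total_volume_ul + 1e-9:
        raise VolumeOverflowError(
            f"equimolar doses sum to {total:.3f} µL, exceeding the "
            f"{spec.target_total_volume_ul} µL target"
        )
    return volumes


def equivolume_volumes(
    part_ids: Sequence[str], spec: MixSpec
) -> tuple[dict[str, float], float]:
    """Equal volumes per part (rounded down to the quantum) plus water remainder."""
    if not part_ids:
        return {}, spec.target_total_volume_ul
    share = quantize_down(
        spec.target_total_volume_ul / len(part_ids), spec.droplet_quantum_nl
    )
    volumes = {pid: share for pid in part_ids}
    water = spec.target_total_volume_ul - share * len(part_ids)
    return volumes, round(water, 9)


def assembly_picklists(
    construct_ids: Sequence[str],
    design: Design,
    fragment_stocks: Mapping[str, ReagentStock],
    spec: MixSpec,
    config: CampaignConfig | None = None,
) -> tuple[list[TransferInstruction], dict[str, WellLocation]]:
    """Picklist mixing each feasible construct's fragments into one well.

    Destination wells are allocated deterministically, one per construct.
    Requesting a construct whose fragments are not all stocked raises a
    :class:`CompileError` naming the missing fragments.
    """
    config = config or CampaignConfig()
    missing: list[str] = []
    for cid in construct_ids:
        c = design.constructs[cid]
        gaps = [fid for fid in c.fragment_ids if fid not in fragment_stocks]
        if gaps:
            missing.append(f"{cid} (missing {', '.join(gaps)})")
    if missing:
        raise CompileError(
            f"{len(missing)} construct(s) not buildable from stocks", missing
        )

    dest = allocate(
        list(construct_ids), config.labware["pcr96"], config.fill_order,
        plate_prefix="assembly",
    )
    vector_part_ids = {p.part_id for p in design.parts.values() if p.role == "vector"}
    transfers = []
    for cid in construct_ids:
        c = design.constructs[cid]
        stocks = [fragment_stocks[fid] for fid in c.fragment_ids]
        if spec.mode == "equimolar":
            vec = {
                s.sample_id for s in stocks
                if design.fragments[s.sample_id].part_id in vector_part_ids
            }
            vols = equimolar_volumes(stocks, spec, vec)
        else:
            vols, _ = equivolume_volumes([s.sample_id for s in stocks], spec)
        for s in stocks:
            transfers.append(
                TransferInstruction(
                    s.location.plate_id, s.location.address,
                    dest[cid].plate_id, dest[cid].address, vols[s.sample_id],
                )
            )
    return transfers, dest


# ---------------------------------------------------------------------------
# bench worklists
# ---------------------------------------------------------------------------

BENCH_STAGES = ("consolidate_pcr", "bead_purify", "dpni_digest", "transform", "plate_qtray")


def bench_worklists(
    stage: str,
    source_layout: Mapping[str, WellLocation | Sequence[WellLocation]],
    config: CampaignConfig | None = None,
    volume_ul: float | Mapping[str, float] = 20.0,
    dest_prefix: str | None = None,
    dest_labware: str = "pcr96",
) -> tuple[list[TransferInstruction], dict[str, WellLocation]]:
    """Deterministic plate-to-plate worklist for one bench stage.

    ``volume_ul`` is either one constant or a per-sample mapping (pooled wells
    carry more liquid forward than single-replicate ones).

    ``consolidate_pcr`` pools each sample's source wells (e.g. all passing
    replicates of a verified fragment) into one well on fresh plates, so the
    output well count equals the number of distinct samples, not reactions;
    ``bead_purify``/``dpni_digest``/``transform`` map wells 1:1 onto a
    same-geometry destination; ``plate_qtray`` spreads each 96-well plate onto
    two 48-well agar trays.
    """
    config = config or CampaignConfig()
    if stage not in BENCH_STAGES:
        raise ValueError(f"unknown bench stage {stage!r}")
    prefix = dest_prefix or stage
    sample_ids = list(source_layout)

    def vol(sid: str) -> float:
        return volume_ul[sid] if isinstance(volume_ul, Mapping) else volume_ul

    def sources(sid: str) -> list[WellLocation]:
        v = source_layout[sid]
        return list(v) if isinstance(v, (list, tuple)) else [v]

    def single(sid: str) -> WellLocation:
        locs = sources(sid)
        if len(locs) != 1:
            raise ValueError(f"{stage}: sample {sid} must have exactly one source well")
        return locs[0]

    if stage == "consolidate_pcr":
        dest = allocate(sample_ids, config.labware[dest_labware],
                        config.fill_order, plate_prefix=prefix)
        transfers = [
            TransferInstruction(loc.plate_id, loc.address,
                                dest[sid].plate_id, dest[sid].address, vol(sid))
            for sid in sample_ids
            for loc in sources(sid)
        ]
        return transfers, dest
    elif stage == "plate_qtray":
        qtray = config.labware["qtray48"]
        dest = {}
        for sid in sample_ids:
            loc = single(sid)
            idx = address_to_index(loc.address, (8, 12), "row_major")
            tray_no = idx // qtray.n_wells + 1
            dest[sid] = WellLocation(
                f"{prefix}_{loc.plate_id}_t{tray_no}",
                index_to_address(idx % qtray.n_wells, qtray, "row_major"),
            )
    else:  # 1:1 stamping stages
        dest = {}
        for sid in sample_ids:
            loc = single(sid)
            r, c = parse_address(loc.address)
            if r >= 8 or c >= 12:
                raise AddressError(
                    f"{stage}: source well {loc.address} not on a 96-well plate"
                )
            dest[sid] = WellLocation(f"{prefix}_{loc.plate_id}", loc.address)

    transfers = [
        TransferInstruction(
            single(sid).plate_id, single(sid).address,
            dest[sid].plate_id, dest[sid].address, vol(sid),
        )
        for sid in sample_ids
    ]
    return transfers, dest


# ---------------------------------------------------------------------------
# emission manifest
# ---------------------------------------------------------------------------

class Manifest:
    """Log of emitted files: path → stage → sha256 of content."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.entries: list[dict[str, str]] = []
        if self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def record(self, emitted: str | Path, stage: str) -> None:
        emitted = Path(emitted)
        digest = hashlib.sha256(emitted.read_bytes()).hexdigest()
        self.entries.append(
            {"file": emitted.name, "stage": stage, "sha256": digest}
        )
        self.path.write_text(json.dumps(self.entries, indent=2))
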