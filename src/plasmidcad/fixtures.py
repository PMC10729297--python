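"""Synthetic campaign generator: designs, instrument outputs, and a closed-loop build.

This module fabricates everything a build campaign consumes — combinatorial
designs, capillary-electrophoresis peak tables, colony-picker output, and
sequencing verdicts — with the statistical structure of a real plasmid
campaign, so every stage and the end-to-end pipeline are testable offline.

The generative model is deliberately simple: each wet-lab stage is an
independent Bernoulli trial per entity (per PCR, per yeast transformation,
per colony...), with stage probabilities defaulting to rates observed in a
large published combinatorial build, and PCR product sizes blurred by
multiplicative Gaussian noise.  Every latent outcome is logged as ground
truth, so with all probabilities at 1 and zero noise the pipeline must
recover the ground truth exactly.

Designs use a shared inter-bin junction model: consecutive bins exchange a
fixed ``homology_bp``-long linker, so every full-factorial combination of
parts has exact overlaps by construction (as docking-domain libraries do in
practice).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compiler import (
    MixSpec,
    PcrReaction,
    ReagentStock,
    assembly_picklists,
    demand_plan,
    pcr_setup,
    plan_reactions,
    bench_worklists,
)
from .config import CampaignConfig, LabwareDef
from .design_io import (
    Design,
    Fragment,
    Oligo,
    Part,
    TargetConstruct,
    write_design,
)
from .pcr_qc import (
    PcrCall,
    PeakTable,
    call_plate,
    call_reaction,
    feasible_constructs,
    fragment_status,
    redo_plan,
    write_peak_table,
)
from .plate_model import (
    Plate,
    TransferInstruction,
    WellLocation,
    allocate,
    apply_transfers,
    write_picklist,
)
from .tracker import (
    BuildState,
    NgsVerdict,
    funnel_report,
    consolidate,
    ingest_ngs,
    ngs_submission,
    register_colonies,
)

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CampaignSimConfig:
    """Conditions of one simulated build campaign.

    Stage probabilities default to empirical per-stage survival rates of a
    published ~900-construct combinatorial build (PCR verification 0.88,
    yeast assembly growth 0.66, E. coli transformation 0.70, colony-PCR pass
    0.41, full sequencing coverage 0.76, zero mutations 0.65).  The default
    design is a 3-bin full factorial of 2×3×4 = 24 constructs with a 60-bp
    homology linker between bins.
    """

    n_bins: int = 3
    parts_per_bin: int | tuple[int, ...] = (2, 3, 4)
    fragment_length_range: tuple[int, int] = (1000, 3000)
    homology_bp: int = 60
    pcr_pass: float = 0.88
    yeast_growth: float = 0.66
    coli_growth: float = 0.70
    colony_pcr_pass: float = 0.41
    full_coverage: float = 0.76
    zero_mutation: float = 0.65
    size_noise_sd: float = 0.03
    seed: int = 0
    include_sequences: bool = True

    def __post_init__(self) -> None:
        for name in ("pcr_pass", "yeast_growth", "coli_growth",
                     "colony_pcr_pass", "full_coverage", "zero_mutation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_bins < 2:
            raise ValueError("a combinatorial design needs at least 2 bins")

    @property
    def stage_probs(self) -> dict[str, float]:
        return {
            "pcr_pass": self.pcr_pass,
            "yeast_growth": self.yeast_growth,
            "coli_growth": self.coli_growth,
            "colony_pcr_pass": self.colony_pcr_pass,
            "full_coverage": self.full_coverage,
            "zero_mutation": self.zero_mutation,
        }

    @property
    def bin_sizes(self) -> tuple[int, ...]:
        if isinstance(self.parts_per_bin, int):
            return (self.parts_per_bin,) * self.n_bins
        if len(self.parts_per_bin) != self.n_bins:
            raise ValueError("parts_per_bin length must equal n_bins")
        return tuple(self.parts_per_bin)

    def all_success(self) -> "CampaignSimConfig":
        """The perfect-information limit: every stage succeeds, zero noise."""
        return replace(
            self, pcr_pass=1.0, yeast_growth=1.0, coli_growth=1.0,
            colony_pcr_pass=1.0, full_coverage=1.0, zero_mutation=1.0,
            size_noise_sd=0.0,
        )


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

def generate_design(config: CampaignSimConfig, design_id: str | None = None) -> Design:
    """Full-factorial combinatorial design with exact inter-bin overlaps.

    Bin 0 holds vector parts; each fragment is its part's core flanked by the
    two junction linkers it shares with its neighbouring bins, so adjacent
    fragments of *every* construct overlap by exactly ``homology_bp``.
    Constructs are the cartesian product of the bins (circular plasmids).
    Seeded and bit-for-bit reproducible.
    """
    rng = np.random.default_rng(config.seed)
    h = config.homology_bp
    lo, hi = config.fragment_length_range
    if lo <= 2 * h + 20:
        raise ValueError(
            f"fragment length range {config.fragment_length_range} too small "
            f"for two {h}-bp homology arms plus a core"
        )
    sizes = config.bin_sizes
    n = len(sizes)
    design = Design(design_id=design_id or f"sim{config.seed}", homology_bp=h)

    # linkers[i] joins bin i to bin (i+1) % n
    linkers = [_random_seq(rng, h) if config.include_sequences else "" for _ in range(n)]

    for i, n_parts in enumerate(sizes):
        role = "vector" if i == 0 else "insert"
        for j in range(n_parts):
            part_id = f"b{i}p{j}"
            frag_id = f"f_{part_id}"
            length = int(rng.integers(lo, hi + 1))
            core_len = length - 2 * h
            if config.include_sequences:
                core = _random_seq(rng, core_len)
                frag_seq = linkers[(i - 1) % n] + core + linkers[i]
                fwd = frag_seq[h - 10:h + 10]
                rev = _revcomp(frag_seq[length - h - 10:length - h + 10])
                design.parts[part_id] = Part(part_id, core, f"bin{i}", role)
            else:
                frag_seq = None
                fwd = _random_seq(rng, 20)
                rev = _random_seq(rng, 20)
            for suffix, seq in (("F", fwd), ("R", rev)):
                oid = f"{frag_id}_{suffix}"
                design.oligos[oid] = Oligo(oid, seq, name=oid)
            design.fragments[frag_id] = Fragment(
                fragment_id=frag_id, part_id=part_id, length_bp=length,
                left_overlap_bp=h, right_overlap_bp=h,
                template_id=f"tpl_{part_id}",
                forward_oligo_id=f"{frag_id}_F", reverse_oligo_id=f"{frag_id}_R",
                sequence=frag_seq,
            )

    combos = itertools.product(*[
        [f"f_b{i}p{j}" for j in range(n_parts)] for i, n_parts in enumerate(sizes)
    ])
    for k, frag_ids in enumerate(combos):
        cid = f"C{k:05d}"
        design.constructs[cid] = TargetConstruct(cid, tuple(frag_ids), circular=True)
    design.validate()
    return design


def generate_design_bundle(
    config: CampaignSimConfig, bundle_dir: str | Path
) -> Design:
    """Generate a design and write its bundle files (byte-identical per seed)."""
    design = generate_design(config)
    write_design(design, bundle_dir)
    return design


# ---------------------------------------------------------------------------
# campaign simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent outcomes of every simulated stage, for exact-recovery assertions."""

    reaction_success: dict[str, bool] = field(default_factory=dict)
    yeast: dict[str, bool] = field(default_factory=dict)
    coli: dict[str, bool] = field(default_factory=dict)
    colony_pcr: dict[str, bool] = field(default_factory=dict)
    coverage: dict[str, bool] = field(default_factory=dict)
    mutations: dict[str, int] = field(default_factory=dict)


@dataclass
class CampaignResult:
    """Everything one simulated campaign produced."""

    design: Design
    state: BuildState
    funnel: pd.DataFrame
    ground_truth: GroundTruth
    picklists: dict[str, list[TransferInstruction]]
    peak_tables: dict[str, PeakTable]
    picker_rows: list[dict[str, str]]
    plates: dict[str, Plate]
    calls: list[PcrCall]


def _ensure_plates(
    plates: dict[str, Plate],
    transfers: Sequence[TransferInstruction],
    labware: LabwareDef,
) -> None:
    for t in transfers:
        if t.dest_plate not in plates:
            plates[t.dest_plate] = Plate(t.dest_plate, labware)


def _simulate_peaks(
    rng: np.random.Generator,
    reactions: Sequence[PcrReaction],
    config: CampaignSimConfig,
    gt: GroundTruth,
) -> dict[str, PeakTable]:
    """Draw per-reaction outcomes and build one peak table per PCR plate.

    A successful reaction yields a peak at the expected size times
    ``1 + N(0, size_noise_sd)``; a failure yields either a grossly wrong-sized
    product or an empty lane (half and half).
    """
    tables: dict[str, dict[str, list[tuple[int, float]]]] = {}
    for r in reactions:
        assert r.layout is not None
        wells = tables.setdefault(r.layout.plate_id, {})
        success = bool(rng.random() < config.pcr_pass)
        gt.reaction_success[r.reaction_id] = success
        conc = float(rng.uniform(5.0, 50.0))
        if success:
            size = max(1, int(round(
                r.expected_size_bp * (1.0 + rng.normal(0.0, config.size_noise_sd))
            )))
            wells[r.layout.address] = [(size, conc)]
        elif rng.random() < 0.5:
            factor = rng.uniform(1.5, 2.5) if rng.random() < 0.5 else rng.uniform(0.3, 0.6)
            wells[r.layout.address] = [(max(1, int(r.expected_size_bp * factor)), conc)]
        else:
            wells[r.layout.address] = []
    return {
        pid: PeakTable(wells=w, plate_id=pid) for pid, w in sorted(tables.items())
    }


def simulate_campaign(
    design: Design,
    sim: CampaignSimConfig,
    config: CampaignConfig | None = None,
    emit_dir: str | Path | None = None,
) -> CampaignResult:
    """Run a full closed-loop campaign on synthetic instrument data.

    Compiles real picklists at every stage, simulates them against plate
    volumes (validation precedes every mutation), feeds synthetic peak tables
    back through QC and redo planning, and tracks the campaign to the
    consolidated archive.  Entirely driven by ``sim.seed``.
    """
    rng = np.random.default_rng(sim.seed)
    config = config or CampaignConfig(homology_bp=design.homology_bp)
    gt = GroundTruth()
    state = BuildState(design_id=design.design_id, n_designed=len(design.constructs))
    plates: dict[str, Plate] = {}
    picklists: dict[str, list[TransferInstruction]] = {}
    peak_tables: dict[str, PeakTable] = {}

    # reagent stocks on acoustic source plates
    echo = config.labware["echo_source_384"]
    oligo_ids = sorted(design.oligos)
    template_ids = sorted({f.template_id for f in design.fragments.values()})
    oligo_layout = allocate(oligo_ids, echo, config.fill_order, "oligo_src")
    template_layout = allocate(template_ids, echo, config.fill_order, "tpl_src")
    for sid, loc in {**oligo_layout, **template_layout}.items():
        plates.setdefault(loc.plate_id, Plate(loc.plate_id, echo))
        plates[loc.plate_id].fill(loc.address, sid, 40.0)
    oligo_stocks = {
        oid: ReagentStock(oid, oligo_layout[oid], 100.0, 40.0) for oid in oligo_ids
    }
    template_stocks = {
        tid: ReagentStock(tid, template_layout[tid], 10.0, 40.0)
        for tid in template_ids
    }

    # --- PCR rounds with QC and redo planning -----------------------------
    state.demand = demand_plan(design, config.capacity_uses_per_reaction)
    reactions = plan_reactions(design, config)
    reaction_index: dict[str, PcrReaction] = {}
    all_calls: list[PcrCall] = []
    pcr96 = config.labware["pcr96"]
    round_no = 0
    while reactions:
        round_no = reactions[0].round_no
        reaction_index.update({r.reaction_id: r for r in reactions})
        transfers = pcr_setup(reactions, oligo_stocks, template_stocks, config)
        _ensure_plates(plates, transfers, pcr96)
        apply_transfers(plates, transfers)
        picklists[f"pcr_setup_r{round_no}"] = transfers
        # thermal cycling replaces each reaction well with amplified product
        for r in reactions:
            assert r.layout is not None
            plates[r.layout.plate_id].wells[r.layout.address] = [(r.reaction_id, 50.0)]
        tables = _simulate_peaks(rng, reactions, sim, gt)
        peak_tables.update(tables)
        by_plate: dict[str, list[PcrReaction]] = {}
        for r in reactions:
            by_plate.setdefault(r.layout.plate_id, []).append(r)
        round_calls: list[PcrCall] = []
        for pid in sorted(by_plate):
            round_calls.extend(call_plate(by_plate[pid], tables[pid], config))
        all_calls.extend(round_calls)
        reactions = redo_plan(round_calls, reaction_index, round_no, config)

    state.reactions = reaction_index
    state.calls = all_calls
    state.fragment_status = fragment_status(
        all_calls, state.demand, config.max_pcr_rounds
    )
    feasible = sorted(feasible_constructs(design, state.fragment_status))
    state.feasible = feasible

    # --- consolidate passing replicates, purify, digest -------------------
    passing_wells: dict[str, list[WellLocation]] = {}
    for call in all_calls:
        if call.passed:
            loc = reaction_index[call.reaction_id].layout
            assert loc is not None
            passing_wells.setdefault(call.fragment_id, []).append(loc)
    # pooled wells scale with replicate count; downstream volumes follow them
    deep = config.labware["deep96"]
    reps = {fid: len(locs) for fid, locs in passing_wells.items()}
    cons_tr, cons_layout = bench_worklists(
        "consolidate_pcr", passing_wells, config, volume_ul=45.0,
        dest_labware="deep96",
    )
    _ensure_plates(plates, cons_tr, deep)
    apply_transfers(plates, cons_tr)
    picklists["consolidate_pcr"] = cons_tr

    pur_tr, pur_layout = bench_worklists(
        "bead_purify", cons_layout, config,
        {fid: 45.0 * reps[fid] - 15.0 for fid in cons_layout},
    )
    _ensure_plates(plates, pur_tr, deep)
    apply_transfers(plates, pur_tr)
    picklists["bead_purify"] = pur_tr

    dig_tr, dig_layout = bench_worklists(
        "dpni_digest", pur_layout, config,
        {fid: 45.0 * reps[fid] - 30.0 for fid in pur_layout},
    )
    _ensure_plates(plates, dig_tr, deep)
    apply_transfers(plates, dig_tr)
    picklists["dpni_digest"] = dig_tr

    # --- assembly mixing ---------------------------------------------------
    fragment_stocks = {
        fid: ReagentStock(
            fid, dig_layout[fid], float(rng.uniform(40.0, 80.0)),
            45.0 * reps[fid] - 30.0,
            length_bp=design.fragments[fid].length_bp,
        )
        for fid in sorted(dig_layout)
    }
    mix = MixSpec(
        mode=config.mix_mode,
        target_total_volume_ul=config.target_total_volume_ul,
        target_fmol_per_part=config.target_fmol_per_part,
        vector_excess_ratio=config.vector_excess_ratio,
        droplet_quantum_nl=config.droplet_quantum_nl,
    )
    asm_tr, asm_layout = assembly_picklists(
        feasible, design, fragment_stocks, mix, config
    )
    _ensure_plates(plates, asm_tr, pcr96)
    apply_transfers(plates, asm_tr)
    picklists["assembly"] = asm_tr
    state.assembly_attempted = list(feasible)
    for cid, loc in asm_layout.items():  # water backfill to the mix total
        gap = config.target_total_volume_ul - plates[loc.plate_id].well_volume(loc.address)
        if gap > 1e-9:
            plates[loc.plate_id].fill(loc.address, "water", gap)

    # --- yeast assembly, extraction, E. coli transformation ----------------
    grew = []
    for cid in feasible:
        ok = bool(rng.random() < sim.yeast_growth)
        gt.yeast[cid] = ok
        if ok:
            grew.append(cid)
    state.yeast_growth = grew

    ext_layout = allocate(grew, pcr96, config.fill_order, "extract")
    for cid, loc in ext_layout.items():
        plates.setdefault(loc.plate_id, Plate(loc.plate_id, pcr96))
        plates[loc.plate_id].fill(loc.address, f"{cid}.plasmid", 20.0)
    tfm_tr, tfm_layout = bench_worklists("transform", ext_layout, config, 5.0)
    _ensure_plates(plates, tfm_tr, deep)
    apply_transfers(plates, tfm_tr)
    picklists["transform"] = tfm_tr
    for cid, loc in tfm_layout.items():  # recovery medium added in bulk
        gap = 500.0 - plates[loc.plate_id].well_volume(loc.address)
        plates[loc.plate_id].fill(loc.address, "medium", gap)

    coli = []
    for cid in grew:
        ok = bool(rng.random() < sim.coli_growth)
        gt.coli[cid] = ok
        if ok:
            coli.append(cid)
    state.coli_growth = coli

    qtr_tr, plating = bench_worklists("plate_qtray", tfm_layout, config, 100.0)
    _ensure_plates(plates, qtr_tr, config.labware["qtray48"])
    apply_transfers(plates, qtr_tr)
    picklists["plate_qtray"] = qtr_tr
    state.plating_layout = plating

    # --- colony picking ----------------------------------------------------
    colony_slots = [
        (cid, k) for cid in coli for k in range(config.picks_per_construct)
    ]
    culture_layout = allocate(
        [f"{cid}.pick{k}" for cid, k in colony_slots], deep, config.fill_order,
        "culture",
    )
    picker_rows = [
        {
            "source_plate": plating[cid].plate_id,
            "source_well": plating[cid].address,
            "dest_plate": culture_layout[f"{cid}.pick{k}"].plate_id,
            "dest_well": culture_layout[f"{cid}.pick{k}"].address,
        }
        for cid, k in colony_slots
    ]
    registry, _unknown = register_colonies(
        picker_rows, plating, config.picks_per_construct
    )
    state.colonies = registry
    for col in registry.values():
        plates.setdefault(col.culture_plate, Plate(col.culture_plate, deep))
        plates[col.culture_plate].fill(col.culture_well, col.colony_id, 1000.0)

    # --- colony PCR (full-CDS size check), sequencing, verdicts -------------
    from .design_io import expected_size  # local import avoids cycle at module load

    verdicts: dict[str, NgsVerdict] = {}
    for colony_id in sorted(registry):
        col = registry[colony_id]
        ok = bool(rng.random() < sim.colony_pcr_pass)
        gt.colony_pcr[colony_id] = ok
        cds = expected_size(design.constructs[col.construct_id], design)
        pseudo = PcrReaction(
            reaction_id=f"cpcr.{colony_id}", fragment_id=col.construct_id,
            template_id=colony_id, forward_oligo_id="", reverse_oligo_id="",
            expected_size_bp=cds, annealing_c=55.0,
        )
        if ok:
            size = max(1, int(round(cds * (1.0 + rng.normal(0.0, sim.size_noise_sd)))))
            peaks = [(size, float(rng.uniform(5.0, 50.0)))]
        else:
            peaks = []
        call = call_reaction(pseudo, peaks, config.size_tolerance,
                             config.min_concentration_ng_ul)
        if call.passed:
            covered = bool(rng.random() < sim.full_coverage)
            muts = 0 if rng.random() < sim.zero_mutation else int(rng.integers(1, 6))
            gt.coverage[colony_id] = covered
            gt.mutations[colony_id] = muts
            verdicts[colony_id] = NgsVerdict(colony_id, covered, muts)
    state.verdicts = verdicts

    verified_map = ingest_ngs(verdicts.values(), registry, config)
    state.verified_constructs = sorted(
        cid for cid, ok in verified_map.items() if ok
    )

    cons2_tr, manifest, _missing = consolidate(verdicts, registry, config, 50.0)
    _ensure_plates(plates, cons2_tr, config.labware["archive96"])
    apply_transfers(plates, cons2_tr)
    picklists["consolidate_archive"] = cons2_tr
    state.consolidation = manifest.to_dict("records")
    state.check_provenance()

    funnel = funnel_report(state, config)
    result = CampaignResult(
        design=design, state=state, funnel=funnel, ground_truth=gt,
        picklists=picklists, peak_tables=peak_tables,
        picker_rows=picker_rows, plates=plates, calls=all_calls,
    )
    if emit_dir is not None:
        write_campaign_files(result, emit_dir, config)
    return result


def write_campaign_files(
    result: CampaignResult, out_dir: str | Path, config: CampaignConfig | None = None
) -> Path:
    """Emit every campaign artifact as delimited text under ``out_dir``."""
    config = config or CampaignConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(result.design, out / "design_bundle")
    for pid, table in result.peak_tables.items():
        write_peak_table(table, out / f"peaks_{pid}.csv")
    for stage, transfers in result.picklists.items():
        write_picklist(transfers, out / f"picklist_{stage}.csv")
    pd.DataFrame(result.picker_rows).to_csv(out / "picker_output.csv", index=False)
    pd.DataFrame(
        [
            {"sample_id": v.colony_id,
             "coverage": "full" if v.coverage_full else "partial",
             "mutations": v.mutation_count}
            for v in result.state.verdicts.values()
        ],
        columns=["sample_id", "coverage", "mutations"],
    ).to_csv(out / "ngs_verdicts.csv", index=False)
    if result.state.colonies and result.design.parts:
        ngs_submission(
            result.state.colonies, result.design,
            out / "ngs_submission.csv", out / "expected_sequences.fasta",
        )
    result.funnel.to_csv(out / "funnel.csv", index=False)
    result.state.save(out / "state.json")
    return out
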