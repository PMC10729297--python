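"""Demand, ordering, PCR setup, thermocycler grouping and mix stoichiometry."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from plasmidcad import (
    CampaignConfig,
    CampaignSimConfig,
    Design,
    MixSpec,
    Oligo,
    PcrReaction,
    ReagentStock,
    TargetConstruct,
    WellLocation,
    assembly_picklists,
    bench_worklists,
    demand_plan,
    ds_molecular_weight,
    equimolar_volumes,
    equivolume_volumes,
    generate_design,
    pcr_setup,
    plan_reactions,
    purchase_order,
    thermocycler_groups,
)
from plasmidcad.compiler import fragment_usage
from plasmidcad.errors import CompileError, VolumeOverflowError

from helpers_oracles import oracle_demand, oracle_thermocycler


# ---------------------------------------------------------------------------
# demand planning
# ---------------------------------------------------------------------------

def test_demand_ceiling_rule(small_design):
    plan = demand_plan(small_design, 4)
    uses = fragment_usage(small_design)
    for fid, count in plan.items():
        assert count == math.ceil(uses[fid] / 4)
    # a fragment used once needs one reaction regardless of capacity
    d = small_design
    single = Design("one", homology_bp=60)
    single.fragments = {k: d.fragments[k] for k in list(d.fragments)[:2]}
    f1, f2 = list(single.fragments)
    single.constructs["c"] = TargetConstruct("c", (f1, f2))
    assert demand_plan(single, 100) == {f1: 1, f2: 1}


@pytest.mark.parametrize("seed", range(5))
def test_demand_matches_incidence_oracle(seed):
    sim = CampaignSimConfig(
        n_bins=4, parts_per_bin=(2, 3, 2, 2), seed=seed,
        fragment_length_range=(200, 400), include_sequences=False,
    )
    d = generate_design(sim)
    for capacity in (1, 3, 4, 7):
        assert demand_plan(d, capacity) == oracle_demand(d, capacity)


# ---------------------------------------------------------------------------
# purchase orders
# ---------------------------------------------------------------------------

def test_purchase_order_pigeonhole_and_coverage(config):
    d = Design("big", homology_bp=60)
    for i in range(97):
        tag = "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(4))
        d.oligos[f"o{i}"] = Oligo(f"o{i}", "ACGTACGTACGTACGT" + tag, f"n{i}")
    sheet = purchase_order(d, config)
    assert len(sheet) == 97
    assert sheet["Plate"].nunique() == 2

    empty = purchase_order(Design("none", homology_bp=60), config)
    assert len(empty) == 0
    assert list(empty.columns) == ["Plate", "Well", "Name", "Sequence"]


def test_purchase_order_covers_every_reaction_oligo(small_design, config):
    sheet = purchase_order(small_design, config)
    ordered = set(sheet["Sequence"])
    referenced = {
        small_design.oligos[oid].sequence
        for f in small_design.fragments.values()
        for oid in (f.forward_oligo_id, f.reverse_oligo_id)
    }
    assert referenced == ordered
    assert sheet["Sequence"].is_unique or not sheet.empty  # one row per oligo
    assert len(sheet) == len(small_design.oligos)


def test_duplicate_oligo_sequences_warn_and_collapse(config):
    d = Design("dup", homology_bp=60)
    d.oligos["a"] = Oligo("a", "ACGTACGTACGTACGTACGT", "a")
    d.oligos["b"] = Oligo("b", "ACGTACGTACGTACGTACGT", "b")
    with pytest.warns(UserWarning, match="duplicates"):
        sheet = purchase_order(d, config)
    assert len(sheet) == 2
    with pytest.warns(UserWarning):
        collapsed = purchase_order(d, config, collapse_duplicates=True)
    assert len(collapsed) == 1


# ---------------------------------------------------------------------------
# PCR setup
# ---------------------------------------------------------------------------

def _stocks_for(design, config):
    from plasmidcad.plate_model import allocate

    echo = config.labware["echo_source_384"]
    oligo_layout = allocate(sorted(design.oligos), echo, plate_prefix="osrc")
    tpl_ids = sorted({f.template_id for f in design.fragments.values()})
    tpl_layout = allocate(tpl_ids, echo, plate_prefix="tsrc")
    oligos = {o: ReagentStock(o, oligo_layout[o], 100.0, 40.0) for o in oligo_layout}
    tpls = {t: ReagentStock(t, tpl_layout[t], 10.0, 40.0) for t in tpl_layout}
    return oligos, tpls


def test_pcr_setup_three_transfers_per_reaction(small_design, config):
    reactions = plan_reactions(small_design, config)
    oligos, tpls = _stocks_for(small_design, config)
    transfers = pcr_setup(reactions, oligos, tpls, config)
    assert len(transfers) == 3 * len(reactions)
    # recipe: 0.5 µL each primer + 0.5 µL template per reaction
    per_rxn = sum(t.volume_ul for t in transfers[:3])
    assert per_rxn == pytest.approx(1.5)
    # every volume is a multiple of the droplet quantum
    q = config.droplet_quantum_nl / 1000.0
    for t in transfers:
        assert (t.volume_ul / q) == pytest.approx(round(t.volume_ul / q))


def test_pcr_setup_shared_template_draws_twice(config):
    sim = CampaignSimConfig(seed=2, fragment_length_range=(200, 400),
                            include_sequences=False)
    d = generate_design(sim)
    # force two replicates of one fragment: both draw the same template well
    reactions = plan_reactions(d, config)
    by_tpl = {}
    for t_id in {r.template_id for r in reactions}:
        by_tpl[t_id] = [r for r in reactions if r.template_id == t_id]
    oligos, tpls = _stocks_for(d, config)
    transfers = pcr_setup(reactions, oligos, tpls, config)
    tpl_id, group = max(by_tpl.items(), key=lambda kv: len(kv[1]))
    loc = tpls[tpl_id].location
    from_well = [t for t in transfers
                 if (t.source_plate, t.source_well) == (loc.plate_id, loc.address)]
    assert len(from_well) == len(group)


def test_pcr_setup_missing_stock_lists_blocked(small_design, config):
    reactions = plan_reactions(small_design, config)
    oligos, tpls = _stocks_for(small_design, config)
    victim = reactions[0]
    del tpls[victim.template_id]
    with pytest.raises(CompileError) as exc:
        pcr_setup(reactions, oligos, tpls, config)
    assert any(victim.reaction_id in b for b in exc.value.blocked)


# ---------------------------------------------------------------------------
# thermocycler grouping
# ---------------------------------------------------------------------------

def _rxn(i, temp, size=1000):
    return PcrReaction(f"r{i}", f"f{i}", "t", "o1", "o2", size, temp)


def test_span_rule_and_extension_time(config):
    groups = thermocycler_groups([_rxn(0, 60.0), _rxn(1, 60.5), _rxn(2, 66.0)],
                                 max_groups=8, config=config)
    assert len(groups) == 2
    assert {len(g.reaction_ids) for g in groups} == {1, 2}
    # extension: 1000 bp at 1000 bp / 30 s → 30 s; 2500 bp → 75 s
    one = thermocycler_groups([_rxn(0, 60.0, size=2500)], 4, config)
    assert one[0].extension_s == 75
    assert one[0].annealing_c == 60.0


def test_single_reaction_gets_own_conditions(config):
    groups = thermocycler_groups([_rxn(0, 63.2, 800)], 1, config)
    assert len(groups) == 1
    assert groups[0].annealing_c == 63.2


@settings(max_examples=40, deadline=None)
@given(
    temps=st.lists(st.floats(50.0, 72.0).map(lambda x: round(x, 1)),
                   min_size=1, max_size=8),
    max_groups=st.integers(1, 4),
)
def test_grouping_matches_bruteforce_optimum(temps, max_groups):
    """Group count ≤ k, and the achieved span is the brute-force optimum when
    the default span must be widened."""
    cfg = CampaignConfig()
    reactions = [_rxn(i, t) for i, t in enumerate(temps)]
    groups = thermocycler_groups(reactions, max_groups, cfg)
    assert len(groups) <= max_groups
    by_id = {r.reaction_id: r for r in reactions}
    spans = [
        max(by_id[i].annealing_c for i in g.reaction_ids)
        - min(by_id[i].annealing_c for i in g.reaction_ids)
        for g in groups
    ]
    achieved = max(spans)
    optimal = oracle_thermocycler(temps, max_groups)
    assert achieved <= max(cfg.annealing_span_c, optimal) + 1e-9


def test_empty_reaction_list():
    assert thermocycler_groups([], 4) == []


# ---------------------------------------------------------------------------
# mix stoichiometry
# ---------------------------------------------------------------------------

def test_equimolar_worked_example():
    """1000 bp at 50 ng/µL, 10 fmol target → 123.6 nL, rounded up to 125 nL."""
    stock = ReagentStock("frag", WellLocation("p", "A1"), 50.0, 20.0, length_bp=1000)
    spec = MixSpec(target_fmol_per_part=10.0, droplet_quantum_nl=2.5)
    vols = equimolar_volumes([stock], spec)
    assert vols["frag"] == pytest.approx(0.125)
    assert ds_molecular_weight(1000) == pytest.approx(617996.04)
    # the same dose at the coarser 25 nL quantum still lands on 125 nL
    vols25 = equimolar_volumes([stock], MixSpec(droplet_quantum_nl=25.0))
    assert vols25["frag"] == pytest.approx(0.125)


def test_equimolar_symmetry_and_vector_excess():
    a = ReagentStock("a", WellLocation("p", "A1"), 40.0, 20.0, length_bp=2000)
    b = ReagentStock("b", WellLocation("p", "A2"), 40.0, 20.0, length_bp=2000)
    spec = MixSpec(vector_excess_ratio=2.0)
    vols = equimolar_volumes([a, b], spec)
    assert vols["a"] == vols["b"]
    boosted = equimolar_volumes([a, b], spec, vector_ids={"a"})
    assert boosted["a"] >= 2 * vols["a"] - spec.droplet_quantum_nl / 1000.0
    assert boosted["b"] == vols["b"]


def test_equimolar_overflow_is_an_error_not_a_rescale():
    thin = ReagentStock("x", WellLocation("p", "A1"), 0.5, 20.0, length_bp=5000)
    with pytest.raises(VolumeOverflowError):
        equimolar_volumes([thin], MixSpec(target_total_volume_ul=5.0))


def test_equimolar_requires_length():
    nolen = ReagentStock("x", WellLocation("p", "A1"), 50.0, 20.0)
    with pytest.raises(CompileError):
        equimolar_volumes([nolen], MixSpec())


@settings(max_examples=40, deadline=None)
@given(
    lengths=st.lists(st.integers(500, 5000), min_size=1, max_size=7),
    concs=st.lists(st.floats(20.0, 100.0), min_size=7, max_size=7),
)
def test_equimolar_delivers_target_moles_within_one_droplet(lengths, concs):
    """Achieved fmol per part is within one droplet quantum's worth of moles."""
    spec = MixSpec(target_fmol_per_part=10.0, droplet_quantum_nl=25.0,
                   target_total_volume_ul=50.0)
    stocks = [
        ReagentStock(f"s{i}", WellLocation("p", "A1"), concs[i], 20.0, length_bp=L)
        for i, L in enumerate(lengths)
    ]
    vols = equimolar_volumes(stocks, spec)
    for s in stocks:
        fmol = vols[s.sample_id] * s.concentration / (ds_molecular_weight(s.length_bp) * 1e-6)
        droplet_fmol = (spec.droplet_quantum_nl / 1000.0) * s.concentration / (
            ds_molecular_weight(s.length_bp) * 1e-6
        )
        assert spec.target_fmol_per_part - 1e-9 <= fmol <= spec.target_fmol_per_part + droplet_fmol + 1e-9


def test_equivolume_rounds_down_with_water_remainder():
    vols, water = equivolume_volumes(["a", "b", "c"], MixSpec(
        mode="equivolume", target_total_volume_ul=10.0, droplet_quantum_nl=25.0))
    assert all(v == pytest.approx(3.325) for v in vols.values())
    assert water == pytest.approx(10.0 - 3 * 3.325)
    none, all_water = equivolume_volumes([], MixSpec(mode="equivolume"))
    assert none == {} and all_water == 10.0


# ---------------------------------------------------------------------------
# assembly picklists and bench worklists
# ---------------------------------------------------------------------------

def _fragment_stocks(design, config):
    from plasmidcad.plate_model import allocate

    layout = allocate(sorted(design.fragments), config.labware["pcr96"],
                      plate_prefix="purified")
    return {
        fid: ReagentStock(fid, layout[fid], 60.0, 30.0,
                          length_bp=design.fragments[fid].length_bp)
        for fid in layout
    }


def test_assembly_picklist_shape_and_volume_cap(small_design, config):
    stocks = _fragment_stocks(small_design, config)
    spec = MixSpec(target_total_volume_ul=10.0)
    cids = sorted(small_design.constructs)
    transfers, dest = assembly_picklists(cids, small_design, stocks, spec, config)
    assert len(dest) == len(cids)
    for cid in cids:
        into = [t for t in transfers
                if (t.dest_plate, t.dest_well) == (dest[cid].plate_id, dest[cid].address)]
        assert len(into) == len(small_design.constructs[cid].fragment_ids)
        assert sum(t.volume_ul for t in into) <= spec.target_total_volume_ul + 1e-9


def test_assembly_refuses_unstocked_construct(small_design, config):
    stocks = _fragment_stocks(small_design, config)
    victim = sorted(small_design.constructs)[0]
    gone = small_design.constructs[victim].fragment_ids[0]
    del stocks[gone]
    with pytest.raises(CompileError) as exc:
        assembly_picklists([victim], small_design, stocks, MixSpec(), config)
    assert gone in "".join(exc.value.blocked)


def test_qtray_plating_pigeonhole(config):
    layout = {
        f"c{i}": WellLocation("asm1", f"{'ABCDEFGH'[i // 12]}{i % 12 + 1}")
        for i in range(96)
    }
    transfers, dest = bench_worklists("plate_qtray", layout, config, 100.0)
    trays = {loc.plate_id for loc in dest.values()}
    assert len(trays) == 2
    per_tray = {t: sum(1 for v in dest.values() if v.plate_id == t) for t in trays}
    assert set(per_tray.values()) == {48}


def test_bead_purify_one_to_one_constant_volume(config):
    layout = {f"f{i}": WellLocation("cons1", f"A{i + 1}") for i in range(12)}
    transfers, dest = bench_worklists("bead_purify", layout, config, 30.0)
    assert len(transfers) == 12
    assert {t.volume_ul for t in transfers} == {30.0}
    assert all(dest[s].address == layout[s].address for s in layout)


def test_consolidation_pools_replicates_per_fragment(config):
    """Output well count = distinct fragments; replicate wells pool into one."""
    sources = {
        "fA": [WellLocation("r1", "A1"), WellLocation("r2", "B5")],
        "fB": [WellLocation("r1", "A2")],
        "fC": [WellLocation("r3", "C7"), WellLocation("r1", "D1"),
               WellLocation("r2", "E2")],
    }
    transfers, dest = bench_worklists("consolidate_pcr", sources, config, 40.0)
    assert len(dest) == 3
    assert len(transfers) == 6
    for fid, locs in sources.items():
        into = [t for t in transfers
                if (t.dest_plate, t.dest_well) == (dest[fid].plate_id, dest[fid].address)]
        assert len(into) == len(locs)
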