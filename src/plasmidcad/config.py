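"""Campaign configuration.

Everything an instrument vendor or a wet-lab protocol would otherwise hard-code
lives here: labware geometries and dead volumes, the acoustic droplet quantum,
PCR recipe volumes, QC thresholds, redo policy.  A single YAML file overrides
any subset of the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class LabwareDef:
    """Geometry and liquid limits of one plate type."""

    labware_id: str
    rows: int
    cols: int
    well_capacity_ul: float
    dead_volume_ul: float
    kind: str  # pcr96 | echo_source_384 | deep96 | qtray48 | archive96

    def __post_init__(self) -> None:
        if self.rows * self.cols not in (48, 96, 384):
            raise ValueError(
                f"{self.labware_id}: {self.rows}x{self.cols} is not a supported geometry"
            )
        if self.dead_volume_ul >= self.well_capacity_ul:
            raise ValueError(f"{self.labware_id}: dead volume >= capacity")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols


#: Stock labware. Dead volumes are defaults, not vendor gospel — override in YAML.
DEFAULT_LABWARE: dict[str, LabwareDef] = {
    "pcr96": LabwareDef("pcr96", 8, 12, 200.0, 5.0, "pcr96"),
    "echo_source_384": LabwareDef("echo_source_384", 16, 24, 65.0, 2.5, "echo_source_384"),
    "deep96": LabwareDef("deep96", 8, 12, 2000.0, 10.0, "deep96"),
    "qtray48": LabwareDef("qtray48", 6, 8, 5000.0, 0.0, "qtray48"),
    "archive96": LabwareDef("archive96", 8, 12, 1000.0, 20.0, "archive96"),
}


@dataclass
class CampaignConfig:
    """Tunable parameters of a build campaign with documented defaults."""

    # design ingestion
    homology_bp: int = 60          # minimum homologous overlap between parts
    max_oligo_nt: int = 60         # vendor synthesis ceiling for ssDNA oligos

    # demand / PCR setup
    capacity_uses_per_reaction: int = 4   # constructs one PCR product can feed
    primer_volume_ul: float = 0.5
    template_volume_ul: float = 0.5
    droplet_quantum_nl: float = 25.0      # acoustic dispense granularity
    fill_order: str = "row_major"         # or column_major for 8-channel heads

    # thermocycling
    annealing_span_c: float = 2.0         # max within-group annealing spread
    extension_s_per_kb: float = 30.0      # polymerase rate: 1000 bp per 30 s

    # capillary-electrophoresis QC
    size_tolerance: float = 0.10          # relative size error for a pass
    min_concentration_ng_ul: float = 1.0
    marker_sizes_bp: tuple[int, ...] = (1, 6000)   # alignment markers to strip
    max_pcr_rounds: int = 6

    # assembly mixing
    mix_mode: str = "equimolar"           # or equivolume
    target_total_volume_ul: float = 10.0
    target_fmol_per_part: float = 10.0
    vector_excess_ratio: float = 1.0

    # colony handling / NGS policy
    picks_per_construct: int = 3
    require_full_coverage: bool = True
    max_mutations: int = 0

    labware: dict[str, LabwareDef] = field(
        default_factory=lambda: dict(DEFAULT_LABWARE)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        labware_raw = raw.pop("labware", {})
        cfg = cls(**raw)
        for lw_id, spec in labware_raw.items():
            cfg.labware[lw_id] = LabwareDef(labware_id=lw_id, **spec)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["labware"] = {
            k: {f: v for f, v in asdict(lw).items() if f != "labware_id"}
            for k, lw in self.labware.items()
        }
        d["marker_sizes_bp"] = list(self.marker_sizes_bp)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
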