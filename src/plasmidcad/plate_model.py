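"""Labware geometry, well addressing, 96↔384 quadrant stamping and volume accounting.

Every worklist the compiler emits is a list of :class:`TransferInstruction`;
every emitted picklist can be *simulated* against :class:`Plate` objects with
:func:`apply_transfers` before it ever reaches an instrument.  Validation is
all-or-nothing per picklist: a batch that would underflow any source well
mutates nothing.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .config import LabwareDef
from .errors import AddressError, InsufficientVolumeError

_ADDRESS_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d*)$")

ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def parse_address(address: str) -> tuple[int, int]:
    """Parse ``"A1"``/``"A01"`` into 0-based (row, col). Case-insensitive."""
    m = _ADDRESS_RE.match(address.strip())
    if not m:
        raise AddressError(f"malformed well address {address!r}")
    return ROW_LETTERS.index(m.group(1).upper()), int(m.group(2)) - 1


def format_address(row: int, col: int) -> str:
    """0-based (row, col) → unpadded address like ``"H12"``."""
    return f"{ROW_LETTERS[row]}{col + 1}"


def address_to_index(
    address: str, geometry: LabwareDef | tuple[int, int], order: str = "row_major"
) -> int:
    """Map a well address to its linear index in [0, rows*cols).

    ``order`` is ``row_major`` (A1, A2, ...) or ``column_major`` (A1, B1, ...).
    """
    rows, cols = _geometry(geometry)
    r, c = parse_address(address)
    if r >= rows or c >= cols:
        raise AddressError(f"address {address!r} outside {rows}x{cols} geometry")
    if order == "row_major":
        return r * cols + c
    if order == "column_major":
        return c * rows + r
    raise ValueError(f"unknown fill order {order!r}")


def index_to_address(
    index: int, geometry: LabwareDef | tuple[int, int], order: str = "row_major"
) -> str:
    rows, cols = _geometry(geometry)
    if not 0 <= index < rows * cols:
        raise AddressError(f"index {index} outside {rows}x{cols} geometry")
    if order == "row_major":
        return format_address(index // cols, index % cols)
    if order == "column_major":
        return format_address(index % rows, index // rows)
    raise ValueError(f"unknown fill order {order!r}")


def _geometry(geometry: LabwareDef | tuple[int, int]) -> tuple[int, int]:
    if isinstance(geometry, LabwareDef):
        return geometry.rows, geometry.cols
    return geometry


def quadrant_map(address96: str, quadrant: int) -> str:
    """Map a 96-well address into one interleaved quadrant of a 384-well plate.

    Convention: row384 = 2*row96 + quadrant//2, col384 = 2*col96 + quadrant%2,
    the standard interleaved stamp of four 96-well plates onto one 384.
    Bijective over (address96, quadrant).
    """
    if quadrant not in (0, 1, 2, 3):
        raise ValueError(f"quadrant must be 0..3, got {quadrant}")
    r, c = parse_address(address96)
    if r >= 8 or c >= 12:
        raise AddressError(f"{address96!r} is not a 96-well address")
    return format_address(2 * r + quadrant // 2, 2 * c + quadrant % 2)


def quadrant_unmap(address384: str) -> tuple[str, int]:
    """Inverse of :func:`quadrant_map`."""
    r, c = parse_address(address384)
    if r >= 16 or c >= 24:
        raise AddressError(f"{address384!r} is not a 384-well address")
    return format_address(r // 2, c // 2), 2 * (r % 2) + (c % 2)


@dataclass(frozen=True)
class WellLocation:
    plate_id: str
    address: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.plate_id}:{self.address}"


def allocate(
    sample_ids: Sequence[str],
    labware: LabwareDef,
    fill_order: str = "row_major",
    plate_prefix: str = "plate",
    start_plate: int = 1,
) -> dict[str, WellLocation]:
    """Lay samples onto sequentially numbered plates, in order.

    Deterministic and *stable*: appending samples never moves earlier ones.
    Plate count is ``ceil(n / wells_per_plate)``.
    """
    layout: dict[str, WellLocation] = {}
    per_plate = labware.n_wells
    for i, sid in enumerate(sample_ids):
        if sid in layout:
            raise ValueError(f"duplicate sample id {sid!r} in allocation request")
        plate_no = start_plate + i // per_plate
        addr = index_to_address(i % per_plate, labware, fill_order)
        layout[sid] = WellLocation(f"{plate_prefix}{plate_no}", addr)
    return layout


@dataclass(frozen=True)
class TransferInstruction:
    """One liquid movement — the atom of every picklist."""

    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    volume_ul: float

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError("transfer volume must be positive")


def quantize_up(volume_ul: float, quantum_nl: float) -> float:
    """Round a volume UP to the droplet quantum (µL in, µL out)."""
    q_ul = quantum_nl / 1000.0
    return math.ceil(round(volume_ul / q_ul, 9)) * q_ul


def quantize_down(volume_ul: float, quantum_nl: float) -> float:
    q_ul = quantum_nl / 1000.0
    return math.floor(round(volume_ul / q_ul, 9)) * q_ul


@dataclass
class Plate:
    """A physical plate: labware definition plus per-well contents.

    ``wells`` maps address → list of (sample_id, volume µL). Multiple entries
    per well model mixes; total volume is what liquid handling cares about.
    """

    plate_id: str
    labware: LabwareDef
    wells: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def fill(self, address: str, sample_id: str, volume_ul: float) -> None:
        r, c = parse_address(address)
        if r >= self.labware.rows or c >= self.labware.cols:
            raise AddressError(
                f"{address!r} outside {self.labware.labware_id} geometry"
            )
        addr = format_address(r, c)
        cur = self.well_volume(addr) + volume_ul
        if cur > self.labware.well_capacity_ul + 1e-9:
            raise InsufficientVolumeError(
                f"well {self.plate_id}:{addr} over capacity "
                f"({cur:.2f} > {self.labware.well_capacity_ul} µL)",
                well=addr,
            )
        self.wells.setdefault(addr, []).append((sample_id, volume_ul))

    def well_volume(self, address: str) -> float:
        return sum(v for _, v in self.wells.get(address, ()))

    def total_volume(self) -> float:
        return sum(v for entries in self.wells.values() for _, v in entries)

    def samples_in(self, address: str) -> list[str]:
        return [s for s, _ in self.wells.get(address, ())]


def apply_transfers(
    plates: dict[str, Plate], transfers: Iterable[TransferInstruction]
) -> dict[str, Plate]:
    """Execute a picklist against a set of plates, conserving volume.

    Validation precedes mutation: the whole batch is simulated first, and any
    underflow below a source's dead volume (or a missing plate/well) aborts the
    batch with the offending well and shortfall — the input plates are
    untouched on error.
    """
    transfers = list(transfers)

    # pass 1: validate against projected volumes
    projected: dict[tuple[str, str], float] = {}
    for t in transfers:
        if t.source_plate not in plates:
            raise InsufficientVolumeError(f"unknown source plate {t.source_plate!r}")
        if t.dest_plate not in plates:
            raise InsufficientVolumeError(f"unknown destination plate {t.dest_plate!r}")
        src = plates[t.source_plate]
        key = (t.source_plate, t.source_well)
        avail = projected.get(key, src.well_volume(t.source_well))
        remaining = avail - t.volume_ul
        if remaining < src.labware.dead_volume_ul - 1e-9:
            shortfall = src.labware.dead_volume_ul - remaining
            raise InsufficientVolumeError(
                f"transfer of {t.volume_ul} µL from {t.source_plate}:{t.source_well} "
                f"would leave {remaining:.3f} µL, below dead volume "
                f"{src.labware.dead_volume_ul} µL (short {shortfall:.3f} µL)",
                well=f"{t.source_plate}:{t.source_well}",
                shortfall_ul=shortfall,
            )
        projected[key] = remaining
        dkey = (t.dest_plate, t.dest_well)
        dst = plates[t.dest_plate]
        davail = projected.get(dkey, dst.well_volume(t.dest_well))
        projected[dkey] = davail  # destination capacity checked in pass 2 via fill

    # pass 2: mutate
    for t in transfers:
        src = plates[t.source_plate]
        dst = plates[t.dest_plate]
        entries = src.wells.get(t.source_well, [])
        _drain(entries, t.volume_ul)
        label = entries[0][0] if entries else f"{t.source_plate}:{t.source_well}"
        dst.fill(t.dest_well, label, t.volume_ul)
    return plates


def _drain(entries: list[tuple[str, float]], volume_ul: float) -> None:
    """Remove ``volume_ul`` proportionally across a well's content entries."""
    total = sum(v for _, v in entries)
    if total <= 0:
        return
    frac = volume_ul / total
    for i, (sid, v) in enumerate(entries):
        entries[i] = (sid, v * (1 - frac))


PICKLIST_HEADER = [
    "Source Plate Name",
    "Source Well",
    "Destination Plate Name",
    "Destination Well",
    "Transfer Volume",
]


def write_picklist(
    transfers: Sequence[TransferInstruction],
    path: str | Path,
    volume_unit: str = "nL",
) -> None:
    """Write an instrument picklist CSV.

    Acoustic dispensers take volumes in nL, tip-based handlers in µL; the unit
    is declared per file via ``volume_unit``.
    """
    scale = {"nL": 1000.0, "uL": 1.0}[volume_unit]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PICKLIST_HEADER)
        for t in transfers:
            vol = t.volume_ul * scale
            w.writerow(
                [t.source_plate, t.source_well, t.dest_plate, t.dest_well,
                 f"{vol:g}"]
            )


def read_picklist(path: str | Path, volume_unit: str = "nL") -> list[TransferInstruction]:
    scale = {"nL": 1000.0, "uL": 1.0}[volume_unit]
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TransferInstruction(
                    row["Source Plate Name"],
                    row["Source Well"],
                    row["Destination Plate Name"],
                    row["Destination Well"],
                    float(row["Transfer Volume"]) / scale,
                )
            )
    return out
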