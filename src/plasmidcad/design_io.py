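"""Read/write combinatorial assembly design bundles and derive expected constructs.

A *design bundle* is a directory of delimited-text tables in the native dialect
documented by :data:`DIALECT` (and exportable as a JSON schema file): oligos,
parts, fragments (one PCR product each, homology arms included in their
length), and target constructs (ordered fragment lists).  Real exports from an
upstream primer-design tool are adapted through a per-table column mapping, so
the package is not tied to any particular version of that tool's CSV layout.

The expected sequence of a construct is the ordered merge of its fragments with
each shared junction overlap emitted once; for a circular plasmid of *n*
fragments there are *n* junctions, for a linear product *n − 1*, giving

    size = Σ fragment lengths − Σ junction overlaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError, JunctionError

_DNA = set("ACGT")


def _clean_seq(seq: str) -> str:
    return "".join(seq.split()).upper()


@dataclass(frozen=True)
class Part:
    """One alternative DNA part occupying a bin of the combinatorial design."""

    part_id: str
    sequence: str
    bin_id: str
    role: str = "insert"  # vector | insert
    meta: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_seq(self.sequence))
        if not self.sequence or set(self.sequence) - _DNA:
            raise ValueError(f"part {self.part_id}: sequence must be non-empty ACGT")
        if self.role not in ("vector", "insert"):
            raise ValueError(f"part {self.part_id}: role must be vector|insert")


@dataclass(frozen=True)
class Oligo:
    """A single-stranded primer as ordered from a synthesis vendor."""

    oligo_id: str
    sequence: str
    name: str = ""
    meta: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_seq(self.sequence))
        if not 10 <= len(self.sequence):
            raise ValueError(f"oligo {self.oligo_id}: length < 10 nt")
        if set(self.sequence) - _DNA:
            raise ValueError(f"oligo {self.oligo_id}: non-ACGT sequence")


@dataclass(frozen=True)
class Fragment:
    """One PCR product; homology arms are *included* in ``length_bp``."""

    fragment_id: str
    part_id: str
    length_bp: int
    left_overlap_bp: int
    right_overlap_bp: int
    template_id: str
    forward_oligo_id: str
    reverse_oligo_id: str
    sequence: str | None = None
    meta: tuple = ()

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"fragment {self.fragment_id}: length must be > 0")
        if self.left_overlap_bp < 0 or self.right_overlap_bp < 0:
            raise ValueError(f"fragment {self.fragment_id}: overlaps must be >= 0")
        if self.sequence is not None:
            object.__setattr__(self, "sequence", _clean_seq(self.sequence))
            if len(self.sequence) != self.length_bp:
                raise ValueError(
                    f"fragment {self.fragment_id}: sequence length "
                    f"{len(self.sequence)} != length_bp {self.length_bp}"
                )


@dataclass(frozen=True)
class TargetConstruct:
    """An ordered list of fragments to be assembled into one plasmid."""

    construct_id: str
    fragment_ids: tuple[str, ...]
    circular: bool = True
    meta: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_ids", tuple(self.fragment_ids))
        if len(self.fragment_ids) < 2:
            raise ValueError(f"construct {self.construct_id}: needs >= 2 fragments")
        if len(set(self.fragment_ids)) != len(self.fragment_ids):
            raise ValueError(f"construct {self.construct_id}: duplicate fragments")


@dataclass
class Design:
    """A referentially intact combinatorial design."""

    design_id: str
    parts: dict[str, Part] = field(default_factory=dict)
    oligos: dict[str, Oligo] = field(default_factory=dict)
    fragments: dict[str, Fragment] = field(default_factory=dict)
    constructs: dict[str, TargetConstruct] = field(default_factory=dict)
    homology_bp: int = 60

    def validate(self) -> None:
        """Raise :class:`IntegrityError` listing every dangling reference."""
        offenders = []
        for c in self.constructs.values():
            for fid in c.fragment_ids:
                if fid not in self.fragments:
                    offenders.append(f"{c.construct_id}->{fid}")
        for f in self.fragments.values():
            for oid in (f.forward_oligo_id, f.reverse_oligo_id):
                if oid and self.oligos and oid not in self.oligos:
                    offenders.append(f"{f.fragment_id}->{oid}")
            if self.parts and f.part_id and f.part_id not in self.parts:
                offenders.append(f"{f.fragment_id}->{f.part_id}")
        if offenders:
            raise IntegrityError(
                "dangling references: " + ", ".join(sorted(offenders)), offenders
            )


# ---------------------------------------------------------------------------
# native dialect
# ---------------------------------------------------------------------------

#: Native table layout; keys are file stems, values the required column order.
DIALECT: dict[str, list[str]] = {
    "oligos": ["oligo_id", "name", "sequence"],
    "parts": ["part_id", "bin_id", "role", "sequence"],
    "fragments": [
        "fragment_id", "part_id", "length_bp", "left_overlap_bp",
        "right_overlap_bp", "template_id", "forward_oligo_id",
        "reverse_oligo_id", "sequence",
    ],
    "constructs": ["construct_id", "fragment_ids", "circular"],
}

_OPTIONAL_COLUMNS = {("fragments", "sequence"), ("constructs", "circular")}
_FRAGMENT_LIST_SEP = ";"


def dump_dialect_schema(path: str | Path) -> None:
    """Write a JSON description of the native CSV dialect."""
    schema = {
        "format": "RFC-4180 CSV, UTF-8, one table per file",
        "tables": {
            name: {
                "columns": cols,
                "optional": [c for t, c in _OPTIONAL_COLUMNS if t == name],
            }
            for name, cols in DIALECT.items()
        },
        "notes": {
            "fragment_ids": f"ordered, {_FRAGMENT_LIST_SEP!r}-separated",
            "circular": "true/false, default true",
            "meta": "unknown columns are preserved verbatim on round-trip",
        },
    }
    Path(path).write_text(json.dumps(schema, indent=2))


def _remap(df: pd.DataFrame, table: str, column_map: Mapping[str, Mapping[str, str]] | None) -> pd.DataFrame:
    if column_map and table in column_map:
        df = df.rename(columns={src: dst for dst, src in column_map[table].items()})
    missing = [
        c for c in DIALECT[table]
        if c not in df.columns and (table, c) not in _OPTIONAL_COLUMNS
    ]
    if missing:
        raise FormatError(f"table {table!r}: missing required column(s) {missing}")
    return df


def _meta(row: pd.Series, table: str) -> tuple:
    extra = [(k, row[k]) for k in row.index if k not in DIALECT[table]]
    return tuple((k, str(v)) for k, v in extra if pd.notna(v))


def parse_design(
    bundle_dir: str | Path,
    column_map: Mapping[str, Mapping[str, str]] | None = None,
    design_id: str | None = None,
) -> Design:
    """Parse a design bundle directory into a validated :class:`Design`.

    ``column_map`` adapts foreign exports: ``{table: {native_col: source_col}}``.
    Unknown columns survive round-trip as opaque metadata.  Row order is never
    semantically significant.
    """
    bundle_dir = Path(bundle_dir)
    meta_path = bundle_dir / "design.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    design = Design(
        design_id=design_id or meta.get("design_id", bundle_dir.name),
        homology_bp=int(meta.get("homology_bp", 60)),
    )

    def load(table: str) -> pd.DataFrame | None:
        path = bundle_dir / f"{table}.csv"
        if not path.exists():
            if table == "parts":
                return None
            raise FormatError(f"bundle missing required table {table}.csv")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return _remap(df, table, column_map)

    oligos = load("oligos")
    for _, r in oligos.iterrows():
        o = Oligo(r["oligo_id"], r["sequence"], r["name"], meta=_meta(r, "oligos"))
        if o.oligo_id in design.oligos:
            raise IntegrityError(f"duplicate oligo_id {o.oligo_id}")
        design.oligos[o.oligo_id] = o

    parts = load("parts")
    if parts is not None:
        for _, r in parts.iterrows():
            p = Part(r["part_id"], r["sequence"], r["bin_id"], r["role"],
                     meta=_meta(r, "parts"))
            if p.part_id in design.parts:
                raise IntegrityError(f"duplicate part_id {p.part_id}")
            design.parts[p.part_id] = p

    for _, r in load("fragments").iterrows():
        seq = r.get("sequence", "") or None
        f = Fragment(
            r["fragment_id"], r["part_id"], int(r["length_bp"]),
            int(r["left_overlap_bp"]), int(r["right_overlap_bp"]),
            r["template_id"], r["forward_oligo_id"], r["reverse_oligo_id"],
            sequence=seq, meta=_meta(r, "fragments"),
        )
        if f.fragment_id in design.fragments:
            raise IntegrityError(f"duplicate fragment_id {f.fragment_id}")
        design.fragments[f.fragment_id] = f

    for _, r in load("constructs").iterrows():
        circ = str(r.get("circular", "true")).strip().lower() != "false"
        c = TargetConstruct(
            r["construct_id"],
            tuple(x for x in r["fragment_ids"].split(_FRAGMENT_LIST_SEP) if x),
            circular=circ, meta=_meta(r, "constructs"),
        )
        if c.construct_id in design.constructs:
            raise IntegrityError(f"duplicate construct_id {c.construct_id}")
        design.constructs[c.construct_id] = c

    design.validate()
    return design


def write_design(design: Design, bundle_dir: str | Path) -> Path:
    """Write a design bundle in the native dialect; inverse of :func:`parse_design`."""
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    (bundle_dir / "design.json").write_text(json.dumps(
        {"design_id": design.design_id, "homology_bp": design.homology_bp}, indent=2
    ))

    def dump(table: str, rows: list[dict]) -> None:
        cols = list(DIALECT[table])
        extra = sorted({k for r in rows for k in r} - set(cols))
        pd.DataFrame(rows, columns=cols + extra).to_csv(
            bundle_dir / f"{table}.csv", index=False
        )

    dump("oligos", [
        {"oligo_id": o.oligo_id, "name": o.name, "sequence": o.sequence,
         **dict(o.meta)}
        for o in design.oligos.values()
    ])
    dump("parts", [
        {"part_id": p.part_id, "bin_id": p.bin_id, "role": p.role,
         "sequence": p.sequence, **dict(p.meta)}
        for p in design.parts.values()
    ])
    dump("fragments", [
        {"fragment_id": f.fragment_id, "part_id": f.part_id,
         "length_bp": f.length_bp, "left_overlap_bp": f.left_overlap_bp,
         "right_overlap_bp": f.right_overlap_bp, "template_id": f.template_id,
         "forward_oligo_id": f.forward_oligo_id,
         "reverse_oligo_id": f.reverse_oligo_id,
         "sequence": f.sequence or "", **dict(f.meta)}
        for f in design.fragments.values()
    ])
    dump("constructs", [
        {"construct_id": c.construct_id,
         "fragment_ids": _FRAGMENT_LIST_SEP.join(c.fragment_ids),
         "circular": "true" if c.circular else "false", **dict(c.meta)}
        for c in design.constructs.values()
    ])
    return bundle_dir


# ---------------------------------------------------------------------------
# expected assemblies
# ---------------------------------------------------------------------------

def _junction_overlap(left: Fragment, right: Fragment) -> int:
    if left.right_overlap_bp != right.left_overlap_bp:
        raise JunctionError(
            f"junction {left.fragment_id}|{right.fragment_id}: declared overlaps "
            f"disagree ({left.right_overlap_bp} vs {right.left_overlap_bp} bp)",
            left.fragment_id, right.fragment_id,
        )
    return left.right_overlap_bp


def expected_size(construct: TargetConstruct, design: Design) -> int:
    """Closed-form assembled size: Σ lengths − Σ junction overlaps.

    Circular constructs have as many junctions as fragments; linear ones, one
    fewer.
    """
    frags = [design.fragments[fid] for fid in construct.fragment_ids]
    size = sum(f.length_bp for f in frags)
    for a, b in zip(frags, frags[1:]):
        size -= _junction_overlap(a, b)
    if construct.circular:
        size -= _junction_overlap(frags[-1], frags[0])
    return size


def expected_assembly(
    construct: TargetConstruct, design: Design
) -> tuple[str, int]:
    """Merge a construct's fragments into its expected sequence.

    Each junction overlap must be an exact sequence match of at least the
    design's ``homology_bp``; a mismatch raises :class:`JunctionError` naming
    the offending pair.
    """
    frags = [design.fragments[fid] for fid in construct.fragment_ids]
    for f in frags:
        if f.sequence is None:
            raise JunctionError(
                f"fragment {f.fragment_id} has no sequence; cannot assemble",
                f.fragment_id, "",
            )

    def check(a: Fragment, b: Fragment) -> int:
        ov = _junction_overlap(a, b)
        if ov < design.homology_bp:
            raise JunctionError(
                f"junction {a.fragment_id}|{b.fragment_id}: overlap {ov} bp "
                f"below campaign homology minimum {design.homology_bp} bp",
                a.fragment_id, b.fragment_id,
            )
        if a.sequence[-ov:] != b.sequence[:ov]:
            raise JunctionError(
                f"junction {a.fragment_id}|{b.fragment_id}: terminal {ov} bp "
                "do not match",
                a.fragment_id, b.fragment_id,
            )
        return ov

    seq = frags[0].sequence
    for a, b in zip(frags, frags[1:]):
        ov = check(a, b)
        seq += b.sequence[ov:]
    if construct.circular:
        ov = check(frags[-1], frags[0])
        # the wrap junction appears at both ends of the linear concatenation;
        # emit it once by trimming the trailing copy
        seq = seq[: len(seq) - ov]
    return seq, len(seq)


def export_expected_sequences(
    design: Design,
    path: str | Path,
    fmt: str = "fasta",
    construct_ids: Iterable[str] | None = None,
) -> Path:
    """Write one FASTA/GenBank record per construct (id = construct_id)."""
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"format must be fasta|genbank, got {fmt!r}")
    records = []
    ids = list(construct_ids) if construct_ids is not None else list(design.constructs)
    for cid in ids:
        c = design.constructs[cid]
        seq, _ = expected_assembly(c, design)
        rec = SeqRecord(Seq(seq), id=cid, description="expected assembly")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if c.circular else "linear"
        records.append(rec)
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)
    return path
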