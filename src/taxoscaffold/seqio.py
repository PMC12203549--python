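"""Sequence and lineage IO.

Canonical in-memory forms are :class:`SeqRecord` and :class:`Lineage`.
Two taxonomy header dialects are understood:

* ``gtdb`` — ``d__Archaea;p__Thermoproteota;...`` (7 ``__``-prefixed ranks)
* ``sintax`` — ``d:Archaea,p:Thermoproteota,...`` (as carried in a
  ``;tax=`` FASTA header annotation)

Reference FASTA emitted by this package uses the sintax dialect
(``>id;tax=d:...,p:...``); query FASTA may carry UPARSE-style ``;size=N``
abundance annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Rank order used everywhere, shallowest first.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
_SINTAX_PREFIXES = ("d:", "p:", "c:", "o:", "f:", "g:", "s:")

_UNAMBIGUOUS = set("ACGTN")
_IUPAC_AMBIGUITY = set("RYSWKMBDHV")


class RankStatus(str, Enum):
    NAMED = "named"
    PUTATIVE = "putative"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class RankLabel:
    """A single rank assignment: a name plus its provenance status."""

    name: str
    status: RankStatus

    def __post_init__(self) -> None:
        if (self.status is RankStatus.UNRESOLVED) != (self.name == "?"):
            raise ValueError(
                f"unresolved labels must be named '?' (got {self.name!r}, "
                f"{self.status.value})"
            )

    @property
    def resolved(self) -> bool:
        return self.status is not RankStatus.UNRESOLVED


UNRESOLVED = RankLabel("?", RankStatus.UNRESOLVED)


def make_label(name: str, rank: str) -> RankLabel:
    """Build a RankLabel from a bare name, inferring its status.

    ``?`` (or empty) is unresolved; ``cl_<rank>_<centroid>`` is a putative
    cluster taxon for that rank; anything else is a named taxon.
    """
    if name in ("?", ""):
        return UNRESOLVED
    if name.startswith(f"cl_{rank}_"):
        return RankLabel(name, RankStatus.PUTATIVE)
    return RankLabel(name, RankStatus.NAMED)


def putative_label(rank: str, centroid_id: str) -> RankLabel:
    return RankLabel(f"cl_{rank}_{centroid_id}", RankStatus.PUTATIVE)


@dataclass(frozen=True)
class Lineage:
    """An ordered 7-rank taxonomy, domain through species."""

    ranks: tuple[RankLabel, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"a lineage has exactly {len(RANKS)} ranks")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "Lineage":
        """Lineage from up to 7 bare names (trailing ranks unresolved)."""
        if len(names) > len(RANKS):
            raise ValueError("more than 7 rank names")
        labels = [make_label(n, r) for n, r in zip(names, RANKS)]
        labels += [UNRESOLVED] * (len(RANKS) - len(labels))
        return cls(tuple(labels))

    @classmethod
    def empty(cls) -> "Lineage":
        return cls((UNRESOLVED,) * len(RANKS))

    def __getitem__(self, rank: str) -> RankLabel:
        return self.ranks[RANKS.index(rank)]

    def names(self) -> tuple[str, ...]:
        return tuple(lbl.name for lbl in self.ranks)

    @property
    def depth(self) -> int:
        """Number of leading resolved ranks (prefix depth)."""
        d = 0
        for lbl in self.ranks:
            if not lbl.resolved:
                break
            d += 1
        return d

    @property
    def is_full(self) -> bool:
        return all(lbl.resolved for lbl in self.ranks)

    def has_prefix_property(self) -> bool:
        """True if no resolved rank occurs below an unresolved one."""
        seen_gap = False
        for lbl in self.ranks:
            if not lbl.resolved:
                seen_gap = True
            elif seen_gap:
                return False
        return True

    def replace(self, rank: str, label: RankLabel) -> "Lineage":
        i = RANKS.index(rank)
        return Lineage(self.ranks[:i] + (label,) + self.ranks[i + 1 :])

    def to_gtdb(self) -> str:
        return ";".join(p + lbl.name for p, lbl in zip(_GTDB_PREFIXES, self.ranks))

    def to_sintax(self) -> str:
        return ",".join(p + lbl.name for p, lbl in zip(_SINTAX_PREFIXES, self.ranks))


def parse_lineage(header_tax: str, dialect: str = "gtdb") -> Lineage:
    """Parse a taxonomy string in the ``gtdb`` or ``sintax`` dialect.

    Missing trailing ranks become unresolved; a literal ``?`` name is
    unresolved; ``cl_<rank>_*`` names are putative. Ranks out of order or
    unknown rank prefixes are errors.
    """
    if dialect == "gtdb":
        prefixes, sep = _GTDB_PREFIXES, ";"
    elif dialect == "sintax":
        prefixes, sep = _SINTAX_PREFIXES, ","
    else:
        raise ValueError(f"unknown lineage dialect {dialect!r}")

    fields = [f.strip() for f in header_tax.strip().split(sep) if f.strip()]
    if len(fields) > len(RANKS):
        raise ValueError(f"more than {len(RANKS)} ranks in {header_tax!r}")

    labels: list[RankLabel] = []
    pos = 0
    for fld in fields:
        matched = None
        for i, pfx in enumerate(prefixes):
            if fld.startswith(pfx):
                matched = i
                break
        if matched is None:
            raise ValueError(f"unknown rank prefix in field {fld!r}")
        if matched < pos:
            raise ValueError(f"rank {prefixes[matched]!r} out of order in {header_tax!r}")
        # ranks skipped in the middle are unresolved
        labels += [UNRESOLVED] * (matched - pos)
        labels.append(make_label(fld[len(prefixes[matched]) :], RANKS[matched]))
        pos = matched + 1
    labels += [UNRESOLVED] * (len(RANKS) - len(labels))
    return Lineage(tuple(labels))


@dataclass
class SeqRecord:
    """One DNA sequence with identity, provenance and optional abundance."""

    id: str
    seq: str
    source: str = ""
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id) or ";" in self.id:
            raise ValueError(f"illegal sequence id {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.seq) - _UNAMBIGUOUS
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in sequence {self.id!r}"
            )
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")

    @property
    def length(self) -> int:
        return len(self.seq)


def normalize_residues(raw: str, seq_id: str) -> str:
    """Uppercase, U->T, IUPAC ambiguity codes (other than N) -> N."""
    s = raw.upper().replace("U", "T")
    residues = set(s)
    ambig = residues & _IUPAC_AMBIGUITY
    if ambig:
        logger.warning(
            "sequence %s: mapping IUPAC ambiguity codes %s to N",
            seq_id,
            "".join(sorted(ambig)),
        )
        s = "".join("N" if c in _IUPAC_AMBIGUITY else c for c in s)
    bad = set(s) - _UNAMBIGUOUS
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)} in sequence {seq_id!r}")
    return s


def _parse_header(raw_id: str) -> tuple[str, dict[str, str]]:
    """Split ``id;size=5;tax=...`` into the bare id and its annotations."""
    parts = raw_id.split(";")
    annots: dict[str, str] = {}
    for part in parts[1:]:
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed header annotation {part!r} in {raw_id!r}")
        key, val = part.split("=", 1)
        annots[key] = val
    return parts[0], annots


def read_fasta(path: str | Path, source: str = "") -> list[SeqRecord]:
    """Read FASTA into SeqRecords, honouring ``;size=N`` abundances.

    Residues are normalized (uppercase, U->T, ambiguity codes to N).
    Duplicate ids, empty sequences and non-IUPAC residues are hard errors.
    """
    records, _ = read_annotated_fasta(path, source=source)
    return records


def read_annotated_fasta(
    path: str | Path, dialect: str = "sintax", source: str = ""
) -> tuple[list[SeqRecord], dict[str, Lineage]]:
    """Read FASTA plus any ``;tax=`` lineage annotations in the headers.

    Returns the records (file order) and a map from id to Lineage for the
    records that carried a ``tax=`` annotation.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    lineages: dict[str, Lineage] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, annots = _parse_header(rec.id)
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        seq = normalize_residues(str(rec.seq), seq_id)
        abundance = float(annots["size"]) if "size" in annots else 1.0
        records.append(SeqRecord(seq_id, seq, source=source, abundance=abundance))
        if "tax" in annots:
            lineages[seq_id] = parse_lineage(annots["tax"], dialect=dialect)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records, lineages


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | Path,
    lineages: Mapping[str, Lineage] | None = None,
    with_size: bool = False,
    width: int = 80,
) -> None:
    """Write FASTA, optionally annotating headers with ``;size=`` / ``;tax=``."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if with_size:
                size = int(rec.abundance) if rec.abundance == int(rec.abundance) else rec.abundance
                header += f";size={size}"
            if lineages is not None and rec.id in lineages:
                header += f";tax={lineages[rec.id].to_sintax()}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_taxonomy_table(
    assignments: Mapping[str, Lineage], path: str | Path
) -> None:
    """Write a TSV taxonomy table: id then 7 rank columns, ``?`` literal.

    Row order follows the mapping's iteration order (insertion order for
    dicts), so output is deterministic for a given input.
    """
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(RANKS) + "\n")
        for seq_id, lineage in assignments.items():
            fh.write(seq_id + "\t" + "\t".join(lineage.names()) + "\n")


def read_taxonomy_table(path: str | Path) -> dict[str, Lineage]:
    """Inverse of :func:`write_taxonomy_table`."""
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", *RANKS]:
            raise ValueError(f"unexpected taxonomy table header in {path}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(RANKS) + 1:
                raise ValueError(f"malformed taxonomy row {line!r}")
            labels = tuple(
                make_label(name, rank) for name, rank in zip(fields[1:], RANKS)
            )
            out[fields[0]] = Lineage(labels)
    return out
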