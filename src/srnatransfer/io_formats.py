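"""Reading and writing of on-disk artifacts.

All sequences are held internally in the RNA alphabet {A, C, G, U}; DNA input
(T) is normalized to U on read.  Supported formats are plain or gzipped FASTA,
4-line FASTQ, and tab-separated collapsed count tables.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: the six library roles of the infestation experiment
ROLES = ("PC", "PW", "LC", "LW", "LE", "WN")

#: reference collection categories the pipeline distinguishes
REFERENCE_CATEGORIES = (
    "genome",
    "transcriptome",
    "ncrna",
    "virus",
    "symbiont",
    "mirna_catalog",
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA_TO_DNA = str.maketrans("U", "T")


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, U} (case-insensitive)."""


def normalize_sequence(raw: str) -> str:
    """Uppercase, convert T->U and validate against the RNA alphabet."""
    seq = raw.strip().upper().replace("T", "U")
    if not seq:
        raise SequenceAlphabetError("empty sequence")
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise SequenceAlphabetError(f"invalid characters {bad} in sequence {raw!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet (U pairs A; U==T for matching)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.translate(_RNA_TO_DNA)


@dataclass(frozen=True)
class SRNARecord:
    """One small-RNA read or sequence: identifier plus RNA-alphabet sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq or not set(self.seq) <= RNA_ALPHABET:
            raise SequenceAlphabetError(
                f"record {self.id!r}: sequence must be non-empty over A/C/G/U"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class CollapsedLibrary:
    """Non-redundant sequence->count map for one library role.

    ``total_reads`` is the number of reads retained at the stage the library
    represents and always equals the sum of the counts.
    """

    role: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq, count in self.counts.items():
            if count <= 0:
                raise ValueError(f"non-positive count {count} for {seq}")
            if not set(seq) <= RNA_ALPHABET:
                raise SequenceAlphabetError(f"invalid sequence key {seq!r}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def sequences(self) -> set[str]:
        return set(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, seq: str) -> bool:
        return seq in self.counts


@dataclass
class ReferenceSet:
    """A named FASTA collection with a category tag.

    Entries are (id, sequence) pairs in the internal RNA alphabet, in file
    order.  Catalog entries may carry a taxon tag using the ``id|taxon``
    header convention.
    """

    name: str
    category: str
    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in REFERENCE_CATEGORIES:
            raise ValueError(f"unknown reference category {self.category!r}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with _open_text(path) as handle:
        first = handle.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        # empty file: treat as an empty FASTA
        return "fasta"
    raise ValueError(f"cannot determine sequence format of {path}")


def read_sequences(path: str | Path, format: str = "auto") -> list[SRNARecord]:
    """Read FASTA/FASTQ into :class:`SRNARecord` objects, order preserved.

    FASTQ quality strings are parsed and discarded.  Records with characters
    outside {A,C,G,T,U} raise :class:`SequenceAlphabetError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {format!r}")
    records: list[SRNARecord] = []
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, format):
            records.append(SRNARecord(id=entry.id, seq=normalize_sequence(str(entry.seq))))
    return records


def write_fasta(records: Iterable[SRNARecord], path: str | Path, *, as_dna: bool = False) -> None:
    with _open_text(Path(path), "wt") as handle:
        for rec in records:
            seq = rna_to_dna(rec.seq) if as_dna else rec.seq
            handle.write(f">{rec.id}\n{seq}\n")


def write_fastq(
    records: Iterable[SRNARecord],
    path: str | Path,
    *,
    as_dna: bool = True,
    quality_char: str = "I",
) -> None:
    """Write 4-line FASTQ with a constant placeholder quality string."""
    with _open_text(Path(path), "wt") as handle:
        for rec in records:
            seq = rna_to_dna(rec.seq) if as_dna else rec.seq
            handle.write(f"@{rec.id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_reference(path: str | Path, name: str, category: str) -> ReferenceSet:
    """Read a reference FASTA into a :class:`ReferenceSet` (T normalized to U)."""
    records = read_sequences(path, format="fasta")
    return ReferenceSet(
        name=name, category=category, entries=[(r.id, r.seq) for r in records]
    )


def write_reference(ref: ReferenceSet, path: str | Path, *, as_dna: bool = False) -> None:
    write_fasta((SRNARecord(rid, seq) for rid, seq in ref.entries), path, as_dna=as_dna)


def write_count_table(
    lib: CollapsedLibrary,
    path: str | Path,
    rpkm: Mapping[str, float] | None = None,
) -> None:
    """Write a collapsed library as a diff-able TSV.

    Layout: a '#'-prefixed header line naming the role and total reads,
    a '#'-prefixed column line, then one tab-separated row per sequence
    (descending count, ties lexicographic).
    """
    with _open_text(Path(path), "wt") as handle:
        handle.write(f"# role={lib.role}\ttotal_reads={lib.total_reads}\n")
        cols = "sequence\tcount" + ("\trpkm" if rpkm is not None else "")
        handle.write(f"# {cols}\n")
        for seq in sorted(lib.counts, key=lambda s: (-lib.counts[s], s)):
            row = f"{seq}\t{lib.counts[seq]}"
            if rpkm is not None:
                row += f"\t{rpkm.get(seq, 0.0):.6g}"
            handle.write(row + "\n")


def read_count_table(path: str | Path) -> CollapsedLibrary:
    """Read a count-table TSV back into a :class:`CollapsedLibrary`.

    Raises on duplicate sequence rows and on non-positive counts; sequence and
    count round-trip losslessly.
    """
    path = Path(path)
    role = "NA"
    counts: dict[str, int] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("role="):
                        role = token.split("=", 1)[1]
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed count-table row: {line!r}")
            seq = normalize_sequence(fields[0])
            count = int(fields[1])
            if seq in counts:
                raise ValueError(f"duplicate sequence row {seq}")
            if count <= 0:
                raise ValueError(f"non-positive count {count} for {seq}")
            counts[seq] = count
    return CollapsedLibrary(role=role, counts=counts)
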