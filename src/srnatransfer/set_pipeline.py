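"""Set-algebra core: collapsing, RPKM, subtraction, intersection, genome
exclusion, and the two-branch candidate derivation.

The experiment contrasts six small-RNA libraries: phloem exudate from control
(PC) and whitefly-infested (PW) leaflets, control leaflets (LC), infested
leaflets with nymphs removed (LW), leaflets carrying only eggs (LE), and the
whitefly nymphs themselves (WN).  Candidate insect-to-plant transferred
sequences are those present in the infested plant samples, absent from every
control, not of host-genome origin, and present in the nymphs:

    phloem branch:  (PW - PC) ∩ WN
    leaf branch:    genome_unmapped((LW - LC) - LE) ∩ WN
    final:          phloem branch ∩ leaf branch

All operations use exact full-length sequence identity; subtraction is
presence/absence (a sequence seen in a control removes it regardless of
abundance, tunable via ``min_count_in_control``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .filtering import matched_sequences
from .io_formats import CollapsedLibrary, ReferenceSet, SRNARecord


@dataclass
class RPKMTable:
    """Per-sequence RPKM values with the per-million denominator used.

    rpkm(s) = count(s) * 1e9 / (length(s) * denominator_reads); the kilobase
    term uses the sequence's own length, the million term the library's
    retained read total.
    """

    values: dict[str, float]
    denominator_reads: int

    def __getitem__(self, seq: str) -> float:
        return self.values[seq]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PipelineResult:
    """Outcome of the two-branch derivation plus per-stage cardinalities."""

    phloem_set: set[str]
    leaf_set: set[str]
    final_set: set[str]
    stage_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.final_set <= self.phloem_set:
            raise ValueError("final set escapes the phloem branch")
        if not self.final_set <= self.leaf_set:
            raise ValueError("final set escapes the leaf branch")

    def stage_counts_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.stage_counts, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def collapse(records: Sequence[SRNARecord], role: str = "NA") -> CollapsedLibrary:
    """Collapse reads to the non-redundant sequence->count map."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.seq] = counts.get(rec.seq, 0) + 1
    return CollapsedLibrary(role=role, counts=counts)


def rpkm(lib: CollapsedLibrary, denominator: int | None = None) -> RPKMTable:
    """Reads per kilobase of sequence per million retained reads.

    ``denominator`` defaults to the library's own retained read total.
    """
    if denominator is None:
        denominator = lib.total_reads
    if denominator <= 0:
        raise ValueError("RPKM denominator must be positive")
    values = {
        seq: count * 1e9 / (len(seq) * denominator)
        for seq, count in lib.counts.items()
    }
    return RPKMTable(values=values, denominator_reads=denominator)


def subtract(
    a: CollapsedLibrary,
    b: CollapsedLibrary,
    min_count_in_control: int = 1,
) -> set[str]:
    """Presence/absence subtraction: sequences of ``a`` not present in ``b``.

    A sequence is "present" in the control ``b`` when its count reaches
    ``min_count_in_control`` (default 1: any single control read excludes).
    """
    return {
        s
        for s in a.counts
        if b.counts.get(s, 0) < min_count_in_control
    }


def intersect(a: Iterable[str], b: CollapsedLibrary) -> set[str]:
    """Sequences of ``a`` that occur in library ``b``."""
    return {s for s in a if s in b.counts}


def genome_exclude(
    seqs: Iterable[str],
    genome: ReferenceSet,
    max_mismatches: int = 0,
) -> set[str]:
    """Keep only sequences that do NOT map to the host genome.

    Matching semantics are identical to the contaminant screen (substring on
    either strand, <= max_mismatches substitutions); the unmatched complement
    is returned.
    """
    if len(genome) == 0:
        raise ValueError("genome reference is empty")
    seqs = set(seqs)
    hit = matched_sequences(seqs, genome, max_mismatches, both_strands=True)
    return seqs - hit


def run_pipeline(
    libraries: Mapping[str, CollapsedLibrary],
    genome: ReferenceSet,
    min_count_in_control: int = 1,
    genome_max_mismatches: int = 0,
) -> PipelineResult:
    """Run the two-branch derivation over the six pre-filtered libraries.

    ``libraries`` maps each role in {PC, PW, LC, LW, LE, WN} to its collapsed,
    length- and contaminant-filtered library.  ``stage_counts`` records the
    non-redundant cardinality after every stage, in workflow order.
    """
    missing = {"PC", "PW", "LC", "LW", "LE", "WN"} - set(libraries)
    if missing:
        raise ValueError(f"missing library roles: {sorted(missing)}")

    pc, pw = libraries["PC"], libraries["PW"]
    lc, lw, le = libraries["LC"], libraries["LW"], libraries["LE"]
    wn = libraries["WN"]

    stage_counts: dict[str, int] = {
        f"{role}_nonredundant": len(libraries[role]) for role in ("PC", "PW", "LC", "LW", "LE", "WN")
    }

    pw_minus_pc = subtract(pw, pc, min_count_in_control)
    stage_counts["PW_minus_PC"] = len(pw_minus_pc)
    phloem_set = intersect(pw_minus_pc, wn)
    stage_counts["phloem_branch_in_WN"] = len(phloem_set)

    lw_minus_lc = subtract(lw, lc, min_count_in_control)
    stage_counts["LW_minus_LC"] = len(lw_minus_lc)
    lw_lc_le = {
        s for s in lw_minus_lc if le.counts.get(s, 0) < min_count_in_control
    }
    stage_counts["LW_minus_LC_minus_LE"] = len(lw_lc_le)
    genome_unmapped = genome_exclude(lw_lc_le, genome, genome_max_mismatches)
    stage_counts["leaf_genome_unmapped"] = len(genome_unmapped)
    leaf_set = intersect(genome_unmapped, wn)
    stage_counts["leaf_branch_in_WN"] = len(leaf_set)

    final_set = phloem_set & leaf_set
    stage_counts["final"] = len(final_set)

    result = PipelineResult(
        phloem_set=phloem_set,
        leaf_set=leaf_set,
        final_set=final_set,
        stage_counts=stage_counts,
    )
    result.validate()
    return result


def recovery_metrics(final_set: set[str], truth_transferred: set[str]) -> dict[str, float]:
    """Sensitivity and false-discovery rate of the final set vs ground truth."""
    tp = len(final_set & truth_transferred)
    sensitivity = tp / len(truth_transferred) if truth_transferred else float("nan")
    fdr = (len(final_set) - tp) / len(final_set) if final_set else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "true_positives": float(tp)}
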