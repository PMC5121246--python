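"""Stage-1 read cleanup: length filter and contaminant screens.

The contaminant screen replaces an external short-read aligner with an exact
(or bounded-substitution) substring scan: an 18-40-nt query is "matched" when
it occurs as a contiguous substring of a reference entry, on either strand,
with at most ``max_mismatches`` substitutions and no indels.  This is the
dominant behaviour of end-to-end short-read alignment at these query lengths,
is fully deterministic, and makes the matching semantics a single knob.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import CollapsedLibrary, ReferenceSet, SRNARecord, reverse_complement

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 40

#: fixed, logged screen order so removed_by_category is well-defined
DEFAULT_SCREEN_ORDER = ("virus", "ncrna", "transcriptome")


@dataclass
class FilterReport:
    """Accounting of a cleanup stage; counts always add up to the input."""

    input_count: int = 0
    retained_count: int = 0
    removed_by_length: int = 0
    removed_by_category: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        total = (
            self.retained_count
            + self.removed_by_length
            + sum(self.removed_by_category.values())
        )
        if total != self.input_count:
            raise ValueError(
                f"filter accounting broken: {total} != input {self.input_count}"
            )
        if min(
            [self.input_count, self.retained_count, self.removed_by_length]
            + list(self.removed_by_category.values()),
            default=0,
        ) < 0:
            raise ValueError("negative filter count")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "input_count": self.input_count,
                "retained_count": self.retained_count,
                "removed_by_length": self.removed_by_length,
                "removed_by_category": self.removed_by_category,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def length_filter(
    records: Sequence[SRNARecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[SRNARecord], FilterReport]:
    """Keep reads with min_len <= length <= max_len (inclusive), order preserved.

    Defaults drop everything shorter than 18 nt or longer than 40 nt, the
    standard small-RNA retention window.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    retained = [r for r in records if min_len <= r.length <= max_len]
    report = FilterReport(
        input_count=len(records),
        retained_count=len(retained),
        removed_by_length=len(records) - len(retained),
    )
    report.validate()
    return retained, report


def _matched_sequences_exact(
    queries: Iterable[str], ref: ReferenceSet, both_strands: bool
) -> set[str]:
    """Exact substring screen via a sliding-window membership scan."""
    by_len: dict[int, set[str]] = defaultdict(set)
    for q in queries:
        by_len[len(q)].add(q)
    matched: set[str] = set()
    targets = []
    for _, seq in ref.entries:
        targets.append(seq)
        if both_strands:
            targets.append(reverse_complement(seq))
    for target in targets:
        n = len(target)
        for length, qs in by_len.items():
            if length > n:
                continue
            pending = qs - matched
            if not pending:
                continue
            for i in range(n - length + 1):
                window = target[i : i + length]
                if window in pending:
                    matched.add(window)
                    pending.discard(window)
                    if not pending:
                        break
    return matched


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _matches_with_mismatches(query: str, target: str, k: int) -> bool:
    """True if query occurs in target with <= k substitutions (no indels)."""
    m, n = len(query), len(target)
    if m > n:
        return False
    q = _encode(query)
    t = _encode(target)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != q).sum(axis=1)
    return bool((mism <= k).any())


def _matched_sequences_mismatch(
    queries: Iterable[str], ref: ReferenceSet, k: int, both_strands: bool
) -> set[str]:
    targets = []
    for _, seq in ref.entries:
        targets.append(seq)
        if both_strands:
            targets.append(reverse_complement(seq))
    matched: set[str] = set()
    for q in queries:
        for target in targets:
            if _matches_with_mismatches(q, target, k):
                matched.add(q)
                break
    return matched


def matched_sequences(
    queries: Iterable[str],
    ref: ReferenceSet,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> set[str]:
    """Subset of ``queries`` matching ``ref`` under the screen's semantics."""
    queries = set(queries)
    if max_mismatches == 0:
        return _matched_sequences_exact(queries, ref, both_strands)
    return _matched_sequences_mismatch(queries, ref, max_mismatches, both_strands)


def contaminant_screen(
    lib: CollapsedLibrary,
    ref: ReferenceSet,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> tuple[CollapsedLibrary, CollapsedLibrary, FilterReport]:
    """Partition a collapsed library into (clean, matched) against a reference.

    The partition conserves counts exactly: every read of the input ends up in
    exactly one of the two output libraries.
    """
    if len(ref) == 0:
        raise ValueError("reference set is empty")
    hit = matched_sequences(lib.counts, ref, max_mismatches, both_strands)
    clean_counts = {s: c for s, c in lib.counts.items() if s not in hit}
    matched_counts = {s: c for s, c in lib.counts.items() if s in hit}
    clean = CollapsedLibrary(role=lib.role, counts=clean_counts)
    matched = CollapsedLibrary(role=lib.role, counts=matched_counts)
    report = FilterReport(
        input_count=lib.total_reads,
        retained_count=clean.total_reads,
        removed_by_category={ref.category: matched.total_reads},
    )
    report.validate()
    return clean, matched, report


def screen_library(
    lib: CollapsedLibrary,
    references: Sequence[ReferenceSet],
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> tuple[CollapsedLibrary, FilterReport]:
    """Apply a sequence of contaminant screens in the given (logged) order."""
    report = FilterReport(input_count=lib.total_reads)
    current = lib
    for ref in references:
        current, _, stage = contaminant_screen(current, ref, max_mismatches, both_strands)
        for category, removed in stage.removed_by_category.items():
            report.removed_by_category[category] = (
                report.removed_by_category.get(category, 0) + removed
            )
    report.retained_count = current.total_reads
    report.validate()
    return current, report
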