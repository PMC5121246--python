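"""Length-distribution profiling, miRNA-catalog matching and candidate selection.

Candidates for experimental validation are drawn from the pipeline's final
set under four criteria: (1) length within a window (default 23-24 nt),
(2) among the highest nymph (WN) counts, (3) present in LW, PW and WN while
absent from LC, LE and PC, and (4) best catalog homolog is insect-like or
unknown.  Homology annotation uses minimal Levenshtein distance against a
miRNA catalog whose FASTA headers may carry an ``id|taxon`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import edlib

from .io_formats import CollapsedLibrary, ReferenceSet, rna_to_dna
from .set_pipeline import PipelineResult, rpkm

PROFILE_MIN_LEN = 18
PROFILE_MAX_LEN = 40


def length_profile(lib: CollapsedLibrary) -> dict[int, float]:
    """Read-weighted fraction of reads per length, zero-filled over 18-40 nt."""
    if lib.total_reads == 0:
        raise ValueError("cannot profile an empty library")
    profile = {length: 0.0 for length in range(PROFILE_MIN_LEN, PROFILE_MAX_LEN + 1)}
    total = lib.total_reads
    for seq, count in lib.counts.items():
        length = len(seq)
        if length in profile:
            profile[length] += count / total
        else:
            profile[length] = count / total
    return profile


def profile_modes(profile: Mapping[int, float]) -> list[int]:
    """Lengths sorted by descending fraction (ties by length)."""
    return sorted(profile, key=lambda L: (-profile[L], L))


def _edit_distance(a: str, b: str) -> int:
    # edlib works on byte strings; DNA alphabet avoids any U/T ambiguity
    return edlib.align(rna_to_dna(a), rna_to_dna(b), task="distance")["editDistance"]


def split_catalog_id(header: str) -> tuple[str, str]:
    """Split an ``id|taxon`` catalog header; missing taxon -> empty string."""
    if "|" in header:
        cid, taxon = header.split("|", 1)
        return cid, taxon
    return header, ""


def catalog_match(
    lib: CollapsedLibrary,
    catalog: ReferenceSet,
    mode: str = "exact",
    k: int = 2,
) -> dict[str, tuple[str, int]]:
    """Match library sequences against a miRNA catalog.

    ``exact`` mode reports full-sequence identity only; ``edit`` mode reports
    the catalog entry of minimal Levenshtein distance <= k, ties broken by
    catalog order.  Returns sequence -> (catalog id, distance) for matched
    sequences only.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if mode not in {"exact", "edit"}:
        raise ValueError(f"unknown mode {mode!r}")
    matches: dict[str, tuple[str, int]] = {}
    if mode == "exact":
        by_seq: dict[str, str] = {}
        for header, seq in catalog.entries:
            by_seq.setdefault(seq, header)
        for seq in lib.counts:
            if seq in by_seq:
                matches[seq] = (by_seq[seq], 0)
        return matches
    for seq in lib.counts:
        best: tuple[str, int] | None = None
        for header, cat_seq in catalog.entries:
            dist = _edit_distance(seq, cat_seq)
            if dist <= k and (best is None or dist < best[1]):
                best = (header, dist)
                if dist == 0:
                    break
        if best is not None:
            matches[seq] = best
    return matches


def best_homolog(
    seq: str, catalog: ReferenceSet, k: int = 2
) -> tuple[str, int] | None:
    """Minimal-distance catalog homolog within ``k`` edits, or None."""
    best: tuple[str, int] | None = None
    for header, cat_seq in catalog.entries:
        dist = _edit_distance(seq, cat_seq)
        if dist <= k and (best is None or dist < best[1]):
            best = (header, dist)
            if dist == 0:
                break
    return best


@dataclass
class SelectionParams:
    """Knobs of the four-criterion candidate selection."""

    min_len: int = 23
    max_len: int = 24
    top_k_wn: int = 50
    homology_filter: bool = True
    homology_k: int = 2
    insect_taxa: frozenset[str] = frozenset({"insect"})


@dataclass
class CandidateSRNA:
    """One final-set sequence with its per-library counts and criteria flags."""

    seq: str
    counts: dict[str, int]
    rpkm_wn: float
    wn_rank: int
    length_ok: bool
    abundant_in_wn: bool
    presence_pattern_ok: bool
    homology_pref_ok: bool
    best_homolog: tuple[str, int] | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def selected(self) -> bool:
        return (
            self.length_ok
            and self.abundant_in_wn
            and self.presence_pattern_ok
            and self.homology_pref_ok
        )


def annotate_candidates(
    result: PipelineResult,
    libraries: Mapping[str, CollapsedLibrary],
    catalog: ReferenceSet,
    params: SelectionParams | None = None,
) -> list[CandidateSRNA]:
    """Compute the four criteria flags for every final-set sequence.

    Output is sorted by WN count descending, ties by sequence lexicographic;
    ``wn_rank`` is the 1-based position in that order and drives the
    abundance criterion (rank <= top_k_wn).
    """
    params = params or SelectionParams()
    wn = libraries["WN"]
    ordered = sorted(
        result.final_set, key=lambda s: (-wn.counts.get(s, 0), s)
    )
    wn_rpkm = rpkm(wn) if wn.total_reads else None
    candidates: list[CandidateSRNA] = []
    for rank, seq in enumerate(ordered, start=1):
        counts = {role: libraries[role].counts.get(seq, 0) for role in libraries}
        present = all(counts.get(r, 0) > 0 for r in ("LW", "PW", "WN"))
        absent = all(counts.get(r, 0) == 0 for r in ("LC", "LE", "PC"))
        homolog = best_homolog(seq, catalog, params.homology_k)
        if not params.homology_filter or homolog is None:
            pref = True
        else:
            _, taxon = split_catalog_id(homolog[0])
            pref = taxon in params.insect_taxa or taxon == ""
        candidates.append(
            CandidateSRNA(
                seq=seq,
                counts=counts,
                rpkm_wn=wn_rpkm[seq] if wn_rpkm and seq in wn_rpkm.values else 0.0,
                wn_rank=rank,
                length_ok=params.min_len <= len(seq) <= params.max_len,
                abundant_in_wn=rank <= params.top_k_wn,
                presence_pattern_ok=present and absent,
                homology_pref_ok=pref,
                best_homolog=homolog,
            )
        )
    return candidates


def select_candidates(
    result: PipelineResult,
    libraries: Mapping[str, CollapsedLibrary],
    catalog: ReferenceSet,
    params: SelectionParams | None = None,
) -> list[CandidateSRNA]:
    """Candidates passing all four criteria, WN-count order."""
    return [c for c in annotate_candidates(result, libraries, catalog, params) if c.selected]


def write_candidate_table(
    candidates: Sequence[CandidateSRNA], path: str | Path
) -> None:
    """Candidate report TSV: sequence, length, per-role counts, WN RPKM,
    homolog and distance, the four flags, and the selection verdict."""
    roles = ("PC", "PW", "LC", "LW", "LE", "WN")
    with open(path, "w") as handle:
        handle.write(
            "# id\tsequence\tlength\t"
            + "\t".join(f"count_{r}" for r in roles)
            + "\trpkm_wn\twn_rank\tbest_homolog\thomolog_distance"
            "\tlength_ok\tabundant_in_wn\tpresence_pattern_ok\thomology_pref_ok\tselected\n"
        )
        for i, c in enumerate(candidates, start=1):
            homolog_id, dist = ("", "")
            if c.best_homolog is not None:
                homolog_id, dist = c.best_homolog[0], str(c.best_homolog[1])
            handle.write(
                f"cand_{i:05d}\t{c.seq}\t{c.length}\t"
                + "\t".join(str(c.counts.get(r, 0)) for r in roles)
                + f"\t{c.rpkm_wn:.4f}\t{c.wn_rank}\t{homolog_id}\t{dist}"
                + "".join(
                    f"\t{int(flag)}"
                    for flag in (
                        c.length_ok,
                        c.abundant_in_wn,
                        c.presence_pattern_ok,
                        c.homology_pref_ok,
                        c.selected,
                    )
                )
                + "\n"
            )
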