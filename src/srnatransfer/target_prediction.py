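"""Plant mRNA target prediction for candidate sRNAs.

Implements the classic expectation-score scheme used by plant sRNA target
servers: the sRNA's 5'-most scoring region (default 20 nt) is slid antisense
along each transcript; every aligned position contributes 0 for a
Watson-Crick pair, 0.5 for a G:U wobble and 1.0 for a mismatch (2.0 per gap
when gapped search is enabled), and penalties are doubled when the sRNA
position falls in the core region (positions 2-13 from the 5' end).  Sites
with total expectation <= cutoff (default 5.0) are reported.  Target-site
accessibility (UPE) is a plug-in contract only: when a callable is supplied
it receives (transcript sequence, site start, site end) and returns an
opening energy; hits above ``upe_cutoff`` are then dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .io_formats import ReferenceSet, normalize_sequence

#: Watson-Crick antisense pairs in the RNA alphabet
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
#: G:U wobble pairs
_GU = {("G", "U"), ("U", "G")}

AccessibilityFn = Callable[[str, int, int], float]


@dataclass
class TargetParams:
    """Scoring parameters; defaults reconstruct the standard server scheme."""

    scoring_region_len: int = 20
    expectation_cutoff: float = 5.0
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    core_region: tuple[int, int] = (2, 13)  # 1-based, inclusive, on the sRNA
    upe_cutoff: float = 25.0

    def validate(self) -> None:
        if self.scoring_region_len < 1:
            raise ValueError("scoring_region_len must be >= 1")
        if min(self.mismatch_penalty, self.gu_penalty, self.gap_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        if self.expectation_cutoff < 0:
            raise ValueError("expectation_cutoff must be non-negative")


@dataclass
class TargetHit:
    """One predicted sRNA->transcript site.

    ``start``/``end`` are 1-based inclusive on the transcript sense strand.
    ``alignment`` holds (sRNA 5'->3', pairing marks, target site 3'->5') with
    '|' for Watson-Crick, 'o' for G:U wobble and '.' for mismatch.
    """

    srna_seq: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    alignment: tuple[str, str, str]
    upe: float | None = None


def _position_penalty(s_base: str, t_base: str, pos_1based: int, params: TargetParams) -> tuple[float, str]:
    pair = (s_base, t_base)
    if pair in _WC:
        return 0.0, "|"
    lo, hi = params.core_region
    factor = 2.0 if lo <= pos_1based <= hi else 1.0
    if pair in _GU:
        return params.gu_penalty * factor, "o"
    return params.mismatch_penalty * factor, "."


def score_site(srna_region: str, site: str, params: TargetParams) -> tuple[float, tuple[str, str, str]]:
    """Expectation of one ungapped antisense alignment.

    ``site`` is the transcript window on the sense strand, same length as the
    scoring region; sRNA position p (5'->3') pairs with site position
    len(site)-p (the site read 3'->5').
    """
    if len(srna_region) != len(site):
        raise ValueError("scoring region and site length differ")
    total = 0.0
    marks = []
    site_rev = site[::-1]  # align 3'->5' under the sRNA 5'->3'
    for i, (s_base, t_base) in enumerate(zip(srna_region, site_rev)):
        penalty, mark = _position_penalty(s_base, t_base, i + 1, params)
        total += penalty
        marks.append(mark)
    return total, (srna_region, "".join(marks), site_rev)


def predict_targets(
    srna: str,
    transcripts: ReferenceSet,
    params: TargetParams | None = None,
    accessibility: AccessibilityFn | None = None,
) -> list[TargetHit]:
    """Scan every transcript position for antisense pairing of the sRNA.

    The scoring region is the sRNA's first ``scoring_region_len`` nucleotides
    from the 5' end, truncated to the sRNA length when shorter.  Hits are
    sorted by (expectation, transcript id, start).
    """
    params = params or TargetParams()
    params.validate()
    srna = normalize_sequence(srna)
    region_len = min(params.scoring_region_len, len(srna))
    region = srna[:region_len]
    hits: list[TargetHit] = []
    for transcript_id, tseq in transcripts.entries:
        n = len(tseq)
        for start0 in range(n - region_len + 1):
            site = tseq[start0 : start0 + region_len]
            expectation, alignment = score_site(region, site, params)
            if expectation > params.expectation_cutoff:
                continue
            upe = None
            if accessibility is not None:
                upe = accessibility(tseq, start0 + 1, start0 + region_len)
                if upe > params.upe_cutoff:
                    continue
            hits.append(
                TargetHit(
                    srna_seq=srna,
                    transcript_id=transcript_id,
                    start=start0 + 1,
                    end=start0 + region_len,
                    expectation=expectation,
                    alignment=alignment,
                    upe=upe,
                )
            )
    hits.sort(key=lambda h: (h.expectation, h.transcript_id, h.start))
    return hits


def recompute_expectation(hit: TargetHit, params: TargetParams | None = None) -> float:
    """Audit: re-derive the expectation from the stored alignment strings."""
    params = params or TargetParams()
    srna_aln, _, site_rev = hit.alignment
    total = 0.0
    for i, (s_base, t_base) in enumerate(zip(srna_aln, site_rev)):
        penalty, _ = _position_penalty(s_base, t_base, i + 1, params)
        total += penalty
    return total


def format_target_table(
    hits: Sequence[TargetHit],
    annotations: Mapping[str, str] | None = None,
    path: str | Path | None = None,
) -> list[dict[str, object]]:
    """One report row per hit: sRNA sequence/length, target, score, annotation."""
    annotations = annotations or {}
    rows: list[dict[str, object]] = []
    for hit in hits:
        rows.append(
            {
                "srna_sequence": hit.srna_seq,
                "length": len(hit.srna_seq),
                "mrna_target": hit.transcript_id,
                "target_start": hit.start,
                "target_end": hit.end,
                "expectation": hit.expectation,
                "upe": "n/a" if hit.upe is None else f"{hit.upe:.2f}",
                "annotation": annotations.get(hit.transcript_id, ""),
            }
        )
    if path is not None:
        header = [
            "srna_sequence", "length", "mrna_target", "target_start",
            "target_end", "expectation", "upe", "annotation",
        ]
        with open(path, "w") as handle:
            handle.write("# " + "\t".join(header) + "\n")
            for row in rows:
                handle.write("\t".join(str(row[col]) for col in header) + "\n")
    return rows
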