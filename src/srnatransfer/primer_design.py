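"""Stem-loop RT-PCR primer design for small RNAs.

Follows the pulsed stem-loop RT scheme: a universal hairpin RT primer whose
3' end is extended with the reverse complement of the sRNA's last
``anchor_len`` nucleotides (default 6), an sRNA-specific forward primer built
from the sRNA 5' prefix plus a GC-rich 5' extension tuned into a melting
temperature window, and a universal reverse primer nested in the hairpin.
All primers are emitted in the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .io_formats import normalize_sequence, reverse_complement, rna_to_dna

#: published universal stem-loop backbone (hairpin) for pulsed RT
DEFAULT_BACKBONE = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"
#: published universal reverse primer nested in the hairpin
DEFAULT_UNIVERSAL_REVERSE = "GTGCAGGGTCCGAGGT"
#: GC-rich 5' tail drawn from when the forward primer needs a Tm boost
DEFAULT_EXTENSION_TAIL = "GCGCGC"


@dataclass
class PrimerParams:
    """Constants of the stem-loop scheme; loadable from YAML config."""

    anchor_len: int = 6
    backbone: str = DEFAULT_BACKBONE
    universal_reverse: str = DEFAULT_UNIVERSAL_REVERSE
    extension_tail: str = DEFAULT_EXTENSION_TAIL
    tm_target: tuple[float, float] = (50.0, 62.0)
    min_forward_core: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrimerParams":
        data = yaml.safe_load(Path(path).read_text())
        if "tm_target" in data:
            data["tm_target"] = tuple(data["tm_target"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {**self.__dict__, "tm_target": list(self.tm_target)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class PrimerSet:
    """The three primers detecting one sRNA, plus the expected amplicon size."""

    srna_seq: str
    rt_primer: str
    forward_primer: str
    forward_extension: str
    reverse_primer: str
    forward_tm: float
    tm_in_window: bool
    expected_amplicon_len: int


def wallace_tm(primer: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C), degrees C."""
    at = sum(primer.count(b) for b in "AT")
    gc = sum(primer.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def design_stemloop(srna: str, params: PrimerParams | None = None) -> PrimerSet:
    """Design the RT, forward and universal reverse primers for one sRNA.

    The RT primer is backbone + revcomp(3'-terminal ``anchor_len`` nt, DNA).
    The forward primer core is a prefix of the sRNA reaching at most up to the
    anchored 3' region; it is trimmed from its 3' side or extended with the GC
    tail to bring the Wallace Tm into the target window (best-effort, flagged
    when unattainable).
    """
    params = params or PrimerParams()
    seq = normalize_sequence(srna)
    if len(seq) < params.anchor_len + 8:
        raise ValueError(
            f"sRNA of {len(seq)} nt too short for anchor_len={params.anchor_len}"
        )

    anchor = seq[-params.anchor_len:]
    rt_primer = params.backbone + rna_to_dna(reverse_complement(anchor))

    core_full = rna_to_dna(seq[: len(seq) - params.anchor_len])
    lo, hi = params.tm_target

    # candidate forward primers: every 3'-trim of the prefix core, then
    # GC-tail extensions of the full core; prefer in-window, then longest
    candidates: list[tuple[str, str]] = []  # (extension, core_used)
    for core_len in range(params.min_forward_core, len(core_full) + 1):
        candidates.append(("", core_full[:core_len]))
    for ext_len in range(1, len(params.extension_tail) + 1):
        candidates.append((params.extension_tail[-ext_len:], core_full))

    def keyed(cand: tuple[str, str]) -> tuple[float, int]:
        ext, core = cand
        tm = wallace_tm(ext + core)
        dist = 0.0 if lo <= tm <= hi else min(abs(tm - lo), abs(tm - hi))
        return (dist, -len(core))

    extension, core = min(candidates, key=keyed)
    forward = extension + core
    tm = wallace_tm(forward)

    amplicon = len(params.backbone) + len(seq) - params.anchor_len + len(extension)
    return PrimerSet(
        srna_seq=seq,
        rt_primer=rt_primer,
        forward_primer=forward,
        forward_extension=extension,
        reverse_primer=params.universal_reverse,
        forward_tm=tm,
        tm_in_window=lo <= tm <= hi,
        expected_amplicon_len=amplicon,
    )


def write_primer_table(
    primer_sets: Sequence[PrimerSet], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write(
            "# srna_sequence\trt_primer\tforward_primer\treverse_primer"
            "\tforward_tm\ttm_in_window\texpected_amplicon_len\n"
        )
        for ps in primer_sets:
            handle.write(
                f"{ps.srna_seq}\t{ps.rt_primer}\t{ps.forward_primer}\t"
                f"{ps.reverse_primer}\t{ps.forward_tm:.1f}\t{int(ps.tm_in_window)}\t"
                f"{ps.expected_amplicon_len}\n"
            )
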