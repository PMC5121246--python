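"""Ground-truth simulator for the six-library infestation experiment.

Emulates the statistical structure the analysis assumes: plant libraries
(PC, PW, LC, LW, LE) carry a host-genome read background with a major 24-nt
and a minor 21-nt length peak; the insect library (WN) carries peaks at 22 nt
(miRNA-sized) and 29-30 nt (piRNA-sized); "transferred" sequences are planted
only in {WN, PW, LW}, egg-specific sequences only in {LE, LW}, and a shared
contaminant pool (ncRNA/virus-derived windows) is mixed into every library.

Transferred and egg sequences are generated by rejection sampling to share no
18-mer (either strand) with the host genome or the contaminant references, so
genome exclusion and contaminant screens cannot silently delete them.  A
``n_decoys`` knob plants genome-derived sequences with the transferred
presence pattern to verify the pipeline drops host-origin look-alikes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io_formats import (
    ROLES,
    CollapsedLibrary,
    ReferenceSet,
    SRNARecord,
    reverse_complement,
    write_fastq,
    write_reference,
)

#: published whitefly-associated candidate sRNA sequences with the species
#: group of their best-known miRNA homolog ('' = no known homolog); these seed
#: every synthetic miRNA catalog so homology annotation has realistic anchors.
KNOWN_INSECT_SRNAS: tuple[tuple[str, str, str], ...] = (
    ("wfl-cand-01", "ACCGGCGGCGCGGUGAGGCACC", ""),
    ("wfl-cand-02", "CACCGGCGGCGCGGUGAGGCACC", ""),
    ("api-miR-263b", "CACCGGAAGGAUUGACAGAUU", "insect"),
    ("bmo-miR-1175", "UGAGAUUCAACUCCUCCAUCUUAU", "insect"),
    ("mdo-miR-885", "AGCAGAGUGGCGCAGUGGAAGC", "vertebrate"),
    ("wfl-cand-3182", "UAGUAGCUAACGACGAUUCCUUU", ""),
    ("pre-miR-124", "UAAGGCACGCGGUGAAUGCCAUU", "nematode"),
    ("api-miR-2765", "UGGUAACUCCACACCACCGUUGGC", "insect"),
    ("ppy-miR-118", "GCGGGUGUCGGCGGCCGUG", "vertebrate"),
    ("ame-bantam", "UGAGAUCAUCGUGAAAGCUGAUA", "insect"),
    ("pma-miR-133a", "CAAGCUCGUUGAAGUAUACCCAU", "vertebrate"),
    ("dpu-miR-252a", "UAAGUACUCCGUGCCGCAGGA", "insect"),
    ("esi-miR3453", "UCAGGCGGGCAAUCGCCGGG", "other"),
    ("ppy-miR-1181", "UCGCGGGUGUCGGCGGCCGUGAGC", "vertebrate"),
    ("mmu-miR-3104", "GGCGGCAAUCGCCGGGGCCCU", "vertebrate"),
    ("dme-miR-184", "UGGACGGAGAACUGAUAAGGGCU", "insect"),
    ("mdo-miR-7398j", "AUACAGGGGAGUAAGGGUUUGU", "vertebrate"),
    ("bmo-miR-1175-3p", "UGAGAUUCAACUCCUCCAUCUUA", "insect"),
    ("eca-miR-1905a", "GAAGGCCCUACAACGCGGACCCC", "vertebrate"),
    ("dme-miR-13b-1", "UAUCACAGCCAUUUUGACGUGCCU", "insect"),
    ("dme-miR-305", "AUUGUACUUCAUCAGGUGCUCUGU", "insect"),
    ("oan-miR-1334", "UUAAAAAGUGAUUUCACCACGG", "vertebrate"),
)

_LENGTHS = tuple(range(18, 41))
_BASES = np.array(list("ACGU"))
_KMER = 18  # disjointness granularity == minimum retained read length


def _default_plant_weights() -> dict[int, float]:
    """Leaf-like profile: major 24-nt peak (~37%), minor 21-nt peak."""
    rest = (1.0 - 0.37 - 0.12) / (len(_LENGTHS) - 2)
    w = {length: rest for length in _LENGTHS}
    w[24] = 0.37
    w[21] = 0.12
    return w


def _default_insect_weights() -> dict[int, float]:
    """Nymph-like profile: miRNA peak at 22 nt, piRNA peak at 29-30 nt."""
    rest = (1.0 - 0.13 - 0.095 - 0.095) / (len(_LENGTHS) - 3)
    w = {length: rest for length in _LENGTHS}
    w[22] = 0.13
    w[29] = 0.095
    w[30] = 0.095
    return w


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; the seed fully determines output."""

    seed: int = 0
    reads_per_library: dict[str, int] = field(
        default_factory=lambda: {role: 100_000 for role in ROLES}
    )
    n_transferred: int = 50
    n_egg_specific: int = 30
    n_insect_only: int = 500
    n_plant_loci: int = 20
    locus_length: int = 5_000
    n_transcripts: int = 60
    contaminant_fraction: float = 0.05
    n_contaminant_windows: int = 200
    plant_length_weights: dict[int, float] = field(default_factory=_default_plant_weights)
    insect_length_weights: dict[int, float] = field(default_factory=_default_insect_weights)
    transferred_length_range: tuple[int, int] = (21, 24)
    sequencing_error_rate: float = 0.0
    detection_floor: int = 5
    transferred_extra_mean: float = 5.0
    egg_in_lw_rate: float = 0.3
    n_decoys: int = 0
    n_catalog_random: int = 60
    catalog_in_wn: int = 25
    transferred_from_catalog_fraction: float = 0.2

    def validate(self) -> None:
        for name, weights in (
            ("plant_length_weights", self.plant_length_weights),
            ("insect_length_weights", self.insect_length_weights),
        ):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} has negative weights")
        for role in ROLES:
            if self.reads_per_library.get(role, 0) < 0:
                raise ValueError("read counts must be non-negative")
        for n in (self.n_transferred, self.n_egg_specific, self.n_insect_only,
                  self.n_plant_loci, self.n_decoys):
            if n < 0:
                raise ValueError("counts must be non-negative")
        lo, hi = self.transferred_length_range
        if not (1 <= lo <= hi):
            raise ValueError("bad transferred_length_range")
        if not (0.0 <= self.contaminant_fraction <= 1.0):
            raise ValueError("contaminant_fraction must be in [0,1]")
        if not (0.0 <= self.sequencing_error_rate < 1.0):
            raise ValueError("sequencing_error_rate must be in [0,1)")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            **self.__dict__,
            "transferred_length_range": list(self.transferred_length_range),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "transferred_length_range" in data:
            data["transferred_length_range"] = tuple(data["transferred_length_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TruthTable:
    """Ground-truth label per planted/background sequence.

    Labels are mutually exclusive over {transferred, plant, insect_only, egg,
    contaminant}; genome-derived decoys planted with the transferred presence
    pattern carry label 'plant' and are additionally listed in ``decoys``.
    """

    labels: dict[str, str] = field(default_factory=dict)
    decoys: set[str] = field(default_factory=set)

    @property
    def transferred(self) -> set[str]:
        return {s for s, lab in self.labels.items() if lab == "transferred"}

    def of(self, label: str) -> set[str]:
        return {s for s, lab in self.labels.items() if lab == label}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("# sequence\tlabel\tdecoy\n")
            for seq in sorted(self.labels):
                decoy = 1 if seq in self.decoys else 0
                handle.write(f"{seq}\t{self.labels[seq]}\t{decoy}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        labels: dict[str, str] = {}
        decoys: set[str] = set()
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            seq, label, decoy = line.split("\t")
            labels[seq] = label
            if decoy == "1":
                decoys.add(seq)
        return cls(labels=labels, decoys=decoys)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _kmers(seq: str, k: int = _KMER) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _both_strand_kmers(seq: str, k: int = _KMER) -> set[str]:
    return _kmers(seq, k) | _kmers(reverse_complement(seq), k)


def _sample_novel(
    rng: np.random.Generator,
    length: int,
    occupied: set[str],
    max_tries: int = 200,
) -> str:
    """Random sequence sharing no k-mer (either strand) with ``occupied``."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if not (_both_strand_kmers(seq) & occupied):
            return seq
    raise RuntimeError("could not sample a category-disjoint sequence")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    positions = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGU" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_references(config: SimulationConfig) -> dict[str, ReferenceSet]:
    """Build all reference sets with cross-category k-mer disjointness.

    The host genome is ``n_plant_loci`` random loci; the transcriptome is exact
    substrings of the genome; ncRNA, virus and symbiont sets share no 18-mer
    (either strand) with the genome or each other; the miRNA catalog combines
    the built-in published sequences with random insect-like 20-24-nt entries.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    loci = [
        (f"locus_{i:03d}", _random_seq(rng, config.locus_length))
        for i in range(config.n_plant_loci)
    ]
    genome = ReferenceSet("host_genome", "genome", loci)

    occupied: set[str] = set()
    for _, seq in loci:
        occupied |= _both_strand_kmers(seq)

    transcripts = []
    for i in range(config.n_transcripts):
        _, locus = loci[rng.integers(0, len(loci))]
        tlen = int(rng.integers(200, min(1200, len(locus)) + 1))
        start = int(rng.integers(0, len(locus) - tlen + 1))
        transcripts.append((f"mRNA_{i:04d}", locus[start : start + tlen]))
    transcriptome = ReferenceSet("host_transcriptome", "transcriptome", transcripts)

    def disjoint_entries(prefix, count, lo, hi):
        entries = []
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = _sample_novel(rng, length, occupied)
            occupied.update(_both_strand_kmers(seq))
            entries.append((f"{prefix}_{i:03d}", seq))
        return entries

    ncrna = ReferenceSet("ncrna", "ncrna", disjoint_entries("ncRNA", 30, 60, 300))
    virus = ReferenceSet("plant_virus", "virus", disjoint_entries("virus", 10, 100, 400))
    symbiont = ReferenceSet(
        "symbiont_genome", "symbiont", disjoint_entries("symbiont", 5, 800, 1200)
    )

    catalog_entries = [
        (f"{cid}|{taxon}" if taxon else cid, seq)
        for cid, seq, taxon in KNOWN_INSECT_SRNAS
    ]
    for i in range(config.n_catalog_random):
        length = int(rng.integers(20, 25))
        catalog_entries.append((f"syn-miR-{i:03d}|insect", _sample_novel(rng, length, occupied)))
    catalog = ReferenceSet("mirna_catalog", "mirna_catalog", catalog_entries)

    return {
        "genome": genome,
        "transcriptome": transcriptome,
        "ncrna": ncrna,
        "virus": virus,
        "symbiont": symbiont,
        "mirna_catalog": catalog,
    }


def _occupied_kmers(references: Mapping[str, ReferenceSet]) -> set[str]:
    occupied: set[str] = set()
    for key in ("genome", "ncrna", "virus", "symbiont"):
        for _, seq in references[key].entries:
            occupied |= _both_strand_kmers(seq)
    return occupied


def generate_experiment(
    config: SimulationConfig,
    references: Mapping[str, ReferenceSet],
    outdir: str | Path,
) -> tuple[dict[str, Path], TruthTable]:
    """Emit the six FASTQ libraries plus a ground-truth table.

    Returns the role->path map and the :class:`TruthTable`.  Under error rate
    0 every planted transferred sequence appears with count >= detection_floor
    in each of WN, PW, LW and count 0 in PC, LC, LE.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 2])

    genome_loci = [seq for _, seq in references["genome"].entries]
    occupied = _occupied_kmers(references)
    planted: set[str] = set()

    def plant_novel(length: int) -> str:
        while True:
            seq = _sample_novel(rng, length, occupied)
            if seq not in planted:
                planted.add(seq)
                return seq

    # transferred sequences: some derived from insect catalog entries by 1-2
    # substitutions (still genome/contaminant-disjoint), the rest fully novel
    lo, hi = config.transferred_length_range
    insect_catalog = [
        seq for rid, seq in references["mirna_catalog"].entries
        if rid.endswith("|insect") and lo <= len(seq) <= hi
    ]
    transferred: list[str] = []
    n_from_catalog = int(round(config.n_transferred * config.transferred_from_catalog_fraction))
    while len(transferred) < config.n_transferred:
        if insect_catalog and len(transferred) < n_from_catalog:
            base = insect_catalog[int(rng.integers(0, len(insect_catalog)))]
            seq = _mutate(rng, base, int(rng.integers(1, 3)))
            if (_both_strand_kmers(seq) & occupied) or seq in planted:
                continue
            planted.add(seq)
        else:
            seq = plant_novel(int(rng.integers(lo, hi + 1)))
        transferred.append(seq)

    egg = [plant_novel(int(rng.integers(20, 31))) for _ in range(config.n_egg_specific)]

    # insect-only pool: random novel sequences plus a slice of the synthetic
    # catalog, so the nymph library contains exactly-matchable known miRNAs
    insect_lengths = sorted(config.insect_length_weights)
    insect_probs = np.array([config.insect_length_weights[L] for L in insect_lengths])
    pool_by_len: dict[int, list[str]] = {L: [] for L in insect_lengths}
    catalog_slice = [
        seq for rid, seq in references["mirna_catalog"].entries if rid.endswith("|insect")
    ][: config.catalog_in_wn]
    for seq in catalog_slice:
        if len(seq) in pool_by_len and seq not in planted:
            planted.add(seq)
            pool_by_len[len(seq)].append(seq)
    for _ in range(config.n_insect_only):
        length = int(insect_lengths[rng.choice(len(insect_lengths), p=insect_probs)])
        pool_by_len[length].append(plant_novel(length))
    for length in insect_lengths:
        if not pool_by_len[length]:
            pool_by_len[length].append(plant_novel(length))
    # skewed within-length abundances, fixed across libraries
    pool_weights = {
        length: rng.exponential(1.0, size=len(seqs)) for length, seqs in pool_by_len.items()
    }
    for length in pool_weights:
        pool_weights[length] /= pool_weights[length].sum()

    # genome-derived decoys planted with the transferred presence pattern
    decoys: list[str] = []
    while len(decoys) < config.n_decoys:
        locus = genome_loci[int(rng.integers(0, len(genome_loci)))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(locus) - length + 1))
        seq = locus[start : start + length]
        if seq not in planted:
            planted.add(seq)
            decoys.append(seq)

    # shared contaminant pool: windows of ncRNA/virus entries, lengths drawn
    # from the plant profile (rRNA/tRNA degradation products are plant-sized)
    contaminant_sources = references["ncrna"].entries + references["virus"].entries
    plant_lengths = sorted(config.plant_length_weights)
    plant_probs = np.array([config.plant_length_weights[L] for L in plant_lengths])
    contaminant_pool: list[str] = []
    while len(contaminant_pool) < config.n_contaminant_windows:
        _, src = contaminant_sources[int(rng.integers(0, len(contaminant_sources)))]
        length = int(plant_lengths[rng.choice(len(plant_lengths), p=plant_probs)])
        if length > len(src):
            continue
        start = int(rng.integers(0, len(src) - length + 1))
        contaminant_pool.append(src[start : start + length])

    truth = TruthTable()
    for seq in transferred:
        truth.labels[seq] = "transferred"
    for seq in egg:
        truth.labels[seq] = "egg"
    for seqs in pool_by_len.values():
        for seq in seqs:
            truth.labels[seq] = "insect_only"
    for seq in contaminant_pool:
        truth.labels.setdefault(seq, "contaminant")
    for seq in decoys:
        truth.labels[seq] = "plant"
        truth.decoys.add(seq)

    def planted_counts(role: str) -> Counter:
        counts: Counter = Counter()
        if role in ("WN", "PW", "LW"):
            for seq in transferred + decoys:
                counts[seq] += config.detection_floor + int(
                    rng.poisson(config.transferred_extra_mean)
                )
        if role == "LE":
            for seq in egg:
                counts[seq] += config.detection_floor + int(
                    rng.poisson(config.transferred_extra_mean)
                )
        if role == "LW":
            for seq in egg:
                extra = int(rng.poisson(config.detection_floor * config.egg_in_lw_rate))
                if extra:
                    counts[seq] += extra
        return counts

    def sample_plant_reads(n: int) -> list[str]:
        lengths = rng.choice(plant_lengths, size=n, p=plant_probs)
        loci_idx = rng.integers(0, len(genome_loci), size=n)
        offsets = rng.random(n)
        out = []
        for L, li, u in zip(lengths, loci_idx, offsets):
            locus = genome_loci[li]
            start = int(u * (len(locus) - L + 1))
            out.append(locus[start : start + L])
        return out

    def sample_insect_reads(n: int) -> list[str]:
        lengths = rng.choice(insect_lengths, size=n, p=insect_probs)
        out = []
        for length, n_len in zip(*np.unique(lengths, return_counts=True)):
            seqs = pool_by_len[int(length)]
            idx = rng.choice(len(seqs), size=int(n_len), p=pool_weights[int(length)])
            out.extend(seqs[int(i)] for i in idx)
        return out

    paths: dict[str, Path] = {}
    for role in ROLES:
        n_total = config.reads_per_library.get(role, 0)
        path = outdir / f"{role}.fastq"
        paths[role] = path
        if n_total == 0:
            warnings.warn(f"library {role} configured with 0 reads; emitting empty file")
            path.write_text("")
            continue
        counts = planted_counts(role)
        n_planted = sum(counts.values())
        n_contam = int(round(n_total * config.contaminant_fraction))
        n_background = max(0, n_total - n_planted - n_contam)
        reads: list[str] = []
        for seq, c in counts.items():
            reads.extend([seq] * c)
        for idx in rng.integers(0, len(contaminant_pool), size=n_contam):
            reads.append(contaminant_pool[int(idx)])
        background = sample_insect_reads if role == "WN" else sample_plant_reads
        reads.extend(background(n_background))
        if role != "WN":
            for seq in reads[n_planted + n_contam:]:
                truth.labels.setdefault(seq, "plant")
        order = rng.permutation(len(reads))
        records = []
        for out_idx, read_idx in enumerate(order):
            seq = reads[int(read_idx)]
            if config.sequencing_error_rate > 0:
                n_err = int(rng.binomial(len(seq), config.sequencing_error_rate))
                if n_err:
                    seq = _mutate(rng, seq, n_err)
            records.append(SRNARecord(f"{role}_{out_idx:07d}", seq))
        write_fastq(records, path)

    truth.write_tsv(outdir / "truth.tsv")
    return paths, truth


def simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate references and libraries under one output directory.

    Writes reference FASTAs, six FASTQ libraries, ``truth.tsv`` and the
    resolved ``config.yaml``; returns a name->path map for every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references = generate_references(config)
    paths: dict[str, Path] = {}
    for key, ref in references.items():
        path = outdir / f"{key}.fasta"
        write_reference(ref, path)
        paths[key] = path
    lib_paths, _ = generate_experiment(config, references, outdir)
    paths.update(lib_paths)
    paths["truth"] = outdir / "truth.tsv"
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths


def collapse_truth_counts(path: str | Path) -> CollapsedLibrary:
    """Convenience: collapse an emitted FASTQ directly (for audits)."""
    from .set_pipeline import collapse
    from .io_formats import read_sequences

    records = read_sequences(path, format="fastq")
    return collapse(records, role=Path(path).stem)
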