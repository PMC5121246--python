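# Methods

## The comparative model

The package treats cross-kingdom sRNA transfer detection as a pure
presence/absence problem over non-redundant sequence sets. The underlying
assumptions are: (i) a sequence transferred by the feeding insect appears in
the infested plant samples (PW phloem, LW leaf) and in the insect itself
(WN), but not in any uninfested control (PC, LC) nor in the egg-only control
(LE, which corrects for egg material left on the leaf surface); (ii) host
reads — including those from repetitive regions that escape the control
subtractions — map to the host genome and can be excluded on the leaf
branch; (iii) identity is exact and full-length. No clustering of
near-identical reads is performed: the contract is set membership on unique
sequences, and a fuzzy variant would change the semantics of every
subtraction. Abundance is ignored by the subtractions (one control read
excludes a sequence); a `min_count_in_control` knob exists for sensitivity
analysis and defaults to 1.

The two branches are evaluated in the narrated order — phloem
`(PW − PC) ∩ WN`; leaf `((LW − LC) − LE)`, then genome exclusion, then
`∩ WN` — and the final set is their intersection. Per-stage non-redundant
cardinalities are recorded so a run is auditable end to end.

## Matching semantics

Contaminant screens and genome exclusion use an internal substring scan
instead of an external aligner: a query matches a reference iff it occurs as
a contiguous substring of a reference entry or its reverse complement
(U ≡ T) with at most `max_mismatches` substitutions and no indels. For
18–40-nt queries this is the dominant behaviour of end-to-end short-read
alignment, it is exactly reproducible, and the mismatch tolerance is a
single documented knob (default 0, i.e. exact). Exact matching is a
per-length sliding-window set-membership scan (O(reference length × number
of distinct query lengths)); the mismatch path compares windows with numpy.
Screens run in a fixed, logged order — virus, ncRNA, transcriptome — so the
per-category removal counts are well defined.

## Normalisation

RPKM is `count × 10⁹ / (length × denominator)` with the denominator equal to
the reads retained for that library after length and contaminant filtering.
The "per million mapped reads" denominator is genuinely ambiguous for a
library whose insect reads have no host genome to map to; retained-read
normalisation is the package's documented choice and the denominator is
stored alongside every table so the counts are exactly recoverable
(`rpkm · length · denominator / 10⁹`).

## Candidate selection

Four predicates, each stored as an independent flag so the conjunction is
auditable: length within 23–24 nt (the plant-silencing-competent sizes
among the transferred range); WN-count rank ≤ `top_k_wn` (default 50 — the
abundance criterion is stated qualitatively in the field, so a rank cutoff
is used and both rank and raw count are reported); the strict six-library
presence/absence pattern; and a best catalog homolog that is insect-like or
unknown. Homology uses minimal Levenshtein distance (edlib) with k = 2 for
annotation; the exact-match mode used for catalog-overlap statistics is
separate. Catalog FASTA headers may carry an `id|taxon` tag; untagged
entries count as unknown and therefore pass the preference filter.

## Target prediction

The expectation score is a reconstruction of the classic plant sRNA target
server scheme: the sRNA's 5′-most 20 nt (truncated for shorter sRNAs) is
slid antisense along each transcript; Watson–Crick pairs cost 0, G:U wobbles
0.5, mismatches 1.0, gaps 2.0, and any penalty at sRNA positions 2–13 is
doubled; sites with expectation ≤ 5.0 are kept. The default scan is ungapped,
which makes it exactly checkable against a brute-force per-position rescoring
oracle; gapped alignment is out of the default path. Whether the published
"seed region length of 20" denotes the scoring window (assumed here) or a
core-doubling region is ambiguous; both are independent parameters
(`scoring_region_len`, `core_region`). Target-site accessibility (UPE,
cutoff 25) is a plug-in contract — a callable from (transcript, site start,
site end) to an opening energy — because secondary-structure thermodynamics
is outside this package's scope; without a plug-in the UPE filter is skipped
and hits carry `upe: n/a`.

## Primer design

The stem-loop scheme: RT primer = universal hairpin backbone + DNA reverse
complement of the sRNA's 3′-terminal `anchor_len` (6) nucleotides; forward
primer = optional GC tail + a prefix of the sRNA (DNA), with the prefix
trimmed from its 3′ side or tail-extended to reach a Wallace-rule Tm window
of 50–62 °C (best effort, flagged when unattainable, minimum core 10 nt);
universal reverse primer constant. Expected amplicon length =
backbone + sRNA length − anchor + forward extension. The backbone and
universal reverse default to the published universal stem-loop sequences
and live in a YAML-loadable config, not in the algorithm. Wallace
(`2(A+T) + 4(G+C)`) is the default Tm model: for primers this short it is
standard, dependency-free and monotone in composition, which is all the
trimming loop needs.

## The simulator

`synthetic_data` generates the whole experiment with known labels:

- **Host genome**: 20 random loci of 5 kb. **Transcriptome**: 60 exact
  genome substrings (200–1200 nt), so plant degradation products are
  screened realistically. **ncRNA / virus / symbiont** sets are generated
  with no shared 18-mer (either strand) with the genome or each other;
  18 is the minimum retained read length, so category disjointness is exact
  at the read level.
- **Plant background** reads are genome windows with a length profile
  peaking at 24 nt (37 %) and 21 nt (12 %), the canonical leaf pattern.
  **Insect (WN) background** reads come from a 500-sequence pool with
  skewed abundances and peaks at 22 nt (13 %) and 29–30 nt (9.5 % each),
  the miRNA + piRNA pattern of whitefly nymphs. One length profile is used
  for all plant libraries; phloem in reality peaks slightly lower (23–24 nt)
  but nothing downstream depends on that distinction.
- **Transferred** sequences (default 50, lengths 21–24 nt) are planted in
  WN, PW and LW at `detection_floor` (5) + Poisson(5) copies and are, by
  rejection sampling, absent from the genome and every contaminant
  reference — so the pipeline's screens cannot silently delete them, and a
  failure to recover one is a pipeline defect, not a simulation artifact.
  A fraction (20 %) is derived from insect catalog entries by 1–2
  substitutions so homology annotation has realistic near-matches.
  `n_decoys` plants genome-derived windows with the same presence pattern to
  verify the genome-exclusion step removes host-origin look-alikes.
- **Egg-specific** sequences occur in LE (at the floor) and at a lower rate
  in LW, exercising the LE subtraction. **Contaminants** are windows of the
  ncRNA/virus references shared across all six libraries, 5 % of reads,
  with plant-profile lengths.
- A per-base substitution error knob (default 0) measures the sensitivity
  cost of exact matching; the presence/absence guarantees hold exactly only
  at rate 0.

What the simulator does not emulate: base-quality structure, adapters,
ligation or PCR bias, true genomic repeat structure, spike-ins, and real
miRNA biogenesis (sequences are i.i.d. uniform). Passing tests therefore
demonstrate the correctness of the algebra, the screens and the selection
logic under the design's assumptions — not robustness to real-library
artifacts such as adapter read-through or abundance-dependent ligation bias.

## Numerical and degenerate-input choices

Everything outside the simulator is deterministic; simulator output is fully
determined by the seed (single generator, fixed draw order). Ties in WN-count
ranking and in output ordering break lexicographically on the sequence; ties
in catalog homology break by catalog order. Empty libraries are legal
everywhere except length profiling (error) and RPKM with a zero denominator
(error); a zero-read library role is emitted as an empty FASTQ with a
warning. Sequences with characters outside {A,C,G,T,U} are rejected at
parse time with an exception naming the offending characters.

## Problem sizes

Unit tests run the six-library design at 8,000 reads per library; the
acceptance workflow uses the default 100,000 reads per library (600,000
total), 50 transferred sequences, floor 5 — large enough that empirical
length histograms sit within ±3 percentage points of their configured
weights and the recovery statement (sensitivity 1.0, FDR 0.0) is exercised
against ~90,000 non-redundant background sequences per plant library.

## Known limitations

- Exact-identity algebra is brittle to sequencing error by construction;
  the error knob quantifies the cost but the package offers no
  error-tolerant collapsing.
- The substring screen is not a spliced or gapped aligner; references with
  introns relative to the reads would need external preprocessing.
- Homology annotation depends entirely on the supplied catalog; taxon tags
  are taken at face value from headers.
- Target prediction reconstructs a scoring scheme; absolute agreement with
  any particular web server version is not guaranteed and gapped sites are
  not searched by default.
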