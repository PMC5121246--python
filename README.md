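# srnatransfer

Detection of insect small RNAs transferred into host-plant tissue from
comparative small-RNA sequencing, built around the whitefly–tomato feeding
system: phloem-feeding whitefly nymphs salivate into the sieve elements of
the leaflets they colonise, and sRNAs of insect origin can be recovered from
the host phloem and leaf sRNA-seq libraries. The package implements the
complete comparative workflow — read cleanup, non-redundant collapsing and
RPKM normalisation, presence/absence set algebra across six libraries,
candidate selection with miRNA-catalog homology annotation, plant mRNA
target prediction, and stem-loop RT-PCR primer design — together with a
ground-truth simulator that generates the entire experiment synthetically so
every step can be validated against a known answer.

## The design and the statistic

Six libraries are compared: control phloem (PC), whitefly-infested phloem
(PW), control leaf (LC), infested leaf with nymphs removed (LW), leaf
carrying only whitefly eggs (LE) and the whitefly nymphs themselves (WN).
After an 18–40-nt length filter and contaminant screens (plant viruses,
rRNA/tRNA/snoRNA-type ncRNA, degraded transcriptome), each library is
collapsed to its non-redundant sequence set and candidates putatively
transferred from insect to plant are derived by exact set algebra:

```
phloem branch:  (PW − PC) ∩ WN
leaf branch:    genome_unmapped((LW − LC) − LE) ∩ WN
final set:      phloem branch ∩ leaf branch
```

A sequence in the final set is present in infested phloem and infested leaf,
absent from every control (including the egg-only control, which corrects
for eggs left on the leaf surface), does not map to the host genome, and is
carried by the nymphs. Abundances are reported as RPKM,
`count · 10⁹ / (length · retained reads)`. Validation candidates are then
chosen by four criteria: length 23–24 nt, among the highest WN counts,
the strict presence/absence pattern above, and a best miRNA-catalog homolog
that is insect-like or unknown. For each candidate the package predicts
host mRNA targets by an expectation score over a 20-nt antisense scoring
window (mismatch 1, G:U wobble 0.5, gap 2, doubled in the core positions
2–13; sites with expectation ≤ 5 reported) and designs stem-loop RT-PCR
primer sets (hairpin RT primer anchored on the sRNA 3′-terminal hexamer,
sRNA-specific forward primer tuned to a Tm window, universal reverse).

## Worked example

```
$ srnatransfer simulate --config wf.yaml --outdir wf_sim     # 6 × 20,000 reads, 40 planted
$ srnatransfer run --indir wf_sim --outdir wf_run
...
INFO srnatransfer: stage PW_minus_PC: 7148
INFO srnatransfer: stage phloem_branch_in_WN: 40
INFO srnatransfer: stage LW_minus_LC: 7217
INFO srnatransfer: stage LW_minus_LC_minus_LE: 6610
INFO srnatransfer: stage leaf_genome_unmapped: 40
INFO srnatransfer: stage leaf_branch_in_WN: 40
INFO srnatransfer: stage final: 40
final_set=40 selected=20
$ srnatransfer report --rundir wf_run
...
Length-profile modes:
  LC: mode 24 nt (37.3% of reads)
  WN: mode 22 nt (12.9% of reads)
```

The run planted 40 transferred sequences; the set algebra narrows ~7,000
infestation-specific phloem sequences down to exactly those 40 (`final: 40`,
sensitivity 1.0, no false discoveries), of which 20 also satisfy the four
selection criteria (the others fall outside the 23–24-nt window or the WN
abundance cutoff). Leaf libraries show the plant-typical 24-nt peak, the
nymph library the insect-typical 22-nt miRNA peak plus a 29–30-nt piRNA-like
peak. Primer design for a 23-nt candidate:

```
$ srnatransfer primers --srna UAGUAGCUAACGACGAUUCCUUU --out primers.tsv
# rt_primer ends in AAAGGA — the DNA reverse complement of the 3' hexamer UCCUUU
GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACAAAGGA   (RT, 50 nt)
CTAGTAGCTAACGACGAT                                   (forward, Tm 52 °C)
GTGCAGGGTCCGAGGT                                     (universal reverse)
```

Target prediction against the synthetic transcriptome
(`srnatransfer targets --srna ... --transcripts wf_sim/transcriptome.fasta`)
reports no sites at the default cutoff, as expected for random reference
sequences with no planted complementarity.

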