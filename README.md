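# mosste

Measuring transposable-element (TE) activity in compact plant genomes —
expression, insertion age and recent mobility — the careful way.

In moss-like genomes (the motivating system is *Physcomitrium patens*,
where TEs cover more than half the genome), fragmented and degenerate TE
copies vastly outnumber complete, potentially functional elements. Counting
RNA-Seq reads against the TE annotation therefore overestimates family
expression: solo-LTRs transcribed by read-through from a neighbouring gene
promoter, antisense slices, and chimeric transcription units all look like
TE expression but are not. `mosste` implements the alternative: treat
*assembled transcripts* as the unit of evidence, put each assembly through
a keep/discard curation cascade, quantify only sense reads on the
survivors, date the LTR retrotransposon copies compatible with each
expressed transcript, and post-process insertion-polymorphism calls from
resequenced accessions. A synthetic-data module generates genomes,
transcripts, reads and call tables with known truth, so every stage is
scored against ground truth.

## The core statistics

**Filtering cascade** (per assembly, in order): no credible TE-library hit
(e-value proxy > 10⁻⁵) → `no_hit`; best family flagged as a non-TE library
entry → `poor_annotation`; class-I hit with no alignment > 1000 nt →
`short_classI`; hits confined to the exemplar's LTR regions → `solo_ltr`;
two families each covering ≥ 30% of the query → `chimeric`; best
protein-domain hit on the minus strand (six-frame translation vs. domain
consensus) → `antisense`; otherwise kept.

**Expression** of a kept assembly in a condition:

    value = sense_reads / (assembly_length_kb × total_trimmed_reads) × 10⁶

**Insertion age** of an LTR retrotransposon copy, from its two LTRs
(identical at insertion, diverging independently afterwards): with P and Q
the transition and transversion proportions over gap-free aligned columns,

    K = −½ ln((1 − 2P − Q)·√(1 − 2Q))        (Kimura two-parameter)
    T = K / (2r),   r = 9 × 10⁻⁹ substitutions/site/year

**Expressed-copy rule (80/80)**: a genomic copy is compatible with an
expressed assembly when it shows ≥ 80% identity over ≥ 80% of the
assembly's length (or, in best-hit mode, an e-value proxy ≤ 10⁻⁹⁰).

**Mobility**: keep non-reference insertion calls with zygosity ≥ 0.7, bin
each by point-to-interval distance to the nearest gene (`inside` / `near`,
< 1 kb / `far`), and report the accession × family count matrix and the
near-gene percentage.

## Worked example

One command generates a synthetic study system (two LTR families — one
with young and degenerate old copies — plus a Mariner-like DNA family,
genes, 17 transcripts spanning the genuine class and every decoy class,
reads for four conditions, and insertion calls for three accessions) and
runs all three arms:

```bash
$ mosste demo --seed 42 --out demo/
demo complete: 17 assemblies (3 kept), 10 copies dated, 72 insertion calls kept -> demo/
```

`demo/expression/verdicts.tsv` — exactly the three genuine transcripts
survive; every decoy is discarded with its reason:

```text
assembly_id        best_family  te_class  orientation  verdict    discard_reason  top_hit_identity
ASM_genuine_te_1   RLC_B        I         sense        kept                       0.9967
ASM_genuine_te_2   RLG_A        I         sense        kept                       0.9965
ASM_genuine_te_3   PpTc_C       II        sense        kept                       0.9958
ASM_te_fragment_1  RLG_A        I         unknown      discarded  short_classI    0.9937
```

`demo/expression/expression.tsv` — sense read counts and normalized values
per condition (e.g. 120 reads on a 5.4 kb assembly out of 1167 trimmed
reads in gametophores → 120/(5.4 × 1167) × 10⁶ ≈ 19042):

```text
assembly_id       condition         sense_read_count  assembly_len_kb  total_trimmed_reads  value
ASM_genuine_te_1  gametophore       120               5.4              1167                 19042.18
ASM_genuine_te_1  green_sporophyte  172               5.4              1101                 28929.93
```

`demo/dating/ages.tsv` — K2P distance and age per complete copy, with the
expressed-compatible flag. The young planted copies (~0.3–0.4 Myr) are the
expressed ones; the degenerate old copy is dated ~28 Myr and is not:

```text
copy_id      family  P        Q        K        T_years      expressed_flag
RLC_B_full1  RLC_B   0.00333  0.00167  0.00502  278825       1
RLC_B_full3  RLC_B   0.00583  0.00167  0.00755  419235       1
RLC_B_full4  RLC_B   0.20380  0.15026  0.49742  27634243     0
```

`demo/mobility/summary.tsv` — of 83 calls, 72 pass the zygosity/
non-reference filter, 34.7% of them inside or within 1 kb of a gene:

```text
n_calls_in  n_kept  near_gene_percent
83          72      34.7
```

The same stages are available separately (`mosste classify`, `quantify`,
`date`, `mobility`, `sim ...`, `io validate`, `run --config cfg.yaml`) and
as plain library functions (`mosste.transcripts.filter_assemblies`,
`mosste.dating.kimura2p`, `mosste.mobility.polymorphism_count_matrix`, ...).

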