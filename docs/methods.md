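# Methods

`mosste` re-implements, as a tested pipeline, a strategy for measuring
transposable-element (TE) activity in a compact plant genome of the
*Physcomitrium patens* kind: most TE-derived sequence in such genomes is
fragmented or degenerate, so read counting against the TE annotation
overestimates family expression, and the defensible unit of measurement is
the *assembled transcript* that survives a curation cascade. Around that
core the package adds LTR-pair insertion dating, identification of the
genomic copies compatible with each expressed transcript, and
post-processing of TE insertion-polymorphism calls. Everything is
exercisable on synthetic data with known ground truth.

## Transcript classification cascade

Assemblies (e.g. Trinity contigs built from TE-mapping RNA-Seq reads; the
package consumes them, it does not assemble) are aligned to a TE family
library and filtered in a fixed order. Each rule mechanizes one failure
mode of naive TE expression measurement:

1. **no_hit** — no library alignment passes the e-value cutoff (10⁻⁵ on the
   proxy below) at ≥ 75% identity.
2. **poor_annotation** — the best family is flagged as a non-TE library
   entry (repetitive genes and similar).
3. **short_classI** — for class I (retrotransposon) hits, no alignment
   longer than 1000 nt. Complete LTR retrotransposons are several kb, so a
   short assembly is a fragment — often a bare LTR — not an element mRNA.
4. **solo_ltr** — ≥ 90% of the aligned span falls inside the exemplar's
   annotated LTR regions with ≤ 5% internal-region coverage. Solo-LTRs are
   recombination relics; their transcripts are typically read-through from
   a neighbouring gene promoter. Families without LTR coordinates skip this
   rule (it is undefined for them).
5. **chimeric** — two different families each cover ≥ 30% of the query:
   several degenerate fragments transcribed as one unit.
6. **antisense** — the surviving assembly's best protein-domain hit lies on
   the minus strand (six-frame translation against a domain-consensus
   library, BLOSUM62 local alignment). Antisense transcripts may regulate
   TEs but are not productive TE expression.

The original curation was partly manual; rules 2, 4 and 5 are the
mechanized versions, with thresholds stated in `ClassifierConfig`. The
orientation score threshold (default 100) sits far above the empirical
null — shuffled sequences of the same composition score ≈ 30–45 — and far
below a genuine domain hit (hundreds to thousands).

### Alignment engine and e-value proxy

BLAST is replaced by a self-contained seeded local aligner: exact k-mer
seeding (k = 11) on both strands, diagonal-band chaining, gapped extension
of each chained window (edlib, infix mode), and maximal-scoring end
trimming (Kadane on per-column scores: match +1, mismatch −2, gap −2).
Tool-specific e-values are replaced by a fixed Karlin–Altschul-style proxy
`E = K·m·n·exp(−λ·S)` with λ = 1.28, K = 0.46, m the query length and n
the search-space length (total library length during classification, the
genome length during copy matching). The cutoffs 10⁻⁵ (classification) and
10⁻⁹⁰ (stringent assembly-to-genome matching) are applied to this proxy.
The aligner is validated against a full Smith–Waterman oracle with the
same scoring (identity within 0.02, strand exact, 50 random pairs ≤ 2 kb).

## Expression quantification

Reads are assigned best-hit to the kept assemblies (ties to the smallest
assembly id; placements scoring below half the read length are dropped).
Only sense-strand assignments are counted. The normalized value is

    value = sense_reads / (assembly_length_kb × total_trimmed_reads) × 10⁶,

i.e. reads per kb per million trimmed reads in the condition. The 10⁶
factor is a readability constant — the source procedure's normalization
does not state one — and every cross-condition comparison is invariant to
it. Multi-mapping reads count once at their best placement rather than
fractionally: deterministic and sufficient at the family-consensus level
where the kept assemblies are well separated.

`flag_readthrough` formalizes the neighbour-gene check used to demote
solo-LTR and gene-adjacent TE expression: a TE profile is flagged as
read-through when its Pearson correlation with the neighbouring gene's
profile is ≥ 0.8 across ≥ 4 shared conditions, the distance is ≤ 1 kb and
the strands agree. Zero-variance profiles are reported as not computable
and never flagged.

## LTR-pair insertion dating

The two LTRs of an element are identical at insertion and diverge
independently afterwards. Per copy, the annotated ltr5/ltr3 sequences are
aligned globally (Needleman–Wunsch; match +1, mismatch −1, gap open −2,
extend −1) and the Kimura two-parameter distance is computed over the
gap-free, N-free columns:

    K = −½ ln((1 − 2P − Q)·√(1 − 2Q)),   T = K / (2r),   r = 9×10⁻⁹ /site/yr.

The divisor 2r (not the literal reading "K/2 × r" of the usual shorthand)
is the standard molecular-clock form: the pairwise distance accumulates
along two lineages. Saturated pairs (the log argument ≤ 0) and alignments
with < 50 usable columns are rejected rather than reported. Gap columns
are excluded from the counts; with ≤ 40% divergence this matters little
and keeps P + Q ≤ 1 by construction.

Copies compatible with an expressed assembly ("potentially expressed") are
found either in best-hit mode (e-value proxy ≤ 10⁻⁹⁰) or by the 80/80
rule — identity ≥ 80% over ≥ 80% of the assembly length — and the age
distribution of that subset is compared to all complete copies of the
family with per-group median K/T, fixed-width K histograms (bin width
0.01) and a one-sided Mann–Whitney rank-sum test for "expressed younger";
groups of fewer than 3 are marked `insufficient n`.

## Insertion-polymorphism post-processing

Caller output (a frozen 7-column TSV dialect: accession, seq_id, position,
family, zygosity, in_reference, support; a documented adapter maps real
PoPoolationTE2 "separate mode" output onto it) is filtered to
non-reference calls with zygosity ≥ 0.7 — inclusive, as appropriate for a
haploid-dominant organism where a real insertion should dominate the
locus. Each call is then binned by point-to-interval distance to the
nearest gene, strand-ignored (the bedtools-closest default): `inside`
(distance 0), `near` (< 1 kb), `far` (otherwise; a distance of exactly
1 kb is `far`, since the published bin labels "< 1 kb" and "> 1 kb" leave
the boundary unassigned). Reports are the accession × family count matrix
(totals always recomputed, never stored) and the near-gene percentage.
Family labels are counted verbatim from the caller; an optional alias map
merges labels (e.g. a truncated form with its full-length family) at
counting time instead of guessing.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code and define the package's study
conditions:

- **LTR elements** (`gen_ltr_element`): each LTR is mutated independently
  from a common ancestor under a single-hit K2P process — per site, one
  substitution with probability r·T, a transition with odds R:1 (R the
  expected transition:transversion count ratio, default 2). Expected
  pairwise divergence is 2rT; configurations implying > 0.4 are rejected
  as the saturation regime. Single-hit is adequate below that cap, which
  is also where the dating statistic is trustworthy.
- **Genomes** (`gen_te_genome`): i.i.d. uniform background (no GC
  structure — no stage uses composition), non-overlapping placements of
  full elements, fragments (10–60% slices) and solo-LTRs, with fragments +
  solo-LTRs outnumbering full copies by default, genes of 2 kb, and a
  configurable fraction of TE copies placed within 1 kb of a gene. When
  solo-LTRs, genes and a nonzero adjacency fraction coexist, the first
  solo-LTR per family is forced gene-adjacent so read-through decoys are
  always constructible. A per-copy `extra_divergence` knob models
  lineage-specific degeneration, letting old copies fall below the 80/80
  rule without saturating their LTR pair (age alone cannot take identity
  below ~0.8 within the saturation cap). Simulation LTRs default to
  1200 nt so solo-LTR transcripts exercise the solo-LTR rule rather than
  the length rule; dating simulations use 1 kb.
- **Transcripts** (`gen_transcript_set`): one genuine class (full element
  mRNA, sense) and five decoy classes — short sense fragments (< 1 kb),
  gene-tail + solo-LTR read-through concatenations, antisense
  coding-region slices, two-family chimeras, and plain gene transcripts.
- **Reads** (`gen_reads`): single-end, uniform starts, exact planted
  per-condition counts, per-base substitution errors (default 0.5%), read
  names encode source and strand. Paired-end structure is not simulated:
  the only paired-end consumer (insertion calling) enters as pre-made
  call tables.
- **Insertion calls** (`gen_insertion_calls`): true calls with zygosity
  from a configurable distribution (default U(0.8, 1)), plus a
  false-positive admixture (default zygosity U(0, 0.7), i.e. below the
  confidence cutoff).

Passing tests on this bench show the *logic* is right — the cascade
separates the planted classes, dating is unbiased and monotone, binning
matches an oracle. They do not show robustness to what the bench omits:
real error profiles and quality decay, transcript-assembly artifacts,
nested/recombined TE structures, GC and methylation structure, or mapper
idiosyncrasies.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere in memory; GFF3 is
  converted at the boundary (1-based inclusive on disk).
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical outputs, and every TSV a pipeline arm writes
  starts with a comment line recording version, config hash and seed.
  (FASTA/FASTQ outputs carry no header comment — the formats do not admit
  one cleanly.)
- Ties are broken deterministically throughout: alignment hits by (score,
  subject id, position), equal-scoring families lexicographically, read
  placements by assembly id.
- N bases are allowed; they mismatch everything during alignment and are
  excluded from divergence counts.
- Problem sizes in the tests and the acceptance script (genomes of
  0.2–1 Mb, cohorts of 100 assemblies, 100 dating replicates per age) were
  chosen as the smallest sizes at which the binomial noise of the
  Monte-Carlo checks is comfortably inside the stated tolerances.

## Known limitations

- The aligner is a desk-scale stand-in: no minimizer indexing, no affine
  X-drop extension; it is not meant for genome-scale BLAST workloads.
- Orientation calling uses consensus-sequence alignment, not profile HMMs;
  highly diverged domains may come back `unknown` (never a false
  antisense, which is the damaging direction).
- De novo LTR boundary detection is out of scope; dating requires
  ltr5/ltr3 annotation.
- The e-value proxy is calibrated for determinism, not for agreement with
  any BLAST version's e-values; only the *relative* use (fixed cutoffs) is
  meaningful.
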