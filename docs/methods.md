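# Methods

`caseikit` re-implements, as one tested pipeline, the comparative-genomics
workflow used to delimit clades within the *Lactobacillus casei* group
(*L. casei* / *L. paracasei* / *L. rhamnosus* / *L. zeae*) and to find
clade-diagnostic gene content. This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Pairwise genome metrics

**ANIb.** The query genome is cut into consecutive 1,020-bp fragments (a
final fragment ≥ 100 bp is kept). Each fragment is placed on the subject by
exact 11-mer seeds (every third query k-mer is looked up in a sorted
k-mer/position index of the subject; the best-supported diagonal bin, widened
to neighbouring diagonals within 5 kb, defines the alignment window) and
aligned semi-globally with edlib. Because a unit-cost semi-global aligner
smears regions absent from the subject into mismatches rather than gaps, the
alignment columns are re-scored blastn-style (match +1, mismatch/gap −2) and
the maximal-scoring run defines the *covered* part of the fragment; identity
is reported over the full terminal-trimmed alignment so it reflects the
fragment's overall divergence. A fragment contributes to ANI when identity
> 30% and the covered part exceeds 70% of the fragment — the JSpecies
convention. `exhaustive=True` disables the seed prefilter and scans the whole
subject; on small genomes the two modes agree exactly (tested). Both
directions are computed; classification and reporting use their mean.
Self-ANI is exactly 100; a pair with no passing fragment has undefined
(missing) ANI, never 0.

**TETRA.** Tetranucleotide counts over all contigs and both strands (windows
containing N skipped); the expected count of w1w2w3w4 is
n(w1w2w3)·n(w2w3w4)/n(w2w3), z = (obs − exp)/√exp with z = 0 where exp = 0
(the variance is approximated by the expected count). The TETRA statistic
between two genomes is the Pearson correlation of their 256-element z-score
vectors.

**Species assignment** follows the type-strain proposal: a genome takes the
species of its best-scoring type strain iff the mean two-direction ANI
reaches the cutoff (default 95%); ties break by kept-fragment count, then by
type-strain id, and are flagged.

## Orthology and markers

All-vs-all protein similarity uses Smith–Waterman with BLOSUM62
(open −11 / extend −1) behind a shared-5-mer prefilter (≥ 2 shared), a
length-ratio gate (the min of the two coverages cannot reach the 50% floor
when the shorter is less than half the longer) and a score-only pregate
(normalized score < 0.2 cannot clear the identity floor). An edge is kept at
identity ≥ 50% and coverage ≥ 50%; its normalized score is the raw score over
the self-score of the shorter protein. Orthogroups are connected components
after pruning edges below normalized score 0.5 — one similarity backbone
serving both published parameterizations (family inference and marker
selection), with connected components in place of MCL: the pruning threshold
is set so families planted at ≥ 70% identity always merge and ≤ 40% never
merge (tested). Core orthogroups are those present in strictly more than 95%
of genomes. Markers are orthogroups single-copy in ≥ 96% of genomes with
within-group minimum pairwise identity ≥ 70% (read from the similarity
edges; a missing edge disqualifies). The outgroup contributes its best hit
per marker when coverage > 75% and identity > 50%, otherwise that marker
carries an all-gap outgroup row.

## Phylogeny and clade extraction

Marker DNA sequences are aligned per family with MAFFT (FFT-NS-2; G-INS-i
for inputs under 200 nt, where the FFT heuristic is unreliable) and
concatenated with all-gap blocks for missing taxa. Distances are uncorrected
p-distances over mutually ungapped columns (Jukes–Cantor optional); trees are
neighbor joining (scikit-bio) with negative branch lengths clamped to zero.
Maximum-likelihood inference is deliberately replaced by NJ + nonparametric
bootstrap: the quantity this pipeline is judged on is clade recovery, not
branch-length estimation. Bootstrap support of an internal edge is the
percentage of column-resampled replicate trees containing the same
bipartition; an all-identical-row supermatrix reports supports as missing.

Clades are delimited by rooting at the outgroup pendant edge, removing the
outgroup, and cutting well-supported internal edges (support ≥ 70, the
conventional "strong" threshold): candidate edges are sorted by branch
length and the cut set is the head of that order up to the largest relative
length gap (a gap ratio below 2 means no depth separation — one clade). This
branch-length-gap rule is this package's own formalization of the visual
delimitation of deep, internally shallow clades; `k` can be forced
explicitly. Clades are labelled by the type strain they contain.

## Functional profiles

Orthogroup→category assignments (single letters, the COG/eggNOG alphabet,
multi-membership allowed) are an input table — category inference itself is
out of scope. Per category, genomes are compared by Bray–Curtis dissimilarity
over orthogroup count vectors and ordinated by classical PCoA
(double-centering, eigh; negative eigenvalues dropped and counted). A pair
of all-zero profiles gets distance 0 with a warning.

## Feature screening

Three independent routes, mirroring common practice: case-insensitive
keyword regexes over product annotations; best local alignment against
reference family variants (call at identity > 50% and reference coverage
> 75%); and a profile-HMM scan. The HMM machinery implements the HMMER3
ASCII profile subset (match/insert emissions, seven core transitions,
optional Viterbi Gumbel calibration) and a uni-hit local Viterbi with
uniform 1/M entry/exit, background-scored flanks and model insert emissions;
scores are in bits and are pinned against a brute-force path-enumeration
oracle in the tests. E-values use the file's calibration when present, else
a documented Gumbel default (λ = 0.69, τ = log₂(400·M)); tests pin bit
scores, not E-values. GT-family HMM calls additionally apply the
conventional 1e-18 E-cutoff. Per (gene, family) the best route wins;
within a subtype group (heme vs Mn catalase, Fe-Mn vs Cu SOD) the
best-scoring family is kept, reference route winning ties, with a conflict
flag when routes disagree. A k-mer prescreen limits reference alignments and
HMM scans to plausible candidates. The 16S screen aligns reference 16S
sequences (all required > 1,200 nt) against the genome and returns the
best species above 90% identity.

## GT clusters and serine-rich adhesins

A cluster is GT-enriched when ≥ 3 GT genes occur with ≤ 5 kb between
successive GTs; the gap is the count of intervening bases
(start − end − 1), so exactly 5,000 intervening bases still joins and 5,001
breaks — midpoint anchoring is available as an option. Clusters are matched
across genomes into archetypes by orthogroup-content Jaccard ≥ 0.5 (single
linkage); an archetype is present in a genome when ≥ 80% of its orthogroups
have a member there, and clade-specific when present in one clade only.
These two thresholds are package choices; the original analysis matched
clusters by manual orthogroup inspection.

Srr adhesin candidates are genes ≥ 2,400 bp with serine fraction ≥ 0.10
(floors chosen to include, with margin, the two known exemplars at 15% and
38% serine); they are motif-scanned for the KxYKxGKxW export signal within
the first 120 residues and an LPxTG-like anchor within the last 60,
generalized to L-P-x-[TQ]-[GS] to admit the printed LPQTS variant (a strict
mode exists). Frameshifts are detected against an intact homolog by global
unit-cost alignment; indel events closer than 10 bp are coalesced (an
optimal unit-cost alignment may split one 2-bp gap), and a net non-multiple
-of-3 event is reported with its homopolymer context (for insertions, the
longer flanking run — gap placement inside a repeat is ambiguous) and its
predicted effect: N-terminal loss within the first 10% of the gene, internal
split otherwise. Consensus reconstruction of a gene from partial copies uses
a shared-15-mer overlap layout (fragments are assumed indel-free relative to
each other, which holds for same-gene copies across close strains) and
per-column majority vote, ties going to the longest fragment. Contig
ordering against a reference anchors each contig (or its central 10 kb) in
both orientations and sorts by best hit position; unanchored contigs are
appended and reported.

## Synthetic data: what it emulates

The generator builds a root genome (gene grid of ~60 core and ~30 accessory
protein-coding genes, a 16S gene, intergenic spacers and filler to 300 kb)
and evolves three clade ancestors and leaves so that *pairwise* divergence is
0.02 within and 0.15 between clades; the outgroup branch is 0.22. On every
branch, the A/T↔G/C flips needed to reach the clade GC target (A 46.3%,
B 47.75%, C 46.7%) are folded into the substitution budget, the remaining
substitutions are GC-balanced and transition-rich (~2:1), gene substitutions
avoid stops and are ~70% synonymous (substitution events are redirected to
silent sites, a crude purifying-selection stand-in that keeps core-marker
protein identity near 85–90% between clades), and short geometric indels
fall only between genes. Substitution events that land on protected windows
(start/stop codons, adhesin motifs, 16S, the conserved A₅ hotspot) are
re-spent on intergenic sites so realized divergence matches the nominal
rate; measured ANI recovers 98 ± 0.5 within and 85 ± 1 between clades, and
GC lands within ±0.15 points.

Planted content: Fe-Mn SOD in all clade-A genomes; a 487-aa heme catalase in
all clade-B genomes and a 269-aa Mn catalase in 7 of 10; a core EPS cluster
(priming GT, GT2, GT4) in every genome; and in 6 of 10 clade-B genomes an
accessory-Sec locus ordered srr1 – GT4 ×2 – GT8 ×3 (opposite strand) –
SecA2/SecY2/Asp1-3 – GT4 – unknown gene – srr2. The adhesins are built with
exact serine counts (srr1: 8,868 bp at 15%; srr2: 22,113 bp at 38%, with the
LPQTS anchor variant) and evolve under synonymous-only substitutions so
their composition remains a recoverable truth. Default defect plans put a
2-bp deletion near the 5′ end of srr1 in one carrier, an A₅→A₆ insertion at
~3.8% of srr2 in another (the A₅ run is planted at the root so every copy
shares the hotspot), and a contig break through srr2 in a third; frameshifted
genes are re-annotated as the ORFs the mutated sequence actually supports.
All fixture sequences are synthetic stand-ins generated from a fixed
internal seed — nothing is downloaded — and every output is
byte-deterministic given the config seed.

What passing does *not* show: the simulator has no recombination or
horizontal transfer (real intra-clade trees show low supports for exactly
that reason), no repeat-driven misassembly, no annotation noise beyond the
planted defects, and its serine-rich regions are compositionally biased but
not literally repetitive; real Srr repeats are harder to assemble and align
than these.

## Scale and defaults

The study-scale run used throughout testing is 30 genomes (10 per clade) of
300 kb with 100 bootstrap replicates — small enough to run the whole
pipeline in minutes on one core while keeping every stage's statistics
meaningful. QC defaults follow the published filter (N75 ≥ 10 kb, ≤ 500
N/100 kb); the genome-size window is adaptive around the input median by
default (0.3–3×), with the absolute window for real assemblies of this group
(1.5–4.5 Mb) available explicitly. The pipeline recomputes everything on
each invocation; with fixed seeds the report JSON is byte-identical across
reruns, which substitutes for stage caching at this scale.
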