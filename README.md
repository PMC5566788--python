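# caseikit

Comparative phylogenomics of the *Lactobacillus casei* group (*L. casei*,
*L. paracasei*, *L. rhamnosus*, *L. zeae*) — a reusable, tested
implementation of the workflow that delimits the group's three clades and
finds their diagnostic gene content, for microbial genomicists who want the
whole analysis reproducible from FASTA to report.

The pipeline combines:

* **assembly QC** — N50/N75, undetermined-base density, GC content, and the
  inclusion filter (N75 ≥ 10 kb, ≤ 500 N per 100 kb, genome-size window);
* **ANIb** — average nucleotide identity by the fragment convention: 1,020-bp
  query fragments aligned to the subject, kept at identity > 30% over > 70%
  coverage, ANI = mean identity of kept fragments (~95–96% is the species
  boundary); **TETRA** — Pearson correlation of 256-element tetranucleotide
  z-score vectors, z = (obs − exp)/√exp with exp(w₁w₂w₃w₄) =
  n(w₁w₂w₃)·n(w₂w₃w₄)/n(w₂w₃);
* **pangenome orthology** — all-vs-all Smith–Waterman (BLOSUM62) similarity
  graph, orthogroups as connected components, core = present in > 95% of
  genomes, single-copy markers at ≥ 70% identity in ≥ 96% of genomes;
* **core-genome phylogeny** — per-marker MAFFT alignments concatenated into a
  supermatrix, neighbor joining on p-distances with nonparametric bootstrap,
  outgroup rooting, and clade extraction by cutting deep well-supported
  edges (support > 70);
* **functional profiles** — Bray–Curtis distances over per-category
  orthogroup counts, ordinated by PCoA;
* **interest-driven screening** — catalases (heme / Mn), superoxide
  dismutases, glycosyltransferases (GT2/GT4/GT8/GT83 + priming GT) and
  accessory-Sec components by three routes (annotation keywords, reference
  alignment, profile-HMM Viterbi scan with the 1e-18 GT E-cutoff); the
  GT-cluster enrichment rule (≥ 3 GTs with ≤ 5 kb between successive GTs);
  serine-rich repeat (Srr) adhesin detection with KxYKxGKxW / LPxTG-like
  motif scanning, homopolymer frameshift detection and consensus
  reconstruction from partial copies;
* **a synthetic-data generator** — clade-structured genome sets with planted,
  truth-tracked features (clade GC targets, 2%/15% intra/inter divergence,
  clade-specific catalase/SOD genes, the GT-rich accessory-Sec locus with
  both adhesins, frameshifts and contig breaks), so the whole pipeline is
  testable end to end with no downloads.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Generate a three-clade dataset and run the full pipeline:

```python
from caseikit.simulate import SimConfig, simulate_group
from caseikit.pipeline import PipelineConfig, input_from_dataset, run_pipeline

ds = simulate_group(SimConfig(seed=1))          # 3 clades x 10 genomes, 300 kb
report = run_pipeline(input_from_dataset(ds),
                      PipelineConfig(bootstrap_reps=100, bootstrap_seed=1))
```

which logs

```
qc: 30/30 genomes passed
pairwise: ANI/TETRA over 30 genomes; 0 near-duplicate groups
orthology: 108 orthogroups (63 core), 62 markers
phylogeny: supermatrix 31 x 57279, 100 bootstraps
screening: 204 feature calls
clusters: 2 archetypes, 13 srr calls
```

Reading the report: all 30 genomes pass QC; the 63 core orthogroups match
the generator's plant exactly and 62 of them qualify as single-copy markers;
the NJ tree over the 57 kb supermatrix splits the genomes into three clades
identical to the truth (adjusted Rand index 1.0) on edges with bootstrap
support 100. Within-clade ANI averages 97.9 and between-clade ANI 85.8 —
recovering the generator's 2% and 15% divergence settings — with the lowest
within-clade TETRA (0.797) above the highest between-clade value (0.741), so
both metrics separate the clades. Screening finds every planted catalase,
SOD, GT and accessory-Sec gene (recall 100%, zero false calls): the heme
catalase in 10/10 clade-B genomes, the Mn catalase in 7/10, SOD only in
clade A, and the GT-rich accessory-Sec locus in 6/10 clade-B genomes as a
clade-B-specific cluster archetype. The srr table shows the two adhesins at
their planted sizes and compositions — srr1 8,868 bp at 15.0% serine, srr2
22,113 bp at 38.0% serine — and flags the frameshifted and contig-broken
copies as defective.

A CLI mirrors the stages (`caseikit simulate | qc | ani | tetra | classify |
run`); `caseikit run --genomes <dir> --annotations <dir> --outgroup <id>`
writes the report JSON and TSV bundle for real annotated assemblies.

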