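"""End-to-end orchestration: QC → ANI/TETRA → orthology → phylogeny →
clades → screening → functional profiles → clusters/adhesins.

`run_pipeline` takes either an in-memory :class:`~caseikit.simulate.SimulatedDataset`
or directories of FASTA genomes with GFF3+FAA annotations, runs every stage
with the thresholds collected in :class:`PipelineConfig`, and returns a
:class:`RunReport` whose JSON serialization is byte-identical across reruns
with the same inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_io import (
    GenomeRecord,
    GeneCall,
    assembly_stats,
    gene_sequence,
    qc_filter,
    read_fasta,
    read_gff3,
    read_protein_fasta,
)
from .orthology import (
    all_vs_all,
    core_accessory,
    infer_orthogroups,
    outgroup_augment,
    single_copy_markers,
)
from .pairwise import (
    anib_matrix,
    report_near_duplicates,
    symmetric_ani,
    tetra_matrix,
)
from .phylogeny import bootstrap_support, concatenate, extract_clades, progressive_msa
from .profiles import CategoryMap, bray_curtis, pcoa
from .clusters import cluster_presence, find_gt_clusters, find_srr
from .screen import ScreenConfig, default_screen_config, feature_table, screen_genome


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, in one place.

    Defaults follow the conventions of the comparative study this pipeline
    reproduces: QC at N75 >= 10 kb and <= 500 N/100 kb; markers at 70%
    identity present in 96% of genomes; core orthogroups at presence > 95%;
    outgroup hits at coverage > 75% and identity > 50%; ANIb on 1,020-bp
    fragments with a 95% species cutoff; bootstrap-strong edges above 70;
    GT clusters of >= 3 GTs within 5 kb under an HMM E-cutoff of 1e-18.
    """

    qc_n75_min: int = 10_000
    qc_max_n_per_100kb: float = 500.0
    qc_size_window: tuple[int, int] | None = None  # None: adaptive around the median
    marker_min_identity: float = 70.0
    marker_min_presence: float = 0.96
    core_presence: float = 0.95
    outgroup_min_cov: float = 0.75
    outgroup_min_id: float = 50.0
    ani_fragment_len: int = 1020
    ani_species_cutoff: float = 95.0
    near_duplicate_ani: float = 99.99
    bootstrap_reps: int = 100
    bootstrap_seed: int = 0
    strong_support: float = 70.0
    gt_min_gts: int = 3
    gt_max_gap: int = 5000
    gt_evalue_cutoff: float = 1e-18
    srr_min_len: int = 2400
    srr_min_serine: float = 0.10
    cluster_min_jaccard: float = 0.5
    cluster_min_presence: float = 0.8

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineInput:
    genomes: dict[str, GenomeRecord]
    outgroup: GenomeRecord | None
    gene_calls: dict[str, list[GeneCall]]  # includes outgroup when present
    gene_dna: dict[str, dict[str, str]]
    type_strain_labels: dict[str, str] = field(default_factory=dict)
    category_map: CategoryMap | None = None
    # when the category map is keyed by an external orthogroup nomenclature
    # (e.g. the simulator's truth ids), this maps genome -> gene -> that id so
    # categories can be carried over onto the inferred orthogroups
    gene_external_og: dict[str, dict[str, str]] | None = None


@dataclass
class RunReport:
    config_hash: str
    version: str
    n_genomes_in: int
    n_genomes_passed_qc: int
    qc: pd.DataFrame
    ani: pd.DataFrame  # symmetric (mean of directions)
    tetra: pd.DataFrame
    near_duplicates: list[list[str]]
    pangenome: pd.DataFrame
    n_markers: int
    newick: str
    clade_edge_supports: list  # bootstrap support of each clade-defining edge
    clades: pd.DataFrame  # genome_id, clade, species call
    features: pd.DataFrame  # genome x family counts
    feature_calls: pd.DataFrame
    clusters: pd.DataFrame  # archetype presence matrix
    cluster_specificity: dict[str, str | None]
    srr: pd.DataFrame
    profiles_axis1: dict[str, dict[str, float]]  # category -> genome -> PC1
    profile_explained: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "n_genomes_in": self.n_genomes_in,
            "n_genomes_passed_qc": self.n_genomes_passed_qc,
            "qc": self.qc.round(6).to_dict(),
            "ani": self.ani.round(6).to_dict(),
            "tetra": self.tetra.round(6).to_dict(),
            "near_duplicates": self.near_duplicates,
            "pangenome": self.pangenome.round(6).to_dict(),
            "n_markers": self.n_markers,
            "newick": self.newick,
            "clade_edge_supports": self.clade_edge_supports,
            "clades": self.clades.to_dict(),
            "features": self.features.to_dict(),
            "clusters": self.clusters.astype(bool).to_dict(),
            "cluster_specificity": self.cluster_specificity,
            "srr": self.srr.round(6).to_dict(),
            "profiles_axis1": {
                k: {g: round(v, 6) for g, v in d.items()}
                for k, d in self.profiles_axis1.items()
            },
            "profile_explained": {k: round(v, 6) for k, v in self.profile_explained.items()},
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def load_input(genomes_dir: str | Path, annotations_dir: str | Path,
               outgroup_id: str | None = None) -> PipelineInput:
    """Read FASTA genomes plus GFF3/FAA annotation pairs from directories."""
    genomes_dir, annotations_dir = Path(genomes_dir), Path(annotations_dir)
    genomes: dict[str, GenomeRecord] = {}
    gene_calls: dict[str, list[GeneCall]] = {}
    gene_dna: dict[str, dict[str, str]] = {}
    outgroup = None
    for fasta in sorted(genomes_dir.glob("*.fasta")) + sorted(genomes_dir.glob("*.fa")):
        g = read_fasta(fasta)
        proteins = read_protein_fasta(annotations_dir / f"{g.genome_id}.faa")
        calls = read_gff3(annotations_dir / f"{g.genome_id}.gff3", proteins)
        gene_calls[g.genome_id] = calls
        gene_dna[g.genome_id] = {c.gene_id: gene_sequence(g, c) for c in calls}
        if outgroup_id is not None and g.genome_id == outgroup_id:
            outgroup = g
        else:
            genomes[g.genome_id] = g
    return PipelineInput(
        genomes=genomes, outgroup=outgroup, gene_calls=gene_calls, gene_dna=gene_dna
    )


def input_from_dataset(ds) -> PipelineInput:
    """Adapt a SimulatedDataset (with its truth-supplied category map and
    type strains) into pipeline input."""
    cat = CategoryMap({og: set(c) for og, c in ds.truth.category_map.items()})
    type_labels = {gid: sp for gid, sp in ds.truth.type_strains.items()}
    return PipelineInput(
        genomes=dict(ds.genomes),
        outgroup=ds.outgroup,
        gene_calls=dict(ds.gene_calls),
        gene_dna=dict(ds.gene_dna),
        type_strain_labels=type_labels,
        category_map=cat,
        gene_external_og=dict(ds.truth.gene_orthogroups),
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(
    data: PipelineInput,
    config: PipelineConfig | None = None,
    screen_config: ScreenConfig | None = None,
    out_dir: str | Path | None = None,
    log=print,
) -> RunReport:
    config = config or PipelineConfig()
    screen_cfg = screen_config or default_screen_config()

    # --- QC -----------------------------------------------------------------
    qc_rows = {}
    metrics = {g: assembly_stats(rec) for g, rec in data.genomes.items()}
    sizes = sorted(m.total_length for m in metrics.values())
    if config.qc_size_window is not None:
        window = config.qc_size_window
    else:
        med = sizes[len(sizes) // 2]
        window = (int(0.3 * med), int(3.0 * med))
    passed: dict[str, GenomeRecord] = {}
    for g, m in metrics.items():
        decision = qc_filter(m, config.qc_n75_min, config.qc_max_n_per_100kb, window)
        qc_rows[g] = {
            "total_length": m.total_length,
            "n_contigs": m.n_contigs,
            "n50": m.n50,
            "n75": m.n75,
            "undetermined_per_100kb": m.undetermined_per_100kb,
            "gc_percent": m.gc_percent,
            "passed": decision.passed,
            "reasons": ";".join(decision.reasons),
        }
        if decision.passed:
            passed[g] = data.genomes[g]
    qc_table = pd.DataFrame(qc_rows).T.sort_index()
    if len(passed) < 3:
        raise StageError("qc", f"only {len(passed)} genomes passed QC; need >= 3")
    log(f"qc: {len(passed)}/{len(data.genomes)} genomes passed")
    ids = sorted(passed)
    genome_list = [passed[g] for g in ids]

    # --- pairwise metrics ----------------------------------------------------
    ani_dir = anib_matrix(genome_list, fragment_len=config.ani_fragment_len)
    ani = symmetric_ani(ani_dir)
    tetra = tetra_matrix(genome_list)
    dupes = report_near_duplicates(ani, config.near_duplicate_ani)
    log(f"pairwise: ANI/TETRA over {len(ids)} genomes; {len(dupes)} near-duplicate groups")

    # --- orthology ------------------------------------------------------------
    proteomes = {
        g: {c.gene_id: c.translation for c in data.gene_calls[g] if c.translation}
        for g in ids
    }
    edges = all_vs_all(proteomes)
    table = infer_orthogroups(edges, proteomes)
    summary = core_accessory(table, config.core_presence)
    markers = single_copy_markers(
        table,
        proteomes,
        edges,
        min_identity=config.marker_min_identity,
        min_presence=config.marker_min_presence,
    )
    log(
        f"orthology: {table.n_orthogroups} orthogroups "
        f"({summary.n_core} core), {len(markers.orthogroup_ids)} markers"
    )
    if not markers.orthogroup_ids:
        raise StageError("orthology", "no single-copy marker orthogroups found")

    # --- phylogeny ------------------------------------------------------------
    taxa = list(ids)
    aug: dict[str, str | None] = {}
    if data.outgroup is not None:
        out_id = data.outgroup.genome_id
        out_prot = {
            c.gene_id: c.translation for c in data.gene_calls[out_id] if c.translation
        }
        reps = {
            og: proteomes[min(m)][m[min(m)]] for og, m in markers.genes.items()
        }
        aug = outgroup_augment(
            markers, reps, out_prot, out_id,
            min_cov=config.outgroup_min_cov, min_id=config.outgroup_min_id,
        )
        taxa = taxa + [out_id]
    alignments = {}
    for og in markers.orthogroup_ids:
        seqs = {g: data.gene_dna[g][gene] for g, gene in markers.genes[og].items()}
        if data.outgroup is not None and aug.get(og):
            seqs[data.outgroup.genome_id] = data.gene_dna[data.outgroup.genome_id][aug[og]]
        alignments[og] = progressive_msa(seqs)
    sm = concatenate(alignments, taxa)
    tree = bootstrap_support(sm, n_reps=config.bootstrap_reps, seed=config.bootstrap_seed)
    log(f"phylogeny: supermatrix {len(taxa)} x {sm.width}, {config.bootstrap_reps} bootstraps")

    type_labels = dict(data.type_strain_labels)
    if not type_labels:
        for g in ids:
            if passed[g].source_label:
                type_labels.setdefault(g, passed[g].source_label)
    if data.outgroup is not None:
        assignment = extract_clades(
            tree, data.outgroup.genome_id,
            min_support=config.strong_support,
            type_strain_labels=type_labels or None,
        )
        clade_of = assignment.clades
        clade_supports = [s for _, _, s in assignment.defining_edges]
    else:
        clade_of = {g: "A" for g in ids}
        clade_supports = []

    # species call by ANI against the type strains
    species_call = {}
    for g in ids:
        best, best_val = "unassigned", -np.inf
        for ts, label in type_labels.items():
            if ts not in ids:
                continue
            val = ani.to_frame().loc[g, ts]
            if val > best_val:
                best, best_val = label, val
        species_call[g] = best if best_val >= config.ani_species_cutoff else "unassigned"
    clade_table = pd.DataFrame(
        {
            "clade": {g: clade_of[g] for g in ids},
            "species_by_ani": species_call,
        }
    ).sort_index()

    # --- screening ------------------------------------------------------------
    screen_cfg.gt_evalue_cutoff = config.gt_evalue_cutoff
    all_calls = []
    for g in ids:
        all_calls.extend(screen_genome(g, data.gene_calls[g], screen_cfg))
    fc_table = feature_table(all_calls)
    if len(fc_table):
        feature_matrix = (
            fc_table.pivot_table(index="genome", columns="family", values="gene",
                                 aggfunc="count", fill_value=0)
            .reindex(ids, fill_value=0)
        )
    else:
        feature_matrix = pd.DataFrame(index=ids)
    log(f"screening: {len(fc_table)} feature calls")

    # --- GT clusters and adhesins ---------------------------------------------
    per_genome_calls = {g: [c for c in all_calls if c.genome_id == g] for g in ids}
    clusters_by_genome = {
        g: find_gt_clusters(
            data.gene_calls[g], per_genome_calls[g],
            min_gts=config.gt_min_gts, max_gap=config.gt_max_gap, genome_id=g,
        )
        for g in ids
    }
    gene_og = {
        (g, gene): og
        for og, per in table.members.items()
        for g, genes in per.items()
        for gene in genes
    }
    og_presence = {
        og: {g for g, genes in per.items() if genes} for og, per in table.members.items()
    }
    presence_df, specificity, _members = cluster_presence(
        clusters_by_genome, gene_og, clade_of, og_presence,
        min_jaccard=config.cluster_min_jaccard,
        min_presence_frac=config.cluster_min_presence,
    )
    srr_rows = []
    for g in ids:
        for s in find_srr(
            data.gene_calls[g], g,
            min_len=config.srr_min_len, min_serine=config.srr_min_serine,
        ):
            srr_rows.append(
                {
                    "genome": g,
                    "gene": s.gene_id,
                    "length_bp": s.length_bp,
                    "serine_fraction": s.serine_fraction,
                    "n_motif": s.n_motif,
                    "c_motif": s.c_motif,
                    "intact": s.intact,
                    "defect": s.defect,
                }
            )
    srr_table = pd.DataFrame(
        srr_rows,
        columns=["genome", "gene", "length_bp", "serine_fraction",
                 "n_motif", "c_motif", "intact", "defect"],
    )
    log(f"clusters: {presence_df.shape[0]} archetypes, {len(srr_table)} srr calls")

    # --- functional profiles ---------------------------------------------------
    profiles_axis1: dict[str, dict[str, float]] = {}
    profile_explained: dict[str, float] = {}
    cat_map = data.category_map
    if cat_map is not None and data.gene_external_og is not None:
        # translate external (truth) orthogroup categories onto inferred ids
        derived: dict[str, set[str]] = {}
        for og, per in table.members.items():
            cats = set()
            for g, genes in per.items():
                for gene in genes:
                    ext = data.gene_external_og.get(g, {}).get(gene)
                    if ext and ext in cat_map.assignments:
                        cats |= cat_map.assignments[ext]
            if cats:
                derived[og] = cats
        cat_map = CategoryMap(derived)
    if cat_map is not None:
        counts = table.counts()
        for cat in cat_map.categories:
            cols = [og for og in cat_map.orthogroups_in(cat) if og in counts.columns]
            if len(cols) < 2:
                continue
            sub = counts[cols]
            if sub.to_numpy().std() == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-zero profiles distance to 0
                ord_ = pcoa(bray_curtis(sub))
            if ord_.coordinates.shape[1] == 0:
                continue
            profiles_axis1[cat] = dict(
                zip(ord_.coordinates.index, ord_.coordinates.iloc[:, 0])
            )
            profile_explained[cat] = float(ord_.proportion_explained[0])

    pangenome = pd.DataFrame([
        {
            "n_genomes": summary.n_genomes,
            "avg_genes_per_genome": summary.avg_genes_per_genome,
            "sd_genes_per_genome": summary.sd_genes_per_genome,
            "avg_orthogroups_per_genome": summary.avg_orthogroups_per_genome,
            "sd_orthogroups_per_genome": summary.sd_orthogroups_per_genome,
            "n_core": summary.n_core,
            "n_accessory": summary.n_accessory,
        }
    ])

    report = RunReport(
        config_hash=config.config_hash(),
        version=__version__,
        n_genomes_in=len(data.genomes),
        n_genomes_passed_qc=len(passed),
        qc=qc_table,
        ani=ani.to_frame(),
        tetra=tetra.to_frame(),
        near_duplicates=dupes,
        pangenome=pangenome,
        n_markers=len(markers.orthogroup_ids),
        newick=tree.newick(),
        clade_edge_supports=clade_supports,
        clades=clade_table,
        features=feature_matrix,
        feature_calls=fc_table,
        clusters=presence_df,
        cluster_specificity=specificity,
        srr=srr_table,
        profiles_axis1=profiles_axis1,
        profile_explained=profile_explained,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "report.json")
        qc_table.to_csv(out / "qc.tsv", sep="\t")
        report.ani.to_csv(out / "ani.tsv", sep="\t")
        report.tetra.to_csv(out / "tetra.tsv", sep="\t")
        clade_table.to_csv(out / "clades.tsv", sep="\t")
        feature_matrix.to_csv(out / "features.tsv", sep="\t")
        fc_table.to_csv(out / "feature_calls.tsv", sep="\t", index=False)
        srr_table.to_csv(out / "srr.tsv", sep="\t", index=False)
        presence_df.to_csv(out / "clusters.tsv", sep="\t")
        (out / "tree.nwk").write_text(report.newick)
    return report
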