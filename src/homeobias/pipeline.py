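"""End-to-end pipeline driver.

Chains the stages in dependency order — family identification /
protein features -> phylogeny + subgroup assignment -> homeolog
components -> promoter & SNP analysis -> expression-bias classification
— writing one TSV (or Newick) per stage plus a run report that echoes
every parameter actually used, per-stage record counts and input
checksums.  Identical config + inputs + seed give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as hio
from .bias import ExpressionMatrix, call_deg, classify_bias, summarize_bias
from .components import (
    build_homology_graph,
    classify_components,
    components_table,
    edges_from_distance_matrix,
    summarize_components,
)
from .features import compute_features, default_profile, DomainProfile
from .phylo import (
    assign_subgroups,
    bootstrap_support,
    kmer_distance_matrix,
    load_anchor_fixture,
    nj_tree,
    DistanceMatrix,
)
from .regulatory import (
    contrast_density_by_phylo_group,
    count_elements_by_subgenome,
    density_table,
    extract_promoter,
    load_motif_table,
    scan_motifs,
    snp_density,
)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    # inputs
    protein_fasta: str = ""
    gff3: str = ""
    genome_fasta: str = ""
    vcf: str = ""
    fpkm_tsv: str = ""
    design_tsv: str = ""
    outdir: str = "homeobias_out"
    # stage toggles
    run_features: bool = True
    run_phylogeny: bool = True
    run_components: bool = True
    run_regulatory: bool = True
    run_bias: bool = True
    # parameters
    profile_path: str = ""          # empty -> bundled domain profile
    profile_threshold: float | None = None
    k: int = 3
    link_threshold: float = 0.35
    cluster_min: int = 4
    promoter_length: int = 1500
    flank: int = 2000
    fc_threshold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    fpkm_floor: float = 1.0
    bootstrap_reps: int = 0         # NJ bootstrap is opt-in; costly at family scale
    condition_name: str = "treatment"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = hio.read_yaml_config(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    version: str
    parameters: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _validate_inputs(cfg: PipelineConfig) -> None:
    required = [("protein_fasta", cfg.protein_fasta)]
    if cfg.run_components or cfg.run_regulatory or cfg.run_bias:
        required.append(("gff3", cfg.gff3))
    if cfg.run_regulatory:
        required.append(("genome_fasta", cfg.genome_fasta))
        required.append(("vcf", cfg.vcf))
    if cfg.run_bias:
        required.append(("fpkm_tsv", cfg.fpkm_tsv))
        required.append(("design_tsv", cfg.design_tsv))
    for name, path in required:
        if not path:
            raise ValueError(f"config error: {name} is required for the enabled stages")
        if not Path(path).exists():
            raise ValueError(f"config error: {name} does not exist: {path}")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run all enabled stages; aborts with the failing stage's name."""
    _validate_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, parameters=asdict(cfg))
    for name in ("protein_fasta", "gff3", "genome_fasta", "vcf", "fpkm_tsv", "design_tsv"):
        path = getattr(cfg, name)
        if path and Path(path).exists():
            report.input_checksums[name] = hio.sha256_of(path)

    proteins = hio.read_proteins(cfg.protein_fasta)
    if cfg.profile_path:
        profile = DomainProfile.read(cfg.profile_path)
    else:
        profile = default_profile()
    if cfg.profile_threshold is not None:
        profile.threshold = cfg.profile_threshold

    # --- features / family identification -------------------------------
    stage = "features"
    try:
        feats = [compute_features(p, profile) for p in proteins]
        members = {f.id for f in feats if f.n_domain_hits > 0}
        fdf = pd.DataFrame(
            {
                "id": [f.id for f in feats],
                "length": [f.length for f in feats],
                "molecular_weight": [round(f.molecular_weight, 2) for f in feats],
                "isoelectric_point": [round(f.isoelectric_point, 2) for f in feats],
                "n_domain_hits": [f.n_domain_hits for f in feats],
                "membrane_bound": [f.membrane_bound for f in feats],
                "is_family": [f.id in members for f in feats],
            }
        )
        fdf.to_csv(outdir / "features.tsv", sep="\t", index=False)
        report.stage_counts["proteins"] = len(proteins)
        report.stage_counts["family_members"] = len(members)
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError(stage, exc)

    member_records = sorted(
        (p for p in proteins if p.id in members), key=lambda p: p.id
    )

    # --- phylogeny ------------------------------------------------------
    assignment = {}
    if cfg.run_phylogeny and len(member_records) >= 3:
        stage = "phylogeny"
        try:
            anchors, anchor_map = load_anchor_fixture()
            dm_all = kmer_distance_matrix(member_records + anchors, cfg.k)
            tree = nj_tree(dm_all)
            if cfg.bootstrap_reps > 0:
                tree, _ = bootstrap_support(
                    member_records + anchors, cfg.k, cfg.bootstrap_reps,
                    seed=cfg.seed, reference_tree=tree,
                )
            hio.write_newick(tree, outdir / "tree.nwk")
            calls = assign_subgroups(dm_all, anchor_map)
            assignment = {g: c for g, c in calls.items()}
            pd.DataFrame(
                {
                    "gene": list(assignment),
                    "phylo_group": [c.phylo_group for c in assignment.values()],
                    "subgroup": [c.subgroup for c in assignment.values()],
                    "nearest_anchor": [c.nearest_anchor for c in assignment.values()],
                    "ambiguous": [c.ambiguous for c in assignment.values()],
                }
            ).to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
            report.stage_counts["subgroup_assignments"] = len(assignment)
        except Exception as exc:
            raise PipelineError(stage, exc)

    # --- homeolog components --------------------------------------------
    comps = []
    genes = {}
    if cfg.run_components:
        stage = "components"
        try:
            genes = hio.read_gff3(cfg.gff3)
            member_genes = {g: genes[g] for g in genes if g in members}
            dm_members = kmer_distance_matrix(member_records, cfg.k)
            edges = edges_from_distance_matrix(dm_members)
            comps = build_homology_graph(member_genes, edges, cfg.link_threshold)
            classify_components(comps, member_genes, cfg.cluster_min)
            components_table(comps).to_csv(outdir / "components.tsv", sep="\t", index=False)
            summarize_components(comps).to_csv(outdir / "component_summary.tsv",
                                               sep="\t", index=False)
            report.stage_counts["components"] = len(comps)
            report.stage_counts["component_genes"] = sum(len(c.members) for c in comps)
        except Exception as exc:
            raise PipelineError(stage, exc)

    # --- regulatory -----------------------------------------------------
    if cfg.run_regulatory:
        stage = "regulatory"
        try:
            genome = hio.read_fasta(cfg.genome_fasta)
            variants = hio.read_vcf(cfg.vcf)
            motif_table = load_motif_table()
            by_chrom = {
                c: sub["pos"].to_numpy()
                for c, sub in variants.groupby("chrom")
            }
            hits = []
            density_records = []
            for gid in sorted(members):
                if gid not in genes:
                    continue
                g = genes[gid]
                promoter = extract_promoter(g, genome, cfg.promoter_length)
                hits.extend(scan_motifs(gid, promoter, motif_table))
                density_records.extend(
                    snp_density(
                        g,
                        by_chrom.get(g.chromosome, pd.Series([], dtype=int).to_numpy()),
                        cfg.flank,
                        chromosome_length=len(genome[g.chromosome]),
                    )
                )
            pd.DataFrame(
                {
                    "gene": [h.gene for h in hits],
                    "motif": [h.motif for h in hits],
                    "position": [h.position for h in hits],
                    "strand": [h.strand for h in hits],
                }
            ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
            member_models = {g: genes[g] for g in genes if g in members}
            count_elements_by_subgenome(hits, member_models).to_csv(
                outdir / "element_counts.tsv", sep="\t"
            )
            density_table(density_records).to_csv(outdir / "snp_density.tsv",
                                                  sep="\t", index=False)
            if assignment:
                contrast = contrast_density_by_phylo_group(
                    density_records,
                    {g: c.phylo_group for g, c in assignment.items()},
                )
                with open(outdir / "density_contrast.json", "w") as fh:
                    json.dump(contrast, fh, indent=2)
                    fh.write("\n")
            report.stage_counts["motif_hits"] = len(hits)
            report.stage_counts["snp_records"] = len(density_records)
        except Exception as exc:
            raise PipelineError(stage, exc)

    # --- expression bias ------------------------------------------------
    if cfg.run_bias and comps:
        stage = "bias"
        try:
            values, design = hio.read_fpkm(cfg.fpkm_tsv, cfg.design_tsv)
            m = ExpressionMatrix(values=values, design=design)
            degs = call_deg(m, cfg.fc_threshold, cfg.alpha, cfg.pseudocount)
            pd.DataFrame(
                {
                    "gene": list(degs),
                    "mean_control": [d.mean_control for d in degs.values()],
                    "mean_treatment": [d.mean_treatment for d in degs.values()],
                    "log2fc": [d.log2fc for d in degs.values()],
                    "p_value": [d.p_value for d in degs.values()],
                    "call": [d.call for d in degs.values()],
                }
            ).to_csv(outdir / "deg.tsv", sep="\t", index=False)
            calls = [classify_bias(c, degs, m, cfg.fpkm_floor) for c in comps]
            pd.DataFrame(
                {
                    "component_id": [c.component_id for c in calls],
                    "status": [c.status for c in calls],
                    "member_calls": [
                        ";".join(f"{g}={v}" for g, v in c.member_calls.items())
                        for c in calls
                    ],
                }
            ).to_csv(outdir / "bias.tsv", sep="\t", index=False)
            summarize_bias({cfg.condition_name: calls}).to_csv(
                outdir / "bias_summary.tsv", sep="\t", index=False
            )
            report.stage_counts["deg_up"] = sum(d.call == "up" for d in degs.values())
            report.stage_counts["deg_down"] = sum(d.call == "down" for d in degs.values())
            report.stage_counts["bias_calls"] = len(calls)
        except Exception as exc:
            raise PipelineError(stage, exc)

    report.write(outdir / "run_report.json")
    return report
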