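"""Seeded synthetic hexaploid dataset with planted ground truth.

Generates everything the analysis consumes — genome FASTA, GFF3 gene
models, protein FASTA, VCF, replicated FPKM matrix — for a 21-chromosome
genome (7 homologous chromosome numbers x subgenomes A/B/D) carrying a
transcription-factor family organized into planted triad groups, tandem
clusters, two-subgenome pairs and orphans.  Ground-truth tables record
every planted property so downstream recovery can be scored exactly.

What is planted, and how:

* Family members embed the bundled NAC-domain consensus verbatim (plus a
  subgroup signature peptide shared with the anchor fixture), inside
  otherwise random protein sequence; members of one component descend
  from a common ancestor sequence with a small substitution rate outside
  the conserved blocks.  Background (non-family) proteins are random.
* The nucleotide genome is uniform-random A/C/G/T except coding regions
  (back-translated from the proteins with a fixed one-codon-per-residue
  table; codon usage realism is a non-goal) and promoter motif
  instances planted per-motif at configurable rates.
* SNPs are Poisson over gene body + 2-kb flanks at a per-gene rate set
  by the component's phylogenetic group (Group I conserved, Group II
  variable).
* FPKM = lognormal baseline x planted treatment effect x multiplicative
  lognormal noise; planted "sub" components carry the effect on every
  member (same direction), "neo" components on exactly one member.

Genes are placed non-overlapping with gaps of at least 2*flank + 200 bp
so that no two genes' flank windows (or promoters) collide and every
SNP-density region is unambiguous.

The same seed always produces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .components import GeneModel, SUBGENOMES
from .features import NAC_DOMAIN_CONSENSUS, AMINO_ACIDS
from .phylo import GROUP_I_SUBGROUPS
from .regulatory import IUPAC

#: Subgroup signature peptides: planted in members and in the bundled
#: synthetic anchors, so nearest-anchor assignment recovers the planted
#: subgroup.  "none" is the Group II signature.
SUBGROUP_SIGNATURES = {
    "SNAC": "WQDEHNKRYTSMAQF",
    "ANAC34": "DYKENWHQRSTFMAP",
    "SND": "HRQWYDNKESAFTPM",
    "NAC1": "KWEYHQDNRSPTAMF",
    "NAM/CUC3": "QHWDKYENRMSFTAP",
    "TIP": "EWHKQYDRNTASMPF",
    "none": "YQWHEDKNRFSPTAM",
}

#: Fixed back-translation table (one codon per residue).
CODONS = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_HYDROPHOBIC = "ILVFA"
TM_SEGMENT_LENGTH = 25


class GenerationError(RuntimeError):
    pass


def _default_motif_rates() -> dict[str, float]:
    # planting rates chosen to echo the reported element prevalences
    # (ABRE ~80%, CGTCA-motif ~77%, ARE ~65% of family genes)
    return {
        "ABRE": 0.80,
        "CGTCA-motif": 0.77,
        "ARE": 0.65,
        "W box": 0.40,
        "MBS": 0.35,
        "LTR": 0.30,
        "TC-rich repeats": 0.30,
        "GCN4_motif": 0.25,
    }


@dataclass
class SynthConfig:
    seed: int = 0
    n_chromosomes_per_subgenome: int = 7
    chromosome_length: int = 300_000
    n_groups: int = 60
    n_clusters: int = 5
    n_pairs: int = 4
    n_orphans: int = 10
    n_background: int = 30
    cluster_size_range: tuple[int, int] = (4, 6)
    pair_size_range: tuple[int, int] = (2, 3)
    gene_length_range: tuple[int, int] = (450, 1500)
    promoter_length: int = 1500
    promoter_motif_rates: dict[str, float] = field(default_factory=_default_motif_rates)
    snp_rate_groupI: float = 0.9   # SNPs per kb, conserved Group I
    snp_rate_groupII: float = 2.0  # SNPs per kb, variable Group II
    fraction_groupII: float = 0.36
    n_replicates: int = 3
    fpkm_baseline_lognormal: tuple[float, float] = (3.5, 0.8)
    bias_effect_log2fc: float = 2.0
    noise_sigma: float = 0.25
    fraction_sub: float = 0.34
    fraction_neo: float = 0.33
    fraction_null: float = 0.33
    fraction_membrane: float = 0.05
    mutation_rate: float = 0.02
    flank: int = 2000

    def validate(self) -> None:
        counts = (
            self.n_chromosomes_per_subgenome, self.chromosome_length,
            self.n_groups, self.n_clusters, self.n_pairs, self.n_orphans,
            self.n_background, self.n_replicates,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.cluster_size_range[0] < 4:
            raise ValueError("cluster_size_range minimum must be >= 4")
        if self.pair_size_range[0] < 2:
            raise ValueError("pair_size_range minimum must be >= 2")
        fracs = (self.fraction_sub, self.fraction_neo, self.fraction_null)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("bias fractions must be in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("bias fractions must sum to 1")
        for name, r in self.promoter_motif_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"motif rate for {name!r} not in [0, 1]")
        if self.bias_effect_log2fc < 0:
            raise ValueError("bias_effect_log2fc must be >= 0")
        min_protein = 1 + 19 + len(NAC_DOMAIN_CONSENSUS) + 15 + 10
        if self.gene_length_range[0] < 3 * min_protein:
            raise ValueError(
                f"gene_length_range minimum must be >= {3 * min_protein} bp "
                "to hold the planted domain architecture"
            )


@dataclass
class GroundTruth:
    """Planted truth: per-gene, per-component and per-motif tables."""

    genes: pd.DataFrame       # indexed by gene_id
    components: pd.DataFrame  # indexed by component_id
    motifs: pd.DataFrame      # gene_id, motif, position

    def __eq__(self, other) -> bool:
        return (
            self.genes.equals(other.genes)
            and self.components.equals(other.components)
            and self.motifs.equals(other.motifs)
        )

    def component_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        fam = self.genes[self.genes["component_id"] != "background"]
        for gid, row in fam.iterrows():
            out.setdefault(row["component_id"], []).append(gid)
        return {c: sorted(ms) for c, ms in out.items()}


@dataclass
class SyntheticBundle:
    config: SynthConfig
    outdir: Path
    genome_fasta: Path
    gff3: Path
    protein_fasta: Path
    vcf: Path
    fpkm_tsv: Path
    design_tsv: Path
    truth: GroundTruth


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

@dataclass
class _CompPlan:
    id: str
    cls: str
    chrom_number: int
    subgenomes: list[str]        # one entry per member
    phylo_group: str             # I | II
    subgroup: str                # one of GROUP_I_SUBGROUPS or "none"
    bias_label: str              # sub | neo | null
    bias_direction: int          # +1 | -1 | 0
    neo_carrier: int             # member index, -1 if n/a
    members: list[str] = field(default_factory=list)


def _plan_components(cfg: SynthConfig, rng: np.random.Generator) -> list[_CompPlan]:
    plans: list[_CompPlan] = []
    n_chr = cfg.n_chromosomes_per_subgenome

    def subgroup_draw() -> tuple[str, str]:
        if rng.random() < cfg.fraction_groupII:
            return "II", "none"
        return "I", GROUP_I_SUBGROUPS[rng.integers(0, len(GROUP_I_SUBGROUPS))]

    def bias_draw(n_members: int) -> tuple[str, int, int]:
        if n_members < 2:
            return "null", 0, -1
        u = rng.random()
        if u < cfg.fraction_sub:
            label = "sub"
        elif u < cfg.fraction_sub + cfg.fraction_neo:
            label = "neo"
        else:
            label = "null"
        direction = 1 if rng.random() < 0.5 else -1
        carrier = int(rng.integers(0, n_members)) if label == "neo" else -1
        if label == "null":
            direction = 0
        return label, direction, carrier

    counter = 0

    def new(cls: str, subgenomes: list[str]) -> None:
        nonlocal counter
        counter += 1
        pg, sg = subgroup_draw()
        label, direction, carrier = bias_draw(len(subgenomes))
        plans.append(
            _CompPlan(
                id=f"tcomp{counter:04d}",
                cls=cls,
                chrom_number=int(rng.integers(1, n_chr + 1)),
                subgenomes=subgenomes,
                phylo_group=pg,
                subgroup=sg,
                bias_label=label,
                bias_direction=direction,
                neo_carrier=carrier,
            )
        )

    for _ in range(cfg.n_groups):
        new("group", list(SUBGENOMES))
    for _ in range(cfg.n_clusters):
        size = int(rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1))
        subg = list(SUBGENOMES)
        for _ in range(size - 3):
            subg.append(SUBGENOMES[rng.integers(0, 3)])
        new("cluster", subg)
    for _ in range(cfg.n_pairs):
        size = int(rng.integers(cfg.pair_size_range[0], cfg.pair_size_range[1] + 1))
        two = sorted(rng.choice(3, size=2, replace=False))
        subg = [SUBGENOMES[two[0]], SUBGENOMES[two[1]]]
        for _ in range(size - 2):
            subg.append(SUBGENOMES[two[rng.integers(0, 2)]])
        new("pair", subg)
    for _ in range(cfg.n_orphans):
        new("orphan", [SUBGENOMES[rng.integers(0, 3)]])
    return plans


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)
    )


def _member_protein(ancestor: str, protected: tuple[int, int],
                    rate: float, rng: np.random.Generator) -> str:
    """Substitute residues outside the protected [start, end) block."""
    seq = list(ancestor)
    for i in range(len(seq)):
        if protected[0] <= i < protected[1]:
            continue
        if rng.random() < rate:
            seq[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return "".join(seq)


def _make_proteins(
    plans: list[_CompPlan], cfg: SynthConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, bool]]:
    """Member + background proteins; returns sequences and planted-TM flags."""
    consensus = NAC_DOMAIN_CONSENSUS
    proteins: dict[str, str] = {}
    planted_tm: dict[str, bool] = {}
    gene_no = 0
    for plan in plans:
        lo, hi = cfg.gene_length_range
        plen = int(rng.integers(lo // 3, hi // 3 + 1))
        sig = SUBGROUP_SIGNATURES[plan.subgroup]
        head = "M" + _random_protein(rng, 19)
        core = consensus + sig
        tail_len = plen - len(head) - len(core)
        ancestor = head + core + _random_protein(rng, tail_len)
        protected = (len(head), len(head) + len(core))
        for _ in plan.subgenomes:
            gene_no += 1
            gid = f"synNAC{gene_no:04d}"
            seq = _member_protein(ancestor, protected, cfg.mutation_rate, rng)
            tm = rng.random() < cfg.fraction_membrane
            if tm and len(seq) - TM_SEGMENT_LENGTH > protected[1]:
                tm_seg = "".join(
                    _HYDROPHOBIC[i]
                    for i in rng.integers(0, len(_HYDROPHOBIC), size=TM_SEGMENT_LENGTH)
                )
                seq = seq[:-TM_SEGMENT_LENGTH] + tm_seg
            else:
                tm = False
            proteins[gid] = seq
            planted_tm[gid] = tm
            plan.members.append(gid)
    for _ in range(cfg.n_background):
        gene_no += 1
        gid = f"synBG{gene_no:04d}"
        lo, hi = cfg.gene_length_range
        proteins[gid] = _random_protein(rng, int(rng.integers(lo // 3, hi // 3 + 1)))
        planted_tm[gid] = False
    return proteins, planted_tm


def back_translate(protein: str) -> str:
    return "".join(CODONS[aa] for aa in protein)


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_REVCOMP)[::-1]


# ---------------------------------------------------------------------------
# placement and genome assembly
# ---------------------------------------------------------------------------

def _place_genes(
    plans: list[_CompPlan],
    background: list[str],
    proteins: dict[str, str],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> dict[str, GeneModel]:
    chrom_names = [
        f"{num}{sg}"
        for sg in SUBGENOMES
        for num in range(1, cfg.n_chromosomes_per_subgenome + 1)
    ]
    assignment: dict[str, list[str]] = {c: [] for c in chrom_names}
    for plan in plans:
        for gid, sg in zip(plan.members, plan.subgenomes):
            assignment[f"{plan.chrom_number}{sg}"].append(gid)
    for gid in background:
        assignment[chrom_names[rng.integers(0, len(chrom_names))]].append(gid)

    min_gap = 2 * cfg.flank + 200  # flank windows of neighbours never collide
    margin = cfg.flank + 200
    genes: dict[str, GeneModel] = {}
    for chrom in chrom_names:
        ids = assignment[chrom]
        rng.shuffle(ids)
        cursor = margin
        for gid in ids:
            gene_len = 3 * len(proteins[gid])
            gap = int(rng.integers(min_gap, min_gap + 3000))
            start = cursor + gap
            end = start + gene_len - 1
            if end > cfg.chromosome_length - margin:
                raise GenerationError(
                    f"cannot place gene {gid} on chromosome {chrom}: "
                    "increase chromosome_length or reduce gene counts"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = GeneModel(id=gid, chromosome=chrom, start=start,
                                   end=end, strand=strand)
            cursor = end
    return genes


def _build_genome(
    genes: dict[str, GeneModel],
    proteins: dict[str, str],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    bases = np.array(list("ACGT"))
    chrom_names = [
        f"{num}{sg}"
        for sg in SUBGENOMES
        for num in range(1, cfg.n_chromosomes_per_subgenome + 1)
    ]
    genome = {
        c: bases[rng.integers(0, 4, size=cfg.chromosome_length)].copy()
        for c in chrom_names
    }
    for gid in sorted(genes):
        g = genes[gid]
        cds = back_translate(proteins[gid])
        if g.strand == "-":
            cds = _revcomp(cds)
        genome[g.chromosome][g.start - 1 : g.end] = list(cds)
    return genome


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def _plant_motifs(
    genome: dict[str, np.ndarray],
    genes: dict[str, GeneModel],
    family_ids: list[str],
    motif_table: dict[str, str],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Write motif instances into promoters; returns the truth table.

    The recorded position is 1-based within the promoter read 5'->3'
    relative to the gene, matching the coordinates the scanner reports.
    """
    rows = []
    plen = cfg.promoter_length
    for gid in family_ids:
        g = genes[gid]
        taken: list[tuple[int, int]] = []
        for motif in sorted(cfg.promoter_motif_rates):
            rate = cfg.promoter_motif_rates[motif]
            if rng.random() >= rate:
                continue
            instance = _resolve_iupac(motif_table[motif], rng)
            m = len(instance)
            pos = None
            for _ in range(50):
                cand = int(rng.integers(1, plen - m + 2))
                if all(cand + m <= s or cand >= e for s, e in taken):
                    pos = cand
                    break
            if pos is None:
                continue
            taken.append((pos, pos + m))
            chrom = genome[g.chromosome]
            if g.strand == "+":
                # promoter is [start - plen, start - 1]
                lo = g.start - plen + pos - 1  # 1-based genome coord
                chrom[lo - 1 : lo - 1 + m] = list(instance)
            else:
                # promoter is revcomp of [end + 1, end + plen]
                hi = g.end + plen - pos + 1
                chrom[hi - m : hi] = list(_revcomp(instance))
            rows.append({"gene_id": gid, "motif": motif, "position": pos})
    df = pd.DataFrame(rows, columns=["gene_id", "motif", "position"])
    return df.sort_values(["gene_id", "position"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# variants and expression
# ---------------------------------------------------------------------------

def _draw_snps(
    genome: dict[str, np.ndarray],
    genes: dict[str, GeneModel],
    snp_rates: dict[str, float],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    bases = "ACGT"
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        rate = snp_rates[gid]
        regions = [
            (max(1, g.start - cfg.flank), g.start - 1),
            (g.start, g.end),
            (g.end + 1, min(len(genome[g.chromosome]), g.end + cfg.flank)),
        ]
        for lo, hi in regions:
            span = hi - lo + 1
            if span <= 0:
                continue
            n = rng.poisson(rate * span / 1000.0)
            if n == 0:
                continue
            n = min(n, span)
            offsets = rng.choice(span, size=n, replace=False)
            for off in sorted(offsets):
                pos = lo + int(off)
                ref = genome[g.chromosome][pos - 1]
                alt = bases[(bases.index(ref) + 1 + rng.integers(0, 3)) % 4]
                rows.append({"chrom": g.chromosome, "pos": pos, "ref": ref, "alt": alt})
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _simulate_expression(
    plans: list[_CompPlan],
    background: list[str],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    mu, sigma = cfg.fpkm_baseline_lognormal
    samples = [f"control_{r}" for r in range(1, cfg.n_replicates + 1)] + [
        f"treatment_{r}" for r in range(1, cfg.n_replicates + 1)
    ]
    design = {
        s: (s.rsplit("_", 1)[0], int(s.rsplit("_", 1)[1])) for s in samples
    }
    gene_rows = []
    effects: list[float] = []
    gene_ids: list[str] = []
    for plan in plans:
        for idx, gid in enumerate(plan.members):
            carries = (
                plan.bias_label == "sub"
                or (plan.bias_label == "neo" and idx == plan.neo_carrier)
            )
            effects.append(plan.bias_direction * cfg.bias_effect_log2fc if carries else 0.0)
            gene_ids.append(gid)
    for gid in background:
        effects.append(0.0)
        gene_ids.append(gid)
    baselines = rng.lognormal(mu, sigma, size=len(gene_ids))
    for gid, base, eff in zip(gene_ids, baselines, effects):
        row = []
        for s in samples:
            fold = 2.0 ** eff if design[s][0] == "treatment" else 1.0
            noise = 2.0 ** (cfg.noise_sigma * rng.standard_normal()) if cfg.noise_sigma else 1.0
            row.append(base * fold * noise)
        gene_rows.append(row)
    values = pd.DataFrame(
        gene_rows, index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    return values.sort_index(), design


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SynthConfig, outdir) -> SyntheticBundle:
    """Generate and write the full synthetic bundle into ``outdir``."""
    from .regulatory import load_motif_table

    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_plan, rng_seq, rng_place, rng_genome, rng_snp, rng_expr = (
        np.random.default_rng(s) for s in streams
    )

    plans = _plan_components(cfg, rng_plan)
    proteins, planted_tm = _make_proteins(plans, cfg, rng_seq)
    family_ids = [gid for plan in plans for gid in plan.members]
    background = sorted(set(proteins) - set(family_ids))
    genes = _place_genes(plans, background, proteins, cfg, rng_place)
    genome = _build_genome(genes, proteins, cfg, rng_genome)
    motif_table = load_motif_table()
    missing = set(cfg.promoter_motif_rates) - set(motif_table)
    if missing:
        raise ValueError(f"motif rates reference unknown motifs: {sorted(missing)}")
    motifs_truth = _plant_motifs(
        genome, genes, sorted(family_ids), motif_table, cfg, rng_genome
    )

    snp_rates = {}
    plan_of = {gid: plan for plan in plans for gid in plan.members}
    for gid in genes:
        if gid in plan_of:
            pg = plan_of[gid].phylo_group
            snp_rates[gid] = cfg.snp_rate_groupI if pg == "I" else cfg.snp_rate_groupII
        else:
            snp_rates[gid] = cfg.snp_rate_groupII
    variants = _draw_snps(genome, genes, snp_rates, cfg, rng_snp)
    fpkm, design = _simulate_expression(plans, background, cfg, rng_expr)

    gene_rows = []
    for gid in sorted(genes):
        g = genes[gid]
        plan = plan_of.get(gid)
        gene_rows.append(
            {
                "gene_id": gid,
                "component_id": plan.id if plan else "background",
                "component_class": plan.cls if plan else "background",
                "chromosome": g.chromosome,
                "subgenome": g.subgenome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "is_family": plan is not None,
                "phylo_group": plan.phylo_group if plan else "",
                "subgroup": plan.subgroup if plan else "",
                "snp_rate": snp_rates[gid],
                "planted_tm": planted_tm[gid],
                "protein_length": len(proteins[gid]),
            }
        )
    genes_df = pd.DataFrame(gene_rows).set_index("gene_id")
    comp_rows = []
    for plan in plans:
        comp_rows.append(
            {
                "component_id": plan.id,
                "class": plan.cls,
                "chromosome_number": plan.chrom_number,
                "n_members": len(plan.members),
                "phylo_group": plan.phylo_group,
                "subgroup": plan.subgroup,
                "bias_label": plan.bias_label,
                "bias_direction": plan.bias_direction,
                "neo_carrier": plan.members[plan.neo_carrier] if plan.neo_carrier >= 0 else "",
            }
        )
    comps_df = pd.DataFrame(comp_rows).set_index("component_id")
    truth = GroundTruth(genes=genes_df, components=comps_df, motifs=motifs_truth)

    paths = SyntheticBundle(
        config=cfg,
        outdir=outdir,
        genome_fasta=outdir / "genome.fa",
        gff3=outdir / "genes.gff3",
        protein_fasta=outdir / "proteins.faa",
        vcf=outdir / "variants.vcf",
        fpkm_tsv=outdir / "fpkm.tsv",
        design_tsv=outdir / "design.tsv",
        truth=truth,
    )
    hio.write_fasta({c: "".join(genome[c]) for c in sorted(genome)}, paths.genome_fasta)
    ordered = dict(
        sorted(genes.items(), key=lambda kv: (kv[1].chromosome, kv[1].start))
    )
    hio.write_gff3(ordered, paths.gff3)
    hio.write_fasta({gid: proteins[gid] for gid in sorted(proteins)}, paths.protein_fasta)
    hio.write_vcf(variants, paths.vcf,
                  contigs={c: cfg.chromosome_length for c in sorted(genome)})
    hio.write_fpkm(fpkm, design, paths.fpkm_tsv, paths.design_tsv)
    write_truth_tables(truth, outdir)
    return paths


def write_truth_tables(truth: GroundTruth, outdir) -> None:
    """Write the three ground-truth TSVs; round-trips exactly."""
    if truth.components.empty:
        raise ValueError("ground truth has no components")
    outdir = Path(outdir)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.components.to_csv(outdir / "truth_components.tsv", sep="\t")
    truth.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)


def read_truth_tables(outdir) -> GroundTruth:
    outdir = Path(outdir)
    genes = pd.read_csv(
        outdir / "truth_genes.tsv", sep="\t", index_col=0,
        dtype={"phylo_group": str, "subgroup": str}, keep_default_na=False,
        na_values=[],
    )
    for col in ("start", "end", "protein_length"):
        genes[col] = genes[col].astype(int)
    genes["snp_rate"] = genes["snp_rate"].astype(float)
    for col in ("is_family", "planted_tm"):
        genes[col] = genes[col].map(lambda v: v is True or v == "True")
    comps = pd.read_csv(
        outdir / "truth_components.tsv", sep="\t", index_col=0,
        keep_default_na=False, na_values=[],
    )
    for col in ("chromosome_number", "n_members", "bias_direction"):
        comps[col] = comps[col].astype(int)
    motifs = pd.read_csv(outdir / "truth_motifs.tsv", sep="\t",
                         keep_default_na=False, na_values=[])
    if not motifs.empty:
        motifs["position"] = motifs["position"].astype(int)
    return GroundTruth(genes=genes, components=comps, motifs=motifs)
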