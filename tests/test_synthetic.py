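"""Synthetic hexaploid generator: planted structure, determinism, truth."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from homeobias import SynthConfig, generate_dataset
from homeobias.io import read_fasta, read_gff3, read_vcf
from homeobias.regulatory import extract_promoter, load_motif_table, scan_motifs
from homeobias.synthetic import (
    GenerationError,
    GroundTruth,
    read_truth_tables,
    write_truth_tables,
)

SMALL = dict(
    n_groups=8, n_clusters=2, n_pairs=2, n_orphans=3, n_background=5,
    chromosome_length=150_000,
)


@pytest.fixture(scope="module")
def small_bundle(tmp_path_factory):
    return generate_dataset(SynthConfig(seed=5, **SMALL), tmp_path_factory.mktemp("sm"))


class TestConfigValidation:
    def test_cluster_minimum_enforced(self):
        with pytest.raises(ValueError, match="cluster_size_range"):
            SynthConfig(cluster_size_range=(3, 5)).validate()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(fraction_sub=0.5, fraction_neo=0.5, fraction_null=0.5).validate()

    def test_motif_rate_range(self):
        with pytest.raises(ValueError, match="rate"):
            SynthConfig(promoter_motif_rates={"ABRE": 1.5}).validate()

    def test_gene_length_floor(self):
        with pytest.raises(ValueError, match="gene_length_range"):
            SynthConfig(gene_length_range=(120, 600)).validate()

    def test_overfull_chromosome_names_it(self, tmp_path):
        cfg = SynthConfig(seed=0, n_groups=200, chromosome_length=60_000,
                          n_clusters=0, n_pairs=0, n_orphans=0, n_background=0)
        with pytest.raises(GenerationError, match="chromosome"):
            generate_dataset(cfg, tmp_path)


class TestPlantedStructure:
    def test_component_counts_match_config(self, small_bundle):
        counts = small_bundle.truth.components["class"].value_counts().to_dict()
        assert counts["group"] == 8
        assert counts["cluster"] == 2
        assert counts["pair"] == 2
        assert counts["orphan"] == 3

    def test_gene_totals_by_construction(self, small_bundle):
        truth = small_bundle.truth
        comp = truth.components
        expected = (
            3 * 8
            + comp.loc[comp["class"] == "cluster", "n_members"].sum()
            + comp.loc[comp["class"] == "pair", "n_members"].sum()
            + 3
        )
        fam = truth.genes[truth.genes["is_family"]]
        assert len(fam) == expected
        assert len(truth.genes) == expected + 5

    def test_chromosome_naming_and_gff_consistency(self, small_bundle):
        genome = read_fasta(small_bundle.genome_fasta)
        expected = {f"{n}{s}" for s in "ABD" for n in range(1, 8)}
        assert set(genome) == expected
        genes = read_gff3(small_bundle.gff3)
        for gid, g in genes.items():
            assert g.chromosome in expected
            assert g.end <= len(genome[g.chromosome])

    def test_groups_have_one_member_per_subgenome_same_chromosome(self, small_bundle):
        truth = small_bundle.truth
        fam = truth.genes[truth.genes["is_family"]]
        for cid, comp in truth.components.iterrows():
            members = fam[fam["component_id"] == cid]
            subg = sorted(members["subgenome"])
            if comp["class"] == "group":
                assert subg == ["A", "B", "D"]
                assert members["chromosome"].str[:-1].nunique() == 1
            elif comp["class"] == "cluster":
                assert len(members) >= 4
                assert set(subg) == {"A", "B", "D"}
                assert max(subg.count(s) for s in "ABD") >= 2
            elif comp["class"] == "pair":
                assert len(set(subg)) == 2
            else:
                assert len(members) == 1

    def test_gene_gaps_keep_flank_windows_disjoint(self, small_bundle):
        genes = sorted(read_gff3(small_bundle.gff3).values(),
                       key=lambda g: (g.chromosome, g.start))
        for a, b in zip(genes, genes[1:]):
            if a.chromosome == b.chromosome:
                assert b.start - a.end > 2 * 2000

    def test_family_proteins_contain_consensus_background_not(self, small_bundle):
        from homeobias.features import NAC_DOMAIN_CONSENSUS

        proteins = read_fasta(small_bundle.protein_fasta)
        truth = small_bundle.truth
        for gid, row in truth.genes.iterrows():
            if row["is_family"]:
                assert NAC_DOMAIN_CONSENSUS in proteins[gid]
            else:
                assert NAC_DOMAIN_CONSENSUS not in proteins[gid]

    def test_cds_back_translation_lands_on_genome(self, small_bundle):
        from homeobias.synthetic import back_translate
        from homeobias.regulatory import reverse_complement

        genome = read_fasta(small_bundle.genome_fasta)
        proteins = read_fasta(small_bundle.protein_fasta)
        genes = read_gff3(small_bundle.gff3)
        for gid in list(proteins)[:10]:
            g = genes[gid]
            cds = genome[g.chromosome][g.start - 1 : g.end]
            if g.strand == "-":
                cds = reverse_complement(cds)
            assert cds == back_translate(proteins[gid])


class TestPlantedMotifs:
    def test_every_planted_motif_is_recovered_by_the_scanner(self, small_bundle):
        genome = read_fasta(small_bundle.genome_fasta)
        genes = read_gff3(small_bundle.gff3)
        table = load_motif_table()
        truth = small_bundle.truth
        for gid, sub in truth.motifs.groupby("gene_id"):
            promoter = extract_promoter(genes[gid], genome, 1500)
            found = {
                (h.motif, h.position)
                for h in scan_motifs(gid, promoter, table)
                if h.strand == "+"
            }
            planted = set(zip(sub["motif"], sub["position"]))
            assert planted <= found

    def test_presence_rate_within_binomial_band(self, default_bundle):
        # background-corrected expected presence probability:
        # q = r + (1 - r) * p_bg with p_bg the chance of >= 1 random
        # match in a 1.5-kb promoter (both strands)
        genome = read_fasta(default_bundle.genome_fasta)
        genes = read_gff3(default_bundle.gff3)
        table = load_motif_table()
        truth = default_bundle.truth
        fam = list(truth.genes.index[truth.genes["is_family"]])
        for motif, rate in (("TC-rich repeats", 0.30), ("GCN4_motif", 0.25)):
            pattern = table[motif]
            m = len(pattern)
            n_words = math.prod(
                {"A": 1, "C": 1, "G": 1, "T": 1}.get(c, 2) for c in pattern
            )
            p_word = n_words / 4 ** m
            p_bg = 1 - (1 - p_word) ** (2 * (1500 - m + 1))
            q = rate + (1 - rate) * p_bg
            present = 0
            for gid in fam:
                promoter = extract_promoter(genes[gid], genome, 1500)
                if any(h.motif == motif for h in scan_motifs(gid, promoter, {motif: pattern})):
                    present += 1
            se = math.sqrt(q * (1 - q) / len(fam))
            assert abs(present / len(fam) - q) <= 3 * se


class TestPlantedSnps:
    def test_empirical_density_converges_to_planted_rate(self, default_bundle):
        variants = read_vcf(default_bundle.vcf)
        genes = read_gff3(default_bundle.gff3)
        truth = default_bundle.truth
        by_chrom = {c: np.sort(sub["pos"].to_numpy()) for c, sub in variants.groupby("chrom")}
        for rate_name, rate in (("I", 0.9), ("II", 2.0)):
            fam = truth.genes[
                truth.genes["is_family"] & (truth.genes["phylo_group"] == rate_name)
            ]
            total_snps = 0
            total_kb = 0.0
            for gid, row in fam.iterrows():
                g = genes[gid]
                lo, hi = g.start - 2000, g.end + 2000
                pos = by_chrom.get(g.chromosome, np.array([], dtype=int))
                total_snps += int(
                    np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left")
                )
                total_kb += (hi - lo + 1) / 1000
            expected = rate * total_kb
            assert abs(total_snps - expected) <= 3 * math.sqrt(expected)

    def test_vcf_ref_matches_genome(self, small_bundle):
        genome = read_fasta(small_bundle.genome_fasta)
        variants = read_vcf(small_bundle.vcf)
        sample = variants.sample(n=min(50, len(variants)), random_state=0)
        for row in sample.itertuples(index=False):
            assert genome[row.chrom][row.pos - 1] == row.ref
            assert row.alt != row.ref


class TestExpression:
    def test_null_genes_have_zero_log2fc_at_zero_noise(self, tmp_path):
        cfg = SynthConfig(seed=3, noise_sigma=0.0, **SMALL)
        bundle = generate_dataset(cfg, tmp_path)
        values = pd.read_csv(bundle.fpkm_tsv, sep="\t", index_col=0)
        truth = bundle.truth
        null_comps = truth.components.index[truth.components["bias_label"] == "null"]
        null_genes = truth.genes.index[
            truth.genes["component_id"].isin(null_comps)
        ]
        ctrl = values.filter(like="control_")
        trt = values.filter(like="treatment_")
        lfc = np.log2(trt.mean(axis=1) + 1) - np.log2(ctrl.mean(axis=1) + 1)
        assert np.abs(lfc.loc[null_genes]).max() == 0.0

    def test_planted_effect_shifts_treatment_means(self, small_bundle):
        values = pd.read_csv(small_bundle.fpkm_tsv, sep="\t", index_col=0)
        truth = small_bundle.truth
        sub_up = truth.components.index[
            (truth.components["bias_label"] == "sub")
            & (truth.components["bias_direction"] == 1)
        ]
        genes = truth.genes.index[truth.genes["component_id"].isin(sub_up)]
        if len(genes):
            ctrl = values.loc[genes].filter(like="control_").mean(axis=1)
            trt = values.loc[genes].filter(like="treatment_").mean(axis=1)
            assert (trt > ctrl).all()


class TestDeterminismAndTruthIO:
    FILES = (
        "genome.fa", "genes.gff3", "proteins.faa", "variants.vcf",
        "fpkm.tsv", "design.tsv", "truth_genes.tsv", "truth_components.tsv",
        "truth_motifs.tsv",
    )

    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_dataset(SynthConfig(seed=9, **SMALL), tmp_path / "a")
        b = generate_dataset(SynthConfig(seed=9, **SMALL), tmp_path / "b")
        for name in self.FILES:
            assert (a.outdir / name).read_bytes() == (b.outdir / name).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        a = generate_dataset(SynthConfig(seed=9, **SMALL), tmp_path / "a")
        b = generate_dataset(SynthConfig(seed=10, **SMALL), tmp_path / "b")
        assert (a.outdir / "genome.fa").read_bytes() != (b.outdir / "genome.fa").read_bytes()

    def test_truth_tables_round_trip_exactly(self, small_bundle):
        assert read_truth_tables(small_bundle.outdir) == small_bundle.truth

    def test_empty_truth_rejected(self, tmp_path):
        empty = GroundTruth(
            genes=pd.DataFrame(), components=pd.DataFrame(), motifs=pd.DataFrame()
        )
        with pytest.raises(ValueError):
            write_truth_tables(empty, tmp_path)
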