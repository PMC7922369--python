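"""Promoter extraction, IUPAC motif scanning, SNP density."""

import itertools

import numpy as np
import pytest

from homeobias.components import GeneModel
from homeobias.regulatory import (
    IUPAC,
    contrast_density_by_phylo_group,
    count_elements_by_subgenome,
    extract_promoter,
    load_motif_table,
    reverse_complement,
    scan_motifs,
    snp_density,
)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestPromoterExtraction:
    def test_plus_strand_window(self):
        chrom = random_dna(np.random.default_rng(0), 5000)
        genome = {"1A": chrom}
        g = GeneModel(id="g", chromosome="1A", start=2001, end=3000, strand="+")
        promoter = extract_promoter(g, genome, length=1500)
        assert promoter == chrom[500:2000]  # positions 501..2000

    def test_minus_strand_is_revcomp_of_downstream(self):
        chrom = random_dna(np.random.default_rng(1), 5000)
        genome = {"1A": chrom}
        g = GeneModel(id="g", chromosome="1A", start=1001, end=2000, strand="-")
        promoter = extract_promoter(g, genome, length=1500)
        assert promoter == reverse_complement(chrom[2000:3500])

    def test_truncated_at_chromosome_start(self):
        chrom = random_dna(np.random.default_rng(2), 5000)
        g = GeneModel(id="g", chromosome="1A", start=100, end=1099, strand="+")
        promoter = extract_promoter(g, {"1A": chrom}, length=1500)
        assert len(promoter) == 99
        assert promoter == chrom[:99]

    def test_missing_chromosome_raises(self):
        g = GeneModel(id="g", chromosome="9Z", start=100, end=200)
        with pytest.raises(KeyError):
            extract_promoter(g, {"1A": "ACGT"})


def regex_expansion_oracle(promoter, pattern, both_strands=True):
    """Expand the IUPAC pattern into every concrete word and substring-scan."""
    hits = []
    for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
        if strand == "-" and not both_strands:
            continue
        words = {"".join(w) for w in itertools.product(*[IUPAC[c] for c in pat])}
        m = len(pat)
        for s in range(len(promoter) - m + 1):
            if promoter[s : s + m] in words:
                hits.append((s + 1, strand))
    return sorted(hits)


class TestMotifScan:
    def test_direct_match_example(self):
        hits = scan_motifs("g", "AAACGTGTT", {"ABRE": "ACGTG"}, both_strands=False)
        assert [(h.position, h.strand) for h in hits] == [(3, "+")]

    def test_empty_table_no_hits(self):
        assert scan_motifs("g", "ACGTACGT", {}) == []

    def test_illegal_iupac_letter_names_motif(self):
        with pytest.raises(ValueError, match="badmotif"):
            scan_motifs("g", "ACGT", {"badmotif": "ACZT"})

    def test_overlapping_self_matches_found(self):
        # CATGCATGCATG contains CATGCATG at positions 1 and 5
        hits = scan_motifs("g", "CATGCATGCATG", {"RY-element": "CATGCATG"})
        plus = [h.position for h in hits if h.strand == "+"]
        assert plus == [1, 5]

    def test_matches_regex_expansion_oracle(self, rng):
        table = load_motif_table()
        for _ in range(5):
            seq = random_dna(rng, 2000)
            got = {
                (h.motif, h.position, h.strand)
                for h in scan_motifs("g", seq, table)
            }
            expected = {
                (name, pos, strand)
                for name, pat in table.items()
                for pos, strand in regex_expansion_oracle(seq, pat)
            }
            assert got == expected

    def test_degenerate_pattern_oracle(self, rng):
        table = {"deg": "RYSWKN"}
        seq = random_dna(rng, 3000)
        got = {(h.position, h.strand) for h in scan_motifs("g", seq, table)}
        assert got == set(regex_expansion_oracle(seq, "RYSWKN"))


class TestElementCounts:
    def _genes(self):
        return {
            "a1": GeneModel(id="a1", chromosome="1A", start=5000, end=6000),
            "b1": GeneModel(id="b1", chromosome="1B", start=5000, end=6000),
        }

    def test_presence_semantics(self):
        from homeobias.regulatory import MotifHit

        hits = [
            MotifHit("a1", "ABRE", 10, "+"),
            MotifHit("a1", "ABRE", 50, "+"),
            MotifHit("a1", "ABRE", 90, "-"),
        ]
        table = count_elements_by_subgenome(hits, self._genes())
        assert table.loc["ABRE", "A"] == 1
        assert table.loc["ABRE", "B"] == 0

    def test_single_subgenome_hits_leave_others_zero(self):
        from homeobias.regulatory import MotifHit

        hits = [MotifHit("a1", "MBS", 3, "+")]
        table = count_elements_by_subgenome(hits, self._genes())
        assert table.loc["MBS", "B"] == 0 and table.loc["MBS", "D"] == 0


class TestSnpDensity:
    def test_arithmetic_example(self):
        g = GeneModel(id="g", chromosome="1A", start=10001, end=12000, strand="+")
        positions = np.array([10001 + 200 * i for i in range(10)])  # all in body
        recs = {r.region: r for r in snp_density(g, positions)}
        assert recs["body"].n_snps == 10
        assert recs["body"].region_len_kb == 2.0
        assert recs["body"].density == pytest.approx(5.0)

    def test_no_variants_all_zero(self):
        g = GeneModel(id="g", chromosome="1A", start=10001, end=12000)
        for r in snp_density(g, np.array([], dtype=int)):
            assert r.n_snps == 0 and r.density == 0.0

    def test_strand_swaps_flanks(self):
        positions = np.array([9500, 12500])
        plus = {r.region: r for r in snp_density(
            GeneModel(id="g", chromosome="1A", start=10001, end=12000, strand="+"),
            positions)}
        minus = {r.region: r for r in snp_density(
            GeneModel(id="g", chromosome="1A", start=10001, end=12000, strand="-"),
            positions)}
        assert plus["up2k"].n_snps == 1 and plus["down2k"].n_snps == 1
        assert minus["up2k"].n_snps == plus["down2k"].n_snps
        assert minus["down2k"].n_snps == plus["up2k"].n_snps

    def test_truncation_shrinks_denominator(self):
        g = GeneModel(id="g", chromosome="1A", start=501, end=1500, strand="+")
        recs = {r.region: r for r in snp_density(g, np.array([], dtype=int),
                                                 chromosome_length=2000)}
        assert recs["up2k"].region_len_kb == pytest.approx(0.5)
        assert recs["down2k"].region_len_kb == pytest.approx(0.5)

    def test_matches_per_position_membership_oracle(self, rng):
        for _ in range(100):
            start = int(rng.integers(3000, 20000))
            length = int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(id="g", chromosome="1A", start=start,
                          end=start + length - 1, strand=strand)
            positions = np.sort(rng.choice(
                np.arange(1, 30000), size=int(rng.integers(0, 200)), replace=False))
            recs = {r.region: r for r in snp_density(g, positions)}
            up = (g.start - 2000, g.start - 1) if strand == "+" else (g.end + 1, g.end + 2000)
            down = (g.end + 1, g.end + 2000) if strand == "+" else (g.start - 2000, g.start - 1)
            oracle = {
                "body": sum(1 for p in positions if g.start <= p <= g.end),
                "up2k": sum(1 for p in positions if up[0] <= p <= up[1]),
                "down2k": sum(1 for p in positions if down[0] <= p <= down[1]),
            }
            for region, n in oracle.items():
                assert recs[region].n_snps == n

    def test_shift_invariance(self, rng):
        start = 5000
        g = GeneModel(id="g", chromosome="1A", start=start, end=start + 999)
        positions = np.sort(rng.choice(np.arange(2000, 9000), size=40, replace=False))
        base = [(r.region, r.n_snps, r.region_len_kb) for r in snp_density(g, positions)]
        shift = 12345
        g2 = GeneModel(id="g", chromosome="1A", start=start + shift, end=start + 999 + shift)
        shifted = [(r.region, r.n_snps, r.region_len_kb)
                   for r in snp_density(g2, positions + shift)]
        assert base == shifted


class TestDensityContrast:
    def _records(self, densities_i, densities_ii):
        from homeobias.regulatory import SNPDensityRecord

        recs, groups = [], {}
        for i, d in enumerate(densities_i):
            recs.append(SNPDensityRecord(gene=f"i{i}", region="body",
                                         n_snps=int(d * 2), region_len_kb=2.0))
            groups[f"i{i}"] = "I"
        for i, d in enumerate(densities_ii):
            recs.append(SNPDensityRecord(gene=f"ii{i}", region="body",
                                         n_snps=int(d * 2), region_len_kb=2.0))
            groups[f"ii{i}"] = "II"
        return recs, groups

    def test_group_means(self):
        recs, groups = self._records([1, 2, 3], [4, 6])
        out = contrast_density_by_phylo_group(recs, groups)
        assert out["I"] == pytest.approx(2.0)
        assert out["II"] == pytest.approx(5.0)
        assert out["overall"] == pytest.approx(16 / 5)

    def test_empty_group_reported_absent(self):
        recs, groups = self._records([1, 2], [])
        out = contrast_density_by_phylo_group(recs, groups)
        assert out["II"] is None

    def test_unassigned_gene_rejected(self):
        recs, groups = self._records([1], [1])
        del groups["i0"]
        with pytest.raises(ValueError):
            contrast_density_by_phylo_group(recs, groups)
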