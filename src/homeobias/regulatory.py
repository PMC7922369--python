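"""Promoter cis-element scanning and gene-centric SNP density.

Promoters are the 1.5 kb upstream of the initiation codon (strand-aware,
truncated at chromosome ends).  Cis-elements are matched exactly against
a bundled, editable IUPAC consensus table on both strands — a local,
reproducible substitute for a web-service lookup; counts use
gene-presence semantics (a gene with three ABRE matches contributes one
to the ABRE count), which is how family surveys report element
abundance.

SNP density is computed per gene over three regions — gene body, 2-kb
upstream and 2-kb downstream (strand-aware) — in SNPs per kb, with
flank windows truncated at chromosome boundaries (the denominator
shrinks accordingly, no padding).  The Group I vs Group II density
contrast summarizes selection-intensity differences between the two
major phylogenetic groups.

Coordinates are 1-based inclusive throughout (GFF3/VCF native).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .components import GeneModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_motif_table() -> dict[str, str]:
    """The bundled cis-element consensus table (name -> IUPAC pattern)."""
    table: dict[str, str] = {}
    path = resources.files("homeobias.data").joinpath("motifs.tsv")
    with open(str(path)) as fh:
        header = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                continue
            name, pattern = line.split("\t")
            table[name] = pattern
    return table


def validate_motif_table(table: dict[str, str]) -> None:
    for name, pattern in table.items():
        if not pattern:
            raise ValueError(f"motif {name!r}: empty pattern")
        bad = [c for c in pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {name!r}: illegal IUPAC letter {bad[0]!r}")


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif: str
    position: int  # 1-based within the promoter (forward coordinates)
    strand: str


@dataclass(frozen=True)
class SNPDensityRecord:
    gene: str
    region: str  # body | up2k | down2k
    n_snps: int
    region_len_kb: float

    @property
    def density(self) -> float:
        return self.n_snps / self.region_len_kb if self.region_len_kb > 0 else 0.0


def extract_promoter(
    gene: GeneModel, genome: dict[str, str], length: int = 1500
) -> str:
    """Upstream promoter sequence, read 5'->3' relative to the gene.

    Plus strand: positions [start - length, start - 1]; minus strand:
    reverse complement of [end + 1, end + length].  Truncated at
    chromosome boundaries, so the result may be shorter than ``length``.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        lo = max(1, gene.start - length)
        return chrom[lo - 1 : gene.start - 1]
    hi = min(len(chrom), gene.end + length)
    return reverse_complement(chrom[gene.end : hi])


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern)
    )


def scan_motifs(
    gene: str,
    promoter: str,
    table: dict[str, str],
    both_strands: bool = True,
) -> list[MotifHit]:
    """All exact IUPAC matches in the promoter, overlapping included.

    Minus-strand hits are reported at the 1-based start of the matching
    window in forward promoter coordinates.  Sorted by position, then
    motif name, then strand.
    """
    validate_motif_table(table)
    # lookahead so self-overlapping matches (e.g. CATGCATG) are all found
    hits: list[MotifHit] = []
    for name in table:
        for strand, pat in (("+", table[name]), ("-", reverse_complement(table[name]))):
            if strand == "-" and not both_strands:
                continue
            rx = re.compile("(?=" + _iupac_regex(pat).pattern + ")")
            for m in rx.finditer(promoter):
                hits.append(MotifHit(gene, name, m.start() + 1, strand))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def count_elements_by_subgenome(
    hits: list[MotifHit], genes: dict[str, GeneModel]
) -> pd.DataFrame:
    """Motif x subgenome table of gene-presence counts."""
    for h in hits:
        if genes[h.gene].subgenome == "unknown":
            raise ValueError(f"gene {h.gene} has no subgenome")
    present: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        present.setdefault((h.motif, genes[h.gene].subgenome), set()).add(h.gene)
    motifs = sorted({h.motif for h in hits})
    data = {
        sg: [len(present.get((m, sg), ())) for m in motifs] for sg in ("A", "B", "D")
    }
    return pd.DataFrame(data, index=pd.Index(motifs, name="motif"))


def snp_density(
    gene: GeneModel,
    positions: np.ndarray,
    flank: int = 2000,
    chromosome_length: int | None = None,
) -> list[SNPDensityRecord]:
    """SNP counts/densities for gene body and strand-aware 2-kb flanks.

    ``positions`` are the sorted 1-based variant positions on the gene's
    chromosome.  Flank windows are truncated at position 1 and, when
    ``chromosome_length`` is given, at the chromosome end; the region
    length (kb denominator) shrinks with truncation.
    """
    positions = np.asarray(positions)
    left = (max(1, gene.start - flank), gene.start - 1)
    right_hi = gene.end + flank
    if chromosome_length is not None:
        right_hi = min(chromosome_length, right_hi)
    right = (gene.end + 1, right_hi)
    if gene.strand == "+":
        regions = {"body": (gene.start, gene.end), "up2k": left, "down2k": right}
    else:
        regions = {"body": (gene.start, gene.end), "up2k": right, "down2k": left}
    out = []
    for name, (lo, hi) in regions.items():
        span = max(0, hi - lo + 1)
        n = int(np.searchsorted(positions, hi, side="right")
                - np.searchsorted(positions, lo, side="left")) if span else 0
        out.append(
            SNPDensityRecord(gene=gene.id, region=name, n_snps=n,
                             region_len_kb=span / 1000.0)
        )
    return out


def density_table(records: list[SNPDensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "region": [r.region for r in records],
            "n_snps": [r.n_snps for r in records],
            "region_len_kb": [r.region_len_kb for r in records],
            "density_per_kb": [r.density for r in records],
        }
    )


def contrast_density_by_phylo_group(
    records: list[SNPDensityRecord], phylo_group: dict[str, str]
) -> dict[str, float | None]:
    """Mean gene-body SNP density (SNPs/kb) per phylogenetic group.

    Returns means for Group I, Group II and overall; a group with no
    genes is reported as ``None`` (absent), never as 0.
    """
    body = [r for r in records if r.region == "body"]
    missing = [r.gene for r in body if r.gene not in phylo_group]
    if missing:
        raise ValueError(f"genes without phylo group: {sorted(set(missing))[:5]}")
    by_group: dict[str, list[float]] = {"I": [], "II": []}
    for r in body:
        by_group[phylo_group[r.gene]].append(r.density)
    overall = [r.density for r in body]
    return {
        "I": float(np.mean(by_group["I"])) if by_group["I"] else None,
        "II": float(np.mean(by_group["II"])) if by_group["II"] else None,
        "overall": float(np.mean(overall)) if overall else None,
    }
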