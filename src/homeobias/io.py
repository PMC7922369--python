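"""File format I/O: FASTA, GFF3, VCF, FPKM/design TSV, Newick, YAML.

Conventions: GFF3 and VCF coordinates are 1-based inclusive and
preserved as such; FASTA ids are the header up to the first whitespace;
everything the pipeline writes round-trips losslessly through these
readers.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .components import GeneModel
from .features import ProteinRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered id -> sequence dict; duplicate ids error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_proteins(path) -> list[ProteinRecord]:
    return [ProteinRecord(id=i, sequence=s) for i, s in read_fasta(path).items()]


def read_gff3(path) -> dict[str, GeneModel]:
    """Gene features from a GFF3 file, keyed by ID attribute.

    The optional ``subgenome`` attribute is not needed: the subgenome is
    derived from the chromosome name ("3B" -> B, "unplaced" -> unknown).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.id
        if gid in genes:
            raise ValueError(f"{path}: duplicate gene ID {gid!r}")
        genes[gid] = GeneModel(
            id=gid,
            chromosome=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
        )
    return genes


def write_gff3(genes: dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.values():
            attrs = f"ID={g.id};subgenome={g.subgenome}"
            fh.write(
                f"{g.chromosome}\thomeobias\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Variants as a DataFrame (chrom, pos, ref, alt), 1-based positions."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        rows.append(
            {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
             "alt": v.ALT[0] if v.ALT else "."}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_vcf(variants: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """Minimal VCF 4.2 writer (sites only, sorted by chrom then pos)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=homeobias-synth\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        if len(variants):
            ordered = variants.sort_values(["chrom", "pos"], kind="stable")
            for row in ordered.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n"
                )


def read_fpkm(matrix_path, design_path) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    """FPKM matrix (genes x samples) plus the design sidecar.

    The sidecar has columns sample / condition / replicate.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    for col in ("sample", "condition", "replicate"):
        if col not in design_df.columns:
            raise ValueError(f"{design_path}: missing column {col!r}")
    design = {
        str(r.sample): (str(r.condition), int(r.replicate))
        for r in design_df.itertuples(index=False)
    }
    return values, design


def write_fpkm(values: pd.DataFrame, design: dict[str, tuple[str, int]],
               matrix_path, design_path) -> None:
    values.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(design_path, "w") as fh:
        fh.write("sample\tcondition\treplicate\n")
        for s in values.columns:
            cond, rep = design[s]
            fh.write(f"{s}\t{cond}\t{rep}\n")


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def files_identical(a, b) -> bool:
    return Path(a).read_bytes() == Path(b).read_bytes()
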