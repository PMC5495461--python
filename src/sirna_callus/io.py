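"""File formats and coordinate conventions.

Internally every interval is 0-based half-open.  GFF3 is 1-based inclusive
and converted exactly on read/write; BED is native 0-based half-open.
Tables travel as TSV through pandas; genomes as FASTA through Biopython.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "gff3_to_internal",
    "internal_to_gff3",
    "read_fasta",
    "write_fasta",
    "write_genes_gff3",
    "read_genes_gff3",
    "write_class_annotation_gff3",
    "read_class_annotation_gff3",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "sha256_file",
]


def gff3_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


@dataclass
class GeneModel:
    """A gene with fixed 5'UTR / CDS / 3'UTR transcript architecture.

    Genomic span is [start, end) on ``chrom``; the transcript is the sense
    strand of that span (reverse-complemented for '-' genes).  UTR/CDS
    lengths are in transcript coordinates.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def transcript_seq(self, genome: dict[str, str]) -> str:
        s = genome[self.chrom][self.start : self.end]
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s.upper()

    def transcript_region(self, position: int) -> str:
        """5'UTR | CDS | 3'UTR for a 0-based transcript position."""
        if position < self.utr5_len:
            return "5'UTR"
        if position < self.utr5_len + self.cds_len:
            return "CDS"
        return "3'UTR"

    def transcript_to_genomic(self, t: int) -> int:
        """Genomic coordinate of 0-based transcript position ``t``."""
        if self.strand == "+":
            return self.start + t
        return self.end - 1 - t

    def utr3_genomic_span(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.end - self.utr3_len, self.end
        return self.start, self.start + self.utr3_len

    def feature_spans(self) -> list[tuple[str, int, int]]:
        """(type, genomic start, genomic end) for UTRs and CDS, half-open."""
        u5, cds, u3 = self.utr5_len, self.cds_len, self.utr3_len
        if self.strand == "+":
            return [
                ("five_prime_UTR", self.start, self.start + u5),
                ("CDS", self.start + u5, self.start + u5 + cds),
                ("three_prime_UTR", self.end - u3, self.end),
            ]
        return [
            ("five_prime_UTR", self.end - u5, self.end),
            ("CDS", self.start + u3, self.start + u3 + cds),
            ("three_prime_UTR", self.start, self.start + u3),
        ]


# --- FASTA ---------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    out = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: truncated FASTA record #{i} ({rec.id!r}) has no sequence")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 ----------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def _gff_line(chrom, source, ftype, start, end, strand, attrs) -> str:
    g1, g2 = internal_to_gff3(start, end)
    return "\t".join([chrom, source, ftype, str(g1), str(g2), ".", strand, ".", attrs])


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = (
            f"ID={g.gene_id};utr5_len={g.utr5_len};cds_len={g.cds_len};"
            f"utr3_len={g.utr3_len}"
        )
        lines.append(_gff_line(g.chrom, "sim", "gene", g.start, g.end, g.strand, attrs))
        for ftype, s, e in g.feature_spans():
            lines.append(
                _gff_line(g.chrom, "sim", ftype, s, e, g.strand, f"Parent={g.gene_id}")
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k] = v
    return out


def read_genes_gff3(path) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        if fields[2] != "gene":
            continue
        start, end = gff3_to_internal(int(fields[3]), int(fields[4]))
        attrs = _parse_attrs(fields[8])
        genes.append(
            GeneModel(
                gene_id=attrs["ID"],
                chrom=fields[0],
                start=start,
                end=end,
                strand=fields[6],
                utr5_len=int(attrs["utr5_len"]),
                cds_len=int(attrs["cds_len"]),
                utr3_len=int(attrs["utr3_len"]),
            )
        )
    return genes


def write_class_annotation_gff3(intervals, path) -> None:
    """(chrom, start, end, class) intervals, internal half-open coordinates."""
    lines = ["##gff-version 3"]
    for i, (chrom, start, end, cls) in enumerate(intervals):
        lines.append(_gff_line(chrom, "sim", cls, start, end, "+", f"ID=excl{i + 1:04d}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_class_annotation_gff3(path) -> list[tuple[str, int, int, str]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        start, end = gff3_to_internal(int(fields[3]), int(fields[4]))
        out.append((fields[0], start, end, fields[2]))
    return out


# --- BED / TSV -----------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    # round_trip float parsing: resumed stages must reload the exact values
    # they wrote, or downstream outputs stop being byte-identical
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
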