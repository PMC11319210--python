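"""Readers and writers for the external formats the toolkit touches.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed)
and VCF POS (1-based) are converted exactly at this boundary, nowhere else.
Readers validate strictly and raise :class:`~panscape.errors.FormatError`
rather than silently coercing malformed input.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .errors import FormatError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted by the FASTA reader.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")

_SV_TYPE_ALIASES = {
    "DEL": "DEL", "DELETION": "DEL",
    "INS": "INS", "INSERTION": "INS",
    "DUP": "DUP", "DUPLICATION": "DUP",
    "INV": "INV", "INVERSION": "INV",
    "TRA": "TRA", "TRANSLOCATION": "TRA", "BND": "TRA",
}

#: Column order of the project SV exchange TSV (0-based half-open coords).
SV_TSV_COLUMNS = ("accession", "chromosome", "start", "end",
                  "type", "length", "inserted_seq")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with its CDS parts.

    ``span`` and every element of ``cds_parts`` are 0-based half-open.
    ``cds_parts`` are sorted 5'->3' on the feature strand, i.e. by
    ascending start on '+' genes and descending start on '-' genes.
    """

    id: str
    chromosome: str
    span: tuple[int, int]
    strand: str
    cds_parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"gene {self.id}: strand must be + or -")
        s, e = self.span
        if not 0 <= s < e:
            raise FormatError(f"gene {self.id}: invalid span {self.span}")
        for cs, ce in self.cds_parts:
            if not (s <= cs < ce <= e):
                raise FormatError(
                    f"gene {self.id}: CDS part ({cs},{ce}) outside span {self.span}")
        starts = [c[0] for c in self.cds_parts]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise FormatError(f"gene {self.id}: CDS parts not in strand order")
        ordered = sorted(self.cds_parts)
        for (a, b), (c, d) in zip(ordered, ordered[1:]):
            if c < b:
                raise FormatError(f"gene {self.id}: overlapping CDS parts")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat annotation interval with a class label such as ``LTR/Gypsy``."""

    chromosome: str
    span: tuple[int, int]
    class_label: str

    def __post_init__(self):
        if not self.class_label:
            raise FormatError("repeat feature with empty class label")
        s, e = self.span
        if not 0 <= s < e:
            raise FormatError(f"invalid repeat span {self.span}")


@dataclass
class GenomeAnnotationBundle:
    """An assembly together with its gene and repeat annotations."""

    assembly: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)

    def validate(self) -> "GenomeAnnotationBundle":
        lengths = {c: len(s) for c, s in self.assembly.items()}
        for g in self.genes:
            if g.chromosome not in lengths:
                raise FormatError(f"gene {g.id} on unknown chromosome {g.chromosome}")
            if g.span[1] > lengths[g.chromosome]:
                raise FormatError(f"gene {g.id} extends past chromosome end")
        for r in self.repeats:
            if r.chromosome not in lengths:
                raise FormatError(f"repeat on unknown chromosome {r.chromosome}")
            if r.span[1] > lengths[r.chromosome]:
                raise FormatError("repeat extends past chromosome end")
        return self

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.assembly.items()}


# ---------------------------------------------------------------------------
# Coordinate conversion (the only place GFF/VCF conventions appear)
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed GFF interval to 0-based half-open."""
    if start < 1 or end < start:
        raise FormatError(f"invalid GFF interval {start}..{end}")
    return start - 1, end


def internal_to_gff(span: tuple[int, int]) -> tuple[int, int]:
    """Inverse of :func:`gff_to_internal`; exact bijection on integers."""
    s, e = span
    return s + 1, e


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}`` with strict validation."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-IUPAC characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file into gene models.

    CDS parts are attached to their gene via the mRNA Parent chain; a CDS
    falling outside its parent gene span is a format error.
    """
    import gffutils

    text = Path(path).read_text()
    if not any(line.strip() and not line.startswith("#")
               for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        text, ":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        span = gff_to_internal(g.start, g.end)
        cds = []
        for c in db.children(g, featuretype="CDS"):
            cspan = gff_to_internal(c.start, c.end)
            if not (span[0] <= cspan[0] and cspan[1] <= span[1]):
                raise FormatError(
                    f"CDS {cspan} outside parent gene {g.id} span {span}")
            cds.append(cspan)
        cds.sort(reverse=g.strand == "-")
        genes.append(GeneModel(id=g.id, chromosome=g.seqid, span=span,
                               strand=g.strand, cds_parts=tuple(cds)))
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = internal_to_gff(g.span)
            fh.write(f"{g.chromosome}\tpanscape\tgene\t{s}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            fh.write(f"{g.chromosome}\tpanscape\tmRNA\t{s}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={g.id}.t1;Parent={g.id}\n")
            for i, part in enumerate(sorted(g.cds_parts)):
                cs, ce = internal_to_gff(part)
                fh.write(f"{g.chromosome}\tpanscape\tCDS\t{cs}\t{ce}\t.\t"
                         f"{g.strand}\t0\tID={g.id}.cds{i};Parent={g.id}.t1\n")


# ---------------------------------------------------------------------------
# Repeat BED
# ---------------------------------------------------------------------------

def read_bed_repeats(path) -> list[RepeatFeature]:
    """Read a 4-column BED (chrom, start, end, class label)."""
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 BED columns")
            chrom, start, end, label = parts[:4]
            try:
                span = (int(start), int(end))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            feats.append(RepeatFeature(chrom, span, label))
    return feats


def write_bed_repeats(repeats: Iterable[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chromosome}\t{r.span[0]}\t{r.span[1]}\t{r.class_label}\n")


# ---------------------------------------------------------------------------
# SV tables (VCF 4.2 symbolic alleles, or the project TSV dialect)
# ---------------------------------------------------------------------------

def _map_sv_type(raw: str) -> str:
    t = _SV_TYPE_ALIASES.get(raw.strip().upper())
    if t is None:
        raise FormatError(f"unknown SV type code {raw!r}")
    return t


def read_sv_table(path, dialect: str = "tsv", accession: str | None = None,
                  min_len: int = 21) -> list["SvRecord"]:
    """Read per-accession SVs from VCF or project TSV.

    Records shorter than ``min_len`` (default 21 bp, i.e. the >20 bp floor)
    are excluded; the number excluded is logged.  INS records occupy a
    zero-length anchor; their length field carries inserted-sequence length.
    """
    from .svscape import SvRecord

    records: list[SvRecord] = []
    n_short = 0
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
        missing = set(SV_TSV_COLUMNS[:6]) - set(df.columns)
        if missing:
            raise FormatError(f"SV TSV missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            svtype = _map_sv_type(row.type)
            length = int(row.length)
            if length < 0:
                raise FormatError(f"negative SV length {length}")
            if length < min_len:
                n_short += 1
                continue
            ins_seq = getattr(row, "inserted_seq", None)
            if isinstance(ins_seq, float) and np.isnan(ins_seq):
                ins_seq = None
            records.append(SvRecord(
                accession=row.accession, chromosome=row.chromosome,
                span=(int(row.start), int(row.end)), type=svtype,
                length=length, inserted_seq=ins_seq or None))
    elif dialect == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        if accession is None:
            if len(vcf.samples) != 1:
                raise FormatError(
                    "VCF must have exactly one sample, or pass accession=")
            accession = vcf.samples[0]
        for v in vcf:
            raw = v.INFO.get("SVTYPE")
            if raw is None:
                alt = v.ALT[0] if v.ALT else ""
                raw = alt.strip("<>")
            svtype = _map_sv_type(raw)
            start = v.POS - 1 if svtype == "INS" else v.start
            end = start if svtype == "INS" else v.end
            svlen = v.INFO.get("SVLEN")
            if svlen is not None:
                length = abs(int(svlen))
            elif svtype == "INS" and v.ALT and not v.ALT[0].startswith("<"):
                length = len(v.ALT[0]) - len(v.REF)
            else:
                length = end - start
            if length < 0:
                raise FormatError(f"negative SV length at {v.CHROM}:{v.POS}")
            if length < min_len:
                n_short += 1
                continue
            ins_seq = None
            if svtype == "INS" and v.ALT and not v.ALT[0].startswith("<"):
                ins_seq = v.ALT[0][len(v.REF):] or None
            records.append(SvRecord(
                accession=accession, chromosome=v.CHROM, span=(start, end),
                type=svtype, length=length, inserted_seq=ins_seq))
    else:
        raise FormatError(f"unknown SV dialect {dialect!r}")
    if n_short:
        logger.info("read_sv_table: excluded %d records shorter than %d bp",
                    n_short, min_len)
    read_sv_table.last_excluded = n_short
    return records


read_sv_table.last_excluded = 0


def write_sv_tsv(records: Iterable["SvRecord"], path) -> None:
    rows = [{"accession": r.accession, "chromosome": r.chromosome,
             "start": r.span[0], "end": r.span[1], "type": r.type,
             "length": r.length, "inserted_seq": r.inserted_seq or ""}
            for r in records]
    pd.DataFrame(rows, columns=list(SV_TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PAV matrix TSV
# ---------------------------------------------------------------------------

def read_pav_matrix(path) -> "PavMatrix":
    """Read a PAV TSV: families as rows, accessions as columns, cells in {0,1}.

    An optional first line ``#species<TAB>sp1<TAB>sp2...`` carries the
    species of each accession column, in column order.
    """
    from .pangenome import PavMatrix

    with open(path) as fh:
        first = fh.readline()
        species_row = None
        if first.startswith("#species"):
            species_row = first.rstrip("\n").split("\t")[1:]
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if header[0] != "family":
            raise FormatError("PAV TSV must start with a 'family' column")
        accessions = header[1:]
        families, rows = [], []
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(accessions) + 1:
                raise FormatError(f"PAV row {ln}: wrong column count")
            families.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"PAV row {ln}: cell value {cell!r} is not 0/1")
                row.append(cell == "1")
            rows.append(row)
    if species_row is not None and len(species_row) != len(accessions):
        raise FormatError("#species line length mismatch")
    species_of = (dict(zip(accessions, species_row)) if species_row
                  else {a: "unknown" for a in accessions})
    return PavMatrix(families=families, accessions=accessions,
                     presence=np.array(rows, dtype=bool),
                     species_of=species_of)


def write_pav_matrix(pav: "PavMatrix", path) -> None:
    with open(path, "w") as fh:
        fh.write("#species\t" + "\t".join(pav.species_of[a]
                                          for a in pav.accessions) + "\n")
        fh.write("family\t" + "\t".join(pav.accessions) + "\n")
        for fam, row in zip(pav.families, pav.presence):
            fh.write(fam + "\t" + "\t".join("1" if x else "0" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, branch lengths to 6 significant digits."""
    for node in tree.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))
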