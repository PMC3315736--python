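"""Readers and writers for the formats the pipeline touches.

Conventions: VCF and GTF are 1-based inclusive on disk and converted to the
internal 0-based half-open representation here, in one place. Missing
values are ``.`` in VCF and ``NA`` in TSV. VCF parsing goes through pysam,
GTF parsing through gffutils (in-memory database), FASTA through Biopython.
"""

from __future__ import annotations

import math
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel
from .calling import call_variants
from .errors import FormatError, StructureError

__all__ = [
    "read_fasta", "write_fasta",
    "read_gene_models", "write_gtf",
    "read_counts_tsv", "write_counts_tsv",
    "read_variants", "write_variants_vcf", "write_variants_tsv",
    "write_truth_vcf",
    "read_pedigree_tsv", "write_pedigree_tsv",
]

NA = "NA"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF

def _gtf_attrs(gene_id: str, transcript_id: str | None = None) -> str:
    s = f'gene_id "{gene_id}";'
    if transcript_id is not None:
        s += f' transcript_id "{transcript_id}";'
    return s


def write_gtf(models: list[GeneModel], path) -> None:
    """Emit gene/transcript/exon/CDS features, 1-based inclusive."""
    lines = []
    for m in models:
        start, end = m.span
        lines.append("\t".join([
            m.chrom, "pooldiver", "gene", str(start + 1), str(end),
            ".", m.strand, ".", _gtf_attrs(m.gene_id)]))
        lines.append("\t".join([
            m.chrom, "pooldiver", "transcript", str(start + 1), str(end),
            ".", m.strand, ".", _gtf_attrs(m.gene_id, m.transcript_id)]))
        for s, e in m.exons:
            lines.append("\t".join([
                m.chrom, "pooldiver", "exon", str(s + 1), str(e),
                ".", m.strand, ".",
                _gtf_attrs(m.gene_id, m.transcript_id)]))
        cds_tx_order = m.cds if m.strand == "+" else list(reversed(m.cds))
        cum = 0
        frames = {}
        for s, e in cds_tx_order:
            frames[(s, e)] = (3 - cum % 3) % 3
            cum += e - s
        for s, e in m.cds:
            lines.append("\t".join([
                m.chrom, "pooldiver", "CDS", str(s + 1), str(e),
                ".", m.strand, str(frames[(s, e)]),
                _gtf_attrs(m.gene_id, m.transcript_id)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path, flank: int = 3000,
                     strict_frame: bool = True) -> list[GeneModel]:
    """Assemble transcript models from a GTF.

    Raises :class:`StructureError` naming the transcript when a CDS falls
    outside the exons or (with ``strict_frame``) when the total CDS length
    is not a multiple of 3.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)
    models = []
    for tx in db.features_of_type("transcript"):
        tid = tx.attributes["transcript_id"][0]
        gid = tx.attributes["gene_id"][0]
        exons = [(f.start - 1, f.end)
                 for f in db.children(tx, featuretype="exon")]
        cds = [(f.start - 1, f.end)
               for f in db.children(tx, featuretype="CDS")]
        if not exons:
            raise StructureError(f"transcript {tid}: no exons")
        model = GeneModel(gene_id=gid, transcript_id=tid,
                          chrom=tx.seqid, strand=tx.strand,
                          exons=exons, cds=cds, flank=flank)
        if strict_frame and cds and not model.coding_usable:
            raise StructureError(
                f"transcript {tid}: CDS length {model.cds_length} "
                f"is not a multiple of 3")
        models.append(model)
    return sorted(models, key=lambda m: (m.chrom, m.span, m.transcript_id))


# ---------------------------------------------------------------------------
# count tables and variant calls

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "pool",
                 "ref_count", "alt_count"]
CALL_COLUMNS = ["chrom", "pos", "ref", "alt",
                "ref_low", "alt_low", "ref_high", "alt_high",
                "depth_low", "depth_high", "af_low", "af_high", "called"]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: count table missing columns {sorted(missing)}")
    return df


def write_variants_tsv(calls: pd.DataFrame, path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def _fmt_float(x: float) -> str:
    return f"{x:.10g}"


_VCF_CALL_HEADER = [
    '##INFO=<ID=AF_LOW,Number=1,Type=Float,Description='
    '"Alt allele frequency in the low pool">',
    '##INFO=<ID=AF_HIGH,Number=1,Type=Float,Description='
    '"Alt allele frequency in the high pool">',
    '##INFO=<ID=DP_LOW,Number=1,Type=Integer,Description='
    '"Post-filter depth in the low pool">',
    '##INFO=<ID=DP_HIGH,Number=1,Type=Integer,Description='
    '"Post-filter depth in the high pool">',
    '##INFO=<ID=ALT_LOW,Number=1,Type=Integer,Description='
    '"Alt-supporting reads in the low pool">',
    '##INFO=<ID=ALT_HIGH,Number=1,Type=Integer,Description='
    '"Alt-supporting reads in the high pool">',
    '##INFO=<ID=CALLED,Number=0,Type=Flag,Description='
    '"Site reaches the alt-read calling threshold">',
]


def _vcf_header(extra_info: list[str], chrom_maxpos: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=pooldiver"]
    for chrom, maxpos in sorted(chrom_maxpos.items()):
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1000}>")
    lines += extra_info
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_variants_vcf(calls: pd.DataFrame, path) -> None:
    """Write a variant-call table as VCF v4.2 with count-bearing INFO."""
    maxpos = (calls.groupby("chrom")["pos"].max().to_dict()
              if len(calls) else {})
    body = []
    for r in calls.itertuples():
        info = []
        if not (isinstance(r.af_low, float) and math.isnan(r.af_low)):
            info.append(f"AF_LOW={_fmt_float(r.af_low)}")
        if not (isinstance(r.af_high, float) and math.isnan(r.af_high)):
            info.append(f"AF_HIGH={_fmt_float(r.af_high)}")
        info += [f"DP_LOW={int(r.depth_low)}",
                 f"DP_HIGH={int(r.depth_high)}",
                 f"ALT_LOW={int(r.alt_low)}",
                 f"ALT_HIGH={int(r.alt_high)}"]
        if bool(r.called):
            info.append("CALLED")
        body.append("\t".join([
            str(r.chrom), str(int(r.pos)), ".", str(r.ref), str(r.alt),
            ".", "PASS", ";".join(info)]))
    text = _vcf_header(_VCF_CALL_HEADER, maxpos)
    text += "\n".join(body) + ("\n" if body else "")
    Path(path).write_text(text)


def read_variants(path) -> pd.DataFrame:
    """Read a variant-call table from VCF (via pysam) or TSV.

    The format is chosen by extension (.vcf vs anything else). Frequencies
    and depths are recomputed from the stored counts, so TSV and VCF
    encodings of the same calls yield identical tables.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for i, rec in enumerate(vf):
                try:
                    dp_low = int(rec.info["DP_LOW"])
                    dp_high = int(rec.info["DP_HIGH"])
                    alt_low = int(rec.info["ALT_LOW"])
                    alt_high = int(rec.info["ALT_HIGH"])
                except KeyError as exc:
                    raise FormatError(
                        f"{path}: record {i + 1} at {rec.chrom}:{rec.pos} "
                        f"missing INFO field {exc}") from exc
                rows.append({
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": rec.alts[0],
                    "ref_low": dp_low - alt_low, "alt_low": alt_low,
                    "ref_high": dp_high - alt_high, "alt_high": alt_high,
                })
        wide = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "ref_low",
                           "alt_low", "ref_high", "alt_high"])
    else:
        df = pd.read_csv(path, sep="\t", na_values=[NA])
        missing = {"chrom", "pos", "ref", "alt", "ref_low", "alt_low",
                   "ref_high", "alt_high"} - set(df.columns)
        if missing:
            raise FormatError(
                f"{path}: call table missing columns {sorted(missing)}")
        wide = df
    if wide.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return call_variants(wide)


def write_truth_vcf(truth: pd.DataFrame, path) -> None:
    """Planted-truth VCF with TRUE_AF_LOW / TRUE_AF_HIGH / TRUE_CLASS."""
    header = [
        '##INFO=<ID=TRUE_AF_LOW,Number=1,Type=Float,Description='
        '"True alt frequency in the low pool">',
        '##INFO=<ID=TRUE_AF_HIGH,Number=1,Type=Float,Description='
        '"True alt frequency in the high pool">',
        '##INFO=<ID=TRUE_CLASS,Number=1,Type=String,Description='
        '"Planted annotation class">',
        '##INFO=<ID=DIFFERENTIAL,Number=0,Type=Flag,Description='
        '"Locus planted with a frequency differential">',
    ]
    maxpos = (truth.groupby("chrom")["pos"].max().to_dict()
              if len(truth) else {})
    body = []
    for r in truth.itertuples():
        info = []
        if hasattr(r, "f_low"):
            info.append(f"TRUE_AF_LOW={_fmt_float(r.f_low)}")
            info.append(f"TRUE_AF_HIGH={_fmt_float(r.f_high)}")
        if hasattr(r, "true_class"):
            info.append(f"TRUE_CLASS={r.true_class}")
        if getattr(r, "differential", False):
            info.append("DIFFERENTIAL")
        body.append("\t".join([
            str(r.chrom), str(int(r.pos)), ".", str(r.ref), str(r.alt),
            ".", "PASS", ";".join(info) or "."]))
    text = _vcf_header(header, maxpos)
    text += "\n".join(body) + ("\n" if body else "")
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# pedigree

PED_COLUMNS = ["id", "sire", "dam", "ebv", "reliability", "n_daughters"]


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_pedigree_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA],
                     dtype={"id": str, "sire": str, "dam": str})
    missing = {"id", "sire", "dam", "ebv"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: pedigree missing columns {sorted(missing)}")
    return df
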