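"""Feature classification and coding-effect annotation of variants.

Each variant is placed relative to a set of transcript models into exactly
one feature class — coding exon, 5'/3' UTR, intron, 5'/3' flank (default
3 kb, matching a capture design that targets 3 kb of flanking sequence on
each side of a gene) or intergenic — with strand-aware UTR/flank sides.
Coding SNPs are additionally translated: the affected codon is located from
the cumulative CDS position, alleles are complemented on the minus strand,
and the effect is synonymous or non-synonymous under the standard nuclear
genetic code.

Positions in the public API are 1-based (VCF/GTF convention); gene-model
intervals are stored 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ArgumentError, DataError, StructureError

__all__ = [
    "GeneModel",
    "CodingEffect",
    "classify_feature",
    "coding_effect",
    "annotate_variants",
    "summarize_categories",
    "table2_view",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = (
    "exonic_coding", "five_prime_utr", "three_prime_utr",
    "intronic", "five_flank", "three_flank", "intergenic",
)

#: precedence when transcripts disagree (lower = wins)
_PRECEDENCE = {
    "exonic_coding": 0,
    "five_prime_utr": 1, "three_prime_utr": 1,
    "intronic": 2,
    "five_flank": 3, "three_flank": 3,
    "intergenic": 4,
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_FLANK = 3000


@dataclass
class GeneModel:
    """One transcript: exon/CDS intervals, 0-based half-open, sorted.

    ``coding_usable`` is False when the total CDS length is not a multiple
    of 3; such transcripts still support feature classification but no
    coding-effect calls.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    flank: int = DEFAULT_FLANK

    def __post_init__(self):
        if self.strand not in "+-":
            raise StructureError(
                f"transcript {self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for s, e in self.exons + self.cds:
            if e <= s:
                raise StructureError(
                    f"transcript {self.transcript_id}: empty interval "
                    f"({s}, {e})")
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise StructureError(
                    f"transcript {self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise StructureError(
                    f"transcript {self.transcript_id}: CDS {c} outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def coding_usable(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0

    def _in(self, pos0: int, intervals) -> bool:
        return any(s <= pos0 < e for s, e in intervals)

    def classify(self, pos0: int) -> str | None:
        """Feature class of a 0-based position for this transcript alone."""
        start, end = self.span
        if start - self.flank <= pos0 < start:
            left = True
        elif end <= pos0 < end + self.flank:
            left = False
        else:
            left = None
        if start <= pos0 < end:
            if self._in(pos0, self.cds):
                return "exonic_coding"
            if self._in(pos0, self.exons):
                cspan = self.cds_span
                if cspan is None:
                    # non-coding transcript: call exonic positions UTR by
                    # transcript half
                    mid = (start + end) // 2
                    before = pos0 < mid
                else:
                    before = pos0 < cspan[0]
                five = before if self.strand == "+" else not before
                return "five_prime_utr" if five else "three_prime_utr"
            return "intronic"
        if left is None:
            return None
        five = left if self.strand == "+" else not left
        return "five_flank" if five else "three_flank"


@dataclass(frozen=True)
class CodingEffect:
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    codon_number: int  # 1-based codon index within the CDS

    @property
    def effect(self) -> str:
        return "synonymous" if self.ref_aa == self.alt_aa else \
            "non_synonymous"

    @property
    def aa_change(self) -> str:
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


def classify_feature(chrom: str, pos: int, models: list[GeneModel]
                     ) -> tuple[str, str | None]:
    """Classify a 1-based position against a set of transcript models.

    Across transcripts the class with the highest precedence wins
    (coding exon > UTR > intron > flank > intergenic); remaining ties go to
    the transcript with the longest CDS, then the lowest transcript id.

    Returns ``(feature_class, transcript_id)``; transcript id is None for
    intergenic positions.
    """
    pos0 = pos - 1
    best: tuple[int, int, str, str, str] | None = None
    for m in models:
        if m.chrom != chrom:
            continue
        cls = m.classify(pos0)
        if cls is None:
            continue
        key = (_PRECEDENCE[cls], -m.cds_length, m.transcript_id)
        if best is None or key < best[:3]:
            best = key + (cls, m.transcript_id)
    if best is None:
        return "intergenic", None
    return best[3], best[4]


def _coding_sequence(model: GeneModel, chrom_seq: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in model.cds)
    if model.strand == "-":
        s = s.translate(_COMPLEMENT)[::-1]
    return s


def coding_effect(chrom: str, pos: int, ref: str, alt: str,
                  model: GeneModel, reference: str) -> CodingEffect:
    """Codon-level effect of a SNP inside a transcript's CDS.

    Parameters
    ----------
    chrom, pos, ref, alt
        The SNP (1-based position, single-base alleles).
    model
        The transcript to annotate against; must be frame-consistent
        (CDS length a multiple of 3).
    reference
        The chromosome sequence.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ArgumentError("coding effects are called for SNPs only")
    if model.chrom != chrom:
        raise ArgumentError(
            f"variant on {chrom} but transcript {model.transcript_id} "
            f"is on {model.chrom}")
    if not model.coding_usable:
        raise StructureError(
            f"transcript {model.transcript_id}: CDS length "
            f"{model.cds_length} is not a multiple of 3; no coding call")
    pos0 = pos - 1
    if reference[pos0].upper() != ref.upper():
        raise DataError(
            f"reference allele mismatch at {chrom}:{pos}: expected "
            f"{reference[pos0]!r}, variant says {ref!r}")
    offset = 0  # position within the genomic-order concatenated CDS
    for a, b in model.cds:
        if a <= pos0 < b:
            offset += pos0 - a
            break
        offset += b - a
    else:
        raise ArgumentError(
            f"{chrom}:{pos} is not inside the CDS of "
            f"{model.transcript_id}")
    cds_seq = _coding_sequence(model, reference)
    if model.strand == "+":
        cpos = offset
        ref_c, alt_c = ref.upper(), alt.upper()
    else:
        cpos = model.cds_length - 1 - offset
        ref_c = ref.upper().translate(_COMPLEMENT)
        alt_c = alt.upper().translate(_COMPLEMENT)
    if cds_seq[cpos] != ref_c:
        raise DataError(
            f"internal frame inconsistency at {chrom}:{pos} in "
            f"{model.transcript_id}")
    ci = cpos // 3
    within = cpos % 3
    ref_codon = cds_seq[3 * ci: 3 * ci + 3]
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodingEffect(ref_codon, alt_codon, ref_aa, alt_aa, ci + 1)


def annotate_variants(variants: pd.DataFrame, models: list[GeneModel],
                      sequences: dict[str, str]) -> pd.DataFrame:
    """Annotate a variant table (columns chrom, pos, ref, alt).

    Adds ``kind`` (snp/indel), ``feature_class``, ``transcript_id`` and,
    for coding SNPs on frame-consistent transcripts, ``effect`` and
    ``aa_change``; indels get a feature class but no effect call.
    """
    by_tid = {m.transcript_id: m for m in models}
    rows = []
    for v in variants.itertuples():
        kind = "snp" if len(v.ref) == 1 and len(v.alt) == 1 else "indel"
        cls, tid = classify_feature(v.chrom, int(v.pos), models)
        effect = aa_change = None
        if cls == "exonic_coding" and kind == "snp":
            model = by_tid[tid]
            if model.coding_usable:
                ce = coding_effect(v.chrom, int(v.pos), v.ref, v.alt,
                                   model, sequences[v.chrom])
                effect, aa_change = ce.effect, ce.aa_change
        rows.append({"chrom": v.chrom, "pos": int(v.pos), "ref": v.ref,
                     "alt": v.alt, "kind": kind, "feature_class": cls,
                     "transcript_id": tid, "effect": effect,
                     "aa_change": aa_change})
    return pd.DataFrame(rows)


def summarize_categories(annotations: pd.DataFrame,
                         calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate variants by feature class, kind and pool sharing.

    A variant is *unique* to a pool iff its alt allele has at least one
    supporting read in that pool and none in the other; otherwise it is
    *shared*. ``nss`` counts the non-synonymous subset of coding SNPs.
    """
    key = ["chrom", "pos", "ref", "alt"]
    merged = annotations.merge(
        calls[key + ["alt_low", "alt_high"]], on=key, how="left",
        validate="one_to_one")
    if merged[["alt_low", "alt_high"]].isna().any().any():
        raise ArgumentError("every annotated variant needs call counts")
    sharing = np.select(
        [(merged.alt_low > 0) & (merged.alt_high == 0),
         (merged.alt_high > 0) & (merged.alt_low == 0)],
        ["unique_low", "unique_high"], default="shared")
    merged["sharing"] = sharing
    rows = []
    for cls in FEATURE_CLASSES:
        for shr in ("shared", "unique_low", "unique_high"):
            sub = merged[(merged.feature_class == cls)
                         & (merged.sharing == shr)]
            rows.append({
                "feature_class": cls, "sharing": shr,
                "snp": int((sub.kind == "snp").sum()),
                "indel": int((sub.kind == "indel").sum()),
                "nss": int((sub.effect == "non_synonymous").sum()),
            })
    return pd.DataFrame(rows)


_TABLE2_GROUPS = {
    "five_prime_utr": "utr", "three_prime_utr": "utr",
    "five_flank": "utr", "three_flank": "utr",
    "exonic_coding": "exonic",
    "intronic": "intronic",
    "intergenic": "intergenic",
}


def table2_view(summary: pd.DataFrame,
                merge_flanks: bool = True) -> pd.DataFrame:
    """Collapse the per-class summary into the published row categories.

    With ``merge_flanks`` (the default) the UTR row pools annotated UTRs
    with the 3 kb flanks, mirroring a capture design whose "UTR" baits
    covered 3 kb of flanking sequence; with ``merge_flanks=False`` flanks
    are kept as their own row.
    """
    df = summary.copy()
    groups = dict(_TABLE2_GROUPS)
    if not merge_flanks:
        groups["five_flank"] = groups["three_flank"] = "flank"
    df["category"] = df["feature_class"].map(groups)
    out = (df.groupby(["category", "sharing"], sort=False)
           [["snp", "indel", "nss"]].sum().reset_index())
    return out


def category_shares(category_counts: dict[str, int]) -> pd.DataFrame:
    """Percent share of each category in the total variant count.

    ``category_counts`` maps category name to variant count (SNPs +
    indels); shares are rounded to whole percent as in published summary
    text.
    """
    total = sum(category_counts.values())
    if total <= 0:
        raise ArgumentError("total variant count must be positive")
    rows = [{"category": k, "count": v,
             "share_pct": round(100.0 * v / total)}
            for k, v in category_counts.items()]
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


__all__.append("category_shares")
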