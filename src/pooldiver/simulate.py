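"""Synthetic inputs for the pooled-resequencing pipeline.

Four generators cover everything the pipeline consumes:

* a paternal half-sib structured pedigree with EBVs from an additive model
  (parent average plus Mendelian-sampling noise) — the raw material for
  divergent-group selection;
* true per-pool allele frequencies with a configurable fraction of loci
  carrying a planted frequency differential;
* pooled read counts: per-pool depths from an overdispersed
  (negative-binomial) model around unequal means — 56x and 32x by default,
  reflecting the unequal capture efficiency seen between real pools — and
  alt counts binomial at the error-folded frequency
  f' = f(1-e) + (1-f)e;
* a toy genome: one multi-exon gene per chromosome on either strand with
  UTRs, CDS (length a multiple of 3), introns and 3 kb flanks, plus
  planted variants of every annotation class whose labels are re-derived
  from the emitted models before the bundle is returned.

All generators are deterministic in their seed; independent streams are
derived per generator so outputs never alias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import annotate as _ann
from .annotate import GeneModel
from .errors import ArgumentError

__all__ = [
    "SimConfig",
    "ToyGenomeBundle",
    "simulate_pedigree",
    "simulate_truth",
    "simulate_pool_counts",
    "simulate_pileup_records",
    "simulate_genotypes",
    "simulate_toy_genome",
]

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the pooled-resequencing simulation.

    Defaults mirror the design being emulated: two pools of 75 diploid
    animals sequenced at unequal mean depths of 56x (low pool) and 32x
    (high pool), with overdispersed depths, a small post-filter
    substitution error, and a planted frequency differential at a subset
    of loci.
    """

    seed: int = 0
    n_per_group: int = 75
    n_loci: int = 2000
    mean_depth_low: float = 56.0
    mean_depth_high: float = 32.0
    depth_dispersion: float = 0.3
    seq_error_rate: float = 0.001
    frac_differential: float = 0.15
    differential_effect: float = 0.35
    maf_low: float = 0.05
    maf_high: float = 0.5

    def __post_init__(self):
        for name in ("seq_error_rate", "frac_differential", "maf_low",
                     "maf_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ArgumentError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth_low <= 0 or self.mean_depth_high <= 0:
            raise ArgumentError("mean depths must be positive")
        if self.depth_dispersion < 0:
            raise ArgumentError("depth_dispersion must be non-negative")
        if not 0 <= self.differential_effect <= 1:
            raise ArgumentError("differential_effect must be in [0, 1]")
        if self.maf_low > self.maf_high:
            raise ArgumentError("maf_low must not exceed maf_high")
        if self.n_per_group < 1 or self.n_loci < 1:
            raise ArgumentError("counts must be positive")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([stream, seed]))


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(n_animals: int, n_sires: int, seed: int = 0,
                      ebv_sd: float = 4.0) -> pd.DataFrame:
    """Half-sib structured pedigree with additive-model EBVs.

    ``n_sires`` founder sires get EBVs ~ N(0, ebv_sd^2); the remaining
    ``n_animals - n_sires`` animals each draw a sire uniformly from the
    founder set (dams unknown and unrelated) and inherit
    ``0.5 * sire EBV`` plus Mendelian-sampling noise with variance
    ``0.75 * ebv_sd^2``. Reliability (percent) and daughter counts are
    attached as metadata.
    """
    if n_sires < 1 or n_animals < n_sires:
        raise ArgumentError("need n_sires >= 1 and n_animals >= n_sires")
    rng = _rng(seed, 11)
    width = max(4, len(str(n_animals)))
    sire_ids = [f"S{j + 1:0{width}d}" for j in range(n_sires)]
    sire_ebv = rng.normal(0.0, ebv_sd, size=n_sires)
    rows = []
    for sid, ebv in zip(sire_ids, sire_ebv):
        rows.append({"id": sid, "sire": np.nan, "dam": np.nan,
                     "ebv": float(ebv)})
    n_off = n_animals - n_sires
    sire_pick = rng.integers(0, n_sires, size=n_off)
    noise = rng.normal(0.0, ebv_sd * np.sqrt(0.75), size=n_off)
    for j in range(n_off):
        rows.append({
            "id": f"A{j + 1:0{width}d}",
            "sire": sire_ids[sire_pick[j]],
            "dam": np.nan,
            "ebv": float(0.5 * sire_ebv[sire_pick[j]] + noise[j]),
        })
    ped = pd.DataFrame(rows)
    ped["reliability"] = rng.integers(40, 100, size=n_animals)
    ped["n_daughters"] = np.round(
        rng.lognormal(5.3, 1.0, size=n_animals)).astype(int)
    return ped


# ---------------------------------------------------------------------------
# pool frequencies and read counts

def simulate_truth(cfg: SimConfig,
                   genome: "ToyGenomeBundle | None" = None) -> pd.DataFrame:
    """True per-pool allele frequencies with planted differentials.

    Returns one row per locus: ``chrom, pos (1-based), ref, alt, f_low,
    f_high, differential`` where ``differential`` flags loci planted with
    ``|f_low - f_high|`` exactly ``cfg.differential_effect``. When a toy
    genome is supplied, loci are placed on its chromosomes with the true
    reference base; otherwise synthetic loci are spread over five
    chromosome names.
    """
    rng = _rng(cfg.seed, 23)
    n = cfg.n_loci
    if genome is None:
        chroms = np.array([f"chr{1 + i % 5}" for i in range(n)])
        pos = np.zeros(n, dtype=np.int64)
        for c in np.unique(chroms):
            m = chroms == c
            need = int(m.sum())
            draw = np.unique(rng.integers(1, 100_000_001, size=2 * need))
            while draw.size < need:  # vanishingly unlikely at these sizes
                draw = np.unique(np.concatenate(
                    [draw, rng.integers(1, 100_000_001, size=2 * need)]))
            pos[m] = np.sort(rng.choice(draw, size=need, replace=False))
        ref = rng.choice(BASES, size=n)
        alt = np.array([rng.choice([b for b in BASES if b != r])
                        for r in ref])
    else:
        names = sorted(genome.sequences)
        chroms_list, pos_list, ref_list = [], [], []
        per = int(np.ceil(n / len(names)))
        for c in names:
            L = len(genome.sequences[c])
            take = min(per, n - len(pos_list))
            if take <= 0:
                break
            p = np.sort(rng.choice(np.arange(1, L + 1), size=take,
                                   replace=False))
            chroms_list += [c] * take
            pos_list += list(p)
            ref_list += [genome.sequences[c][i - 1] for i in p]
        chroms = np.array(chroms_list)
        pos = np.array(pos_list, dtype=np.int64)
        ref = np.array(ref_list)
        alt = np.array([rng.choice([b for b in BASES if b != r])
                        for r in ref])
        n = len(pos)

    base = rng.uniform(cfg.maf_low, cfg.maf_high, size=n)
    f_low = base.copy()
    f_high = base.copy()
    n_diff = int(round(cfg.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    flag = np.zeros(n, dtype=bool)
    flag[diff_idx] = True
    eff = cfg.differential_effect
    for i in diff_idx:
        up_ok = base[i] + eff <= 1.0
        down_ok = base[i] - eff >= 0.0
        if up_ok and down_ok:
            direction = 1.0 if rng.random() < 0.5 else -1.0
        elif up_ok:
            direction = 1.0
        else:
            direction = -1.0
        # which pool carries the shifted frequency is itself random
        if rng.random() < 0.5:
            f_high[i] = base[i] + direction * eff
        else:
            f_low[i] = base[i] + direction * eff
    return pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
        "f_low": f_low, "f_high": f_high, "differential": flag,
    })


def _draw_depths(rng, mean: float, dispersion: float, n: int) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def simulate_pool_counts(truth: pd.DataFrame, cfg: SimConfig
                         ) -> pd.DataFrame:
    """Binomial read sampling of both pools at every locus.

    Depths are drawn per locus and pool from the configured overdispersed
    model; alt counts are binomial(depth, f') with the sequencing error
    folded into f'. Counts are post-filter (quality filtering is presumed
    upstream). Returns the long count table ``chrom, pos, ref, alt, pool,
    ref_count, alt_count``.
    """
    if truth.empty:
        raise ArgumentError("truth table is empty")
    rng = _rng(cfg.seed, 37)
    n = len(truth)
    e = cfg.seq_error_rate
    frames = []
    for pool, mean, fcol in (("low", cfg.mean_depth_low, "f_low"),
                             ("high", cfg.mean_depth_high, "f_high")):
        depth = _draw_depths(rng, mean, cfg.depth_dispersion, n)
        f = truth[fcol].to_numpy()
        f_eff = f * (1.0 - e) + (1.0 - f) * e
        alt = rng.binomial(depth, f_eff)
        frames.append(pd.DataFrame({
            "chrom": truth["chrom"], "pos": truth["pos"],
            "ref": truth["ref"], "alt": truth["alt"], "pool": pool,
            "ref_count": depth - alt, "alt_count": alt,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_pileup_records(truth: pd.DataFrame, cfg: SimConfig,
                            raw_depth_factor: float = 2.0) -> pd.DataFrame:
    """Raw per-read records with mapping/base qualities, for the filter.

    Each locus gets ``raw_depth_factor`` times the configured mean depth
    in raw reads per pool; qualities are drawn uniformly (MQ 30..60,
    BQ 10..40) so a realistic fraction fails the stringent cutoffs.
    """
    if truth.empty:
        raise ArgumentError("truth table is empty")
    rng = _rng(cfg.seed, 41)
    e = cfg.seq_error_rate
    rows = []
    for pool, mean, fcol in (("low", cfg.mean_depth_low, "f_low"),
                             ("high", cfg.mean_depth_high, "f_high")):
        for t in truth.itertuples():
            f = getattr(t, fcol)
            f_eff = f * (1.0 - e) + (1.0 - f) * e
            depth = max(1, int(rng.poisson(mean * raw_depth_factor)))
            is_alt = rng.random(depth) < f_eff
            mq = rng.integers(30, 61, size=depth)
            bq = rng.integers(10, 41, size=depth)
            for k in range(depth):
                rows.append({
                    "chrom": t.chrom, "pos": t.pos, "ref": t.ref,
                    "alt": t.alt, "pool": pool,
                    "allele": "alt" if is_alt[k] else "ref",
                    "mq": int(mq[k]), "bq": int(bq[k]),
                })
    return pd.DataFrame(rows)


def simulate_genotypes(truth: pd.DataFrame, cfg: SimConfig
                       ) -> dict[str, pd.DataFrame]:
    """Individual diploid genotypes consistent with the pool frequencies.

    For each pool, every animal's genotype at a locus is binomial(2, f) in
    alt copies. Returns ``{"low": frame, "high": frame}`` with SNP ids
    ``chrom:pos`` as rows and animal ids as columns.
    """
    rng = _rng(cfg.seed, 53)
    snp_ids = [f"{c}:{p}" for c, p in zip(truth["chrom"], truth["pos"])]
    out = {}
    for pool, fcol in (("low", "f_low"), ("high", "f_high")):
        f = truth[fcol].to_numpy()
        g = rng.binomial(2, f[:, None],
                         size=(len(truth), cfg.n_per_group))
        cols = [f"{pool}_{j + 1:03d}" for j in range(cfg.n_per_group)]
        out[pool] = pd.DataFrame(g, index=pd.Index(snp_ids, name="snp_id"),
                                 columns=cols)
    return out


# ---------------------------------------------------------------------------
# toy genome

@dataclass
class ToyGenomeBundle:
    """Reference sequences, transcript models and planted truth variants."""

    sequences: dict[str, str]
    models: list[GeneModel]
    variants: pd.DataFrame = field(repr=False)


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.choice(BASES, size=length)


def _plant_snp(rng, seq, pos0):
    ref = seq[pos0]
    alt = rng.choice([b for b in BASES if b != ref])
    return str(ref), str(alt)


def _pick_in(rng, intervals) -> int:
    lens = np.array([e - s for s, e in intervals])
    which = rng.choice(len(intervals), p=lens / lens.sum())
    s, e = intervals[which]
    return int(rng.integers(s, e))


def simulate_toy_genome(n_genes: int, seed: int = 0,
                        flank: int = _ann.DEFAULT_FLANK
                        ) -> ToyGenomeBundle:
    """Toy genome with one multi-exon gene per chromosome.

    Genes land on either strand with 2-4 exons, UTRs, frame-consistent CDS
    and ``flank``-sized flanking regions inside a larger intergenic
    margin. Planted variants cover every feature class, including at least
    one synonymous and one non-synonymous coding SNP and indels; every
    label (and amino-acid change) is re-derived through the annotation
    module before the bundle is returned, so label soundness is enforced
    by construction.
    """
    if n_genes < 1:
        raise ArgumentError("n_genes must be >= 1")
    rng = _rng(seed, 67)
    margin = 600
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    var_rows: list[dict] = []

    for g in range(n_genes):
        chrom = f"chr{g + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        utr5_len = int(rng.integers(100, 300))
        utr3_len = int(rng.integers(100, 300))
        cds_lens = rng.integers(90, 240, size=n_exons)
        rem = int(cds_lens.sum()) % 3
        cds_lens[-1] += (3 - rem) % 3
        intron_lens = rng.integers(200, 800, size=n_exons - 1)

        # exon block lists in transcript order
        exon_blocks = []
        for k in range(n_exons):
            blocks = []
            if k == 0:
                blocks.append(("utr5", utr5_len))
            blocks.append(("cds", int(cds_lens[k])))
            if k == n_exons - 1:
                blocks.append(("utr3", utr3_len))
            exon_blocks.append(blocks)
        introns_t = list(map(int, intron_lens))
        if strand == "-":
            exon_blocks = [list(reversed(b)) for b in reversed(exon_blocks)]
            introns_t = list(reversed(introns_t))

        gene_start = margin + flank
        pos = gene_start
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        regions: dict[str, list[tuple[int, int]]] = {
            "utr5": [], "utr3": [], "cds": [], "intron": []}
        for k, blocks in enumerate(exon_blocks):
            e_start = pos
            for btype, blen in blocks:
                iv = (pos, pos + blen)
                regions[btype].append(iv)
                if btype == "cds":
                    cds.append(iv)
                pos += blen
            exons.append((e_start, pos))
            if k < n_exons - 1:
                regions["intron"].append((pos, pos + introns_t[k]))
                pos += introns_t[k]
        gene_end = pos
        chrom_len = gene_end + flank + margin

        seq = _random_seq(rng, chrom_len)
        # overwrite CDS with stop-free codons (coding orientation)
        n_codons = int(cds_lens.sum()) // 3
        coding = "".join(rng.choice(_CODONS, size=n_codons))
        genomic_cds = coding if strand == "+" else \
            coding.translate(_ann._COMPLEMENT)[::-1]
        cds_positions = np.concatenate(
            [np.arange(s, e) for s, e in cds])
        seq[cds_positions] = list(genomic_cds)

        model = GeneModel(gene_id=f"gene{g + 1}",
                          transcript_id=f"tx{g + 1}",
                          chrom=chrom, strand=strand,
                          exons=exons, cds=cds, flank=flank)
        models.append(model)

        # genomic position of each coding-orientation CDS base
        if strand == "+":
            coding_to_genomic = cds_positions
        else:
            coding_to_genomic = cds_positions[::-1]

        left_flank = [(margin, gene_start)]
        right_flank = [(gene_end, gene_end + flank)]
        five_flank = left_flank if strand == "+" else right_flank
        three_flank = right_flank if strand == "+" else left_flank
        intergenic = [(0, margin),
                      (gene_end + flank, chrom_len)]

        planted: list[dict] = []

        def plant_noncoding(cls, intervals, kind="snp"):
            pos0 = _pick_in(rng, intervals)
            ref = str(seq[pos0])
            if kind == "snp":
                alt = str(rng.choice([b for b in BASES if b != ref]))
            else:
                ins = "".join(rng.choice(BASES,
                                         size=int(rng.integers(1, 4))))
                alt = ref + ins
            planted.append({"chrom": chrom, "pos": pos0 + 1, "ref": ref,
                            "alt": alt, "kind": kind, "true_class": cls,
                            "effect": None, "aa_change": None,
                            "transcript_id":
                                None if cls == "intergenic"
                                else model.transcript_id})

        plant_noncoding("five_prime_utr", regions["utr5"])
        plant_noncoding("three_prime_utr", regions["utr3"])
        plant_noncoding("intronic", regions["intron"])
        plant_noncoding("five_flank", five_flank)
        plant_noncoding("three_flank", three_flank)
        plant_noncoding("intergenic", intergenic)
        plant_noncoding("intronic", regions["intron"], kind="indel")
        plant_noncoding("exonic_coding", regions["cds"], kind="indel")

        def plant_coding(want: str):
            # search random codon positions for a substitution with the
            # wanted effect
            for _ in range(200):
                cpos = int(rng.integers(0, len(coding)))
                ci, within = divmod(cpos, 3)
                codon = coding[3 * ci: 3 * ci + 3]
                alts = [b for b in "ACGT" if b != codon[within]]
                rng.shuffle(alts)
                for b in alts:
                    alt_codon = codon[:within] + b + codon[within + 1:]
                    ref_aa = _ann.Seq(codon).translate()
                    alt_aa = _ann.Seq(alt_codon).translate()
                    effect = ("synonymous" if str(ref_aa) == str(alt_aa)
                              else "non_synonymous")
                    if effect != want:
                        continue
                    gpos = int(coding_to_genomic[cpos])
                    ref_g = str(seq[gpos])
                    alt_g = b if strand == "+" else \
                        b.translate(_ann._COMPLEMENT)
                    planted.append({
                        "chrom": chrom, "pos": gpos + 1, "ref": ref_g,
                        "alt": alt_g, "kind": "snp",
                        "true_class": "exonic_coding", "effect": effect,
                        "aa_change": f"{ref_aa}{ci + 1}{alt_aa}",
                        "transcript_id": model.transcript_id})
                    return
            raise RuntimeError(
                f"no {want} substitution found in gene {g + 1}")

        plant_coding("synonymous")
        plant_coding("non_synonymous")

        chrom_seq = "".join(seq)
        sequences[chrom] = chrom_seq

        # re-derive every label through the annotation module before
        # emission; a mismatch is a construction bug, not a data condition
        for v in planted:
            cls, tid = _ann.classify_feature(chrom, v["pos"], [model])
            assert cls == v["true_class"], (v, cls)
            if v["kind"] == "snp" and cls == "exonic_coding":
                ce = _ann.coding_effect(chrom, v["pos"], v["ref"],
                                        v["alt"], model, chrom_seq)
                assert ce.effect == v["effect"], (v, ce)
                assert ce.aa_change == v["aa_change"], (v, ce)
        var_rows.extend(planted)

    variants = (pd.DataFrame(var_rows)
                .sort_values(["chrom", "pos"], kind="mergesort")
                .reset_index(drop=True))
    return ToyGenomeBundle(sequences=sequences, models=models,
                           variants=variants)
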