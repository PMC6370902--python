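"""Synthetic truth catalogs, depth-dependent call sets and HLA call tables.

This module replaces everything upstream of the evaluation — sequencing,
alignment, duplicate marking and the variant callers — with a statistical
emulation of their *outputs*:

* a diploid truth catalog of SNVs and indels with a configurable
  alternate-allele-frequency spectrum, Hardy-Weinberg genotypes and a
  microarray-like subset carrying call-rate/HWE/MAF/multi-allelism QC
  metadata;
* per-depth call sets in which the read count at each site is
  Poisson(depth), genotypes are re-called from binomially sampled allele
  counts through a maximum-likelihood genotyper, and each emitted record
  carries DP plus the seven hard-filter annotations drawn from
  clean/artifact mixture distributions;
* per-tool HLA genotype calls with configurable per-gene miscall rates.

Depth is simulated per site rather than per read position: the evaluation
consumes genotype calls, not alignments, and per-site Poisson sampling
reproduces the depth-missingness relation at desk scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import hla as hla_mod
from .config import SimulationConfig
from .records import (
    ANNOTATION_KEYS,
    GT_AA,
    GT_RA,
    GT_RR,
    INDEL,
    SNV,
    CallRecord,
)

__all__ = [
    "ArrayMeta",
    "TruthVariant",
    "SimulatedCallSet",
    "generate_truth",
    "simulate_callset",
    "generate_hla_calls",
    "hla_calls_to_frame",
    "write_truth",
    "read_truth",
]

_BASES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_GT_CODES = {GT_RR: 0, GT_RA: 1, GT_AA: 2}
_CODE_GT = (GT_RR, GT_RA, GT_AA)

_SNV_ITEMS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR", "HaplotypeScore")
_INDEL_ITEMS = ("QD", "FS", "ReadPosRankSum", "SOR")


@dataclass
class ArrayMeta:
    """Array-side QC metadata of an on-array truth site."""

    call_rate: float
    hwe_p: float
    maf: float
    multi_allelic: bool


@dataclass
class TruthVariant:
    """One truth site with its diploid genotype and population AAF.

    ``truth_gt == "RR"`` occurs only for on-array evaluation sites (the
    subject carries no alternate allele there but the site is still
    scored); off-array sites describe the subject's own variants and are
    always carriers.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    truth_gt: str
    aaf: float
    on_array: bool
    array_meta: ArrayMeta | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        expected = SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL
        if self.vtype != expected:
            raise ValueError(f"vtype {self.vtype!r} inconsistent with alleles")
        if self.truth_gt == GT_RR and not self.on_array:
            raise ValueError("homozygous-reference truth allowed only on-array")
        if not 0.0 <= self.aaf <= 1.0:
            raise ValueError("aaf must be in [0, 1]")


@dataclass
class SimulatedCallSet:
    """One simulated dataset: records plus per-stage base accounting."""

    target_depth: float
    replicate_id: int
    records: list[CallRecord]
    read_accounting: dict[str, float]
    seed: int


# ---------------------------------------------------------------------------
# truth catalog
# ---------------------------------------------------------------------------


def generate_truth(config: SimulationConfig) -> list[TruthVariant]:
    """Draw the truth catalog defined by ``config`` (deterministic in
    ``base_seed``).

    Genotypes follow Hardy-Weinberg proportions of each site's AAF;
    off-array sites are conditioned on carrying at least one alternate
    allele.  Array MAF is drawn from a Beta centred on the AAF with modest
    concentration, emulating the frequency difference between the array QC
    cohort and the AAF reference population (this keeps the rare-AAF
    stratum populated after MAF-based QC).
    """
    n = config.n_variants
    length = config.genome_length
    if n > length:
        raise ValueError(
            f"cannot place {n} variants on {length} effective bases"
        )
    rng = np.random.default_rng(config.base_seed)

    seen = np.unique(rng.integers(1, length + 1, size=n + max(16, n // 8)))
    while seen.size < n:
        seen = np.union1d(seen, rng.integers(1, length + 1, size=n))
    keep = rng.choice(seen.size, size=n, replace=False)
    pos = np.sort(seen[keep])

    is_indel = rng.random(n) < config.indel_fraction
    ref_idx = rng.integers(0, 4, size=n)
    ts_draw = rng.random(n)
    tv_pick = rng.integers(0, 2, size=n)
    del_draw = rng.random(n) < 0.5
    ind_len = rng.integers(1, 4, size=n)
    ind_seq_idx = rng.integers(0, 4, size=(n, 3))

    aaf = np.clip(config.aaf_spec.draw(rng, n), 1e-6, 1.0 - 1e-6)
    on_array = (rng.random(n) < config.array_fraction) & ~is_indel

    u = rng.random(n)
    p = aaf
    p_rr = (1.0 - p) ** 2
    p_ra = 2.0 * p * (1.0 - p)
    gt = np.where(u < p_rr, 0, np.where(u < p_rr + p_ra, 1, 2))
    v = rng.random(n)
    carrier_het = p_ra / (p_ra + p**2)
    redraw = (gt == 0) & ~on_array
    gt = np.where(redraw, np.where(v < carrier_het, 1, 2), gt)

    call_rate = np.clip(1.0 - rng.exponential(0.004, n), 0.9, 1.0)
    hwe_fail = rng.random(n) < 0.01
    hwe_p = np.where(
        hwe_fail, 10.0 ** (-rng.uniform(6.0, 12.0, n)), rng.random(n)
    )
    conc = 30.0
    q = rng.beta(np.maximum(aaf * conc, 1e-3), np.maximum((1.0 - aaf) * conc, 1e-3))
    maf = np.minimum(q, 1.0 - q)
    multi = rng.random(n) < 0.005

    out: list[TruthVariant] = []
    for i in range(n):
        rbase = _BASES[ref_idx[i]]
        if is_indel[i]:
            seq = "".join(_BASES[j] for j in ind_seq_idx[i, : ind_len[i]])
            if del_draw[i]:
                ref, alt = rbase + seq, rbase
            else:
                ref, alt = rbase, rbase + seq
            vtype = INDEL
        else:
            if ts_draw[i] < config.ts_fraction:
                alt = _TRANSITION[rbase]
            else:
                choices = [
                    b for b in _BASES if b != rbase and b != _TRANSITION[rbase]
                ]
                alt = choices[tv_pick[i]]
            ref, vtype = rbase, SNV
        meta = (
            ArrayMeta(
                call_rate=float(call_rate[i]),
                hwe_p=float(hwe_p[i]),
                maf=float(maf[i]),
                multi_allelic=bool(multi[i]),
            )
            if on_array[i]
            else None
        )
        out.append(
            TruthVariant(
                chrom=config.chrom,
                pos=int(pos[i]),
                ref=ref,
                alt=alt,
                vtype=vtype,
                truth_gt=_CODE_GT[gt[i]],
                aaf=float(aaf[i]),
                on_array=bool(on_array[i]),
                array_meta=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# call-set simulation
# ---------------------------------------------------------------------------


def _ml_genotype(k: np.ndarray, n: np.ndarray, e: float) -> np.ndarray:
    """Maximum-likelihood diploid genotype from alt-read count k of n reads.

    Likelihoods are binomial with alt-allele probabilities e (hom-ref),
    0.5 (het) and 1-e (hom-alt); ties resolve toward the reference.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack(
            [
                binom.logpmf(k, n, e),
                binom.logpmf(k, n, 0.5),
                binom.logpmf(k, n, 1.0 - e),
            ]
        )
    return np.argmax(ll, axis=0)


def simulate_callset(
    truth: Sequence[TruthVariant],
    depth: float,
    seed: int,
    config: SimulationConfig,
    replicate_id: int = 0,
) -> SimulatedCallSet:
    """Emulate one caller run over the truth catalog at a target depth.

    Byte-identical for identical ``(truth, depth, seed, config)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    em = config.error_model
    rng = np.random.default_rng(seed)
    n = len(truth)

    g = np.fromiter((_GT_CODES[t.truth_gt] for t in truth), dtype=np.int64, count=n)
    reads = rng.poisson(depth, n)
    call_floor = max(1, em.min_reads) if em.read_sampling else em.min_reads
    covered = reads >= call_floor

    if em.read_sampling:
        e = min(max(em.per_read_error, 1e-12), 0.49)
        p_alt = np.where(g == 0, e, np.where(g == 1, 0.5, 1.0 - e))
        k = rng.binomial(reads, p_alt)
        call = _ml_genotype(k, reads, e)
    else:
        call = g.copy()

    flip = rng.random(n)
    u_het = rng.random(n)
    u_hom = rng.random(n)
    u_ref = rng.random(n)
    mask = (g == 1) & (u_het < em.het_error_rate)
    call = np.where(mask, np.where(flip < 0.5, 0, 2), call)
    mask = (g == 2) & (u_hom < em.hom_error_rate)
    call = np.where(mask, np.where(flip < 0.5, 0, 1), call)
    mask = (g == 0) & (u_ref < em.ref_error_rate)
    call = np.where(mask, 1, call)

    u_alt = rng.random(n)
    alt_pick = rng.integers(0, 2, size=n)
    u_rep = rng.random(n)
    rep_base = rng.integers(0, 4, size=n)
    p_rep = em.indel_repr_error_max * np.exp(-depth / em.indel_repr_error_scale)

    emitted = np.nonzero(covered & (call != 0))[0]

    # ---- false-positive records at non-truth positions -----------------
    n_fp_raw = rng.poisson(em.fp_site_rate * n)
    fp_reads_raw = rng.poisson(depth, n_fp_raw)
    fp_reads = fp_reads_raw[fp_reads_raw >= max(1, em.min_reads)]
    n_fp = fp_reads.size
    truth_pos = {t.pos for t in truth}
    fp_pos: list[int] = []
    taken = set(truth_pos)
    while len(fp_pos) < n_fp:
        cand = rng.integers(1, config.genome_length + 1, size=2 * (n_fp - len(fp_pos)) + 8)
        for c in cand:
            c = int(c)
            if c not in taken:
                taken.add(c)
                fp_pos.append(c)
                if len(fp_pos) == n_fp:
                    break
    fp_is_indel = rng.random(n_fp) < config.indel_fraction
    fp_ref_idx = rng.integers(0, 4, size=n_fp)
    fp_alt_pick = rng.integers(0, 3, size=n_fp)
    fp_del = rng.random(n_fp) < 0.5
    fp_len = rng.integers(1, 4, size=n_fp)
    fp_seq_idx = rng.integers(0, 4, size=(n_fp, 3))

    # ---- assemble site table (truth-emitted + FP), sorted by position --
    sites: list[tuple[int, str, str, str, str, int]] = []
    for i in emitted:
        t = truth[i]
        ref, alt = t.ref, t.alt
        if t.vtype == SNV:
            if u_alt[i] < em.alt_error_rate:
                others = [b for b in _BASES if b != ref and b != alt]
                alt = others[alt_pick[i] % len(others)]
        else:
            if u_rep[i] < p_rep:
                extra = _BASES[rep_base[i]]
                if len(ref) > len(alt):  # deletion: jitter the deleted run
                    ref = ref + extra
                else:  # insertion: jitter the inserted run
                    alt = alt + extra
        sites.append(
            (t.pos, ref, alt, t.vtype, _CODE_GT[call[i]], int(reads[i]))
        )
    for j in range(n_fp):
        rbase = _BASES[fp_ref_idx[j]]
        if fp_is_indel[j]:
            seq = "".join(_BASES[b] for b in fp_seq_idx[j, : fp_len[j]])
            if fp_del[j]:
                ref, alt = rbase + seq, rbase
            else:
                ref, alt = rbase, rbase + seq
            vtype = INDEL
        else:
            alt = [b for b in _BASES if b != rbase][fp_alt_pick[j]]
            ref, vtype = rbase, SNV
        sites.append((fp_pos[j], ref, alt, vtype, GT_RA, int(fp_reads[j])))
    sites.sort(key=lambda s: s[0])

    records = _annotate_records(sites, depth, em, rng, config.chrom)

    # ---- per-stage base accounting (URD is the target depth) -----------
    acct = config.accounting
    dup_loss = acct.dup_loss_max * depth / (depth + acct.dup_half_sat)
    urd = depth
    mrd = urd / (1.0 - dup_loss)
    rrdat = mrd / acct.map_retention
    rrd = rrdat / acct.trim_retention
    length = float(config.genome_length)
    accounting = {
        "rrd_bases": rrd * length,
        "rrdat_bases": rrdat * length,
        "mrd_bases": mrd * length,
        "urd_bases": urd * length,
    }
    return SimulatedCallSet(
        target_depth=depth,
        replicate_id=replicate_id,
        records=records,
        read_accounting=accounting,
        seed=seed,
    )


def _annotate_records(
    sites: list[tuple[int, str, str, str, str, int]],
    depth: float,
    em,
    rng: np.random.Generator,
    chrom: str,
) -> list[CallRecord]:
    """Draw the seven site annotations for each emitted record.

    Clean values are confined to the hard-filter passing ranges of the
    record's variant type; with a small depth-dependent probability one
    item is replaced by an artifact value past its threshold.
    """
    m = len(sites)
    if m == 0:
        return []
    vt_indel = np.fromiter((s[3] == INDEL for s in sites), dtype=bool, count=m)

    qd = np.clip(rng.normal(20.0, 5.0, m), 2.0, None)
    fs = np.minimum(rng.exponential(5.0, m), np.where(vt_indel, 200.0, 60.0))
    mq = np.clip(rng.normal(60.0, 3.0, m), 40.0, None)
    mqrs = np.clip(rng.normal(0.0, 2.0, m), -12.5, None)
    rprs = np.clip(rng.normal(0.0, 2.0, m), np.where(vt_indel, -20.0, -8.0), None)
    sor = np.minimum(rng.gamma(2.0, 0.5, m), np.where(vt_indel, 10.0, 3.0))
    hs = np.minimum(rng.exponential(2.0, m), 13.0)

    p_low = em.low_cov_artifact_rate * np.exp(-depth / em.low_cov_artifact_scale)
    if depth > em.haplotype_artifact_onset and em.haplotype_artifact_max > 0:
        p_hs = (
            em.haplotype_artifact_max
            * np.log(depth / em.haplotype_artifact_onset)
            / np.log(410.0 / em.haplotype_artifact_onset)
        )
    else:
        p_hs = 0.0
    u_art = rng.random(m)
    item_pick = rng.integers(0, 7, size=m)
    art_exp = rng.exponential(1.0, m)
    art_uni = rng.random(m)

    records: list[CallRecord] = []
    for i, (pos, ref, alt, vtype, gt, dp) in enumerate(sites):
        indel = vtype == INDEL
        ann: dict[str, float] = {
            "QD": qd[i],
            "FS": fs[i],
            "MQ": mq[i],
            "MQRankSum": mqrs[i],
            "ReadPosRankSum": rprs[i],
            "SOR": sor[i],
        }
        if not indel:
            ann["HaplotypeScore"] = hs[i]
        p_total = p_low + (0.0 if indel else p_hs)
        if u_art[i] < p_total:
            if not indel and u_art[i] < p_hs:
                item = "HaplotypeScore"
            else:
                items = _INDEL_ITEMS if indel else _SNV_ITEMS
                item = items[item_pick[i] % len(items)]
            ann[item] = _artifact_value(item, indel, art_exp[i], art_uni[i])
        ann = {k: round(float(v), 4) for k, v in ann.items()}
        records.append(
            CallRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                gt=gt,
                dp=dp,
                ann=ann,
                vtype=vtype,
            )
        )
    return records


def _artifact_value(item: str, indel: bool, ex: float, un: float) -> float:
    """A value strictly past the hard-filter threshold of ``item``."""
    if item == "QD":
        return 0.1 + 1.8 * un
    if item == "FS":
        return (200.0 if indel else 60.0) + 1e-3 + 30.0 * ex
    if item == "MQ":
        return 10.0 + 29.0 * un
    if item == "MQRankSum":
        return -12.5 - 1e-3 - 3.0 * ex
    if item == "ReadPosRankSum":
        return (-20.0 if indel else -8.0) - 1e-3 - 3.0 * ex
    if item == "SOR":
        return (10.0 if indel else 3.0) + 1e-3 + 2.0 * ex
    if item == "HaplotypeScore":
        return 13.0 + 1e-3 + 5.0 * ex
    raise ValueError(f"unknown filter item {item!r}")


# ---------------------------------------------------------------------------
# HLA call simulation
# ---------------------------------------------------------------------------


def generate_hla_calls(
    truth_hla: Iterable[hla_mod.HLAGenotype] | Mapping[str, hla_mod.HLAGenotype],
    tools: Sequence[str],
    depth: float,
    seed: int,
    config: SimulationConfig,
) -> dict[tuple[str, str], hla_mod.HLAGenotype]:
    """Per-tool 4-digit HLA calls with depth-scaled per-gene miscalls.

    Unavailable (tool, gene) combinations are emitted as NA genotypes.
    Each allele of a typed genotype is independently miscalled to a decoy
    allele of the same gene with the configured probability.
    """
    if isinstance(truth_hla, Mapping):
        genotypes = list(truth_hla.values())
    else:
        genotypes = list(truth_hla)
    for gt in genotypes:
        if gt.gene not in hla_mod.GENES:
            raise ValueError(f"unknown HLA gene {gt.gene!r}")
        if gt.is_na:
            raise ValueError(f"truth genotype for {gt.gene} is NA")
    rng = np.random.default_rng(seed)
    calls: dict[tuple[str, str], hla_mod.HLAGenotype] = {}
    for tool in tools:
        for gt in genotypes:
            gene = gt.gene
            if (tool, gene) in hla_mod.UNAVAILABLE:
                calls[(tool, gene)] = hla_mod.HLAGenotype(gene=gene, alleles=None)
                continue
            miscall_p = config.hla_error.rate(tool, gene, depth)
            truth_names = {
                hla_mod.parse_allele(a, gene).name
                for a in gt.alleles  # type: ignore[union-attr]
            }
            # a miscall is an allele outside the truth genotype
            pool = [a for a in hla_mod.DECOY_ALLELES[gene] if a not in truth_names]
            if not pool:
                pool = ["99:99"]
            called = []
            for allele in gt.alleles:  # type: ignore[union-attr]
                if rng.random() < miscall_p:
                    called.append(pool[int(rng.integers(0, len(pool)))])
                else:
                    called.append(allele)
            calls[(tool, gene)] = hla_mod.HLAGenotype(
                gene=gene, alleles=(called[0], called[1])
            )
    return calls


def hla_calls_to_frame(
    calls: Mapping[tuple[str, str], hla_mod.HLAGenotype]
) -> pd.DataFrame:
    """TSV-ready table: (tool, gene, allele1, allele2) with NA for masked pairs."""
    rows = []
    for (tool, gene), gt in calls.items():
        if gt.is_na:
            rows.append({"tool": tool, "gene": gene, "allele1": "NA", "allele2": "NA"})
        else:
            rows.append(
                {
                    "tool": tool,
                    "gene": gene,
                    "allele1": gt.alleles[0],
                    "allele2": gt.alleles[1],
                }
            )
    return pd.DataFrame(rows, columns=["tool", "gene", "allele1", "allele2"])


# ---------------------------------------------------------------------------
# truth-panel TSV round-trip
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vtype",
    "truth_gt",
    "aaf",
    "on_array",
    "call_rate",
    "hwe_p",
    "maf",
    "multi_allelic",
]


def truth_to_frame(truth: Sequence[TruthVariant]) -> pd.DataFrame:
    rows = []
    for t in truth:
        meta = t.array_meta
        rows.append(
            {
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref,
                "alt": t.alt,
                "vtype": t.vtype,
                "truth_gt": t.truth_gt,
                "aaf": t.aaf,
                "on_array": t.on_array,
                "call_rate": meta.call_rate if meta else np.nan,
                "hwe_p": meta.hwe_p if meta else np.nan,
                "maf": meta.maf if meta else np.nan,
                "multi_allelic": meta.multi_allelic if meta else False,
            }
        )
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def write_truth(truth: Sequence[TruthVariant], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthVariant]:
    frame = pd.read_csv(path, sep="\t")
    out: list[TruthVariant] = []
    for row in frame.itertuples(index=False):
        on_array = bool(row.on_array)
        meta = (
            ArrayMeta(
                call_rate=float(row.call_rate),
                hwe_p=float(row.hwe_p),
                maf=float(row.maf),
                multi_allelic=bool(row.multi_allelic),
            )
            if on_array and not pd.isna(row.call_rate)
            else None
        )
        out.append(
            TruthVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                vtype=str(row.vtype),
                truth_gt=str(row.truth_gt),
                aaf=float(row.aaf),
                on_array=on_array,
                array_meta=meta,
            )
        )
    return out
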