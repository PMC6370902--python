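"""Genotype concordance against a truth panel and against a full-depth
call set.

The central object is the 3x3 genotype contingency matrix between truth
and query over the evaluation panel, with an extra alternate-discordant
class for sites where the query calls a different alternate allele.  Panel
sites absent from the query call set are scored as homozygous reference —
a caller that emits no record at a site is asserting the reference
genotype there.

Four summary indices are derived from the matrix:

* CR   — diagonal mass over all panel sites;
* FPR  — truth-reference sites called non-reference, plus all
  alternate-discordant sites, over all panel sites;
* FNR  — truth-non-reference sites called reference (including missing),
  over all panel sites;
* NTPR — concordant non-reference calls over all panel sites at which the
  query made a non-reference call (including alternate-discordant ones).

CR, FPR and FNR are panel-wide; NTPR is confined to sites the query
actually called.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import GT_AA, GT_MISSING, GT_RA, GT_RR, INDEL, SNV, CallRecord
from .simulate import TruthVariant

__all__ = [
    "GT_ORDER",
    "AAF_BIN_LABELS",
    "ConcordanceMatrix",
    "ConcordanceMetrics",
    "qc_filter_truth",
    "classify_site",
    "build_matrix",
    "compute_metrics",
    "het_concordance",
    "assign_aaf_bin",
    "stratify_by_aaf",
    "ts_tv_ratio",
    "ts_tv_counts",
    "allreads_concordance",
    "count_variants",
]

logger = logging.getLogger(__name__)

GT_ORDER = (GT_RR, GT_RA, GT_AA)
ALT_DISCORDANT = "alt_discordant"

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: five AAF strata, high to low; the low side of each interval is open
#: except for the closed boundary at 0.5.
AAF_BIN_LABELS = (">=0.5", "0.1-0.5", "0.05-0.1", "0.01-0.05", "<0.01")


@dataclass
class ConcordanceMatrix:
    """3x3 truth-by-call genotype counts plus the alternate-discordant class.

    Conservation: the nine cells plus ``alt_discordant`` sum to the number
    of evaluated truth sites.
    """

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {(t, c): 0 for t in GT_ORDER for c in GT_ORDER}
    )
    alt_discordant: int = 0

    @property
    def n_truth_sites(self) -> int:
        return sum(self.counts.values()) + self.alt_discordant

    def cell(self, truth_gt: str, call_gt: str) -> int:
        return self.counts[(truth_gt, call_gt)]

    def add(self, outcome: tuple[str, str] | str) -> None:
        if outcome == ALT_DISCORDANT:
            self.alt_discordant += 1
        else:
            self.counts[outcome] += 1


@dataclass(frozen=True)
class ConcordanceMetrics:
    """CR/FPR/FNR in [0, 1]; NTPR is ``None`` when the query called no
    non-reference genotype on the panel."""

    cr: float
    fpr: float
    fnr: float
    ntpr: float | None


def qc_filter_truth(
    panel: Iterable[TruthVariant],
    call_rate_min: float = 0.99,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
) -> list[TruthVariant]:
    """Array-side QC: retain on-array sites with call rate >= 0.99,
    HWE p >= 1e-6, MAF >= 0.01 and a single alternate allele.

    Sites without array metadata are rejected individually with a logged
    reason rather than failing the whole panel.
    """
    kept: list[TruthVariant] = []
    n_no_meta = 0
    for variant in panel:
        if not variant.on_array:
            continue
        meta = variant.array_meta
        if meta is None:
            n_no_meta += 1
            logger.debug("site %s:%d lacks array metadata; excluded",
                         variant.chrom, variant.pos)
            continue
        if meta.call_rate < call_rate_min:
            continue
        if meta.hwe_p < hwe_p_min:
            continue
        if meta.maf < maf_min:
            continue
        if meta.multi_allelic:
            continue
        kept.append(variant)
    if n_no_meta:
        logger.warning("%d on-array sites lacked QC metadata and were excluded",
                       n_no_meta)
    return kept


def classify_site(
    truth: TruthVariant, call: CallRecord | None
) -> tuple[str, str] | str:
    """Place one panel site into a matrix cell or the alternate-discordant
    class.

    An absent or genotype-missing call scores as homozygous reference.  A
    non-reference call whose alternate allele differs from the truth
    allele is alternate-discordant (a false positive regardless of the
    truth genotype).
    """
    if call is None:
        return (truth.truth_gt, GT_RR)
    if (call.chrom, call.pos, call.ref) != (truth.chrom, truth.pos, truth.ref):
        raise ValueError(
            f"call at {call.chrom}:{call.pos}:{call.ref} does not match truth "
            f"site {truth.chrom}:{truth.pos}:{truth.ref}"
        )
    if call.gt in (GT_RR, GT_MISSING):
        return (truth.truth_gt, GT_RR)
    if call.alt == truth.alt:
        return (truth.truth_gt, call.gt)
    return ALT_DISCORDANT


def build_matrix(
    panel: Sequence[TruthVariant],
    records: Iterable[CallRecord],
) -> ConcordanceMatrix:
    """Assemble the concordance matrix of a call set against a panel.

    Only passing records enter the comparison (unfiltered records, with
    ``filter_status`` still unset, are treated as passing).  Multi-allelic
    query records are excluded from the comparison — mirroring the
    array-side multi-allelic exclusion — and counted in a log message.
    """
    by_key: dict[tuple[str, int, str], CallRecord] = {}
    n_multi = 0
    for rec in records:
        if rec.filter_status is not None and not rec.passes:
            continue
        if not rec.is_biallelic:
            n_multi += 1
            continue
        by_key[(rec.chrom, rec.pos, rec.ref)] = rec
    if n_multi:
        logger.info("%d multi-allelic records excluded from panel comparison",
                    n_multi)
    matrix = ConcordanceMatrix()
    for site in panel:
        call = by_key.get((site.chrom, site.pos, site.ref))
        matrix.add(classify_site(site, call))
    return matrix


def compute_metrics(matrix: ConcordanceMatrix) -> ConcordanceMetrics:
    """CR, FPR, FNR and NTPR from the matrix (see module docstring)."""
    n = matrix.n_truth_sites
    if n == 0:
        raise ValueError("empty matrix: metrics undefined")
    diagonal = sum(matrix.cell(g, g) for g in GT_ORDER)
    fp = matrix.cell(GT_RR, GT_RA) + matrix.cell(GT_RR, GT_AA) + matrix.alt_discordant
    fn = matrix.cell(GT_RA, GT_RR) + matrix.cell(GT_AA, GT_RR)
    ntpr_num = matrix.cell(GT_RA, GT_RA) + matrix.cell(GT_AA, GT_AA)
    ntpr_den = (
        sum(matrix.cell(t, c) for t in GT_ORDER for c in (GT_RA, GT_AA))
        + matrix.alt_discordant
    )
    ntpr = ntpr_num / ntpr_den if ntpr_den else None
    return ConcordanceMetrics(
        cr=diagonal / n, fpr=fp / n, fnr=fn / n, ntpr=ntpr
    )


def het_concordance(matrix: ConcordanceMatrix) -> float | None:
    """Concordance restricted to truth-heterozygous panel sites (the RA
    row of the matrix); ``None`` when the panel has no heterozygotes."""
    row = sum(matrix.cell(GT_RA, c) for c in GT_ORDER)
    if row == 0:
        return None
    return matrix.cell(GT_RA, GT_RA) / row


def assign_aaf_bin(aaf: float) -> str:
    """Stratum label for an alternate allele frequency (0.5 belongs to the
    top bin; lower bounds are inclusive)."""
    if aaf >= 0.5:
        return ">=0.5"
    if aaf >= 0.1:
        return "0.1-0.5"
    if aaf >= 0.05:
        return "0.05-0.1"
    if aaf >= 0.01:
        return "0.01-0.05"
    return "<0.01"


def stratify_by_aaf(
    panel: Sequence[TruthVariant],
    records: Iterable[CallRecord],
) -> dict[str, tuple[int, ConcordanceMetrics | None]]:
    """Per-AAF-stratum concordance metrics.

    Returns ``{label: (n_sites, metrics)}`` with ``metrics=None`` for
    empty strata; every one of the five labels is present.
    """
    records = list(records)
    strata: dict[str, list[TruthVariant]] = {label: [] for label in AAF_BIN_LABELS}
    for site in panel:
        strata[assign_aaf_bin(site.aaf)].append(site)
    out: dict[str, tuple[int, ConcordanceMetrics | None]] = {}
    for label, sites in strata.items():
        if sites:
            out[label] = (len(sites), compute_metrics(build_matrix(sites, records)))
        else:
            out[label] = (0, None)
    return out


def ts_tv_counts(records: Iterable[CallRecord]) -> tuple[int, int, int]:
    """(transitions, transversions, skipped) over biallelic SNV records."""
    ts = tv = skipped = 0
    for rec in records:
        if rec.vtype != SNV or not rec.is_biallelic:
            skipped += 1
            continue
        if (rec.ref, rec.alt) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv, skipped


def ts_tv_ratio(records: Iterable[CallRecord]) -> float | None:
    """Transitions over transversions; ``None`` when undefined (no
    transversions)."""
    ts, tv, _ = ts_tv_counts(records)
    if tv == 0:
        return None
    return ts / tv


def allreads_concordance(
    full: Iterable[CallRecord],
    sub: Iterable[CallRecord],
    vtype: str,
) -> float:
    """Concordance of a subsampled call set against the full-depth call set.

    The denominator is the passing calls of the requested type in the
    full-depth set.  SNVs are concordant when the subsampled set carries
    the same genotype and alternate allele at the site (absent scores as
    homozygous reference, hence discordant).  Indels are concordant when
    the subsampled set has an indel at the same position with identical
    ref and alt strings — matching base sequences, not just positions.
    """
    if vtype not in (SNV, INDEL):
        raise ValueError(f"unknown variant type {vtype!r}")

    def _passing(records: Iterable[CallRecord]) -> list[CallRecord]:
        return [
            r
            for r in records
            if (r.filter_status is None or r.passes) and r.is_biallelic
        ]

    full_pass = [r for r in _passing(full) if r.vtype == vtype]
    if not full_pass:
        raise ValueError(f"full-depth set has no passing {vtype} calls")
    sub_pass = [r for r in _passing(sub) if r.vtype == vtype]

    if vtype == SNV:
        sub_by_key = {(r.chrom, r.pos, r.ref): r for r in sub_pass}
        concordant = 0
        for rec in full_pass:
            other = sub_by_key.get((rec.chrom, rec.pos, rec.ref))
            if other is not None and other.gt == rec.gt and other.alt == rec.alt:
                concordant += 1
        return concordant / len(full_pass)

    sub_keys = {(r.chrom, r.pos, r.ref, r.alt) for r in sub_pass}
    concordant = sum(
        1 for rec in full_pass if (rec.chrom, rec.pos, rec.ref, rec.alt) in sub_keys
    )
    return concordant / len(full_pass)


def count_variants(records: Iterable[CallRecord]) -> dict[str, int]:
    """Passing-record counts by variant type."""
    n_snv = n_indel = 0
    for rec in records:
        if rec.filter_status is not None and not rec.passes:
            continue
        if rec.vtype == SNV:
            n_snv += 1
        else:
            n_indel += 1
    return {"n_snv": n_snv, "n_indel": n_indel, "n_total": n_snv + n_indel}
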