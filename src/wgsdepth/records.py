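"""Variant call records and minimal single-sample VCF 4.2 round-trip.

A :class:`CallRecord` is the in-memory form of one called variant: a
diploid genotype against a single alternate allele (multi-allelic records
are carried but excluded from panel comparison), the site read depth, and
the seven GATK-style site annotations consumed by the hard filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "SNV",
    "INDEL",
    "GT_RR",
    "GT_RA",
    "GT_AA",
    "GT_MISSING",
    "GENOTYPES",
    "ANNOTATION_KEYS",
    "CallRecord",
    "classify_vtype",
    "write_vcf",
    "read_vcf",
]

SNV = "SNV"
INDEL = "indel"

GT_RR = "RR"
GT_RA = "RA"
GT_AA = "AA"
GT_MISSING = "missing"
GENOTYPES = (GT_RR, GT_RA, GT_AA)

# order matches the conventional GATK VariantFiltration listing
ANNOTATION_KEYS = (
    "QD",
    "FS",
    "MQ",
    "MQRankSum",
    "ReadPosRankSum",
    "SOR",
    "HaplotypeScore",
)

_GT_TO_INDICES = {GT_RR: (0, 0), GT_RA: (0, 1), GT_AA: (1, 1)}
_INDICES_TO_GT = {v: k for k, v in _GT_TO_INDICES.items()}


def classify_vtype(ref: str, alt: str) -> str:
    """A site is an SNV iff both alleles are single bases."""
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


@dataclass
class CallRecord:
    """One called variant site.

    ``filter_status`` is ``None`` before filtration, the empty tuple for
    PASS, or the tuple of failed filter-item names.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gt: str
    dp: int
    ann: dict[str, float] = field(default_factory=dict)
    vtype: str = SNV
    filter_status: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.gt not in GENOTYPES + (GT_MISSING,):
            raise ValueError(f"invalid genotype {self.gt!r}")
        if self.gt != GT_MISSING and not self.alts:
            raise ValueError("non-missing genotype requires at least one alt")
        if self.vtype not in (SNV, INDEL):
            raise ValueError(f"invalid vtype {self.vtype!r}")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def passes(self) -> bool:
        """True when filtered and no item failed (unfiltered records are not PASS)."""
        return self.filter_status == ()

    @property
    def filter_string(self) -> str:
        if self.filter_status is None:
            return "."
        if not self.filter_status:
            return "PASS"
        return ";".join(self.filter_status)

    def with_filter(self, failed: Sequence[str]) -> "CallRecord":
        return replace(self, filter_status=tuple(failed))


# ---------------------------------------------------------------------------
# VCF 4.2 round-trip (pysam)
# ---------------------------------------------------------------------------

_FILTER_DESCRIPTIONS = {
    "QD": "QD below threshold",
    "FS": "FS above threshold",
    "MQ": "MQ below threshold",
    "MQRankSum": "MQRankSum below threshold",
    "ReadPosRankSum": "ReadPosRankSum below threshold",
    "SOR": "SOR above threshold",
    "HaplotypeScore": "HaplotypeScore above threshold",
}


def _build_header(contigs: dict[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Approximate read depth")
    for key in ANNOTATION_KEYS:
        if key == "DP":
            continue
        header.info.add(key, 1, "Float", f"{key} site annotation")
    for name, desc in _FILTER_DESCRIPTIONS.items():
        header.filters.add(name, None, None, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    return header


def write_vcf(
    records: Iterable[CallRecord],
    path: str | Path,
    contigs: dict[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write records as an uncompressed single-sample VCF 4.2 file."""
    header = _build_header(contigs, sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            vrec.info["DP"] = int(rec.dp)
            for key in ANNOTATION_KEYS:
                if key in rec.ann and rec.ann[key] is not None:
                    vrec.info[key] = round(float(rec.ann[key]), 4)
            if rec.filter_status is not None:
                if rec.filter_status:
                    for item in rec.filter_status:
                        vrec.filter.add(item)
                else:
                    vrec.filter.add("PASS")
            if rec.gt == GT_MISSING:
                vrec.samples[sample]["GT"] = (None, None)
            else:
                vrec.samples[sample]["GT"] = _GT_TO_INDICES[rec.gt]
            out.write(vrec)


def read_vcf(path: str | Path) -> list[CallRecord]:
    """Read a single-sample VCF into :class:`CallRecord` objects."""
    out: list[CallRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, got {len(samples)}")
        sample = samples[0]
        for vrec in vcf:
            alts = tuple(vrec.alts or ())
            gt_idx = vrec.samples[sample].get("GT")
            if gt_idx is None or any(i is None for i in gt_idx):
                gt = GT_MISSING
            else:
                gt = _INDICES_TO_GT.get(tuple(sorted(gt_idx)), GT_MISSING)
            ann = {}
            for key in ANNOTATION_KEYS:
                if key in vrec.info:
                    ann[key] = float(vrec.info[key])
            filters = list(vrec.filter.keys())
            if not filters:
                status: tuple[str, ...] | None = None
            elif filters == ["PASS"]:
                status = ()
            else:
                status = tuple(filters)
            vtype = classify_vtype(vrec.ref, alts[0]) if alts else SNV
            out.append(
                CallRecord(
                    chrom=vrec.chrom,
                    pos=vrec.pos,
                    ref=vrec.ref,
                    alts=alts,
                    gt=gt,
                    dp=int(vrec.info.get("DP", 0)),
                    ann=ann,
                    vtype=vtype,
                    filter_status=status,
                )
            )
    return out
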