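"""Four-digit HLA genotype concordance.

Scores unordered pairs of two-field ("4-digit") classical HLA alleles
against a truth genotype, per gene and per typing tool, with per-allele
credit: a diploid call scores 1 when both alleles match, 0.5 when exactly
one does (the truth pair is treated as a multiset, so truth {X, X} against
call {X, Y} scores 0.5), and 0 otherwise.  Gene-level accuracy is the mean
score over seeded replicates, in percent; the tool-level average is the
unweighted mean over the genes the tool can type.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .util import round_half_up

__all__ = [
    "GENES",
    "TOOLS",
    "UNAVAILABLE",
    "DEFAULT_TRUTH",
    "DEFAULT_MISCALL",
    "HLAAllele",
    "HLAGenotype",
    "parse_allele",
    "score_genotype",
    "gene_accuracy",
    "average_accuracy",
    "accuracy_table",
]

#: the eight classical class I + II genes under evaluation
GENES = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")

TOOLS = ("PHLAT", "HLA-VBseq", "HLA-HD", "HISAT-genotype", "SNP2HLA")

#: (tool, gene) pairs the tool cannot type; emitted as NA and excluded
#: from both gene rows and tool averages.
UNAVAILABLE = frozenset(
    {
        ("PHLAT", "DPA1"),
        ("PHLAT", "DPB1"),
        ("HLA-VBseq", "DPA1"),
        ("HLA-VBseq", "DPB1"),
    }
)

#: default truth genotypes of the simulated subject (4-digit alleles)
DEFAULT_TRUTH: dict[str, tuple[str, str]] = {
    "A": ("24:02", "24:02"),
    "B": ("40:02", "40:02"),
    "C": ("01:02", "03:04"),
    "DRB1": ("09:01", "14:54"),
    "DQA1": ("01:04", "03:02"),
    "DQB1": ("03:03", "05:03"),
    "DPA1": ("01:03", "01:03"),
    "DPB1": ("02:01", "02:01"),
}

#: default per-allele miscall probabilities at the generator's reference
#: depth (13.7x), emulating the heterogeneous per-gene behaviour of the
#: five supported tools at medium coverage.
DEFAULT_MISCALL: dict[str, dict[str, float]] = {
    "PHLAT": {"A": 0.0, "C": 0.40, "B": 0.60, "DRB1": 0.60, "DQA1": 0.0, "DQB1": 0.0},
    "HLA-VBseq": {
        "A": 0.008,
        "C": 0.096,
        "B": 0.02,
        "DRB1": 0.289,
        "DQA1": 0.266,
        "DQB1": 0.796,
    },
    "HLA-HD": {
        "A": 0.05,
        "C": 0.10,
        "B": 0.0,
        "DRB1": 0.0,
        "DQA1": 0.0,
        "DQB1": 0.10,
        "DPA1": 0.0,
        "DPB1": 0.0,
    },
    "HISAT-genotype": {
        "A": 0.099,
        "C": 0.0,
        "B": 0.102,
        "DRB1": 0.214,
        "DQA1": 0.147,
        "DQB1": 0.006,
        "DPA1": 0.0,
        "DPB1": 0.0,
    },
    "SNP2HLA": {
        "A": 0.014,
        "C": 0.0,
        "B": 0.152,
        "DRB1": 0.542,
        "DQA1": 0.083,
        "DQB1": 0.0,
        "DPA1": 0.0,
        "DPB1": 0.018,
    },
}

#: plausible alternative alleles per gene, used as decoys when the
#: generator injects a miscall.
DECOY_ALLELES: dict[str, tuple[str, ...]] = {
    "A": ("02:01", "11:01", "24:02", "26:01", "31:01", "33:03"),
    "B": ("07:02", "15:01", "40:02", "44:03", "51:01", "52:01"),
    "C": ("01:02", "03:03", "03:04", "07:02", "12:02", "14:02"),
    "DRB1": ("01:01", "04:05", "08:03", "09:01", "14:01", "14:54", "15:01"),
    "DQA1": ("01:02", "01:03", "01:04", "03:02", "05:05"),
    "DQB1": ("03:01", "03:02", "03:03", "05:03", "06:01"),
    "DPA1": ("01:03", "02:02"),
    "DPB1": ("02:01", "02:02", "04:01", "05:01"),
}


@dataclass(frozen=True)
class HLAAllele:
    """A two-field (protein-level) HLA allele, e.g. ``A*24:02``."""

    gene: str
    field1: str
    field2: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown HLA gene {self.gene!r}")

    @property
    def name(self) -> str:
        return f"{self.field1}:{self.field2}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.gene}*{self.name}"


def parse_allele(text: str, gene: str | None = None) -> HLAAllele:
    """Parse ``GENE*FF:PP`` or bare ``FF:PP`` (gene from context).

    Fields beyond 4-digit resolution (e.g. ``24:02:01``) are truncated for
    comparison.
    """
    text = text.strip()
    if "*" in text:
        gene_part, _, rest = text.partition("*")
        gene = gene_part.strip()
    else:
        rest = text
    if gene is None:
        raise ValueError(f"no gene context for allele {text!r}")
    fields = rest.split(":")
    if len(fields) < 2:
        raise ValueError(f"allele {text!r} lacks 4-digit resolution")
    return HLAAllele(gene=gene, field1=fields[0], field2=fields[1])


@dataclass(frozen=True)
class HLAGenotype:
    """An unordered pair of 4-digit alleles of one gene; ``None`` alleles
    mark an unavailable (tool, gene) combination."""

    gene: str
    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown HLA gene {self.gene!r}")

    @property
    def is_na(self) -> bool:
        return self.alleles is None

    def normalized(self) -> tuple[str, str]:
        if self.alleles is None:
            raise ValueError("NA genotype has no alleles")
        parsed = tuple(parse_allele(a, self.gene).name for a in self.alleles)
        return tuple(sorted(parsed))  # type: ignore[return-value]


def score_genotype(truth: HLAGenotype, call: HLAGenotype) -> float:
    """Fraction of the diploid genotype recovered: 0, 0.5 or 1.

    Maximum-cardinality matching between the two unordered allele pairs
    (multiset intersection), divided by two; invariant to allele order in
    either argument.
    """
    if truth.gene != call.gene:
        raise ValueError(f"gene mismatch: {truth.gene!r} vs {call.gene!r}")
    if call.is_na:
        raise ValueError("cannot score an NA call")
    if truth.is_na:
        raise ValueError("truth genotype is NA")
    matched = sum((Counter(truth.normalized()) & Counter(call.normalized())).values())
    return matched / 2.0


def gene_accuracy(scores: Sequence[float]) -> float:
    """Mean replicate score as a percent, one decimal, half-up."""
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to average")
    return round_half_up(100.0 * sum(scores) / len(scores), 1)


def average_accuracy(per_gene: Mapping[str, float | None]) -> float:
    """Unweighted mean over available genes, one decimal, half-up.

    Genes mapped to ``None`` (tool cannot type them) are excluded from the
    mean, so tools lacking DPA1/DPB1 are averaged over six genes instead of
    eight.
    """
    values = [v for v in per_gene.values() if v is not None]
    if not values:
        raise ValueError("no typed genes to average")
    return round_half_up(sum(values) / len(values), 1)


def accuracy_table(
    per_tool: Mapping[str, Mapping[str, float | None]],
    genes: Iterable[str] = GENES,
) -> pd.DataFrame:
    """Tool-by-gene accuracy table with an ``Average`` row."""
    genes = list(genes)
    data: dict[str, list[float | None]] = {}
    for tool, per_gene in per_tool.items():
        column = [per_gene.get(g) for g in genes]
        column.append(average_accuracy(per_gene))
        data[tool] = column
    return pd.DataFrame(data, index=[*genes, "Average"])
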