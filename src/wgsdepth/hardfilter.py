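"""GATK-style hard-filter (HF) rules and per-item exclusion rates.

SNVs and indels carry different rule sets; a record fails an item when the
annotation is present and strictly past its threshold (values exactly at a
threshold pass).  Absent annotations never trigger their rule, matching
the VariantFiltration convention — rank-sum annotations are undefined at
homozygous-alternate sites in real caller output.

VQSR-style model-based recalibration is out of scope; the module exposes a
pluggable filtration-strategy registry with the hard filter as the single
substantive built-in and a pass-through strategy for pipelines evaluated
without site filtration.
"""
from __future__ import annotations

import operator
from typing import Iterable, Mapping, Sequence

from .records import INDEL, SNV, CallRecord

__all__ = [
    "SNP_RULES",
    "INDEL_RULES",
    "FILTER_ITEMS",
    "rules_for",
    "apply_hard_filter",
    "apply_hard_filter_all",
    "exclusion_rates",
    "HardFilterStrategy",
    "PassThroughStrategy",
    "STRATEGIES",
    "get_strategy",
]

# (comparison, threshold): a record FAILS the item when comparison holds
SNP_RULES: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "HaplotypeScore": (">", 13.0),
    "SOR": (">", 3.0),
}

INDEL_RULES: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 200.0),
    "ReadPosRankSum": ("<", -20.0),
    "SOR": (">", 10.0),
}

#: all item names, in SNV rule order (for reporting)
FILTER_ITEMS = tuple(SNP_RULES)

_OPS = {"<": operator.lt, ">": operator.gt}


def rules_for(vtype: str) -> Mapping[str, tuple[str, float]]:
    if vtype == SNV:
        return SNP_RULES
    if vtype == INDEL:
        return INDEL_RULES
    raise ValueError(f"unknown variant type {vtype!r}")


def apply_hard_filter(record: CallRecord) -> CallRecord:
    """Return a copy with ``filter_status`` set to the failed items.

    Idempotent: re-filtering a filtered record reproduces the same status.
    """
    rules = rules_for(record.vtype)
    failed = tuple(
        item
        for item, (op, threshold) in rules.items()
        if record.ann.get(item) is not None
        and _OPS[op](record.ann[item], threshold)
    )
    return record.with_filter(failed)


def apply_hard_filter_all(records: Iterable[CallRecord]) -> list[CallRecord]:
    return [apply_hard_filter(r) for r in records]


def exclusion_rates(records: Sequence[CallRecord]) -> dict[str, float]:
    """Percent of records failing each filtration item.

    A record failing k items counts once toward each of its k items; all
    seven item names are reported (0.0 when never failed).
    """
    if not records:
        raise ValueError("no records: exclusion rates undefined")
    if any(r.filter_status is None for r in records):
        raise ValueError("records must be filtered before computing rates")
    total = len(records)
    rates = {}
    for item in FILTER_ITEMS:
        failing = sum(1 for r in records if item in r.filter_status)
        rates[item] = 100.0 * failing / total
    return rates


class HardFilterStrategy:
    """The built-in rule-based filtration."""

    name = "hard_filter"

    def apply(self, records: Iterable[CallRecord]) -> list[CallRecord]:
        return apply_hard_filter_all(records)


class PassThroughStrategy:
    """Marks every record PASS; stands in for model-based recalibration
    when the experiment is run without substantive site filtration."""

    name = "pass_through"

    def apply(self, records: Iterable[CallRecord]) -> list[CallRecord]:
        return [r.with_filter(()) for r in records]


STRATEGIES = {
    HardFilterStrategy.name: HardFilterStrategy,
    PassThroughStrategy.name: PassThroughStrategy,
}


def get_strategy(name: str):
    try:
        return STRATEGIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown filtration strategy {name!r}; available: {sorted(STRATEGIES)}"
        ) from None
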