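"""Six-stage depth accounting and derived reduction/fold-change statistics.

The six stages trace fold-coverage through a short-read pipeline: raw
reads (RRD), raw reads after adapter trimming (RRDaT), mapped reads (MRD),
unique reads after duplicate removal (URD), called variant sites (VD) and
variant sites surviving filtration (VDaF).  The first four are monotone
non-increasing; VD/VDaF carry no ordering constraint against URD — at very
low coverage the mean depth over *called* sites exceeds the genome-wide
mean, because a site needs several reads before a variant can be emitted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import CallRecord
from .util import round_half_up

__all__ = [
    "DepthStageProfile",
    "depth_from_bases",
    "variant_depth",
    "reduction_percent",
    "fold_change",
    "stage_profile",
]

_CHAIN_TOL = 1e-9


@dataclass
class DepthStageProfile:
    """Fold-coverage at the six pipeline stages for one dataset.

    ``vd``/``vdaf`` may be ``None`` when a dataset yields no (passing)
    variant records.
    """

    rrd: float
    rrdat: float
    mrd: float
    urd: float
    vd: float | None = None
    vdaf: float | None = None

    def __post_init__(self) -> None:
        stages = (self.rrd, self.rrdat, self.mrd, self.urd)
        if any(s < 0 for s in stages):
            raise ValueError("stage depths must be non-negative")
        if not (
            self.rrd + _CHAIN_TOL >= self.rrdat
            and self.rrdat + _CHAIN_TOL >= self.mrd
            and self.mrd + _CHAIN_TOL >= self.urd
        ):
            raise ValueError("stage depths must satisfy rrd >= rrdat >= mrd >= urd")


def depth_from_bases(total_bases: float, effective_ref_length: float) -> float:
    """Fold-coverage: sequenced bases divided by effective (non-N) reference bases."""
    if effective_ref_length <= 0:
        raise ValueError("effective_ref_length must be positive")
    if total_bases < 0:
        raise ValueError("total_bases must be non-negative")
    return total_bases / effective_ref_length


def variant_depth(records: Sequence[CallRecord] | Iterable[CallRecord]) -> float:
    """Arithmetic mean DP over variant records."""
    dps = [r.dp for r in records]
    if not dps:
        raise ValueError("no variant records: variant depth undefined")
    return float(np.mean(dps))


def reduction_percent(
    depth_before: float, depth_after: float, ndigits: int | None = 1
) -> float:
    """Percent depth lost between two stages, ``100 * (1 - after/before)``.

    Reported to one decimal (half-up) by default; pass ``ndigits=None``
    for the unrounded value.
    """
    if depth_before <= 0:
        raise ValueError("depth_before must be positive")
    raw = 100.0 * (1.0 - depth_after / depth_before)
    return raw if ndigits is None else round_half_up(raw, ndigits)


def fold_change(depth_from: float, depth_to: float) -> float:
    """Ratio ``depth_to / depth_from`` (e.g. the URD -> VDaF increment at
    very low coverage)."""
    if depth_from <= 0:
        raise ValueError("depth_from must be positive")
    return depth_to / depth_from


def stage_profile(
    callset,
    pass_records: Sequence[CallRecord],
    effective_ref_length: float,
) -> DepthStageProfile:
    """Assemble the six-stage profile of a simulated dataset.

    RRD..URD come from the simulator's read-accounting ledger (alignment
    itself is out of scope); VD/VDaF are mean DP over all and over passing
    variant records.
    """
    acct = callset.read_accounting
    return DepthStageProfile(
        rrd=depth_from_bases(acct["rrd_bases"], effective_ref_length),
        rrdat=depth_from_bases(acct["rrdat_bases"], effective_ref_length),
        mrd=depth_from_bases(acct["mrd_bases"], effective_ref_length),
        urd=depth_from_bases(acct["urd_bases"], effective_ref_length),
        vd=variant_depth(callset.records) if callset.records else None,
        vdaf=variant_depth(pass_records) if pass_records else None,
    )
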