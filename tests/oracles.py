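"""Independent brute-force oracles used by the concordance tests.

These re-derive the concordance indices site by site, without the 3x3
matrix, so matrix-based results can be checked against an independent
recount.
"""
from __future__ import annotations

import numpy as np

from wgsdepth.records import CallRecord
from wgsdepth.simulate import TruthVariant

_BASES = ("A", "C", "G", "T")
_GTS = ("RR", "RA", "AA")


def brute_force_metrics(
    panel: list[TruthVariant],
    calls_by_pos: dict[int, CallRecord],
) -> tuple[float, float, float, float | None]:
    """Site-by-site recount of CR, FPR, FNR and NTPR."""
    n = len(panel)
    concordant = fp = fn = ntpr_num = ntpr_den = 0
    for site in panel:
        call = calls_by_pos.get(site.pos)
        if call is None or call.gt in ("RR", "missing"):
            effective, altdisc = "RR", False
        elif call.alt != site.alt:
            effective, altdisc = None, True
        else:
            effective, altdisc = call.gt, False
        if altdisc:
            fp += 1
            ntpr_den += 1
            continue
        if effective == site.truth_gt:
            concordant += 1
        if site.truth_gt == "RR" and effective != "RR":
            fp += 1
        if site.truth_gt != "RR" and effective == "RR":
            fn += 1
        if effective != "RR":
            ntpr_den += 1
            if effective == site.truth_gt:
                ntpr_num += 1
    ntpr = ntpr_num / ntpr_den if ntpr_den else None
    return concordant / n, fp / n, fn / n, ntpr


def random_panel_and_calls(
    rng: np.random.Generator,
) -> tuple[list[TruthVariant], dict[int, CallRecord]]:
    """A random SNV evaluation panel plus a call set exercising every
    classification outcome (absent, concordant, wrong genotype,
    alternate-discordant)."""
    n = int(rng.integers(1, 1001))
    positions = rng.choice(np.arange(1, 100_001), size=n, replace=False)
    panel: list[TruthVariant] = []
    calls: dict[int, CallRecord] = {}
    for pos in sorted(int(p) for p in positions):
        ref = _BASES[rng.integers(0, 4)]
        alt = [b for b in _BASES if b != ref][rng.integers(0, 3)]
        truth_gt = _GTS[rng.integers(0, 3)]
        panel.append(
            TruthVariant(
                chrom="1",
                pos=pos,
                ref=ref,
                alt=alt,
                vtype="SNV",
                truth_gt=truth_gt,
                aaf=float(rng.random()),
                on_array=True,
                array_meta=None,
            )
        )
        scenario = rng.random()
        if scenario < 0.3:
            continue  # no call at this site
        call_gt = _GTS[rng.integers(0, 3)]
        call_alt = alt
        if scenario > 0.85:  # discordant alternate allele
            others = [b for b in _BASES if b not in (ref, alt)]
            call_alt = others[rng.integers(0, len(others))]
        calls[pos] = CallRecord(
            chrom="1",
            pos=pos,
            ref=ref,
            alts=(call_alt,),
            gt=call_gt,
            dp=int(rng.integers(1, 60)),
            ann={},
            vtype="SNV",
        )
    return panel, calls
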