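"""Concordance matrix, derived indices, AAF strata, Ts/Tv and the
all-reads comparison."""
import dataclasses
import math

import numpy as np
import pytest

from wgsdepth import (
    CallRecord,
    ConcordanceMatrix,
    allreads_concordance,
    assign_aaf_bin,
    build_matrix,
    classify_site,
    compute_metrics,
    count_variants,
    het_concordance,
    qc_filter_truth,
    simulate_callset,
    stratify_by_aaf,
    ts_tv_ratio,
)
from wgsdepth.concordance import AAF_BIN_LABELS
from wgsdepth.records import INDEL, SNV
from wgsdepth.simulate import ArrayMeta, TruthVariant

from conftest import zero_error_model
from oracles import brute_force_metrics, random_panel_and_calls


def _truth(pos=10, gt="RA", alt="C", aaf=0.3, meta=None, on_array=True):
    return TruthVariant(
        chrom="1", pos=pos, ref="A", alt=alt, vtype=SNV, truth_gt=gt,
        aaf=aaf, on_array=on_array, array_meta=meta,
    )


def _call(pos=10, gt="RA", alt="C", ref="A", vtype=SNV, status=()):
    return CallRecord(
        chrom="1", pos=pos, ref=ref, alts=(alt,), gt=gt, dp=30,
        vtype=vtype, filter_status=status,
    )


# ---------------------------------------------------------------------------
# array-panel QC
# ---------------------------------------------------------------------------

def _meta(call_rate=0.995, hwe_p=0.5, maf=0.2, multi=False):
    return ArrayMeta(call_rate=call_rate, hwe_p=hwe_p, maf=maf, multi_allelic=multi)


@pytest.mark.parametrize(
    "meta, kept",
    [
        (_meta(), True),
        (_meta(call_rate=0.98), False),  # call rate below 0.99
        (_meta(call_rate=0.99), True),  # boundary retained
        (_meta(hwe_p=1e-5), True),  # 1e-5 >= 1e-6
        (_meta(hwe_p=1e-7), False),
        (_meta(maf=0.005), False),
        (_meta(multi=True), False),
    ],
)
def test_array_qc_thresholds(meta, kept):
    panel = qc_filter_truth([_truth(meta=meta)])
    assert (len(panel) == 1) == kept


def test_array_qc_skips_sites_without_metadata():
    sites = [_truth(meta=None), _truth(pos=11, meta=_meta())]
    assert [s.pos for s in qc_filter_truth(sites)] == [11]


# ---------------------------------------------------------------------------
# site classification and matrix metrics
# ---------------------------------------------------------------------------

def test_classify_site_outcomes():
    assert classify_site(_truth(), _call()) == ("RA", "RA")
    assert classify_site(_truth(gt="RR"), None) == ("RR", "RR")
    assert classify_site(_truth(), None) == ("RA", "RR")
    assert classify_site(_truth(), _call(gt="missing")) == ("RA", "RR")
    # different alternate allele: alternate-discordant false positive
    assert classify_site(_truth(alt="C"), _call(gt="AA", alt="T")) == "alt_discordant"
    with pytest.raises(ValueError):
        classify_site(_truth(pos=10), _call(pos=11))


def _example_matrix():
    m = ConcordanceMatrix()
    m.counts[("RR", "RR")] = 90
    m.counts[("RA", "RA")] = 5
    m.counts[("RA", "RR")] = 3
    m.counts[("RR", "RA")] = 1
    m.alt_discordant = 1
    return m


def test_metrics_hand_worked_matrix():
    m = _example_matrix()
    assert m.n_truth_sites == 100
    metrics = compute_metrics(m)
    assert metrics.cr == pytest.approx(0.95)
    assert metrics.fpr == pytest.approx(0.02)
    assert metrics.fnr == pytest.approx(0.03)
    assert metrics.ntpr == pytest.approx(5 / 7)
    # het-only concordance restricts to the truth-heterozygous row
    assert het_concordance(m) == pytest.approx(5 / 8)


def test_metrics_perfect_and_degenerate_matrices():
    m = ConcordanceMatrix()
    for g in ("RR", "RA", "AA"):
        m.counts[(g, g)] = 3
    metrics = compute_metrics(m)
    assert (metrics.cr, metrics.fpr, metrics.fnr, metrics.ntpr) == (1.0, 0.0, 0.0, 1.0)

    empty = ConcordanceMatrix()
    with pytest.raises(ValueError):
        compute_metrics(empty)

    only_rr = ConcordanceMatrix()
    only_rr.counts[("RR", "RR")] = 5
    assert compute_metrics(only_rr).ntpr is None  # no non-reference calls


def test_matrix_conservation_against_bruteforce_recount():
    """Matrix metrics equal an independent site-by-site recount, and the
    nine cells plus the alternate-discordant class conserve the panel."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        panel, calls = random_panel_and_calls(rng)
        matrix = build_matrix(panel, calls.values())
        assert matrix.n_truth_sites == len(panel)
        metrics = compute_metrics(matrix)
        cr, fpr, fnr, ntpr = brute_force_metrics(panel, calls)
        assert (metrics.cr, metrics.fpr, metrics.fnr) == (cr, fpr, fnr)
        assert metrics.ntpr == ntpr


def test_multiallelic_query_records_are_excluded():
    panel = [_truth()]
    multi = CallRecord(
        chrom="1", pos=10, ref="A", alts=("C", "T"), gt="RA", dp=9, vtype=SNV,
        filter_status=(),
    )
    matrix = build_matrix(panel, [multi])
    # excluded record leaves the site uncalled -> scored homozygous reference
    assert matrix.cell("RA", "RR") == 1


def test_injected_het_error_recovered_at_small_scale(small_config, small_truth):
    cfg = dataclasses.replace(
        small_config, error_model=zero_error_model(het_error_rate=0.05)
    )
    panel = [t for t in small_truth if t.on_array]
    cs = simulate_callset(small_truth, 30.0, 8, cfg)
    metrics = compute_metrics(build_matrix(panel, cs.records))
    f_het = sum(t.truth_gt == "RA" for t in panel) / len(panel)
    expected = 1.0 - 0.05 * f_het
    se = math.sqrt(expected * (1 - expected) / len(panel))
    assert abs(metrics.cr - expected) <= 3 * se


# ---------------------------------------------------------------------------
# AAF strata
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "aaf, label",
    [
        (0.7, ">=0.5"),
        (0.5, ">=0.5"),  # closed boundary at 0.5
        (0.3, "0.1-0.5"),
        (0.1, "0.1-0.5"),
        (0.07, "0.05-0.1"),
        (0.02, "0.01-0.05"),
        (0.005, "<0.01"),
    ],
)
def test_aaf_bin_assignment(aaf, label):
    assert assign_aaf_bin(aaf) == label


def test_stratified_metrics_with_error_free_calls():
    panel = [
        _truth(pos=i + 1, aaf=aaf, meta=_meta())
        for i, aaf in enumerate([0.8, 0.3, 0.07, 0.02, 0.005])
    ]
    calls = [_call(pos=i + 1) for i in range(5)]
    strata = stratify_by_aaf(panel, calls)
    assert set(strata) == set(AAF_BIN_LABELS)
    for label, (n_sites, metrics) in strata.items():
        assert n_sites == 1
        assert metrics.cr == 1.0


# ---------------------------------------------------------------------------
# Ts/Tv and variant counts
# ---------------------------------------------------------------------------

def test_ts_tv_examples():
    recs = [
        _call(pos=1, ref="A", alt="G"),
        _call(pos=2, ref="C", alt="T"),
        _call(pos=3, ref="A", alt="C"),
    ]
    assert ts_tv_ratio(recs) == pytest.approx(2.0)
    assert ts_tv_ratio([_call(pos=1, ref="A", alt="G")]) is None  # no transversions


def test_ts_tv_recovers_injected_ratio(small_config, small_truth):
    cs = simulate_callset(small_truth, 50.0, 4, small_config)
    snvs = [r for r in cs.records if r.vtype == SNV]
    ratio = ts_tv_ratio(snvs)
    p = small_config.ts_fraction  # 2.1:1 transition:transversion injection
    n = len(snvs)
    se = 3 * math.sqrt(p * (1 - p) / n)
    assert p / (1 - p) == pytest.approx(2.1, abs=0.01)
    assert (p - se) / (1 - p + se) <= ratio <= (p + se) / (1 - p - se)


def test_count_variants_by_type_and_filter():
    recs = [
        _call(pos=1),
        _call(pos=2),
        _call(pos=3, status=("QD",)),
        _call(pos=4, ref="AT", alt="A", vtype=INDEL),
        _call(pos=5, ref="A", alt="AT", vtype=INDEL),
    ]
    assert count_variants(recs) == {"n_snv": 2, "n_indel": 2, "n_total": 4}
    assert count_variants([]) == {"n_snv": 0, "n_indel": 0, "n_total": 0}


# ---------------------------------------------------------------------------
# all-reads comparison
# ---------------------------------------------------------------------------

def test_allreads_identity_and_rules():
    full = [
        _call(pos=100, ref="AT", alt="A", vtype=INDEL),
        _call(pos=200, ref="A", alt="AT", vtype=INDEL),
        _call(pos=500),
        _call(pos=600),
    ]
    assert allreads_concordance(full, full, SNV) == 1.0
    assert allreads_concordance(full, full, INDEL) == 1.0

    # same position, different deleted sequence: discordant
    sub = [
        _call(pos=100, ref="ATT", alt="A", vtype=INDEL),
        _call(pos=200, ref="A", alt="AT", vtype=INDEL),
        _call(pos=500),
    ]
    assert allreads_concordance(full, sub, INDEL) == pytest.approx(0.5)
    # missing SNV counts as homozygous reference, hence discordant
    assert allreads_concordance(full, sub, SNV) == pytest.approx(0.5)

    with pytest.raises(ValueError):
        allreads_concordance([_call(pos=1)], [], INDEL)


def test_allreads_snv_requires_genotype_and_allele_match():
    full = [_call(pos=10, gt="RA", alt="C")]
    assert allreads_concordance(full, [_call(pos=10, gt="AA", alt="C")], SNV) == 0.0
    assert allreads_concordance(full, [_call(pos=10, gt="RA", alt="T")], SNV) == 0.0
    assert allreads_concordance(full, [_call(pos=10, gt="RA", alt="C")], SNV) == 1.0
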