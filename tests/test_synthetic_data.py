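"""Truth catalog, call-set and HLA-call generators."""
import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from wgsdepth import (
    SimulationConfig,
    generate_hla_calls,
    generate_truth,
    read_truth,
    simulate_callset,
    write_truth,
    write_vcf,
)
from wgsdepth.concordance import assign_aaf_bin
from wgsdepth.config import AAFSpec
from wgsdepth.hla import DEFAULT_TRUTH, GENES, HLAGenotype, TOOLS, score_genotype
from wgsdepth.records import GT_RA, SNV

from conftest import zero_error_model


def test_truth_catalog_is_deterministic_and_well_formed(small_config, small_truth):
    again = generate_truth(small_config)
    assert len(small_truth) == small_config.n_variants
    assert [dataclasses.astuple(t) for t in again] == [
        dataclasses.astuple(t) for t in small_truth
    ]
    positions = [t.pos for t in small_truth]
    assert positions == sorted(positions)
    assert len(set(positions)) == len(positions)
    # indel share within 3 binomial SE of the configured fraction
    n = len(small_truth)
    k = sum(t.vtype == "indel" for t in small_truth)
    p = small_config.indel_fraction
    assert abs(k / n - p) <= 3 * math.sqrt(p * (1 - p) / n)
    # on-array sites are SNVs and carry QC metadata; off-array are carriers
    for t in small_truth:
        if t.on_array:
            assert t.vtype == SNV and t.array_meta is not None
        else:
            assert t.truth_gt != "RR"


def test_indel_fraction_zero_yields_only_snvs(small_config):
    cfg = dataclasses.replace(small_config, indel_fraction=0.0, n_variants=500)
    assert all(t.vtype == SNV for t in generate_truth(cfg))


def test_hardy_weinberg_heterozygote_share_at_half_frequency():
    """At a fixed AAF of 0.5 the heterozygote share is 2pq = 0.5."""
    cfg = SimulationConfig(
        genome_length=2_000_000,
        n_variants=20_000,
        indel_fraction=0.0,
        array_fraction=1.0,  # allow hom-reference genotypes
        aaf_spec=AAFSpec(fixed=0.5),
        base_seed=11,
    )
    truth = generate_truth(cfg)
    het = sum(t.truth_gt == GT_RA for t in truth) / len(truth)
    se = math.sqrt(0.5 * 0.5 / len(truth))
    assert abs(het - 0.5) <= 3 * se


def test_aaf_bins_recover_configured_spectrum():
    """Empirical occupancy of the five AAF strata matches the Beta spec."""
    cfg = SimulationConfig(
        genome_length=2_000_000, n_variants=20_000, base_seed=13
    )
    truth = generate_truth(cfg)
    n = len(truth)
    dist = stats.beta(cfg.aaf_spec.alpha, cfg.aaf_spec.beta)
    edges = {
        ">=0.5": (0.5, 1.0),
        "0.1-0.5": (0.1, 0.5),
        "0.05-0.1": (0.05, 0.1),
        "0.01-0.05": (0.01, 0.05),
        "<0.01": (0.0, 0.01),
    }
    counts = {label: 0 for label in edges}
    for t in truth:
        counts[assign_aaf_bin(t.aaf)] += 1
    for label, (lo, hi) in edges.items():
        expected = dist.cdf(hi) - dist.cdf(lo)
        se = math.sqrt(expected * (1 - expected) / n)
        assert counts[label] > 0
        assert abs(counts[label] / n - expected) <= 3 * se, label


def test_truth_rejects_oversized_catalog():
    with pytest.raises(ValueError, match="bases"):
        generate_truth(SimulationConfig(genome_length=100, n_variants=200))


def test_callset_vcf_output_is_byte_identical(small_config, small_truth, tmp_path):
    paths = []
    for name in ("a.vcf", "b.vcf"):
        cs = simulate_callset(small_truth, 5.0, 424, small_config)
        path = tmp_path / name
        write_vcf(
            cs.records, path, contigs={small_config.chrom: small_config.genome_length}
        )
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_zero_error_calls_reproduce_truth_exactly(small_config, small_truth):
    cfg = dataclasses.replace(small_config, error_model=zero_error_model())
    cs = simulate_callset(small_truth, 100.0, 99, cfg)
    by_pos = {r.pos: r for r in cs.records}
    carriers = [t for t in small_truth if t.truth_gt != "RR"]
    assert len(by_pos) == len(carriers)
    for t in carriers:
        rec = by_pos[t.pos]
        assert (rec.gt, rec.ref, rec.alt) == (t.truth_gt, t.ref, t.alt)


def test_low_depth_sites_mostly_absent(small_config, small_truth):
    """At 0.05x coverage the Poisson zero class alone removes ~95% of sites."""
    cfg = dataclasses.replace(
        small_config, error_model=zero_error_model(min_reads=1)
    )
    cs = simulate_callset(small_truth, 0.05, 5, cfg)
    carriers = sum(t.truth_gt != "RR" for t in small_truth)
    absent = 1.0 - len(cs.records) / carriers
    assert absent > 0.9


def test_callset_records_carry_depth_and_annotations(small_config, small_truth):
    cs = simulate_callset(small_truth, 20.0, 3, small_config)
    positions = [r.pos for r in cs.records]
    assert positions == sorted(positions)
    for rec in cs.records[:50]:
        assert rec.dp >= small_config.error_model.min_reads
        assert {"QD", "FS", "MQ", "SOR"} <= set(rec.ann)
        if rec.vtype == SNV:
            assert "HaplotypeScore" in rec.ann


def test_truth_tsv_roundtrip(small_truth, tmp_path):
    path = tmp_path / "truth.tsv"
    write_truth(small_truth, path)
    back = read_truth(path)
    assert len(back) == len(small_truth)
    for a, b in zip(small_truth, back):
        assert dataclasses.astuple(a)[:6] == dataclasses.astuple(b)[:6]
        assert b.aaf == pytest.approx(a.aaf)
        assert b.on_array == a.on_array
        if a.array_meta is not None:
            assert b.array_meta is not None
            assert b.array_meta.call_rate == pytest.approx(a.array_meta.call_rate)


@pytest.fixture(scope="module")
def truth_hla():
    return [HLAGenotype(gene=g, alleles=DEFAULT_TRUTH[g]) for g in GENES]


def test_hla_calls_respect_masks_and_error_extremes(truth_hla, small_config):
    cfg = dataclasses.replace(
        small_config,
        hla_error=dataclasses.replace(
            small_config.hla_error,
            miscall={tool: {g: 0.0 for g in GENES} for tool in TOOLS},
        ),
    )
    calls = generate_hla_calls(truth_hla, TOOLS, 30.0, 1, cfg)
    truth_by_gene = {g.gene: g for g in truth_hla}
    for (tool, gene), call in calls.items():
        if (tool, gene) in {
            ("PHLAT", "DPA1"),
            ("PHLAT", "DPB1"),
            ("HLA-VBseq", "DPA1"),
            ("HLA-VBseq", "DPB1"),
        }:
            assert call.is_na
        else:
            assert score_genotype(truth_by_gene[gene], call) == 1.0

    # certain miscall for one tool drives its downstream accuracy to zero
    cfg_bad = dataclasses.replace(
        cfg,
        hla_error=dataclasses.replace(
            cfg.hla_error,
            miscall={
                tool: {g: (1.0 if tool == "PHLAT" else 0.0) for g in GENES}
                for tool in TOOLS
            },
        ),
    )
    calls_bad = generate_hla_calls(truth_hla, TOOLS, 13.7, 2, cfg_bad)
    for (tool, gene), call in calls_bad.items():
        if tool == "PHLAT" and not call.is_na:
            assert score_genotype(truth_by_gene[gene], call) == 0.0


def test_hla_calls_reject_unknown_gene(small_config):
    with pytest.raises(ValueError, match="unknown HLA gene"):
        HLAGenotype(gene="XYZ", alleles=("01:01", "01:01"))
    bad = [HLAGenotype(gene="A", alleles=None)]
    with pytest.raises(ValueError, match="NA"):
        generate_hla_calls(bad, TOOLS, 10.0, 1, small_config)


def test_hla_calls_deterministic(truth_hla, small_config):
    a = generate_hla_calls(truth_hla, TOOLS, 5.0, 77, small_config)
    b = generate_hla_calls(truth_hla, TOOLS, 5.0, 77, small_config)
    assert a == b
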