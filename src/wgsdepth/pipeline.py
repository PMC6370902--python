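"""Orchestration of the full depth sweep and report generation.

``run_sweep`` executes simulate -> filter -> concordance -> HLA for every
(depth, replicate) dataset of a configuration and writes one tidy TSV per
analysis plus a long-format summary table and a JSON manifest.  Re-running
with the same configuration and seed reproduces byte-identical outputs.
The full-depth reference for the all-reads comparison is the
maximum-depth dataset of the schedule.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hla as hla_mod
from .concordance import (
    AAF_BIN_LABELS,
    allreads_concordance,
    build_matrix,
    compute_metrics,
    count_variants,
    het_concordance,
    qc_filter_truth,
    stratify_by_aaf,
    ts_tv_ratio,
)
from .config import SimulationConfig
from .depths import stage_profile
from .hardfilter import exclusion_rates, get_strategy
from .records import INDEL, SNV
from .simulate import generate_hla_calls, generate_truth, write_truth
from .subsample import plan_replicates

__all__ = ["RunManifest", "run_sweep", "make_report"]

logger = logging.getLogger(__name__)

_OUTPUT_FILES = (
    "truth_catalog.tsv",
    "truth_panel.tsv",
    "depth_stages.tsv",
    "variant_counts.tsv",
    "tstv.tsv",
    "exclusion_rates.tsv",
    "array_concordance.tsv",
    "allreads_concordance.tsv",
    "hla_accuracy.tsv",
    "summary.tsv",
)


@dataclass
class RunManifest:
    """Provenance of one sweep: config digest, seeds and output paths."""

    config_digest: str
    version: str
    base_seed: int
    depth_schedule: list[float]
    seeds: dict[str, list[int]]
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _truth_hla(config: SimulationConfig) -> list[hla_mod.HLAGenotype]:
    table = config.hla_truth if config.hla_truth is not None else hla_mod.DEFAULT_TRUTH
    return [
        hla_mod.HLAGenotype(gene=g, alleles=tuple(table[g]))
        for g in hla_mod.GENES
        if g in table
    ]


def run_sweep(config: SimulationConfig, outdir: str | Path) -> RunManifest:
    """Run the whole titration experiment and write its report tables."""
    from .simulate import simulate_callset  # local to keep import graph flat

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strategy = get_strategy(config.filtration)

    truth = generate_truth(config)
    panel = qc_filter_truth(truth)
    truth_hla = _truth_hla(config)
    write_truth(truth, outdir / "truth_catalog.tsv")
    write_truth(panel, outdir / "truth_panel.tsv")

    schedule = sorted(config.depth_schedule)
    plans = {
        depth: plan_replicates(depth, config, depth_index=config.depth_schedule.index(depth))
        for depth in schedule
    }
    ref_depth = schedule[-1]

    # full-depth reference dataset (replicate 0 of the top depth)
    ref_callset = simulate_callset(
        truth, ref_depth, plans[ref_depth].seeds[0], config, replicate_id=0
    )
    ref_filtered = strategy.apply(ref_callset.records)
    ref_cache = {(ref_depth, 0): (ref_callset, ref_filtered)}

    stage_rows = []
    count_rows = []
    tstv_rows = []
    excl_rows = []
    conc_rows = []
    allreads_rows = []
    hla_rows = []
    summary_rows = []
    failed_depths = []

    for depth in schedule:
        plan = plans[depth]
        try:
            for rep, seed in enumerate(plan.seeds):
                if (depth, rep) in ref_cache:
                    callset, filtered = ref_cache[(depth, rep)]
                else:
                    callset = simulate_callset(
                        truth, depth, seed, config, replicate_id=rep
                    )
                    filtered = strategy.apply(callset.records)
                pass_records = [r for r in filtered if r.passes]

                profile = stage_profile(callset, pass_records, config.genome_length)
                stage_rows.append(
                    {
                        "target_depth": depth,
                        "replicate": rep,
                        "rrd": profile.rrd,
                        "rrdat": profile.rrdat,
                        "mrd": profile.mrd,
                        "urd": profile.urd,
                        "vd": profile.vd,
                        "vdaf": profile.vdaf,
                    }
                )

                counts = count_variants(filtered)
                count_rows.append({"depth": depth, "replicate": rep, **counts})

                ratio = ts_tv_ratio(pass_records)
                tstv_rows.append(
                    {"depth": depth, "replicate": rep, "tstv": ratio}
                )

                if filtered:
                    for item, rate in exclusion_rates(filtered).items():
                        excl_rows.append(
                            {
                                "depth": depth,
                                "replicate": rep,
                                "item": item,
                                "rate_pct": rate,
                            }
                        )

                matrix = build_matrix(panel, pass_records)
                metrics = compute_metrics(matrix)
                het_cr = het_concordance(matrix)
                conc_rows.append(
                    {
                        "depth": depth,
                        "replicate": rep,
                        "stratum": "all",
                        "n_sites": matrix.n_truth_sites,
                        "cr": metrics.cr,
                        "fpr": metrics.fpr,
                        "fnr": metrics.fnr,
                        "ntpr": metrics.ntpr,
                        "het_cr": het_cr,
                    }
                )
                for label, (n_sites, m) in stratify_by_aaf(panel, pass_records).items():
                    conc_rows.append(
                        {
                            "depth": depth,
                            "replicate": rep,
                            "stratum": label,
                            "n_sites": n_sites,
                            "cr": m.cr if m else None,
                            "fpr": m.fpr if m else None,
                            "fnr": m.fnr if m else None,
                            "ntpr": m.ntpr if m else None,
                            "het_cr": None,
                        }
                    )

                for vtype in (SNV, INDEL):
                    try:
                        value = allreads_concordance(ref_filtered, filtered, vtype)
                    except ValueError:
                        value = None
                    allreads_rows.append(
                        {
                            "depth": depth,
                            "replicate": rep,
                            "vtype": vtype,
                            "concordance": value,
                        }
                    )

                hla_calls = generate_hla_calls(
                    truth_hla, hla_mod.TOOLS, depth, seed, config
                )
                truth_by_gene = {g.gene: g for g in truth_hla}
                for (tool, gene), call in hla_calls.items():
                    score = (
                        None
                        if call.is_na
                        else hla_mod.score_genotype(truth_by_gene[gene], call)
                    )
                    hla_rows.append(
                        {
                            "depth": depth,
                            "replicate": rep,
                            "tool": tool,
                            "gene": gene,
                            "score": score,
                        }
                    )
        except Exception:
            logger.exception("depth %.3g failed; skipping", depth)
            failed_depths.append(depth)
            continue

    _frame(stage_rows).to_csv(outdir / "depth_stages.tsv", sep="\t", index=False)
    _frame(count_rows).to_csv(outdir / "variant_counts.tsv", sep="\t", index=False)
    _frame(tstv_rows).to_csv(outdir / "tstv.tsv", sep="\t", index=False)
    _frame(excl_rows).to_csv(outdir / "exclusion_rates.tsv", sep="\t", index=False)
    _frame(conc_rows).to_csv(outdir / "array_concordance.tsv", sep="\t", index=False)
    _frame(allreads_rows).to_csv(
        outdir / "allreads_concordance.tsv", sep="\t", index=False
    )
    _frame(hla_rows).to_csv(outdir / "hla_accuracy.tsv", sep="\t", index=False)

    summary_rows = _build_summary(
        conc_rows, tstv_rows, count_rows, allreads_rows, hla_rows, stage_rows
    )
    _frame(summary_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config_digest=config.digest(),
        version=__version__,
        base_seed=config.base_seed,
        depth_schedule=list(config.depth_schedule),
        seeds={f"{d:g}": list(plans[d].seeds) for d in schedule},
        outputs=list(_OUTPUT_FILES),
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True, default=list) + "\n"
    )
    if failed_depths:
        raise RuntimeError(f"sweep failed at depths {failed_depths}")
    return manifest


def _frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def _build_summary(conc, tstv, counts, allreads, hla, stages) -> list[dict]:
    """One row per (depth, replicate, metric, stratum); no duplicates."""
    rows: list[dict] = []

    def add(depth, rep, metric, stratum, value):
        rows.append(
            {
                "depth": depth,
                "replicate": rep,
                "metric": metric,
                "stratum": stratum,
                "value": value,
            }
        )

    for r in conc:
        for metric in ("cr", "fpr", "fnr", "ntpr", "het_cr"):
            if metric == "het_cr" and r["stratum"] != "all":
                continue
            add(r["depth"], r["replicate"], metric, r["stratum"], r[metric])
    for r in tstv:
        add(r["depth"], r["replicate"], "tstv", "all", r["tstv"])
    for r in counts:
        for metric in ("n_snv", "n_indel", "n_total"):
            add(r["depth"], r["replicate"], metric, "all", r[metric])
    for r in allreads:
        add(
            r["depth"],
            r["replicate"],
            f"allreads_cr_{'snv' if r['vtype'] == SNV else 'indel'}",
            "all",
            r["concordance"],
        )
    for r in stages:
        for metric in ("urd", "vd", "vdaf"):
            add(r["target_depth"], r["replicate"], metric, "all", r[metric])
    # per-tool HLA averages over available genes
    by_dataset: dict[tuple[float, int, str], dict[str, float | None]] = {}
    for r in hla:
        key = (r["depth"], r["replicate"], r["tool"])
        by_dataset.setdefault(key, {})[r["gene"]] = (
            None if r["score"] is None else 100.0 * r["score"]
        )
    for (depth, rep, tool), per_gene in sorted(by_dataset.items()):
        values = [v for v in per_gene.values() if v is not None]
        mean = float(np.mean(values)) if values else None
        add(depth, rep, f"hla_avg_{tool}", "all", mean)
    return rows


def make_report(
    outdir: str | Path,
    threshold_cr: float = 0.99,
    plots: bool = False,
) -> dict:
    """Aggregate replicate means from a sweep directory.

    Writes ``report_summary.tsv`` (replicate means and SDs per depth,
    metric and stratum) and ``report.json`` (threshold annotations, e.g.
    the first depth whose mean CR exceeds ``threshold_cr``).  With
    ``plots=True``, depth-vs-metric curves are rendered on a log-scaled
    depth axis under ``plots/``.
    """
    outdir = Path(outdir)
    summary_path = outdir / "summary.tsv"
    if not summary_path.exists():
        raise FileNotFoundError(f"no sweep summary at {summary_path}")
    summary = pd.read_csv(summary_path, sep="\t")
    if summary.empty:
        raise ValueError("sweep summary is empty")

    grouped = (
        summary.groupby(["depth", "metric", "stratum"], dropna=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_replicates="count")
        .reset_index()
        .sort_values(["metric", "stratum", "depth"], kind="mergesort")
    )
    grouped.to_csv(outdir / "report_summary.tsv", sep="\t", index=False)

    cr = grouped[(grouped["metric"] == "cr") & (grouped["stratum"] == "all")]
    above = cr[cr["mean"] > threshold_cr].sort_values("depth")
    first_depth = float(above["depth"].iloc[0]) if not above.empty else None
    report = {
        "threshold_cr": threshold_cr,
        "first_depth_cr_above_threshold": first_depth,
        "n_depths": int(cr.shape[0]),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    if plots:
        _render_plots(grouped, outdir / "plots")
    return report


def _render_plots(grouped: pd.DataFrame, plotdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    for metric in ("cr", "fpr", "fnr", "ntpr", "tstv", "n_total"):
        sub = grouped[(grouped["metric"] == metric) & (grouped["stratum"] == "all")]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(sub["depth"], sub["mean"], marker="o", ms=3)
        ax.set_xscale("log")
        ax.set_xlabel("depth (x, log scale)")
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(plotdir / f"{metric}_vs_depth.png", dpi=120)
        plt.close(fig)
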