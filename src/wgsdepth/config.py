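"""Run configuration for the depth-titration experiment.

Every source of randomness in the package flows from
:attr:`SimulationConfig.base_seed`.  Each simulated dataset gets the derived
seed ``base_seed + 1000 * depth_index + replicate_id`` so that any single
dataset can be regenerated in isolation without replaying the whole sweep.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AAFSpec",
    "ErrorModel",
    "ReadAccountingModel",
    "HLAErrorConfig",
    "SimulationConfig",
    "default_depth_schedule",
]

DEPTH_MIN = 0.05
DEPTH_MAX = 410.0


def default_depth_schedule() -> list[float]:
    """54 depth levels spanning 0.05x-410x.

    The grid is the union of a 30-point log-spaced series and a 25-point
    linear series from 10x upward (they share the 410x endpoint), so both
    the sub-1x regime and the high-depth regime are sampled at roughly even
    visual density on a log axis.  Fully overridable through
    :attr:`SimulationConfig.depth_schedule`.
    """
    log_part = np.geomspace(DEPTH_MIN, DEPTH_MAX, 30)
    lin_part = np.linspace(10.0, DEPTH_MAX, 25)
    levels = np.unique(np.round(np.concatenate([log_part, lin_part]), 3))
    return [float(x) for x in levels]


@dataclass
class AAFSpec:
    """Alternate-allele-frequency distribution of the truth catalog.

    The default Beta(0.3, 0.7) gives a site-frequency-like spectrum whose
    mass covers all five AAF strata (>=0.5 down to <0.01) used in the
    stratified concordance analysis.  Setting ``fixed`` pins every site to
    one frequency (useful for Hardy-Weinberg checks).
    """

    alpha: float = 0.3
    beta: float = 0.7
    fixed: float | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.fixed is not None:
            return np.full(n, float(self.fixed))
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass
class ErrorModel:
    """Parameters of the emulated caller output.

    Depth acts per site: the read count at a site is Poisson(depth) and a
    site needs at least ``min_reads`` reads to produce a call.  With
    ``read_sampling`` on, diploid genotypes are re-called from a binomial
    allele-count draw through a maximum-likelihood genotyper with per-read
    error ``per_read_error`` — this is what makes heterozygote accuracy
    improve mechanistically with depth.  The four ``*_error_rate`` knobs
    inject additional depth-independent genotype errors (used for parameter
    recovery experiments); they default to 0.

    Annotation values are drawn from a "clean" component confined to the
    hard-filter passing ranges, plus an "artifact" component that pushes one
    item past its threshold.  The artifact weight has a low-coverage term
    decaying with depth (poorly supported sites at low coverage) and a
    HaplotypeScore term that switches on above
    ``haplotype_artifact_onset`` and grows to ``haplotype_artifact_max`` at
    410x, emulating haplotype-count inflation in very deep data.

    ``indel_repr_error_*`` control the probability that an indel is
    reported in a non-canonical allele representation (local assembly and
    left-alignment ambiguity), decaying slowly with depth — this is what
    makes indel all-reads concordance lag far behind SNVs.
    """

    per_read_error: float = 0.001
    min_reads: int = 2
    read_sampling: bool = True
    het_error_rate: float = 0.0
    hom_error_rate: float = 0.0
    ref_error_rate: float = 0.0
    alt_error_rate: float = 0.0
    fp_site_rate: float = 0.001
    low_cov_artifact_rate: float = 0.05
    low_cov_artifact_scale: float = 5.0
    haplotype_artifact_max: float = 0.16
    haplotype_artifact_onset: float = 100.0
    indel_repr_error_max: float = 0.5
    indel_repr_error_scale: float = 120.0

    def validate(self) -> None:
        for name in (
            "per_read_error",
            "het_error_rate",
            "hom_error_rate",
            "ref_error_rate",
            "alt_error_rate",
            "fp_site_rate",
            "low_cov_artifact_rate",
            "haplotype_artifact_max",
            "indel_repr_error_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.low_cov_artifact_scale <= 0 or self.indel_repr_error_scale <= 0:
            raise ValueError("artifact decay scales must be positive")
        if self.haplotype_artifact_onset <= 0:
            raise ValueError("haplotype_artifact_onset must be positive")


@dataclass
class ReadAccountingModel:
    """Per-stage base retention used for the depth-stage ledger.

    Trimming and mapping remove small, depth-independent fractions of
    bases; duplicate removal is the dominant loss and its fraction grows
    with depth (PCR/optical duplicates saturate a library), modelled as
    ``dup_loss_max * d / (d + dup_half_sat)``.  The defaults are calibrated
    so a ~500x library loses about 31% of its raw bases by the variant
    stage while a ~10x library loses about 13%.
    """

    trim_retention: float = 0.99
    map_retention: float = 0.98
    dup_loss_max: float = 0.304
    dup_half_sat: float = 19.6

    def validate(self) -> None:
        if not (0 < self.trim_retention <= 1 and 0 < self.map_retention <= 1):
            raise ValueError("retentions must be in (0, 1]")
        if not 0 <= self.dup_loss_max < 1:
            raise ValueError("dup_loss_max must be in [0, 1)")
        if self.dup_half_sat <= 0:
            raise ValueError("dup_half_sat must be positive")


@dataclass
class HLAErrorConfig:
    """Per-tool, per-gene allele miscall probabilities.

    ``miscall`` maps tool -> gene -> per-allele miscall probability at
    ``reference_depth``; ``None`` selects the built-in defaults emulating
    the observed per-gene behaviour of the five supported tools at medium
    depth.  Away from the reference depth the rate is scaled by
    ``(reference_depth / depth) ** depth_exponent`` (capped at 1), so
    typing improves with coverage and degrades below it.
    """

    miscall: dict[str, dict[str, float]] | None = None
    reference_depth: float = 13.7
    depth_exponent: float = 0.7

    def rate(self, tool: str, gene: str, depth: float) -> float:
        from . import hla  # deferred to avoid an import cycle

        table = self.miscall if self.miscall is not None else hla.DEFAULT_MISCALL
        if tool not in table:
            raise ValueError(f"unknown HLA tool {tool!r}")
        if gene not in hla.GENES:
            raise ValueError(f"unknown HLA gene {gene!r}")
        base = float(table[tool].get(gene, 0.0))
        if depth <= 0:
            raise ValueError("depth must be positive")
        scale = (self.reference_depth / depth) ** self.depth_exponent
        return min(1.0, base * scale)

    def validate(self) -> None:
        if self.reference_depth <= 0:
            raise ValueError("reference_depth must be positive")
        if self.miscall is not None:
            for tool, genes in self.miscall.items():
                for gene, v in genes.items():
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(
                            f"miscall[{tool!r}][{gene!r}] must be in [0, 1]"
                        )


@dataclass
class SimulationConfig:
    """Study conditions of one depth-titration run.

    Defaults describe a desk-scale diploid genome: 20,000 truth variants on
    10 Mb of effective (non-N) sequence, 18% indels, a transition share
    giving a genome-like Ts/Tv of ~2.1, 16% of SNVs on a microarray-like
    panel, 54 depth levels from 0.05x to 410x with 10 seeded replicates
    below the 45x threshold.
    """

    genome_length: int = 10_000_000
    n_variants: int = 20_000
    indel_fraction: float = 0.18
    ts_fraction: float = 0.677
    aaf_spec: AAFSpec = field(default_factory=AAFSpec)
    array_fraction: float = 0.16
    depth_schedule: list[float] = field(default_factory=default_depth_schedule)
    replicate_threshold: float = 45.0
    n_replicates: int = 10
    error_model: ErrorModel = field(default_factory=ErrorModel)
    accounting: ReadAccountingModel = field(default_factory=ReadAccountingModel)
    hla_error: HLAErrorConfig = field(default_factory=HLAErrorConfig)
    hla_truth: dict[str, tuple[str, str]] | None = None
    filtration: str = "hard_filter"
    chrom: str = "1"
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must be in [0, 1]")
        if not 0.0 <= self.array_fraction <= 1.0:
            raise ValueError("array_fraction must be in [0, 1]")
        if not self.depth_schedule:
            raise ValueError("depth_schedule must be non-empty")
        if any(d <= 0 for d in self.depth_schedule):
            raise ValueError("depth_schedule values must be positive")
        if self.replicate_threshold <= 0:
            raise ValueError("replicate_threshold must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.error_model.validate()
        self.accounting.validate()
        self.hla_error.validate()

    # -- seeds -----------------------------------------------------------
    def dataset_seed(self, depth_index: int, replicate_id: int) -> int:
        """Collision-free per-dataset seed (stays well below 2**31)."""
        if not 0 <= replicate_id < 1000:
            raise ValueError("replicate_id must be in [0, 1000)")
        return int(self.base_seed + 1000 * depth_index + replicate_id)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "aaf_spec" in data and isinstance(data["aaf_spec"], dict):
            data["aaf_spec"] = AAFSpec(**data["aaf_spec"])
        if "error_model" in data and isinstance(data["error_model"], dict):
            data["error_model"] = ErrorModel(**data["error_model"])
        if "accounting" in data and isinstance(data["accounting"], dict):
            data["accounting"] = ReadAccountingModel(**data["accounting"])
        if "hla_error" in data and isinstance(data["hla_error"], dict):
            data["hla_error"] = HLAErrorConfig(**data["hla_error"])
        if data.get("hla_truth") is not None:
            data["hla_truth"] = {
                gene: tuple(pair) for gene, pair in data["hla_truth"].items()
            }
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def digest(self) -> str:
        """Stable sha256 over the canonical JSON form of the config."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()
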