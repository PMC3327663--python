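"""Configuration objects for the screen simulator and analysis pipeline.

A single :class:`SimConfig` governs every stage: library construction,
two-arm clonal selection, measurement, hit calling, the growth-assay
confirmation round and the qPCR induction check.  Configs are plain
dataclasses serialisable to/from JSON so a whole run is reproducible from
one document plus one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass(frozen=True)
class HitBlock:
    """A block of planted hit genes sharing one pair of fitness effects.

    ``s_normoxia`` / ``s_hypoxia`` are per-passage relative growth-rate
    changes caused by *full* knockdown of the gene under each condition
    (dimensionless; −1 halves the doubling exponent contribution of a
    fully efficacious shRNA, +1 doubles it).
    """

    n_genes: int
    s_normoxia: float = 0.0
    s_hypoxia: float = 0.0


@dataclass(frozen=True)
class GrowthConfig:
    """7-day growth-assay parameters.

    ``doublings`` is the number of population doublings a neutral clone
    undergoes during the assay week (default 7, one per day from the
    1×10⁴ seed).  ``replicate_cv`` is the multiplicative coefficient of
    variation of a replicate's final count.
    """

    n0: float = 1e4
    doublings: float = 7.0
    replicate_cv: float = 0.05
    n_replicates: int = 3


@dataclass(frozen=True)
class QpcrConfig:
    """Real-time PCR simulation parameters.

    Ct values live on the threshold-cycle scale; ``noise_sd`` is the
    per-replicate technical standard deviation in cycles.  The reference
    gene (beta-actin) and the two HIF-1 positive controls are always
    included in simulated plates.
    """

    noise_sd: float = 0.1
    reference_gene: str = "ACTB"
    reference_ct: float = 17.0
    base_ct_low: float = 18.0
    base_ct_high: float = 30.0
    control_folds: dict = field(
        default_factory=lambda: {"GLUT1": 7.0, "PDK1": 4.0}
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Downstream statistical choices shared by the pipeline stages."""

    alpha: float = 0.05
    fold_min: float = 2.0
    use_welch: bool = False
    require_direction: bool = True
    pseudocount: float = 0.0
    n_negative_controls: int = 5
    expression_fn_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration.

    Screen-arm fields mirror the pooled-screen design: ``passages``
    serial passages under 21% vs 1% O2, a multinomial ``bottleneck`` of
    cells carried over at each passage, and a log-normal measurement
    noise with coefficient of variation ``measurement_cv`` applied to
    the final per-probe relative abundances before a ``detection_floor``.
    """

    n_genes: int = 1000
    probes_per_gene_mean: float = 4.0
    fraction_expressed: float = 0.8
    hit_spec: tuple[HitBlock, ...] = ()
    passages: int = 10
    doublings_per_passage: float = 3.0
    bottleneck: int | None = 1_000_000
    measurement_cv: float = 0.2
    detection_floor: float = 1e-3
    signal_scale: float = 1e4
    fold_threshold: float = 5.0
    min_shrnas: int = 4
    efficacy_low: float = 0.7
    efficacy_high: float = 1.0
    hit_min_probes: int | None = None
    seed: int = 0
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.probes_per_gene_mean < 1:
            raise ConfigError("probes_per_gene_mean must be >= 1")
        if not 0.0 <= self.fraction_expressed <= 1.0:
            raise ConfigError("fraction_expressed must lie in [0, 1]")
        if self.passages <= 0:
            raise ConfigError("passages must be positive")
        if self.bottleneck is not None and self.bottleneck <= 0:
            raise ConfigError("bottleneck must be positive or None")
        if self.measurement_cv < 0:
            raise ConfigError("measurement_cv must be non-negative")
        if self.detection_floor < 0:
            raise ConfigError("detection_floor must be non-negative")
        if self.fold_threshold <= 1:
            raise ConfigError("fold_threshold must exceed 1")
        if self.min_shrnas < 1:
            raise ConfigError("min_shrnas must be >= 1")
        if not 0.0 <= self.efficacy_low <= self.efficacy_high <= 1.0:
            raise ConfigError("efficacy range must satisfy 0 <= low <= high <= 1")
        n_hits = sum(b.n_genes for b in self.hit_spec)
        if n_hits > self.n_genes * self.fraction_expressed:
            raise ConfigError(
                "hit_spec plants more genes than the expected expressed pool "
                f"({n_hits} > {self.n_genes} * {self.fraction_expressed})"
            )

    @property
    def hit_probe_floor(self) -> int:
        """Minimum probe count required of a gene before a hit is planted there."""
        return self.min_shrnas if self.hit_min_probes is None else self.hit_min_probes

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "hit_spec" in d:
            d["hit_spec"] = tuple(
                b if isinstance(b, HitBlock) else HitBlock(**b) for b in d["hit_spec"]
            )
        for key, sub in (("growth", GrowthConfig), ("qpcr", QpcrConfig),
                         ("analysis", AnalysisConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def demo_config(seed: int = 0) -> SimConfig:
    """The benchmark screen: 1,000 genes, ~4 shRNAs each, 20 planted hits.

    Ten genes are required for growth under hypoxia (s_hypoxia = −0.5,
    their shRNAs drop out of the hypoxic arm and end up underrepresented)
    and ten under normoxia (s_normoxia = −0.5, the RNF126-style pattern,
    overrepresented in the hypoxia/normoxia ratio).  |s| = 0.5 with
    efficacy in [0.7, 1] over 10 passages of 3 doublings is a strong,
    unambiguous phenotype, the regime the screen's 5-fold threshold was
    designed for.
    """
    return SimConfig(
        n_genes=1000,
        probes_per_gene_mean=4.0,
        fraction_expressed=0.8,
        hit_spec=(
            HitBlock(n_genes=10, s_normoxia=0.0, s_hypoxia=-0.5),
            HitBlock(n_genes=10, s_normoxia=-0.5, s_hypoxia=0.0),
        ),
        seed=seed,
    )


def null_config(seed: int = 0) -> SimConfig:
    """An all-neutral screen (no planted hits) for calibration runs."""
    return SimConfig(n_genes=1000, hit_spec=(), seed=seed)
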