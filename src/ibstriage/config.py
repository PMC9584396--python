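"""Simulation and pipeline configuration.

A single :class:`SimulationConfig` drives every synthetic generator.  All
randomness flows from its integer ``seed`` through named
``numpy.random.Generator`` instances — no global RNG state is touched, so the
same config always yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions at desk scale: an 11-case /
    18-control cohort, a 2000-gene array with 200 genes planted as
    differentially expressed, well-level Ct noise of 0.15 cycles, and the
    replicate structure of the qPCR experiments (2-6 independent plates per
    gene, 3-6 wells per plate, 6 treatment replicates per arm).

    Parameters
    ----------
    seed
        Master seed; every generator derives its stream from it.
    n_genes, n_de_genes
        Array size and number of genes carrying a planted case-vs-control
        effect.
    n_cases, n_controls
        Cohort arm sizes.
    log2_effect_range
        (lo, hi) magnitude range, in log2 units, of planted array effects;
        signs are drawn at random (both induced and repressed genes occur).
    array_noise_sd
        Per-measurement Gaussian noise of log2 array intensities.
    ct_noise_sd
        Per-well Gaussian noise of Ct values, in cycles.
    plate_replicates, well_replicates
        Inclusive ranges from which the number of independent qPCR plates per
        gene and wells per (sample, plate) are drawn.
    n_pooled_controls
        Number of control subjects whose simulated Ct values are averaged to
        emulate the physically pooled control RNA aggregate.
    treatment_replicates
        Replicates per arm in the treated-vs-vehicle cell experiments.
    amplification_efficiency
        Fold amplification per PCR cycle; 2.0 is the 100%-efficiency
        convention under which one cycle equals one doubling.
    treatment_fold_map
        Planted linear fold (treated/vehicle) per gene for the cell
        experiments.
    """

    seed: int = 0
    n_genes: int = 2000
    n_de_genes: int = 200
    n_cases: int = 11
    n_controls: int = 18
    log2_effect_range: tuple[float, float] = (0.5, 2.0)
    array_noise_sd: float = 0.5
    ct_noise_sd: float = 0.15
    plate_replicates: tuple[int, int] = (2, 6)
    well_replicates: tuple[int, int] = (3, 6)
    n_pooled_controls: int = 8
    treatment_replicates: int = 6
    amplification_efficiency: float = 2.0
    treatment_fold_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cases < 0 or self.n_controls < 0:
            raise InvalidConfigError("counts must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise InvalidConfigError(
                f"n_de_genes={self.n_de_genes} must lie in [0, n_genes={self.n_genes}]"
            )
        if self.array_noise_sd < 0 or self.ct_noise_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        lo, hi = self.log2_effect_range
        if lo < 0 or hi < lo:
            raise InvalidConfigError("log2_effect_range must satisfy 0 <= lo <= hi")
        for rng_name in ("plate_replicates", "well_replicates"):
            lo, hi = getattr(self, rng_name)
            if lo < 1 or hi < lo:
                raise InvalidConfigError(f"{rng_name} must be a valid range [lo, hi] with lo >= 1")
        if self.amplification_efficiency <= 1:
            raise InvalidConfigError("amplification_efficiency must exceed 1")
        for gene, fold in dict(self.treatment_fold_map).items():
            if fold <= 0:
                raise InvalidConfigError(f"planted fold for {gene} must be > 0, got {fold}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatment_fold_map"] = dict(self.treatment_fold_map)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("log2_effect_range", "plate_replicates", "well_replicates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw.get("simulation", raw))


def load_pipeline_config(path: str | Path) -> dict:
    """Load the full per-stage pipeline YAML (simulation block plus stage options)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("pipeline config must be a mapping")
    return raw
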