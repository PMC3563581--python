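"""Configuration objects for the simulator and the pipeline.

All thresholds of the genotyping / QC / mapping cascade live in
:class:`PipelineParams`; the synthetic-family generator is configured by
:class:`SimConfig`.  Both round-trip through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class SimConfig:
    """Study design of a simulated outbred full-sib RAD-seq family.

    Defaults emulate a single salmonid full-sib cross: a 29-chromosome
    diploid (2n = 58), 96 offspring, ~49 reads per locus per individual,
    and a minority of collapsed-paralog loci that present as universal
    heterozygotes.

    Parameters
    ----------
    n_chromosomes, markers_per_chromosome :
        Map skeleton; markers are equally informative a priori.
    inter_marker_rf_female, inter_marker_rf_male :
        True recombination fraction between adjacent clean markers, per sex,
        in [0, 0.5).  Transmission is a Markov chain on these fractions.
        Defaults put the simulated female genome near the ~3,000 cM expected
        for a salmonid genome (~2.6 cM per interval at 40 markers per
        chromosome), with male recombination reduced relative to female;
        observed map lengths inflate above the truth when calls are noisy.
    n_offspring :
        Full-sib family size (parents are simulated in addition).
    mean_coverage, coverage_dispersion :
        Negative-binomial reads per locus per individual; ``coverage_dispersion``
        is the NB size parameter k (variance = mu + mu^2/k, so k = mu gives
        variance ~ 2 mu).  ``None`` makes coverage deterministic at
        ``round(mean_coverage)``.
    error_rate :
        Per-read probability that the SNP-site allele is misread (the read
        then carries the other allele).
    psv_fraction :
        Fraction of all simulated loci that are collapsed paralogs (two
        duplicated copies with a fixed difference sequenced under one tag).
        PSV loci are generated in addition to the clean markers — genome
        duplication creates extra apparent loci, it does not remove real
        ones — and interleaved among them.  The default mirrors the roughly
        half of putative RAD SNPs that salmonid data loses to segregation
        distortion, most of it paralog-driven.
    informativeness_mix :
        Proportions of clean-locus cross types
        (het x het, het female only, het male only, fixed difference).
    qual_fail_fraction :
        Fraction of reads emitted with qualities that fail the 80% rule.
    """

    n_chromosomes: int = 29
    markers_per_chromosome: int = 40
    inter_marker_rf_female: float = 0.025
    inter_marker_rf_male: float = 0.021
    n_offspring: int = 96
    mean_coverage: float = 49.0
    coverage_dispersion: float | None = 49.0
    error_rate: float = 0.005
    psv_fraction: float = 0.45
    informativeness_mix: tuple[float, float, float, float] = (0.50, 0.235, 0.235, 0.03)
    qual_fail_fraction: float = 0.02
    barcode_length: int = 5
    tag_length: int = 59
    read_length: int = 80
    platform: str = "GAII"
    lane_size: int = 16
    seed: int = 0

    def validate(self) -> "SimConfig":
        probs = {
            "error_rate": self.error_rate,
            "qual_fail_fraction": self.qual_fail_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.psv_fraction < 1.0:
            raise ConfigError("psv_fraction must be in [0, 1)")
        for name in ("inter_marker_rf_female", "inter_marker_rf_male"):
            rf = getattr(self, name)
            if not 0.0 <= rf < 0.5:
                raise ConfigError(f"{name} must be in [0, 0.5), got {rf}")
        if self.n_offspring < 1:
            raise ConfigError("n_offspring must be >= 1")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ConfigError("need at least one chromosome and one marker")
        mix = tuple(self.informativeness_mix)
        if len(mix) != 4 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError(
                "informativeness_mix must be 4 non-negative proportions summing to 1"
            )
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if self.coverage_dispersion is not None and self.coverage_dispersion <= 0:
            raise ConfigError("coverage_dispersion must be positive or None")
        layout = self.barcode_length + 6 + self.tag_length
        if self.read_length < layout:
            raise ConfigError(
                f"read_length {self.read_length} too short for barcode + remnant "
                f"+ tag layout ({layout} nt)"
            )
        if self.platform not in ("GAII", "HiSeq"):
            raise ConfigError("platform must be 'GAII' or 'HiSeq'")
        return self


@dataclass
class PipelineParams:
    """Every tunable threshold of the analysis cascade, in stage order."""

    # read processing
    quality_threshold: float = 0.80
    barcode_length: int = 5
    remnant: str = "TGCAGG"
    # catalog
    min_tag_count: int = 6
    max_mismatches: int = 3
    # genotype calling
    min_total_reads: int = 10
    het_low: float = 0.28
    het_high: float = 0.80
    # marker QC
    max_inheritance_error: float = 0.10
    distortion_alpha: float = 0.05
    max_missing: float = 0.25
    # linkage mapping
    lod_bin: float = 12.0
    rf_bin: float = 0.01
    lod_group: float = 6.0
    ripple_window: int = 4
    min_group_size: int = 4
    # cross-species tag matching
    unmapped_max_mismatches: int = 1
    mapped_max_mismatches: int = 4
    min_overlap: int = 56

    def validate(self) -> "PipelineParams":
        if not 0.0 < self.quality_threshold <= 1.0:
            raise ConfigError("quality_threshold must be in (0, 1]")
        for name in ("het_low", "het_high", "max_inheritance_error",
                     "distortion_alpha", "max_missing", "rf_bin"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.het_low > self.het_high:
            raise ConfigError("het_low must not exceed het_high")
        if self.min_tag_count < 1 or self.min_total_reads < 1:
            raise ConfigError("count thresholds must be >= 1")
        if self.lod_bin < 0 or self.lod_group < 0:
            raise ConfigError("LOD thresholds must be non-negative")
        if self.ripple_window < 2:
            raise ConfigError("ripple_window must be >= 2")
        if self.min_group_size < 2:
            raise ConfigError("min_group_size must be >= 2")
        if not set(self.remnant) <= set("ACGT"):
            raise ConfigError("remnant must be an ACGT string")
        return self


@dataclass
class PipelineConfig:
    """Bundle of simulation design, analysis thresholds and a master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0
    outdir: str = "radmap_out"

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.params.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["informativeness_mix"] = list(d["sim"]["informativeness_mix"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = dict(d.get("sim", {}))
        if "informativeness_mix" in sim:
            sim["informativeness_mix"] = tuple(sim["informativeness_mix"])
        cfg = cls(
            sim=SimConfig(**sim),
            params=PipelineParams(**d.get("params", {})),
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "radmap_out")),
        )
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
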