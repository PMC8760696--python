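"""Threshold and simulation configuration.

Every tunable the pipeline uses lives here with its default value, so that
a single TOML file can override any of them (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds.

    Defaults follow the validated panel workflow: variants below 5% VAF are
    treated as potential sequencing errors, the 1–5% window is inspected for
    database-pathogenic variants, population polymorphisms are removed at a
    1% MAF cutoff, and amplicons are flagged below 1000x / 100x mean depth.
    """

    vaf_retain: float = 0.05          # calls with vaf < this are artifact-suspect
    rescue_vaf_floor: float = 0.01    # analysis detection floor
    maf_cutoff: float = 0.01          # population-common exclusion, any database
    recurrence_fraction: float = 0.5  # "majority of samples": strictly more than this
    sanger_min_vaf: float = 0.15      # Sanger-confirmability flag (inclusive)
    coverage_critical: float = 100.0
    coverage_warn: float = 1000.0
    target_depth_nominal: float = 5000.0  # reporting only
    merge_large_event_length: int = 25    # > this many bases -> structural caller wins
    gc_window: int = 30
    gc_flag: float = 0.60             # window counts as high-GC above this
    counting_mode: str = "merged"     # sensitivity denominator: "merged" | "per_app"
    concordance_mode: str = "jaccard"  # "jaccard" | "both_detected"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generators.

    ``seed`` fully determines every output: identical configs produce
    byte-identical files. Distributional choices (lognormal depth, logistic
    GC dropout, Beta artifact VAFs) are plumbing; the structurally meaningful
    values are the 5000x target depth, the 1% VAF floor and the 4-read
    detection floor that together reproduce the panel's detection limit.
    """

    seed: int = 0
    n_samples: int = 10
    n_jak2_like: int = 7    # samples carrying the shared exon-14 SNV driver
    n_calr_like: int = 3    # samples carrying a private exon-9 frameshift driver
    target_depth: float = 5000.0
    depth_dispersion: float = 0.3         # lognormal sigma
    gc_dropout_midpoint: float = 0.56     # logistic midpoint of amplification efficiency
    gc_dropout_width: float = 0.011
    error_artifact_rate: float = 3.0      # per-sample Poisson mean
    artifact_vaf_a: float = 1.2           # Beta(a, b) artifact VAFs ...
    artifact_vaf_b: float = 60.0
    artifact_vaf_max: float = 0.035       # ... truncated below the error band
    systematic_artifact_fraction: float = 0.8
    n_systematic_artifacts: int = 2
    germline_het_count: int = 15
    passenger_max: int = 4
    min_alt_reads: int = 4                # caller detection floor (reads)
    vaf_floor: float = 0.01               # caller detection floor (fraction)
    n_amplicons: int = 219
    amplicon_length_range: tuple[int, int] = (150, 250)

    def __post_init__(self) -> None:
        if self.n_jak2_like + self.n_calr_like > self.n_samples:
            raise ValueError("driver mix exceeds sample count")
        for name in ("vaf_floor", "systematic_artifact_fraction", "artifact_vaf_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_alt_reads < 0 or self.n_samples < 0:
            raise ValueError("counts must be non-negative")


def load_config(path: str | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, overriding defaults from a TOML file.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
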