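"""Simulation configuration.

The defaults describe the experimental setting the pipeline targets: four
unamended dark seawater incubations sampled daily for metatranscriptomics
(4-6 samples each) and every half day for microscopy counts, in which
heterotrophic bacteria peak around day 4 and heterotrophic flagellates (HF)
rise from ~10^3 to ~10^4 cells/mL with a peak around day 5-6, while
phototrophic flagellates (PF) and Synechococcus decay in the dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

TROPHIC_MODES = ("heterotroph", "mixotroph", "phototroph")


@dataclass
class SimulationConfig:
    # experiment layout
    n_incubations: int = 4
    samples_per_incubation: tuple[int, int] = (4, 6)
    duration: float = 8.0          # days
    count_interval: float = 0.5    # days between microscopy counts

    # cell-count ranges (cells/mL); (low, high) of the uniform draw per incubation
    bacteria_init: tuple[float, float] = (7e5, 9e5)
    bacteria_peak: tuple[float, float] = (1.5e6, 2.5e6)
    bacteria_peak_day: tuple[float, float] = (3.5, 4.5)
    hf_init: tuple[float, float] = (5e2, 1e3)
    hf_peak: tuple[float, float] = (7e3, 1.3e4)
    hf_peak_day: tuple[float, float] = (5.0, 6.5)
    hf_lag_days: tuple[float, float] = (1.5, 2.5)
    pf_init: tuple[float, float] = (1e3, 3e3)
    syn_init: tuple[float, float] = (1.5e4, 2.5e4)
    decay_rate: float = 0.35       # 1/day, exponential loss of PF / Synechococcus
    count_noise_cv: float = 0.1    # microscopy counting error (CV), distinct from
                                   # the expression noise below

    # community transcript table
    n_transcripts: int = 20000
    ko_annotation_fraction: float = 0.30
    n_kos: int = 800
    n_marker_kos: int = 50
    marker_fold_change: float = 4.0   # growth vs lag expression ratio of planted markers
    marker_expression_boost: float = 5.0  # markers are highly expressed genes
    n_hk_kos: int = 104
    n_photo_kos: int = 25
    two_ko_fraction: float = 0.08     # fraction of annotated transcripts carrying 2 KOs

    # reference species and alignment tables
    n_species: int = 20
    n_cds_per_species: int = 120
    # (fraction of species, % nucleotide divergence from the reference);
    # the remainder of species is absent from the incubations
    species_identity_profile: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.5, 0.4), (0.3, 7.5)]
    )
    tie_fraction: float = 0.02        # transcripts with two equal-score top hits
    min_present_transcripts: int = 150

    # species-level expression / trophic structure
    trophic_mode_proportions: tuple[float, float, float] = (0.48, 0.32, 0.20)
    relative_expression_effect: float = 4.0  # heterotroph / phototroph marker share
    n_species_marker_genes: int = 12
    genes_absent_in_phototrophs: int = 2
    noise_cv: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_incubations < 1:
            raise ConfigError("need at least one incubation")
        lo, hi = self.samples_per_incubation
        if not (1 <= lo <= hi):
            raise ConfigError("samples_per_incubation must be a valid (low, high) range")
        for name in ("ko_annotation_fraction", "two_ko_fraction", "tie_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.trophic_mode_proportions) - 1.0) > 1e-9:
            raise ConfigError("trophic_mode_proportions must sum to 1")
        if any(p < 0 for p in self.trophic_mode_proportions):
            raise ConfigError("trophic_mode_proportions must be non-negative")
        for pop in ("bacteria", "hf"):
            init_hi = getattr(self, f"{pop}_init")[1]
            peak_lo = getattr(self, f"{pop}_peak")[0]
            if peak_lo <= init_hi:
                raise ConfigError(f"{pop}_peak range must lie strictly above {pop}_init range")
        if self.bacteria_peak_day[1] >= self.hf_peak_day[0]:
            raise ConfigError("bacterial peak must precede the HF peak")
        if self.hf_peak_day[1] >= self.duration:
            raise ConfigError(
                "duration too short to place both peaks: the HF peak "
                f"(up to day {self.hf_peak_day[1]}) must fall before day {self.duration}"
            )
        if self.n_marker_kos + self.n_hk_kos + self.n_photo_kos > self.n_kos:
            raise ConfigError("marker + housekeeping + photosynthesis KOs exceed the KO pool")
        profile_total = sum(f for f, _ in self.species_identity_profile)
        if not self.species_identity_profile or profile_total > 1.0 + 1e-9:
            raise ConfigError("species_identity_profile fractions must be non-empty and sum to <= 1")
        if self.noise_cv < 0 or self.count_noise_cv < 0:
            raise ConfigError("noise CVs must be non-negative")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species_identity_profile"] = [list(p) for p in self.species_identity_profile]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for key, val in d.items():
            default = cls.__dataclass_fields__[key].default  # type: ignore[attr-defined]
            if isinstance(default, tuple) and isinstance(val, (list, tuple)):
                d[key] = tuple(val)
        if "species_identity_profile" in d:
            d["species_identity_profile"] = [tuple(p) for p in d["species_identity_profile"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
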