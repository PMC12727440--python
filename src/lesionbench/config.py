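"""Run configuration: every knob of the benchmark in one serializable object.

A run is reproduced bit-exactly by its config: the master seed is the only
source of randomness, and every stochastic operation derives a documented
per-purpose subseed from it (CRC32 of ``"<master>:<purpose>:<indices>"``,
kept below 2^31).
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["LesionProfile", "RunConfig", "subseed"]


def subseed(master_seed: int, purpose: str, *indices) -> int:
    """Deterministic per-purpose RNG seed derived from the master seed."""
    key = ":".join([str(master_seed), purpose, *map(str, indices)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class LesionProfile:
    """One simulated patient profile: lesion morphology plus acquisition gain."""

    tbi_id: str
    n_clusters: int
    target_volume_mm3: float
    laterality: str = "bilateral"
    lesion_intensity: float = 30.0  # hypointense (CSF-like) fill level
    lesion_noise_sd: float = 3.0
    intensity_gain: float = 1.0  # global scanner-gain difference vs controls


@dataclass
class RunConfig:
    # phantom
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissue_means: tuple[float, float, float, float] = (0.0, 30.0, 70.0, 100.0)
    noise_sd: float = 5.0
    n_roi_pairs: int = 31
    # deformations
    warp_max_magnitude_mm: float = 3.0
    warp_smooth_sigma_vox: float = 4.0
    # study layout
    profiles: list[LesionProfile] = field(default_factory=list)
    n_hc_per_tbi: int = 10
    # simulation / fill
    fwhm_mm: float = 2.0
    contrast_threshold: float = 10.0
    # parcellation
    gm_band: tuple[float, float] = (50.0, 85.0)
    reassign_radius: float = 3.0
    coverage_floor: float = 0.5
    parcellation_attempts: int = 2
    # statistics
    outlier_k: float = 1.5
    hist_bins: int = 128
    # reproducibility
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        profiles = [
            p if isinstance(p, LesionProfile) else LesionProfile(**p)
            for p in d.pop("profiles", [])
        ]
        for key in ("grid_shape", "tissue_means", "gm_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(profiles=profiles, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_study_config(n_profiles: int = 4, n_hc_per_tbi: int = 3, seed: int = 0) -> RunConfig:
    """A desk-scale study configuration with mixed lesion profiles.

    Profiles span the heterogeneity the benchmark targets: small unilateral
    through large bilateral, varying cluster counts — a scaled-down analogue
    of a 14-profile clinical table.
    """
    base = [
        LesionProfile("TBI-A", 1, 60.0, "unilateral-right", intensity_gain=1.10),
        LesionProfile("TBI-B", 3, 1500.0, "bilateral", intensity_gain=0.92),
        LesionProfile("TBI-C", 5, 4000.0, "bilateral", intensity_gain=1.18),
        LesionProfile("TBI-D", 2, 9000.0, "unilateral-left", intensity_gain=0.85),
        LesionProfile("TBI-E", 7, 6000.0, "bilateral", intensity_gain=1.05),
        LesionProfile("TBI-F", 4, 12000.0, "bilateral", intensity_gain=1.25),
    ]
    return RunConfig(
        profiles=base[:n_profiles],
        n_hc_per_tbi=n_hc_per_tbi,
        master_seed=seed,
    )
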