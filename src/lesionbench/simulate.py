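"""Construction of (lesion-free, lesioned) image pairs with a bit-exact
outside-mask identity guarantee.

A simulated set couples one healthy-control-like volume (the lesion-free
ground truth) with a copy carrying an inserted hypointense lesion.  The
insertion blends the intensity-matched donor patch under a Gaussian-smoothed
repair mask, so the two images are bit-identical wherever the smoothed mask
weight is zero — the property every downstream accuracy comparison rests on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Volume, check_same_grid
from .phantom import DeformationField, warp_volume

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedSet",
    "fwhm_to_sigma",
    "build_lesion_free",
    "histmatch_scale",
    "insert_lesion",
    "simulation_qc",
]

#: smoothing kernels are truncated at this many standard deviations
SMOOTH_TRUNCATE_SD = 4.0


def fwhm_to_sigma(fwhm: float) -> float:
    """FWHM = 2*sqrt(2 ln 2) * sigma."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SimulatedSet:
    """One (lesion-free, lesioned, filled) triple with status bookkeeping."""

    set_id: str
    tbi_id: str
    hc_id: str
    lesion_free: Volume
    lesioned: Volume
    repair_mask: Volume
    smoothed_mask: Volume
    filled: Volume | None = None
    simulation_ok: bool | None = None
    qc_reasons: list[str] = field(default_factory=list)
    parcellation: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def mark_simulation(self, ok: bool, reasons: list[str]) -> None:
        # status flags are append-only: a failed set never returns to ok
        if self.simulation_ok is False and ok:
            raise ValueError(f"set {self.set_id}: cannot revive a failed simulation")
        self.simulation_ok = ok if self.simulation_ok is None else (self.simulation_ok and ok)
        self.qc_reasons.extend(reasons)


def build_lesion_free(hc: Volume, repaired_tbi: Volume, warp: DeformationField) -> Volume:
    """Resample the healthy-control image into the repaired-subject space.

    The repaired image defines the target grid only; its intensities (and in
    particular any lesion it once carried) never enter the output.
    """
    check_same_grid(hc, repaired_tbi, "HC and repaired subject")
    if hc.shape != warp.grid_shape:
        raise ValueError(f"grid mismatch: HC {hc.shape} vs warp {warp.grid_shape}")
    return warp_volume(hc, warp, order=1)


def histmatch_scale(
    source: Volume, reference: Volume, mask: np.ndarray
) -> tuple[Volume, float]:
    """Global multiplicative intensity match: scale the source so its masked
    median equals the reference's masked median.

    Returns (scaled volume, scale factor).  A single linear factor is the
    whole model; it is exactly reproducible and scale-equivariant
    (``histmatch_scale(c*src, ref)`` returns ``scale/c`` and the same image).
    """
    check_same_grid(source, reference, "source and reference")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("histogram-match mask is empty")
    src_med = float(np.median(source.data[mask]))
    ref_med = float(np.median(reference.data[mask]))
    if src_med == 0.0:
        raise ValueError("cannot scale: masked median of source is zero")
    scale = ref_med / src_med
    if scale <= 0:
        raise ValueError(f"non-positive intensity scale {scale:.4g}")
    return source.with_data(source.data * scale), scale


def smooth_mask(repair_mask: Volume, fwhm_mm: float) -> Volume:
    """Gaussian-smoothed binary mask, clipped to [0, 1]; fwhm 0 keeps it binary."""
    binary = repair_mask.data.astype(float)
    if fwhm_mm == 0:
        return repair_mask.with_data(binary)
    voxel = float(repair_mask.voxel_sizes[0])
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel
    w = ndimage.gaussian_filter(binary, sigma=sigma_vox, truncate=SMOOTH_TRUNCATE_SD)
    return repair_mask.with_data(np.clip(w, 0.0, 1.0))


def insert_lesion(
    lesion_free: Volume,
    tbi_matched: Volume,
    repair_mask: Volume,
    fwhm_mm: float = 2.0,
) -> tuple[Volume, Volume]:
    """Blend the matched lesion patch into the ground truth under a smoothed mask.

    ``out = (1 - w) * lesion_free + w * tbi_matched`` with ``w`` the
    FWHM-smoothed repair mask; voxels with ``w == 0`` are copied bit-exactly
    from the ground truth, so the outside-mask identity holds by construction.
    """
    check_same_grid(lesion_free, tbi_matched, "lesion-free and matched subject")
    check_same_grid(lesion_free, repair_mask, "lesion-free and repair mask")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if not repair_mask.data.any():
        logger.warning("insert_lesion called with an empty repair mask; output equals input")
        w = lesion_free.with_data(np.zeros(lesion_free.shape))
        return lesion_free.copy(), w

    w_vol = smooth_mask(repair_mask, fwhm_mm)
    w = w_vol.data
    blended = (1.0 - w) * lesion_free.data + w * tbi_matched.data
    out = np.where(w == 0.0, lesion_free.data, blended)
    return lesion_free.with_data(out), w_vol


def simulation_qc(
    sim: SimulatedSet, contrast_threshold: float = 10.0
) -> tuple[bool, list[str]]:
    """Verdict on a simulated pair; a failure excludes the whole set downstream.

    Checks: (a) bit-exact identity outside the smoothed-mask support,
    (b) in-mask intensity contrast between lesioned and ground truth of at
    least ``contrast_threshold``, (c) finiteness of both images.  An empty
    repair mask is degenerate but legal: the contrast check is vacuous.
    """
    reasons: list[str] = []
    lf, lesioned = sim.lesion_free.data, sim.lesioned.data
    w = sim.smoothed_mask.data
    mask = sim.repair_mask.data.astype(bool)

    if not (np.isfinite(lf).all() and np.isfinite(lesioned).all()):
        reasons.append("non-finite voxels present")

    outside = w == 0.0
    if not np.array_equal(lf[outside], lesioned[outside]):
        reasons.append("outside-mask identity violated")

    if mask.any():
        contrast = abs(float(lesioned[mask].mean()) - float(lf[mask].mean()))
        if contrast < contrast_threshold:
            reasons.append(
                f"insufficient lesion contrast ({contrast:.2f} < {contrast_threshold})"
            )

    ok = not reasons
    sim.mark_simulation(ok, reasons)
    return ok, reasons
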