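"""Parcellation-accuracy metrics.

Per-ROI Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|), region
volumes, percent volume difference PVD = 100 (V_test − V_ref) / V_ref, and a
binned intensity-histogram RMSE used as a global intensity-alignment score.
ROIs empty in both maps carry no information (both had the same in-mask
portion removed) and are excluded from per-image means rather than scored.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .image import Volume, check_same_grid

__all__ = ["dsc", "pvd", "roi_table", "summarize_image", "histogram_rmse"]


def dsc(roi_ref: np.ndarray, roi_test: np.ndarray) -> float:
    """Dice similarity coefficient of two voxel sets on a shared grid.

    Symmetric; 0 for disjoint sets, 1 for identical nonempty sets.  Raises
    when both sets are empty (the coefficient is undefined there; table
    construction flags such rows as excluded instead).
    """
    a = np.asarray(roi_ref, dtype=bool)
    b = np.asarray(roi_test, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("DSC is undefined for two empty sets")
    return 2.0 * int((a & b).sum()) / (na + nb)


def pvd(vol_ref: float, vol_test: float) -> float:
    """Signed percent volume difference of a test region vs its reference.

    Negative values mean the test region is smaller than the reference.
    """
    if vol_ref <= 0:
        raise ValueError("PVD requires a positive reference volume")
    return 100.0 * (vol_test - vol_ref) / vol_ref


def roi_table(
    ref_labels: Volume,
    test_labels: Volume,
    roi_ids: "list[int] | np.ndarray",
    set_id: str | None = None,
    image_type: str | None = None,
) -> pd.DataFrame:
    """Per-ROI DSC / volume / PVD table for one test map against its reference.

    Both maps must have had identical repair-mask exclusion applied.  Rows
    whose reference region is empty carry an ``excluded_reason`` and no PVD;
    rows empty in both maps are likewise excluded (no information).
    """
    check_same_grid(ref_labels, test_labels, "reference and test label maps")
    voxvol = ref_labels.voxel_volume_mm3
    ref = ref_labels.data
    test = test_labels.data

    rows = []
    for roi in roi_ids:
        a = ref == roi
        b = test == roi
        na, nb = int(a.sum()), int(b.sum())
        vol_ref = na * voxvol
        vol_test = nb * voxvol
        if na + nb == 0:
            rows.append((roi, np.nan, vol_ref, vol_test, np.nan, "empty in both maps"))
            continue
        if na == 0:
            rows.append((roi, np.nan, vol_ref, vol_test, np.nan, "absent in reference"))
            continue
        rows.append((roi, dsc(a, b), vol_ref, vol_test, pvd(vol_ref, vol_test), None))

    table = pd.DataFrame(
        rows,
        columns=["roi_id", "dsc", "vol_ref_mm3", "vol_test_mm3", "pvd", "excluded_reason"],
    )
    if set_id is not None:
        table.insert(0, "set_id", set_id)
    if image_type is not None:
        table.insert(1 if set_id is not None else 0, "image_type", image_type)
    return table


def summarize_image(table: pd.DataFrame) -> dict[str, float]:
    """Unweighted per-image means over the included ROI rows."""
    included = table[table["excluded_reason"].isna()]
    return {
        "n_rois_included": int(len(included)),
        "mean_dsc": float(included["dsc"].mean()) if len(included) else math.nan,
        "mean_pvd": float(included["pvd"].mean()) if len(included) else math.nan,
    }


def histogram_rmse(
    a: Volume, b: Volume, mask: np.ndarray, n_bins: int = 128
) -> float:
    """RMSE between the two images' masked intensity densities.

    Densities are binned over the pooled masked min-max range, so the value
    is 0 exactly when the binned histograms coincide.
    """
    check_same_grid(a, b, "histogram operands")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("histogram mask is empty")
    va, vb = a.data[mask], b.data[mask]
    lo = min(va.min(), vb.min())
    hi = max(va.max(), vb.max())
    if hi == lo:
        raise ValueError("constant images: zero intensity range")
    ha, _ = np.histogram(va, bins=n_bins, range=(lo, hi), density=True)
    hb, _ = np.histogram(vb, bins=n_bins, range=(lo, hi), density=True)
    return float(np.sqrt(np.mean((ha - hb) ** 2)))
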