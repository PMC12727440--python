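"""Seeded synthetic head phantoms with bilateral cortical parcellations.

The phantom is an ellipsoid-shell "head": a CSF rim under the head surface,
a grey-matter ribbon, a white-matter interior and a central CSF ventricle.
Intensities follow T1-weighted contrast (background < CSF < GM < WM).  The
grey-matter ribbon is partitioned into ``n_roi_pairs`` mirror-symmetric
left/right region pairs, standing in for a bilateral cortical atlas
(default 31 pairs, 62 regions).  Everything is deterministic given a seed.

Geometry is deliberately simple: the quantities the downstream benchmark
measures (tissue contrast, label overlap, mask bookkeeping) do not depend
on realistic cortical folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Volume, ras_affine

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "DeformationField",
    "TissueProbabilityMaps",
    "PAIR_OFFSET_DOC",
    "make_template",
    "make_subject",
    "make_deformation_field",
    "make_lesion_mask",
    "warp_volume",
    "warp_labels",
    "head_from_labels",
]

# Left ROI k (1..n_pairs) pairs with right ROI k + n_pairs: the pair offset
# equals n_roi_pairs, so a 31-pair atlas uses labels 1..62.
PAIR_OFFSET_DOC = "right_label = left_label + n_roi_pairs"

# Normalised ellipsoid radii delimiting the tissue shells (fractions of the
# head semi-axes, outermost to innermost).
_R_CSF_OUTER = 1.00
_R_GM_OUTER = 0.90
_R_WM_OUTER = 0.72
_R_VENTRICLE = 0.18

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head.

    ``tissue_means`` are arbitrary-unit intensity levels for
    (background, CSF, GM, WM) and must be strictly increasing, giving the
    T1-like contrast the benchmark relies on.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissue_means: tuple[float, float, float, float] = (0.0, 30.0, 70.0, 100.0)
    noise_sd: float = 5.0
    n_roi_pairs: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError(
                "left-right axis length must be even so the midplane falls "
                "between voxels and hemispheres mirror exactly"
            )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bg, csf, gm, wm = self.tissue_means
        if not (bg < csf < gm < wm):
            raise ValueError("tissue_means must satisfy background < CSF < GM < WM")
        if self.n_roi_pairs < 1:
            raise ValueError("n_roi_pairs must be >= 1")

    @property
    def pair_offset(self) -> int:
        return self.n_roi_pairs


@dataclass(frozen=True)
class LesionSpec:
    """One lesion profile: cluster count, total volume, laterality, intensity."""

    n_clusters: int = 1
    target_volume_mm3: float = 1000.0
    laterality: str = "bilateral"  # unilateral-left | unilateral-right | bilateral
    intensity_level: float = 30.0  # hypointense fill level (CSF-like on T1)
    intensity_noise_sd: float = 3.0
    seed: int = 0
    volume_tolerance: float = 0.20  # realised/target relative tolerance

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.target_volume_mm3 <= 0:
            raise ValueError("target_volume_mm3 must be positive")
        if self.laterality not in ("unilateral-left", "unilateral-right", "bilateral"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass
class DeformationField:
    """Dense displacement field in mm, voxel-indexed, with a norm bound."""

    displacement: np.ndarray  # shape (3, *grid)
    max_magnitude_mm: float

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nx, ny, nz)")
        norms = np.linalg.norm(self.displacement, axis=0)
        if norms.max(initial=0.0) > self.max_magnitude_mm + 1e-9:
            raise ValueError("displacement norm exceeds max_magnitude_mm")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[1:]  # type: ignore[return-value]


@dataclass
class TissueProbabilityMaps:
    """Per-voxel CSF/GM/WM membership probabilities, summing to 1 inside the head."""

    csf: Volume
    gm: Volume
    wm: Volume
    head: Volume  # boolean head support

    def as_dict(self) -> dict[str, Volume]:
        return {"csf": self.csf, "gm": self.gm, "wm": self.wm}


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _normalized_radius(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal radius normalised so the head surface sits at rho = 1."""
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = np.array([0.44, 0.40, 0.42]) * np.asarray(shape, dtype=float)
    idx = np.indices(shape, dtype=float)
    # mirror symmetry across the inter-hemispheric midplane comes from |x - cx|
    u = np.empty_like(idx)
    u[0] = np.abs(idx[0] - centre[0]) / semi[0]
    u[1] = (idx[1] - centre[1]) / semi[1]
    u[2] = (idx[2] - centre[2]) / semi[2]
    return np.sqrt((u**2).sum(axis=0)), u


def _tissue_classes(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (class map, direction components) — 0 bg, 1 CSF, 2 GM, 3 WM."""
    rho, u = _normalized_radius(shape)
    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[rho <= _R_CSF_OUTER] = 1  # outer CSF rim
    tissue[rho <= _R_GM_OUTER] = 2  # grey-matter ribbon
    tissue[rho <= _R_WM_OUTER] = 3  # white-matter interior
    tissue[rho <= _R_VENTRICLE] = 1  # central CSF ventricle
    return tissue, u


def _sector_allocation(n_pairs: int, n_bands: int) -> list[int]:
    """Distribute n_pairs azimuthal sectors over polar bands by solid angle."""
    edges = np.linspace(0.0, math.pi, n_bands + 1)
    weights = np.cos(edges[:-1]) - np.cos(edges[1:])
    raw = weights / weights.sum() * n_pairs
    counts = np.maximum(1, np.floor(raw).astype(int))
    # largest-remainder adjustment to hit the exact total
    while counts.sum() < n_pairs:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > n_pairs:
        over = np.where(counts > 1)[0]
        counts[over[np.argmin((raw - counts)[over])]] -= 1
    return counts.tolist()


def make_template(spec: PhantomSpec) -> tuple[Volume, Volume, TissueProbabilityMaps]:
    """Build the noise-free template intensity volume, bilateral labels and TPMs.

    Returns a triple (template, labels, tpms).  The label map contains exactly
    ``2 * n_roi_pairs`` nonzero labels; left ROI ``k`` mirrors onto right ROI
    ``k + n_roi_pairs`` under a left-right flip of the grid.
    """
    shape = spec.grid_shape
    tissue, u = _tissue_classes(shape)
    means = np.asarray(spec.tissue_means, dtype=float)
    template = means[tissue]

    # --- parcellation of the GM ribbon into mirror-symmetric sectors -------
    gm = tissue == 2
    theta = np.arccos(np.clip(u[2] / np.maximum(np.sqrt((u**2).sum(axis=0)), 1e-12), -1, 1))
    psi = np.arctan2(u[1], u[0])  # u[0] >= 0 -> psi in [-pi/2, pi/2]

    n_pairs = spec.n_roi_pairs
    n_bands = max(1, int(round(math.sqrt(n_pairs))))
    sectors = _sector_allocation(n_pairs, n_bands)
    band_edges = np.linspace(0.0, math.pi, n_bands + 1)

    pair_id = np.zeros(shape, dtype=np.int32)
    next_label = 1
    for b in range(n_bands):
        in_band = gm & (theta >= band_edges[b]) & (theta < band_edges[b + 1] + (1e-9 if b == n_bands - 1 else 0.0))
        n_sec = sectors[b]
        sec_edges = np.linspace(-math.pi / 2, math.pi / 2, n_sec + 1)
        for s in range(n_sec):
            hi_pad = 1e-9 if s == n_sec - 1 else 0.0
            sel = in_band & (psi >= sec_edges[s]) & (psi < sec_edges[s + 1] + hi_pad)
            pair_id[sel] = next_label
            next_label += 1

    centre_x = (shape[0] - 1) / 2.0
    xs = np.arange(shape[0])[:, None, None]
    left = xs < centre_x
    labels = np.where(pair_id > 0, np.where(left, pair_id, pair_id + n_pairs), 0).astype(np.int32)

    present = np.unique(labels[labels > 0])
    if len(present) != 2 * n_pairs:
        raise ValueError(
            f"grid {shape} too small to host {2 * n_pairs} cortical ROIs: "
            f"only {len(present)} labels received voxels"
        )

    # --- tissue probability maps -------------------------------------------
    head = tissue > 0
    probs = []
    for cls in (1, 2, 3):
        p = ndimage.gaussian_filter((tissue == cls).astype(float), sigma=1.0)
        probs.append(p)
    total = np.sum(probs, axis=0)
    tpm = [np.where(head, p / np.maximum(total, 1e-12), 0.0) for p in probs]

    affine = ras_affine(shape, spec.voxel_size_mm)
    tpms = TissueProbabilityMaps(
        csf=Volume(tpm[0], affine),
        gm=Volume(tpm[1], affine),
        wm=Volume(tpm[2], affine),
        head=Volume(head, affine),
    )
    return Volume(template, affine), Volume(labels, affine), tpms


# ---------------------------------------------------------------------------
# deformations and subjects
# ---------------------------------------------------------------------------

def make_deformation_field(
    shape: tuple[int, int, int],
    max_magnitude_mm: float,
    smooth_sigma_vox: float = 4.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> DeformationField:
    """Smooth random displacement field with bounded norm (identity if bound is 0)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if max_magnitude_mm == 0:
        return DeformationField(np.zeros((3, *shape)), 0.0)
    disp = rng.standard_normal((3, *shape))
    for c in range(3):
        disp[c] = ndimage.gaussian_filter(disp[c], sigma=smooth_sigma_vox)
    norms = np.linalg.norm(disp, axis=0)
    peak = norms.max()
    if peak > 0:
        disp *= max_magnitude_mm / peak
    return DeformationField(disp, max_magnitude_mm)


def _check_jacobian_positive(field: DeformationField, voxel_size_mm: float) -> None:
    """Fail if the warp x -> x + d(x) is not locally one-to-one on the grid."""
    d_vox = field.displacement / voxel_size_mm
    grads = np.empty((3, 3, *field.grid_shape))
    for c in range(3):
        g = np.gradient(d_vox[c])
        for ax in range(3):
            grads[c, ax] = g[ax]
    jac = grads.copy()
    for c in range(3):
        jac[c, c] += 1.0
    det = (
        jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
        - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
        + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0])
    )
    if det.min() <= 0:
        raise ValueError(
            f"deformation field is not locally one-to-one "
            f"(min Jacobian determinant {det.min():.4f} <= 0)"
        )


def _sample_coords(field: DeformationField, voxel_size_mm: float) -> np.ndarray:
    idx = np.indices(field.grid_shape, dtype=float)
    return idx + field.displacement / voxel_size_mm


def warp_volume(vol: Volume, field: DeformationField, order: int = 1) -> Volume:
    """Pull-back resampling: out(x) = in(x + d(x)); linear interpolation by default."""
    if vol.shape != field.grid_shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs field {field.grid_shape}")
    voxel = float(vol.voxel_sizes[0])
    coords = _sample_coords(field, voxel)
    out = ndimage.map_coordinates(vol.data.astype(float), coords, order=order, mode="nearest")
    return vol.with_data(out)


def warp_labels(labels: Volume, field: DeformationField) -> Volume:
    """Nearest-neighbour warp for integer label maps and binary masks."""
    if labels.shape != field.grid_shape:
        raise ValueError(f"grid mismatch: labels {labels.shape} vs field {field.grid_shape}")
    voxel = float(labels.voxel_sizes[0])
    coords = _sample_coords(field, voxel)
    out = ndimage.map_coordinates(labels.data, coords, order=0, mode="nearest")
    return labels.with_data(out.astype(labels.data.dtype))


def make_subject(
    template: Volume,
    labels: Volume,
    max_magnitude_mm: float = 3.0,
    noise_sd: float = 5.0,
    smooth_sigma_vox: float = 4.0,
    seed: int = 0,
) -> tuple[Volume, Volume, DeformationField]:
    """Warp the template into one "subject": smooth random deformation + noise.

    The same seed reproduces the subject bit-exactly.  The returned field is
    the ground-truth template-to-subject mapping used for label propagation.
    """
    if template.shape != labels.shape:
        raise ValueError("template and labels must share a grid")
    rng = np.random.default_rng(seed)
    field = make_deformation_field(
        template.shape, max_magnitude_mm, smooth_sigma_vox, rng=rng
    )
    _check_jacobian_positive(field, float(template.voxel_sizes[0]))
    subject = warp_volume(template, field, order=1)
    if noise_sd > 0:
        subject = subject.with_data(subject.data + rng.normal(0.0, noise_sd, template.shape))
    warped_labels = warp_labels(labels, field)
    return subject, warped_labels, field


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

def head_from_labels(labels: Volume) -> np.ndarray:
    """Head interior implied by a cortical label map (filled GM shell)."""
    shell = labels.data > 0
    return ndimage.binary_fill_holes(shell)


def _grow_cluster(
    allowed: np.ndarray,
    target_vox: int,
    rng: np.random.Generator,
    accept_p: float = 0.6,
) -> np.ndarray | None:
    """Grow one 26-connected component by stochastic dilation to an exact size."""
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        return None
    seed_idx = tuple(coords[rng.integers(len(coords))])
    region = np.zeros(allowed.shape, dtype=bool)
    region[seed_idx] = True
    size = 1
    while size < target_vox:
        frontier = ndimage.binary_dilation(region, structure=_STRUCT26) & allowed & ~region
        cand = np.argwhere(frontier)
        if len(cand) == 0:
            return None  # hemisphere / head exhausted around this seed
        keep = rng.random(len(cand)) < accept_p
        if not keep.any():
            keep[rng.integers(len(cand))] = True
        chosen = cand[keep]
        need = target_vox - size
        if len(chosen) > need:
            chosen = chosen[rng.permutation(len(chosen))[:need]]
        region[tuple(chosen.T)] = True
        size += len(chosen)
    return region


def make_lesion_mask(lesion: LesionSpec, labels: Volume, max_attempts: int = 8) -> Volume:
    """Binary repair mask inside the head honouring cluster count and laterality.

    Clusters are grown by seeded stochastic dilation from random in-head
    seeds; 26-connectivity defines a cluster.  Raises when the requested
    volume cannot be placed in the requested hemisphere(s).
    """
    head = head_from_labels(labels)
    voxel_vol = labels.voxel_volume_mm3
    total_vox = max(lesion.n_clusters, int(round(lesion.target_volume_mm3 / voxel_vol)))

    centre_x = (labels.shape[0] - 1) / 2.0
    xs = np.arange(labels.shape[0])[:, None, None]
    left = np.broadcast_to(xs < centre_x, labels.shape)
    right = ~left

    if lesion.laterality == "unilateral-left":
        hemi_for = [head & left] * lesion.n_clusters
    elif lesion.laterality == "unilateral-right":
        hemi_for = [head & right] * lesion.n_clusters
    else:  # bilateral: alternate hemispheres; a single cluster may sit anywhere
        if lesion.n_clusters == 1:
            hemi_for = [head]
        else:
            hemi_for = [head & (left if i % 2 == 0 else right) for i in range(lesion.n_clusters)]

    max_hemi = max(int(h.sum()) for h in hemi_for)
    if total_vox > int(head.sum()):
        raise ValueError(
            f"target volume {lesion.target_volume_mm3} mm^3 exceeds head volume"
        )

    rng = np.random.default_rng(lesion.seed)
    for _attempt in range(max_attempts):
        # split the total among clusters; every cluster gets >= 1 voxel
        props = rng.dirichlet(np.full(lesion.n_clusters, 2.0))
        sizes = np.maximum(1, np.round(props * total_vox).astype(int))
        sizes[np.argmax(sizes)] += total_vox - sizes.sum()
        if sizes.min() < 1:
            continue

        mask = np.zeros(labels.shape, dtype=bool)
        ok = True
        for i in range(lesion.n_clusters):
            # keep clusters separated by one voxel so components stay distinct
            forbidden = ndimage.binary_dilation(mask, structure=_STRUCT26)
            allowed = hemi_for[i] & ~forbidden
            region = _grow_cluster(allowed, int(sizes[i]), rng)
            if region is None:
                ok = False
                break
            mask |= region
        if not ok:
            continue

        n_comp = ndimage.label(mask, structure=_STRUCT26)[1]
        realised = mask.sum() * voxel_vol
        rel_err = abs(realised - lesion.target_volume_mm3) / lesion.target_volume_mm3
        if n_comp == lesion.n_clusters and rel_err <= lesion.volume_tolerance:
            return labels.with_data(mask)

    raise ValueError(
        f"could not place {lesion.n_clusters} cluster(s) of "
        f"{lesion.target_volume_mm3} mm^3 with laterality {lesion.laterality!r} "
        f"(largest admissible hemisphere region: {max_hemi * voxel_vol:.0f} mm^3)"
    )
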