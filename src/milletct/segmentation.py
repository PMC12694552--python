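"""Tissue segmentation of grain CT stacks.

The chain mirrors classical CT image processing: a global automatic
threshold (Otsu) separates grain from air, per-slice Canny edge maps become
barriers for a deterministic 3D region growing, grown regions are pooled
into the four tissue classes by their mean intensity rank, and a final
rule-based refinement reassigns voxels in user-stated intensity ranges
(the counterpart of manual threshold adjustment for poorly contrasted
boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from . import _growth
from .types import DomainError, GRAIN_TISSUES, LabelVolume, Tissue, VoxelVolume


@dataclass
class SegmentationParams:
    histogram_bins: int = 256
    canny_sigma_vox: float = 1.4
    canny_low_frac: float = 0.10
    canny_high_frac: float = 0.25
    growth_tolerance: float = 7000.0
    connectivity: int = 26           # 6 or 26 in 3D (4 or 8 per slice)
    min_region_vox: int = 27         # a 3^3 speckle
    grow_2d: bool = False            # per-slice growth for strict 2D fidelity

    def __post_init__(self) -> None:
        if not 0 < self.canny_low_frac < self.canny_high_frac < 1:
            raise DomainError("need 0 < canny_low_frac < canny_high_frac < 1")
        if self.histogram_bins < 2:
            raise DomainError("histogram_bins must be >= 2")
        if self.min_region_vox < 1:
            raise DomainError("min_region_vox must be >= 1")
        if self.connectivity not in (6, 26):
            raise DomainError("connectivity must be 6 or 26")
        if self.growth_tolerance < 0:
            raise DomainError("growth_tolerance must be >= 0")


DEFAULT_ORDERING = (Tissue.CAVITY, Tissue.HULL, Tissue.ENDOSPERM, Tissue.EMBRYO)


@dataclass
class TissueRule:
    """How intensity-ranked regions map to tissues.

    ``ordering`` lists the four tissues by ascending mean intensity; with
    the default, air in the cavity is darkest and the embryo brightest.
    """

    ordering: tuple = DEFAULT_ORDERING
    check_hull_touches_background: bool = True
    check_cavity_enclosed: bool = True

    def __post_init__(self) -> None:
        if sorted(int(t) for t in self.ordering) != sorted(int(t) for t in GRAIN_TISSUES):
            raise DomainError("ordering must be a permutation of the four tissues")


def otsu_threshold(volume: VoxelVolume | np.ndarray, bins: int = 256) -> float:
    """Otsu's automatic threshold: the bin edge maximizing the between-class
    variance sigma_b^2(t) = w0*w1*(mu0-mu1)^2, ties broken toward the lowest
    threshold. Voxels with intensity <= threshold fall in class 0.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    flat = data.ravel().astype(np.float64)
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise DomainError("constant volume: no contrast for thresholding")
    counts, edges = np.histogram(flat, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(np.float64)
    total = w.sum()
    cw0 = np.cumsum(w)[:-1]
    cw1 = total - cw0
    csum = np.cumsum(w * centers)[:-1]
    tsum = (w * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / cw0
        mu1 = (tsum - csum) / cw1
        sigma_b = cw0 * cw1 * (mu0 - mu1) ** 2
    sigma_b[np.isnan(sigma_b)] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) tie
    return float(edges[best + 1])


def canny_edges(slice_2d: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Classic multi-stage Canny on one slice: Gaussian smoothing, gradient,
    non-maximum suppression and double-threshold hysteresis. The low/high
    fractions are taken relative to the maximum smoothed-gradient magnitude.
    """
    img = np.asarray(slice_2d, dtype=np.float64)
    if img.ndim != 2:
        raise DomainError("canny_edges expects a single-channel 2D slice")
    smoothed = ndimage.gaussian_filter(img, params.canny_sigma_vox, mode="nearest")
    gmax = float(np.hypot(filters.sobel_h(smoothed), filters.sobel_v(smoothed)).max())
    if gmax == 0:
        return np.zeros(img.shape, dtype=bool)
    return feature.canny(
        img,
        sigma=params.canny_sigma_vox,
        low_threshold=params.canny_low_frac * gmax,
        high_threshold=params.canny_high_frac * gmax,
        use_quantiles=False,
        mode="nearest",
    )


def region_grow(
    volume: VoxelVolume,
    barrier_mask: np.ndarray,
    params: SegmentationParams,
) -> np.ndarray:
    """Deterministic seeded region growing into an integer region-id volume.

    Seeds are scanned in lexicographic (z, y, x) order; voxels join a region
    while their intensity stays within ``growth_tolerance`` of the region's
    running mean and no barrier voxel is crossed. Barrier voxels and
    fragments below ``min_region_vox`` are merged into the adjacent region
    with the nearest mean intensity, yielding a total partition.
    """
    barrier = np.asarray(barrier_mask, dtype=bool)
    if barrier.shape != volume.shape:
        raise DomainError("barrier mask shape must match the volume")
    if barrier.all():
        raise DomainError("all-barrier input: no seed voxel available")
    nz, ny, nx = volume.shape
    values = volume.data.astype(np.float64).ravel()
    oz, oy, ox = _growth.connectivity_offsets(params.connectivity)
    if params.grow_2d:
        oz = np.zeros_like(oz)  # restrict growth to within-slice moves
    labels, n_regions = _growth.grow_regions(
        values, barrier.ravel(), nz, ny, nx,
        float(params.growth_tolerance), oz, oy, ox,
    )
    means, counts = _growth.region_stats(labels, values, n_regions)
    labels = _growth.absorb_unassigned(labels, values, means, counts,
                                       nz, ny, nx, oz, oy, ox)
    if params.min_region_vox > 1 and n_regions > 1:
        labels = _growth.merge_small_regions(
            labels, values, means, counts, params.min_region_vox,
            nz, ny, nx, oz, oy, ox,
        )
    # compact region ids to 0..K-1 in first-appearance order (deterministic)
    _, compact = np.unique(labels, return_inverse=True)
    return compact.reshape(volume.shape).astype(np.int32)


def _pool_by_intensity_rank(
    means: np.ndarray, weights: np.ndarray, n_classes: int = 4,
) -> np.ndarray:
    """Pool regions into ``n_classes`` contiguous intensity bands.

    Exact weighted 1-D partition of the sorted region means minimizing the
    within-band weighted sum of squares (the multi-class Otsu objective,
    evaluated on region means weighted by voxel counts). Returns the band
    index (0 = darkest) per region, in input order.
    """
    order = np.argsort(means, kind="stable")
    m = means[order]
    w = weights[order]
    k = len(m)
    if len(np.unique(m)) < n_classes:
        raise DomainError(
            f"under-segmentation: only {len(np.unique(m))} distinct region "
            f"intensities for {n_classes} tissue classes"
        )
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwm = np.concatenate([[0.0], np.cumsum(w * m)])
    cwm2 = np.concatenate([[0.0], np.cumsum(w * m * m)])

    def seg_cost_vec(i, j):  # within-SS of sorted regions i..j-1 pooled
        ww = cw[j] - cw[i]
        s = cwm[j] - cwm[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (cwm2[j] - cwm2[i]) - s * s / ww
        return np.where(ww > 0, out, np.inf)

    # DP over split points; requires every band non-empty
    cost = np.full((n_classes, k + 1), np.inf)
    back = np.zeros((n_classes, k + 1), dtype=int)
    cost[0, 1:] = seg_cost_vec(0, np.arange(1, k + 1))
    for c in range(1, n_classes):
        for j in range(c + 1, k + 1):
            i = np.arange(c, j)
            v = cost[c - 1, i] + seg_cost_vec(i, j)
            arg = int(np.argmin(v))
            cost[c, j] = v[arg]
            back[c, j] = c + arg
    bands_sorted = np.empty(k, dtype=int)
    j = k
    for c in range(n_classes - 1, -1, -1):
        i = back[c, j] if c > 0 else 0
        bands_sorted[i:j] = c
        j = i
    bands = np.empty(k, dtype=int)
    bands[order] = bands_sorted
    return bands


def _face_region_ids(regions: np.ndarray) -> set[int]:
    ids: set[int] = set()
    for axis in range(3):
        ids |= set(np.unique(np.take(regions, 0, axis=axis)).tolist())
        ids |= set(np.unique(np.take(regions, -1, axis=axis)).tolist())
    return ids


def assign_tissues(
    regions: np.ndarray,
    volume: VoxelVolume,
    rule: TissueRule | None = None,
    bins: int = 256,
) -> LabelVolume:
    """Pool grown regions into the five-class label volume.

    Background is every region touching the stack's outer faces whose mean
    intensity lies below the global Otsu threshold. The remaining regions
    are pooled into four intensity bands (multi-level Otsu on non-background
    voxels) and the bands are mapped to tissues by ``rule.ordering``
    (ascending mean intensity). Topology checks then reassign inconsistent
    components.
    """
    rule = rule or TissueRule()
    n_regions = int(regions.max()) + 1
    values = volume.data.astype(np.float64).ravel()
    means, counts = _growth.region_stats(regions.ravel().astype(np.int32),
                                         values, n_regions)
    thr = otsu_threshold(volume, bins)
    face_ids = _face_region_ids(regions)
    background_ids = {r for r in face_ids if means[r] <= thr}

    fg_ids = [r for r in range(n_regions) if r not in background_ids and counts[r] > 0]
    if len(fg_ids) < 4:
        raise DomainError(
            f"under-segmentation: only {len(fg_ids)} non-background regions; "
            "lower growth_tolerance or edge thresholds"
        )
    fg_mask = ~np.isin(regions, sorted(background_ids))
    if not fg_mask.any():
        raise DomainError("all-background stack")
    bands = _pool_by_intensity_rank(
        np.array([means[r] for r in fg_ids]),
        np.array([counts[r] for r in fg_ids], dtype=float),
        n_classes=4,
    )
    lut = np.zeros(n_regions, dtype=np.uint8)
    for r, band in zip(fg_ids, bands):
        lut[r] = int(rule.ordering[band])
    labels = lut[regions]
    labels[~fg_mask] = int(Tissue.BACKGROUND)

    labels = _enforce_topology(labels, volume, rule, means_by_tissue={
        int(t): volume.data[labels == int(t)].mean()
        for t in GRAIN_TISSUES if (labels == int(t)).any()
    })
    return LabelVolume(labels, volume.voxel_size_um)


def _enforce_topology(labels, volume, rule, means_by_tissue):
    """Reassign components violating the nesting topology.

    Hull is the only tissue allowed to touch background; a cavity component
    adjacent to background is outside air and becomes background; an
    embryo/endosperm component adjacent to background becomes the solid
    tissue with the nearest mean intensity among topologically consistent
    classes (the hull).
    """
    bg = labels == int(Tissue.BACKGROUND)
    # pad so the stack border counts as background contact
    bg_dilated = ndimage.binary_dilation(np.pad(bg, 1, constant_values=True),
                                         ndimage.generate_binary_structure(3, 3))
    bg_dilated = bg_dilated[1:-1, 1:-1, 1:-1]
    struct = ndimage.generate_binary_structure(3, 3)
    # a component is "outside" when a meaningful fraction of its voxels
    # contacts background; a single noise-breached pinhole contact does not
    # evict an otherwise enclosed component.
    contact_frac = 0.10
    if rule.check_cavity_enclosed:
        cav = labels == int(Tissue.CAVITY)
        comp, n = ndimage.label(cav, struct)
        if n:
            sizes = np.bincount(comp.ravel())
            contacts = np.bincount(comp[bg_dilated].ravel(), minlength=n + 1)
            for c in range(1, n + 1):
                if contacts[c] > contact_frac * sizes[c]:
                    labels[comp == c] = int(Tissue.BACKGROUND)
    if rule.check_hull_touches_background:
        for t in (Tissue.EMBRYO, Tissue.ENDOSPERM):
            tm = labels == int(t)
            if not tm.any():
                continue
            comp, n = ndimage.label(tm, struct)
            sizes = np.bincount(comp.ravel())
            contacts = np.bincount(comp[bg_dilated].ravel(), minlength=n + 1)
            for c in range(1, n + 1):
                if contacts[c] > contact_frac * sizes[c]:
                    labels[comp == c] = int(Tissue.HULL)
    return labels


def refine_labels(
    lv: LabelVolume,
    volume: VoxelVolume,
    overrides: list[tuple[tuple[float, float], Tissue, Tissue]],
) -> LabelVolume:
    """Manual-override refinement: voxels holding ``from`` whose intensity
    falls in the closed range are reassigned to ``to``, in list order.
    Reapplying the same override list is a no-op (idempotent).
    """
    for i, ((lo_i, hi_i), frm_i, to_i) in enumerate(overrides):
        if lo_i > hi_i:
            raise DomainError(f"override {i}: malformed range ({lo_i}, {hi_i})")
        for j in range(i):
            (lo_j, hi_j), frm_j, to_j = overrides[j]
            if frm_j == frm_i and to_j != to_i and lo_i <= hi_j and lo_j <= hi_i:
                raise DomainError(
                    f"overrides {j} and {i} contradict on overlapping range"
                )
    labels = lv.labels.copy()
    for (lo, hi), frm, to in overrides:
        sel = (labels == int(frm)) & (volume.data >= lo) & (volume.data <= hi)
        labels[sel] = int(to)
    return LabelVolume(labels, lv.voxel_size_um)


def segment_grain(
    volume: VoxelVolume,
    params: SegmentationParams | None = None,
    rule: TissueRule | None = None,
    overrides: list | None = None,
) -> LabelVolume:
    """End-to-end segmentation: Otsu -> per-slice Canny -> region growing ->
    tissue assignment -> override refinement. Deterministic."""
    params = params or SegmentationParams()
    rule = rule or TissueRule()
    barrier = np.stack([canny_edges(sl, params) for sl in volume.data], axis=0)
    regions = region_grow(volume, barrier, params)
    lv = assign_tissues(regions, volume, rule, bins=params.histogram_bins)
    if overrides:
        lv = refine_labels(lv, volume, overrides)
    return lv


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
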