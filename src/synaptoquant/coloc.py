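"""Object-based puncta detection and two-channel colocalization.

Detection walks an intensity cutoff down from ``max_cutoff`` to
``min_cutoff`` one unit at a time. At each cutoff, unmasked pixels at or
above the cutoff are labelled into connected components; components larger
than ``min_region_px`` whose intensity-weighted centroid falls outside
every previously accepted punctum's exclusion margin are accepted as
puncta, and a disk of radius ``exclusion_margin_px`` around each accepted
center is masked against further detection in the same channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as _ndi
from skimage.measure import label as _cc_label

from .errors import ContractError

__all__ = [
    "ColocParams",
    "PunctaRegion",
    "ColocResult",
    "normalize_to_255",
    "detect_puncta",
    "colocalize",
    "MARKER_MARGINS",
]

#: exclusion margin (px) by presynaptic marker; the inhibitory marker is
#: sparser and gets the wider margin.
MARKER_MARGINS = {"vgat": 10.0, "vglut1": 5.0}


@dataclass(frozen=True)
class ColocParams:
    """Constants of the iterative-threshold detection and overlap test."""

    max_cutoff: int = 255
    min_cutoff: int = 95
    min_region_px: int = 25          # strict >
    synapse_radius_px: float = 4.0
    exclusion_margin_px: float = 5.0
    connectivity: int = 2            # skimage convention: 2 = 8-neighbour
    min_circularity: float = 0.0     # optional roundness filter, off by default

    def __post_init__(self):
        if self.max_cutoff < self.min_cutoff:
            raise ContractError("max_cutoff must be >= min_cutoff")
        if self.synapse_radius_px <= 0 or self.exclusion_margin_px <= 0:
            raise ContractError("radii must be positive")
        if self.connectivity not in (1, 2):
            raise ContractError("connectivity must be 1 (4-n) or 2 (8-n)")

    @classmethod
    def for_marker(cls, marker: str, **kwargs) -> "ColocParams":
        try:
            margin = MARKER_MARGINS[marker.lower()]
        except KeyError:
            raise ContractError(
                f"unknown marker {marker!r}; expected one of "
                f"{sorted(MARKER_MARGINS)}")
        return cls(exclusion_margin_px=margin, **kwargs)


@dataclass(frozen=True)
class PunctaRegion:
    """One detected synaptic punctum (nominal disk of radius_px)."""

    center: tuple[float, float]      # (row, col), 0-based, sub-pixel
    radius_px: float
    detection_cutoff: int
    area_px: int


@dataclass(frozen=True)
class ColocResult:
    n_reference: int
    n_marker: int
    n_colocalized: int
    fraction_pct: float


def normalize_to_255(image: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to the 0-255 range, rounded to integers.

    A constant image has no dynamic range and maps to all zeros with a
    warning (no detections possible downstream).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ContractError("empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn(
            "constant image: no dynamic range, normalizing to all zeros",
            RuntimeWarning, stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    out = np.rint((img - lo) * (255.0 / (hi - lo)))
    return out.astype(np.uint8)


def _weighted_centroid(img, rows, cols):
    w = img[rows, cols].astype(np.float64)
    total = w.sum()
    return (float((rows * w).sum() / total), float((cols * w).sum() / total))


def detect_puncta(image: np.ndarray, params: ColocParams | None = None
                  ) -> list[PunctaRegion]:
    """Detect puncta by iterative thresholding with connected components.

    ``image`` must already be normalized to 0-255. Returns regions sorted
    by detection cutoff (descending) then row-major center. Any two
    accepted centers are >= ``exclusion_margin_px`` apart by construction.
    """
    params = params or ColocParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ContractError("expected a single-plane 2D image")
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ContractError("image not normalized to 0-255; "
                            "call normalize_to_255 first")
    img = img.astype(np.float64)
    h, w = img.shape
    mask = np.zeros(img.shape, dtype=bool)
    rr_grid, cc_grid = np.mgrid[0:h, 0:w]
    accepted: list[PunctaRegion] = []
    centers: list[tuple[float, float]] = []
    margin2 = params.exclusion_margin_px**2

    for cutoff in range(params.max_cutoff, params.min_cutoff - 1, -1):
        binary = (img >= cutoff) & ~mask
        if not binary.any():
            continue
        labels, n_labels = _cc_label(binary, connectivity=params.connectivity,
                                     return_num=True)
        areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
        slices = _ndi.find_objects(labels)
        # process components in raster order of their first pixel so the
        # intra-cutoff margin test is order-deterministic
        flat = labels.ravel()
        uniq, first_idx = np.unique(flat, return_index=True)
        order = [int(lab) for _, lab in
                 sorted((first_idx[i], uniq[i]) for i in range(len(uniq))
                        if uniq[i] != 0)]
        for lab in order:
            area = areas[lab]
            if area <= params.min_region_px:
                continue
            sl = slices[lab - 1]
            sub_rows, sub_cols = np.nonzero(labels[sl] == lab)
            rows = sub_rows + sl[0].start
            cols = sub_cols + sl[1].start
            if params.min_circularity > 0.0:
                # 4*pi*area / perimeter^2 proxy via bounding box fill is
                # deliberately simple; off by default.
                bbox_area = ((rows.max() - rows.min() + 1)
                             * (cols.max() - cols.min() + 1))
                if area / bbox_area < params.min_circularity:
                    continue
            cy, cx = _weighted_centroid(img, rows, cols)
            if any((cy - py) ** 2 + (cx - px) ** 2 < margin2
                   for py, px in centers):
                continue
            accepted.append(PunctaRegion(
                center=(cy, cx), radius_px=params.synapse_radius_px,
                detection_cutoff=cutoff, area_px=int(area)))
            centers.append((cy, cx))
            m = int(np.ceil(params.exclusion_margin_px))
            r0, r1 = max(0, int(cy) - m - 1), min(h, int(cy) + m + 2)
            c0, c1 = max(0, int(cx) - m - 1), min(w, int(cx) + m + 2)
            mask[r0:r1, c0:c1] |= (
                (rr_grid[r0:r1, c0:c1] - cy) ** 2
                + (cc_grid[r0:r1, c0:c1] - cx) ** 2) <= margin2

    accepted.sort(key=lambda p: (-p.detection_cutoff, p.center[0], p.center[1]))
    return accepted


def colocalize(reference: list[PunctaRegion], marker: list[PunctaRegion],
               params: ColocParams | None = None, *,
               reference_shape: tuple[int, int] | None = None,
               marker_shape: tuple[int, int] | None = None) -> ColocResult:
    """Count reference puncta whose nominal disk overlaps a marker disk.

    A reference punctum is colocalized iff its center lies within
    ``2 * synapse_radius_px`` (closed disks, touching counts) of any
    marker center. The fraction is computed over reference puncta.
    """
    params = params or ColocParams()
    if (reference_shape is not None and marker_shape is not None
            and tuple(reference_shape) != tuple(marker_shape)):
        raise ContractError(
            f"channel image shapes differ: {reference_shape} vs {marker_shape}")
    thresh2 = (2.0 * params.synapse_radius_px) ** 2
    mk = np.array([m.center for m in marker], dtype=np.float64)
    n_coloc = 0
    for ref in reference:
        if mk.size == 0:
            break
        d2 = ((mk[:, 0] - ref.center[0]) ** 2
              + (mk[:, 1] - ref.center[1]) ** 2)
        if (d2 <= thresh2).any():
            n_coloc += 1
    n_ref = len(reference)
    frac = 100.0 * n_coloc / n_ref if n_ref else float("nan")
    return ColocResult(n_reference=n_ref, n_marker=len(marker),
                       n_colocalized=n_coloc, fraction_pct=frac)
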