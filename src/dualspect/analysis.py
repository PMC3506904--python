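"""Image-quality evaluation: equal-area ROI contrasts and projection profiles.

Contrast follows the standard summed-count definition
``(C_myocardium - C_region) / C_myocardium`` with equal-area regions of
interest on the defect, the healthy myocardium and the left-ventricular
cavity, drawn on the short-axis slice where the defect is best visible.
ROIs are machine-placed from the phantom's known geometry rather than drawn
by hand, so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ActivityVolume
from .phantom import ORGAN_IDS, CardiacPhantom

__all__ = [
    "RoiSet",
    "ContrastResult",
    "roi_counts",
    "contrast",
    "extract_profile",
    "select_defect_slice",
    "place_rois",
    "evaluate_contrast",
]


@dataclass
class RoiSet:
    """Three equal-area planar ROIs on one short-axis slice.

    Each ROI is an ``(n, 2)`` integer array of (row, column) pixel indices.
    """

    slice_index: int
    defect: np.ndarray
    myocardium: np.ndarray
    lv: np.ndarray

    def __post_init__(self) -> None:
        rois = {}
        for name in ("defect", "myocardium", "lv"):
            arr = np.asarray(getattr(self, name), dtype=np.intp).reshape(-1, 2)
            if arr.shape[0] == 0:
                raise ValueError(f"{name} ROI is empty")
            setattr(self, name, arr)
            rois[name] = {tuple(p) for p in arr}
        sizes = {name: len(r) for name, r in rois.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"ROIs must have equal area, got {sizes}")
        names = list(rois)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if rois[a] & rois[b]:
                    raise ValueError(f"ROIs {a!r} and {b!r} overlap")

    @property
    def area(self) -> int:
        return self.defect.shape[0]


@dataclass
class ContrastResult:
    """Summed ROI counts and the two derived contrasts."""

    c_myocardium: float
    c_defect: float
    c_lv: float
    contrast_myocardium_defect: float
    contrast_myocardium_lv: float
    slice_index: int
    roi_area: int


def roi_counts(image: np.ndarray, roi: np.ndarray) -> float:
    """Total counts inside a planar ROI (exact pixel sum)."""
    image = np.asarray(image)
    roi = np.asarray(roi, dtype=np.intp).reshape(-1, 2)
    if roi.shape[0] == 0:
        raise ValueError("empty ROI")
    if (np.any(roi < 0) or np.any(roi[:, 0] >= image.shape[0])
            or np.any(roi[:, 1] >= image.shape[1])):
        raise ValueError("ROI extends outside the image")
    return float(image[roi[:, 0], roi[:, 1]].sum(dtype=np.float64))


def contrast(c_region: float, c_myocardium: float) -> float:
    """(C_myocardium - C_region) / C_myocardium."""
    if c_myocardium <= 0:
        raise ValueError("myocardial counts must be positive")
    return (c_myocardium - c_region) / c_myocardium


def extract_profile(view: np.ndarray, orientation: str, center: int | None = None,
                    width: int = 10) -> np.ndarray:
    """Band-mean profile through a projection view.

    ``orientation == "horizontal"`` runs along the transaxial axis averaging
    a ``width``-pixel axial band; "vertical" is the transpose.  ``width == 1``
    reduces to a single row/column.
    """
    view = np.asarray(view, dtype=np.float64)
    if view.ndim != 2:
        raise ValueError("profile extraction needs a 2-D view")
    if width < 1:
        raise ValueError("band width must be >= 1")
    if orientation == "vertical":
        view = view.T
    elif orientation != "horizontal":
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    n_band = view.shape[1]
    if center is None:
        center = n_band // 2
    lo = max(0, center - width // 2)
    hi = min(n_band, lo + width)
    return view[:, lo:hi].mean(axis=1)


def select_defect_slice(volume: np.ndarray, myo_mask: np.ndarray,
                        defect_mask: np.ndarray) -> int:
    """Short-axis slice where the defect is most conspicuous.

    Deterministic rule: the slice maximising (mean healthy-myocardium value
    minus mean defect value), using the phantom's known masks.  Invariant
    under global intensity scaling of the volume.
    """
    volume = np.asarray(volume)
    if not defect_mask.any():
        raise ValueError("phantom has no defect voxels")
    best, best_score = None, -np.inf
    healthy = myo_mask & ~defect_mask
    for k in range(volume.shape[2]):
        d = defect_mask[:, :, k]
        h = healthy[:, :, k]
        if not d.any() or not h.any():
            continue
        score = float(volume[:, :, k][h].mean() - volume[:, :, k][d].mean())
        if score > best_score:
            best, best_score = k, score
    if best is None:
        raise ValueError("defect mask does not intersect the myocardium")
    return best


def _nearest(mask2d: np.ndarray, target: tuple, n: int) -> np.ndarray:
    pts = np.argwhere(mask2d)
    if pts.shape[0] < n:
        raise ValueError(f"mask holds only {pts.shape[0]} pixels, need {n}")
    d2 = ((pts - np.asarray(target)) ** 2).sum(axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    return pts[order[:n]]


def place_rois(phantom: CardiacPhantom, sector: str,
               slice_index: int | None = None, volume: np.ndarray | None = None,
               area: int = 15) -> RoiSet:
    """Machine-placed equal-area ROIs from the phantom's known geometry.

    The defect ROI takes the pixels of the defect mask nearest its centroid,
    the healthy ROI the myocardial pixels farthest from every defect (the
    machine equivalent of drawing on visibly healthy wall), the LV ROI the
    cavity pixels nearest the cavity centre.  ``area`` is capped at the
    largest size all three masks support so the ROIs stay strictly inside
    their regions.
    """
    defect_mask = phantom.defect_mask(sector)
    myo = phantom.organs == ORGAN_IDS["myocardium"]
    cavity = phantom.organs == ORGAN_IDS["ventricle"]
    all_defects = np.zeros_like(defect_mask)
    for _, m in phantom.defect_masks:
        all_defects |= m
    if slice_index is None:
        ref = phantom.tl.values if volume is None else volume
        slice_index = select_defect_slice(ref, myo, defect_mask)

    d2 = defect_mask[:, :, slice_index]
    h2 = (myo & ~all_defects)[:, :, slice_index]
    c2 = cavity[:, :, slice_index]
    if not (d2.any() and h2.any() and c2.any()):
        raise ValueError(f"slice {slice_index} misses one of the ROI regions")
    n = min(area, int(d2.sum()), int(h2.sum()), int(c2.sum()))

    d_pts = np.argwhere(d2)
    d_centroid = d_pts.mean(axis=0)
    c_pts = np.argwhere(c2)
    lv_centroid = c_pts.mean(axis=0)

    # healthy wall pixels ranked by distance to the nearest defect pixel
    h_pts = np.argwhere(h2)
    all_d2 = np.argwhere(all_defects[:, :, slice_index])
    dist = np.sqrt(((h_pts[:, None, :] - all_d2[None, :, :]) ** 2)
                   .sum(axis=2)).min(axis=1)
    order = np.lexsort((h_pts[:, 1], h_pts[:, 0], -dist))
    healthy = h_pts[order[:n]]

    return RoiSet(
        slice_index=slice_index,
        defect=_nearest(d2, tuple(d_centroid), n),
        myocardium=healthy,
        lv=_nearest(c2, tuple(lv_centroid), n),
    )


def evaluate_contrast(volume: ActivityVolume | np.ndarray,
                      phantom: CardiacPhantom, sector: str,
                      area: int = 15, slice_index: int | None = None,
                      rois: RoiSet | None = None) -> ContrastResult:
    """Defect and LV contrasts of a volume on the best-defect slice."""
    values = volume.values if isinstance(volume, ActivityVolume) else volume
    if rois is None:
        rois = place_rois(phantom, sector, slice_index=slice_index,
                          volume=values, area=area)
    img = values[:, :, rois.slice_index]
    c_myo = roi_counts(img, rois.myocardium)
    c_def = roi_counts(img, rois.defect)
    c_lv = roi_counts(img, rois.lv)
    return ContrastResult(
        c_myocardium=c_myo, c_defect=c_def, c_lv=c_lv,
        contrast_myocardium_defect=contrast(c_def, c_myo),
        contrast_myocardium_lv=contrast(c_lv, c_myo),
        slice_index=rois.slice_index, roi_area=rois.area,
    )
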