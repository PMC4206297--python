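"""Nuclear segmentation from the DAPI channel and target-channel masking.

The default pipeline is the standard DAPI recipe: Otsu threshold, hole
filling, distance-transform watershed to split touching nuclei, area filter,
and border exclusion.  Every step is switchable through
:class:`SegmentationParams`.  Masking the segmented nuclei onto the target
channel yields per-nucleus pixel collections, the input to the
pixel-histogram cytometry in :mod:`irifcyto.histogram`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .simulate import MAX_INTENSITY


@dataclass(frozen=True)
class SegmentationParams:
    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    fill_holes: bool = True
    split_touching: bool = True
    split_min_distance: int = 15            # min peak separation for watershed seeds
    min_area: int = 200
    max_area: int = 10000                   # 50 * min_area
    exclude_border: bool = True

    def validate(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("threshold_method='fixed' requires fixed_threshold")
        if self.min_area >= self.max_area:
            raise ValueError(f"min_area ({self.min_area}) must be < max_area ({self.max_area})")


@dataclass
class NucleusMask:
    """Labelled nuclear regions with per-nucleus properties and provenance."""

    label_map: np.ndarray
    regions: pd.DataFrame       # columns: label, area, centroid_row, centroid_col, bbox_*
    params: SegmentationParams

    @property
    def labels(self) -> np.ndarray:
        return self.regions["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.regions)

    def boolean(self, label: int) -> np.ndarray:
        return self.label_map == label


def _region_table(label_map: np.ndarray) -> pd.DataFrame:
    if label_map.max() == 0:
        return pd.DataFrame(
            columns=["label", "area", "centroid_row", "centroid_col",
                     "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col"]
        )
    t = regionprops_table(
        label_map, properties=("label", "area", "centroid", "bbox")
    )
    df = pd.DataFrame(t).rename(
        columns={
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
            "bbox-0": "bbox_min_row",
            "bbox-1": "bbox_min_col",
            "bbox-2": "bbox_max_row",
            "bbox-3": "bbox_max_col",
        }
    )
    df["area"] = df["area"].astype(int)
    return df


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams = SegmentationParams()) -> NucleusMask:
    """Segment nuclei from a DAPI image.

    Returns an empty mask (not an error) when nothing exceeds the threshold.
    Deterministic for fixed inputs and parameters.
    """
    params.validate()
    dapi = np.asarray(dapi)
    if dapi.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {dapi.shape}")
    if dapi.min() < 0 or dapi.max() > MAX_INTENSITY:
        raise ValueError(f"DAPI values must lie in [0, {MAX_INTENSITY}]")

    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        if dapi.min() == dapi.max():  # constant image: nothing to segment
            return NucleusMask(np.zeros(dapi.shape, np.int32), _region_table(np.zeros(dapi.shape, np.int32)), params)
        thr = threshold_otsu(dapi)
    binary = dapi > thr

    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    if params.split_touching and binary.any():
        distance = ndi.distance_transform_edt(binary)
        components = cc_label(binary)
        peaks = peak_local_max(
            distance, min_distance=params.split_min_distance, labels=components,
            exclude_border=False,
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:  # degenerate: fall back to connected components
            labels = components
        else:
            labels = watershed(-distance, markers, mask=binary)
    else:
        labels = cc_label(binary)

    labels = labels.astype(np.int32)

    # area filter (after hole filling) and border exclusion
    keep = np.unique(labels)
    keep = keep[keep > 0]
    h, w = labels.shape
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}
    out = np.zeros_like(labels)
    next_id = 1
    for lab in keep:
        region = labels == lab
        area = int(region.sum())
        if area < params.min_area or area > params.max_area:
            continue
        if params.exclude_border and lab in border_labels:
            continue
        out[region] = next_id
        next_id += 1

    return NucleusMask(out, _region_table(out), params)


def sample_nuclei(mask: NucleusMask, n: int, seed: int) -> NucleusMask:
    """Uniform random subset of ``n`` nuclei, without replacement, seeded.

    Label values of the retained nuclei are preserved (not relabelled) so the
    subset stays traceable to the parent mask and to ground truth.
    """
    available = len(mask)
    if n > available:
        raise ValueError(f"requested {n} nuclei but only {available} are available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(mask.labels, size=n, replace=False)
    chosen_set = set(int(c) for c in chosen)
    label_map = np.where(np.isin(mask.label_map, list(chosen_set)), mask.label_map, 0)
    regions = mask.regions[mask.regions["label"].isin(chosen_set)].reset_index(drop=True)
    return NucleusMask(label_map, regions, mask.params)


def mask_target(target: np.ndarray, mask: NucleusMask) -> dict[int, np.ndarray]:
    """Per-nucleus multisets of target intensities at each nucleus's pixels.

    The returned collections are disjoint and together cover exactly the
    masked area.
    """
    target = np.asarray(target)
    if target.shape != mask.label_map.shape:
        raise ValueError(
            f"shape mismatch: target {target.shape} vs mask {mask.label_map.shape}"
        )
    out: dict[int, np.ndarray] = {}
    for row in mask.regions.itertuples():
        sl = (slice(int(row.bbox_min_row), int(row.bbox_max_row)),
              slice(int(row.bbox_min_col), int(row.bbox_max_col)))
        sel = mask.label_map[sl] == row.label
        out[int(row.label)] = target[sl][sel]
    return out


def estimate_background(image: np.ndarray, mask: NucleusMask, dilate: int = 5) -> float:
    """Median intensity outside the (dilated) nuclear mask: the camera
    background plus any diffuse extranuclear signal."""
    fg = mask.label_map > 0
    if dilate > 0:
        fg = ndi.binary_dilation(fg, iterations=dilate)
    outside = np.asarray(image)[~fg]
    if outside.size == 0:
        raise ValueError("no extranuclear pixels available for background estimation")
    return float(np.median(outside))


def match_to_truth(mask: NucleusMask, truth_label_map: np.ndarray, iou_threshold: float = 0.8):
    """Greedy one-to-one matching of segmented nuclei to ground-truth nuclei by
    intersection-over-union.  Returns a DataFrame (truth_id, seg_label, iou)
    with NaN seg_label for unmatched truth nuclei."""
    truth_ids = np.unique(truth_label_map)
    truth_ids = truth_ids[truth_ids > 0]
    used: set[int] = set()
    rows = []
    for t in truth_ids:
        t_region = truth_label_map == t
        overlapping, counts = np.unique(mask.label_map[t_region], return_counts=True)
        best_iou, best_lab = 0.0, None
        for lab, inter in zip(overlapping, counts):
            if lab == 0 or int(lab) in used:
                continue
            union = t_region.sum() + (mask.label_map == lab).sum() - inter
            iou = inter / union
            if iou > best_iou:
                best_iou, best_lab = float(iou), int(lab)
        if best_lab is not None and best_iou >= iou_threshold:
            used.add(best_lab)
            rows.append({"truth_id": int(t), "seg_label": best_lab, "iou": best_iou})
        else:
            rows.append({"truth_id": int(t), "seg_label": np.nan, "iou": best_iou})
    return pd.DataFrame(rows)
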