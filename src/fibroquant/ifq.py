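"""Per-channel immunofluorescence object counting.

Each channel of a multi-channel IF field (e.g. DAPI, GATA3, IL-33, PDGFRα)
is processed independently: binarize with a threshold, bridge intermittent
fragments of one cell by a morphological closing, drop small nonspecific
specks, and count the surviving connected components. The count per channel
is the number of stained objects (cells) in the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk
from scipy import ndimage as ndi

__all__ = [
    "IFParams",
    "CellCountResult",
    "binarize_channel",
    "bridge_fragments",
    "remove_small_objects",
    "count_objects",
    "run_if_pipeline",
]


@dataclass
class IFParams:
    """Parameters of the IF counting pipeline.

    threshold : "otsu" or a fixed intensity (applied per channel; a list
        gives one setting per channel).
    bridge_radius : disk radius (px) of the closing that reconnects
        fragments of one cell.
    min_object_area : components smaller than this (px^2) are removed.
    connectivity : 4 or 8 neighbour adjacency for components.
    """

    threshold: str | float | list = "otsu"
    bridge_radius: int = 2
    min_object_area: int = 30
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.bridge_radius < 0:
            raise ValueError("bridge_radius must be >= 0")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def threshold_for(self, channel_index: int):
        if isinstance(self.threshold, (list, tuple)):
            return self.threshold[channel_index]
        return self.threshold


@dataclass
class CellCountResult:
    """Counts and final masks, one entry per channel."""

    counts: list[int]
    masks: list[np.ndarray]
    roi_id: str = ""


def binarize_channel(channel: np.ndarray, method: str | float = "otsu") -> np.ndarray:
    """mask = {intensity > threshold}; Otsu on a constant channel is empty."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError(f"expected a single 2-D intensity plane, got shape {channel.shape}")
    if isinstance(method, str):
        if np.ptp(channel) == 0:
            warnings.warn("constant channel: Otsu undefined, mask is empty", stacklevel=2)
            return np.zeros(channel.shape, dtype=bool)
        thr = float(threshold_otsu(channel))
    else:
        thr = float(method)
    return channel > thr


def bridge_fragments(mask: np.ndarray, bridge_radius: int) -> np.ndarray:
    """Morphological closing with a disk: dilate to merge intermittent
    fragments of one object, erode to cancel the net growth."""
    mask = np.asarray(mask, dtype=bool)
    if bridge_radius == 0:
        return mask.copy()
    selem = disk(bridge_radius)
    out = ndi.binary_dilation(mask, structure=selem, border_value=0)
    out = ndi.binary_erosion(out, structure=selem, border_value=1)
    return out


def remove_small_objects(mask: np.ndarray, min_object_area: int, connectivity: int = 8) -> np.ndarray:
    """Delete connected components with area strictly below min_object_area."""
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if connectivity == 4 else 2
    labels = sk_label(mask, connectivity=conn)
    if labels.max() == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_object_area
    keep[0] = False
    return keep[labels]


def count_objects(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components of the mask."""
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if connectivity == 4 else 2
    return int(sk_label(mask, connectivity=conn).max())


def run_if_pipeline(stack: np.ndarray, params: IFParams | None = None, roi_id: str = "") -> CellCountResult:
    """binarize -> bridge -> remove-small -> count, per channel."""
    if params is None:
        params = IFParams()
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a CxHxW stack, got shape {stack.shape}")
    shape = stack.shape[1:]
    counts: list[int] = []
    masks: list[np.ndarray] = []
    for c, channel in enumerate(stack):
        if channel.shape != shape:
            raise ValueError(f"channel {c} shape {channel.shape} != {shape}")
        m = binarize_channel(channel, params.threshold_for(c))
        m = bridge_fragments(m, params.bridge_radius)
        m = remove_small_objects(m, params.min_object_area, params.connectivity)
        counts.append(count_objects(m, params.connectivity))
        masks.append(m)
    return CellCountResult(counts=counts, masks=masks, roi_id=roi_id)
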