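"""Automated fibrosis scoring of Masson's-trichrome-stained lung sections.

The pipeline turns an RGB image of an MT-stained section into a single
*fibrosis score*: the fraction of the lung-tissue area occupied by
collagen-positive (blue-stained) pixels. It proceeds in five steps:

1. estimate the white slide background (achromatic, bright pixels), fill the
   image border with its mean colour, and segment the dark alveolar-wall
   tissue on the channel-averaged grayscale;
2. recover the whole lung-tissue region by morphologically closing the
   fragmented wall mask (dilate, drop small components, fill holes, erode);
3. locate fibrotic regions as places where the wall mask is densely packed,
   via a 2-D moving average of the wall mask;
4. within the fibrotic wall pixels, unmix collagen (blue) from fibrin/vessel
   (red) by a principal-component analysis of the pixel RGB values --
   the blue-vs-red contrast appears as a single component whose order and
   polarity vary between images and are detected automatically;
5. report |collagen ∩ lung| / |lung|.

Every unnamed threshold is surfaced in :class:`MTParams`. The whole module
is deterministic: no randomness anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from scipy import ndimage as ndi

__all__ = [
    "MTParams",
    "FibrosisResult",
    "MTStepError",
    "estimate_background",
    "fill_edges",
    "segment_alveolar_walls",
    "estimate_lung_region",
    "estimate_fibrotic_region",
    "moving_average_density",
    "extract_collagen_mask",
    "fibrosis_score",
    "run_mt_pipeline",
]


class MTStepError(RuntimeError):
    """A pipeline step failed; ``step`` names the step."""

    def __init__(self, step: str, message: str):
        super().__init__(f"[{step}] {message}")
        self.step = step


@dataclass
class MTParams:
    """Tunable parameters of the MT fibrosis-score pipeline.

    Attributes
    ----------
    cov_threshold : float
        Background pixels must have per-pixel coefficient of variation
        (std/mean over R,G,B) below this. White slide background is
        achromatic, so its CoV is near zero.
    brightness_floor : float
        Background pixels must additionally have channel mean >= this,
        in 8-bit intensity units.
    border_width : int
        Width of the image frame overwritten with the background mean
        before thresholding, to suppress scanner edge artifacts.
    wall_threshold : str | float
        "otsu", or a fixed grayscale value. Pixels darker than the
        threshold become the alveolar-wall mask.
    lung_dilation_radius : int
        Disk radius (px) for the dilate/erode pair that bridges the
        fragmented walls when recovering the lung region.
    min_contour_area : int | None
        Connected components smaller than this (px^2) are discarded as
        artifacts before hole filling. None = 0.1% of the image area.
    density_window : int
        Odd side length (px) of the moving-average box measuring local
        wall density.
    density_threshold : float
        Wall density above which a pixel is called fibrotic, in (0, 1).
    pca_components : tuple[int, ...]
        1-based principal components considered when looking for the
        blue-vs-red stain axis.
    collagen_threshold : str | float
        "otsu", or a fixed value applied to the signed PC projections.
    connectivity : int
        4 or 8; used for connected components and hole filling.
    """

    cov_threshold: float = 0.05
    brightness_floor: float = 200.0
    border_width: int = 8
    wall_threshold: str | float = "otsu"
    lung_dilation_radius: int = 10
    min_contour_area: int | None = None
    density_window: int = 51
    density_threshold: float = 0.35
    pca_components: tuple[int, ...] = (1, 2, 3)
    collagen_threshold: str | float = "otsu"
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.cov_threshold <= 0:
            raise ValueError("cov_threshold must be > 0")
        if self.density_window < 3 or self.density_window % 2 == 0:
            raise ValueError("density_window must be odd and >= 3")
        if not 0.0 < self.density_threshold < 1.0:
            raise ValueError("density_threshold must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if isinstance(self.wall_threshold, str) and self.wall_threshold != "otsu":
            raise ValueError("wall_threshold must be 'otsu' or a number")
        if isinstance(self.collagen_threshold, str) and self.collagen_threshold != "otsu":
            raise ValueError("collagen_threshold must be 'otsu' or a number")
        comps = tuple(int(c) for c in self.pca_components)
        if not comps or any(c < 1 or c > 3 for c in comps):
            raise ValueError("pca_components must be a non-empty subset of {1, 2, 3}")
        self.pca_components = comps

    def resolved_min_contour_area(self, shape: tuple[int, int]) -> int:
        if self.min_contour_area is not None:
            return int(self.min_contour_area)
        return max(1, int(round(0.001 * shape[0] * shape[1])))


@dataclass
class FibrosisResult:
    """All intermediate masks and the final score of one MT image."""

    wall_mask: np.ndarray
    lung_mask: np.ndarray
    fibrotic_mask: np.ndarray
    collagen_mask: np.ndarray
    background_mean_rgb: np.ndarray
    selected_pc_index: int  # 1-based; 0 if unmixing was degenerate
    pc_loading: np.ndarray
    polarity_sign: int
    fibrosis_score: float


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img


def _skimage_connectivity(connectivity: int) -> int:
    # skimage/ndimage express 4-neighbour adjacency as rank-1 connectivity
    return 1 if connectivity == 4 else 2


def estimate_background(
    img: np.ndarray, cov_threshold: float = 0.05, brightness_floor: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Locate achromatic bright slide background and return (mask, mean RGB).

    A pixel is background when std(R,G,B)/mean(R,G,B) < ``cov_threshold``
    and mean(R,G,B) >= ``brightness_floor``.
    """
    img = _as_rgb(img).astype(np.float64)
    mean = img.mean(axis=2)
    sd = img.std(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.inf)
    mask = (cov < cov_threshold) & (mean >= brightness_floor)
    if not mask.any():
        raise MTStepError(
            "estimate_background",
            f"no pixel qualifies as background "
            f"(cov_threshold={cov_threshold}, brightness_floor={brightness_floor})",
        )
    return mask, img[mask].mean(axis=0)


def fill_edges(img: np.ndarray, background_mean: np.ndarray, border_width: int) -> np.ndarray:
    """Overwrite a frame of ``border_width`` pixels with the background mean."""
    img = _as_rgb(img)
    h, w = img.shape[:2]
    if border_width < 0 or border_width >= min(h, w) / 2:
        raise ValueError(f"border_width {border_width} must be in [0, min(H, W)/2)")
    out = img.copy()
    if border_width == 0:
        return out
    fill = np.asarray(background_mean, dtype=np.float64)
    fill = np.clip(np.round(fill), 0, 255).astype(img.dtype)
    b = border_width
    out[:b, :] = fill
    out[-b:, :] = fill
    out[:, :b] = fill
    out[:, -b:] = fill
    return out


def grayscale(img: np.ndarray) -> np.ndarray:
    """Channel-averaged grayscale (the pipeline's only gray conversion)."""
    return _as_rgb(img).astype(np.float64).mean(axis=2)


def segment_alveolar_walls(
    img: np.ndarray,
    background_mean: np.ndarray,
    method: str | float = "otsu",
) -> np.ndarray:
    """Segment tissue darker than the slide background on the grayscale image.

    The threshold is clamped strictly below the background's grayscale mean
    so background can never be called tissue.
    """
    gray = grayscale(img)
    bg_gray = float(np.asarray(background_mean, dtype=np.float64).mean())
    if np.ptp(gray) == 0:
        warnings.warn("constant grayscale image: wall mask is empty", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    if isinstance(method, str):
        thr = float(threshold_otsu(gray))
    else:
        thr = float(method)
    thr = min(thr, np.nextafter(bg_gray, -np.inf))
    return gray < thr


def estimate_lung_region(
    wall_mask: np.ndarray,
    dilation_radius: int = 10,
    min_contour_area: int = 250,
    connectivity: int = 8,
) -> np.ndarray:
    """Close the fragmented wall mask into the whole lung-tissue region.

    dilate(disk) -> drop components below ``min_contour_area`` -> fill the
    holes of what remains -> erode(same disk). On a filled convex shape the
    dilate/erode pair cancels exactly.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        return np.zeros_like(wall_mask)
    selem = disk(dilation_radius) if dilation_radius > 0 else None
    struct = ndi.generate_binary_structure(2, _skimage_connectivity(connectivity))
    m = wall_mask
    if selem is not None:
        m = ndi.binary_dilation(m, structure=selem, border_value=0)
    labels, n = ndi.label(m, structure=struct)
    if n:
        areas = np.bincount(labels.ravel())
        keep = areas >= min_contour_area
        keep[0] = False
        m = keep[labels]
    m = ndi.binary_fill_holes(m, structure=struct)
    if selem is not None:
        # border_value=1 so erosion does not eat tissue touching the frame
        m = ndi.binary_erosion(m, structure=selem, border_value=1)
    return m


def moving_average_density(mask: np.ndarray, window: int) -> np.ndarray:
    """Exact box moving average of a binary mask with zero padding.

    Computed from an integer summed-area table, so the value at every pixel
    is exactly (integer window sum) / window**2 -- bit-identical to a naive
    double-loop implementation.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    r = window // 2
    padded = np.zeros((h + 2 * r + 1, w + 2 * r + 1), dtype=np.int64)
    padded[r + 1 : r + 1 + h, r + 1 : r + 1 + w] = mask
    sat = padded.cumsum(axis=0).cumsum(axis=1)
    # window sum at (i, j) over rows i-r..i+r, cols j-r..j+r (zero outside)
    a = sat[window:, window:]
    b = sat[:-window, window:]
    c = sat[window:, :-window]
    d = sat[:-window, :-window]
    win_sum = a - b - c + d
    return win_sum[:h, :w] / float(window * window)


def estimate_fibrotic_region(
    wall_mask: np.ndarray, density_window: int = 51, density_threshold: float = 0.35
) -> np.ndarray:
    """Pixels whose local wall density exceeds the threshold.

    Fibrotic tissue has thickened, densely packed walls, so the moving
    average of the wall mask is high there and low over the regular sparse
    alveolar lattice.
    """
    density = moving_average_density(wall_mask, density_window)
    return density > density_threshold


def extract_collagen_mask(
    img: np.ndarray,
    fibrotic_mask: np.ndarray,
    wall_mask: np.ndarray,
    params: MTParams | None = None,
) -> tuple[np.ndarray, int, np.ndarray, int]:
    """Unmix collagen (blue) from fibrin/vessel (red) pixels by spectral PCA.

    Candidate pixels are ``fibrotic_mask & wall_mask``. PCA is run on their
    mean-centred RGB triples (unscaled covariance). Among the considered
    components with non-negligible eigenvalue, the one whose loading ``w``
    maximizes ``|w_B - w_R|`` carries the blue-vs-red stain transition; its
    order and sign vary between images, so projections are multiplied by
    ``sign(w_B - w_R)`` to make "more blue" always mean "larger". The
    collagen mask is the candidates whose signed projection exceeds the
    configured threshold.

    Returns ``(mask, selected_pc_index (1-based, 0 if degenerate),
    pc_loading, polarity_sign)``.
    """
    if params is None:
        params = MTParams()
    img = _as_rgb(img).astype(np.float64)
    cand = np.asarray(fibrotic_mask, dtype=bool) & np.asarray(wall_mask, dtype=bool)
    empty = np.zeros(cand.shape, dtype=bool)
    n = int(cand.sum())
    if n < 10:
        warnings.warn(f"only {n} candidate pixels: collagen mask is empty", stacklevel=2)
        return empty, 0, np.zeros(3), 0
    pix = img[cand]
    centered = pix - pix.mean(axis=0)
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 1.0) * 1e-10
    valid = [c for c in params.pca_components if evals[c - 1] > tol]
    if not valid:
        warnings.warn("rank-deficient colour covariance: collagen mask is empty", stacklevel=2)
        return empty, 0, np.zeros(3), 0
    contrasts = [abs(evecs[2, c - 1] - evecs[0, c - 1]) for c in valid]
    sel = valid[int(np.argmax(contrasts))]
    w = evecs[:, sel - 1]
    polarity = int(np.sign(w[2] - w[0]))
    if polarity == 0:
        warnings.warn("degenerate loading (w_B == w_R): collagen mask is empty", stacklevel=2)
        return empty, sel, w, 0
    proj = polarity * (centered @ w)
    if isinstance(params.collagen_threshold, str):
        if np.ptp(proj) == 0:
            warnings.warn("constant projections: collagen mask is empty", stacklevel=2)
            return empty, sel, w, polarity
        thr = float(threshold_otsu(proj))
    else:
        thr = float(params.collagen_threshold)
    mask = empty.copy()
    mask[cand] = proj > thr
    return mask, sel, w, polarity


def fibrosis_score(collagen_mask: np.ndarray, lung_mask: np.ndarray) -> float:
    """|collagen ∩ lung| / |lung|, the final score in [0, 1]."""
    lung = np.asarray(lung_mask, dtype=bool)
    denom = int(lung.sum())
    if denom == 0:
        raise MTStepError("fibrosis_score", "empty lung mask: score undefined")
    num = int((np.asarray(collagen_mask, dtype=bool) & lung).sum())
    return num / denom


def run_mt_pipeline(img: np.ndarray, params: MTParams | None = None) -> FibrosisResult:
    """Run the five-step fibrosis-score pipeline on one RGB image."""
    if params is None:
        params = MTParams()
    img = _as_rgb(img)

    def _step(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MTStepError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with step context
            raise MTStepError(name, str(exc)) from exc

    _, bg_mean = _step("background", estimate_background, img, params.cov_threshold, params.brightness_floor)
    filled = _step("fill_edges", fill_edges, img, bg_mean, params.border_width)
    wall = _step("walls", segment_alveolar_walls, filled, bg_mean, params.wall_threshold)
    lung = _step(
        "lung_region",
        estimate_lung_region,
        wall,
        params.lung_dilation_radius,
        params.resolved_min_contour_area(wall.shape),
        params.connectivity,
    )
    fibrotic = _step(
        "fibrotic_region", estimate_fibrotic_region, wall, params.density_window, params.density_threshold
    )
    collagen, sel, loading, polarity = _step(
        "collagen_unmixing", extract_collagen_mask, filled, fibrotic, wall, params
    )
    score = _step("score", fibrosis_score, collagen, lung)
    return FibrosisResult(
        wall_mask=wall,
        lung_mask=lung,
        fibrotic_mask=fibrotic,
        collagen_mask=collagen,
        background_mean_rgb=np.asarray(bg_mean),
        selected_pc_index=sel,
        pc_loading=np.asarray(loading),
        polarity_sign=polarity,
        fibrosis_score=score,
    )
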