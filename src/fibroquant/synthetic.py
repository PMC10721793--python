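"""Seeded synthetic inputs with planted ground truth.

Three generators emulate the data the quantification pipelines consume:

* :func:`generate_mt_image` -- a trichrome-stained lung section: white slide
  background, an elliptical lung with a sparse dark alveolar-wall lattice
  and a pleural boundary, a densely packed collagen patch (blue, thickened
  walls) occupying a requested fraction of the lung, and red fibrin blobs.
  The planted collagen fraction is the ground-truth fibrosis score.
* :func:`generate_if_stack` -- a multi-channel immunofluorescence field with
  a known number of well-separated bright disk objects per channel.
* :func:`generate_count_matrix` -- a gene-by-cell Poisson count matrix with
  planted low-feature cells, high-mitochondrial cells, a high-signature
  subpopulation, and phase-dependent frequencies of one designated cluster.

Every generator is a pure function of its parameters including the seed:
identical parameters give bitwise-identical output. Masks and membership
lists are fixed before noise is added, so noise never changes ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_selem

from .sc import CountMatrix

__all__ = [
    "MTSceneParams",
    "MTGroundTruth",
    "IFSceneParams",
    "SynthCountParams",
    "generate_mt_image",
    "generate_if_stack",
    "generate_count_matrix",
    "generate_phase_labels",
]

_MOUSE_MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

PHASES = ("intact", "inflammatory", "fibrotic")


# --------------------------------------------------------------------------
# Trichrome scenes
# --------------------------------------------------------------------------

@dataclass
class MTSceneParams:
    """Geometry, stain colours and noise of a synthetic trichrome scene.

    The lung is an ellipse with semi-axes ``lung_axes`` (fractions of the
    half image size). Alveolar walls form a sparse grid lattice
    (``wall_spacing`` / ``wall_thickness``); a pleural boundary line closes
    the lung outline. The collagen patch is a disk in which the lattice is
    twice as dense and the walls are thickened until almost confluent
    (the fibrotic "densely packed" morphology); its radius is solved so the
    collagen-positive pixels occupy ``collagen_patch_fraction`` of the lung
    area. Intra-lung air spaces carry a faint lavender tint so that, unlike
    the achromatic slide background, they have a chromatic coefficient of
    variation and are not mistaken for background.
    """

    image_size: tuple[int, int] = (512, 512)
    lung_axes: tuple[float, float] = (0.70, 0.72)
    wall_spacing: int = 16
    wall_thickness: int = 2
    collagen_wall_spacing: int | None = None   # default: wall_spacing // 2
    collagen_wall_thickness: int | None = None  # default: spacing - 1
    background_color: tuple[int, int, int] = (245, 245, 245)
    airspace_color: tuple[int, int, int] = (245, 210, 250)
    wall_color: tuple[int, int, int] = (150, 90, 130)
    collagen_color: tuple[int, int, int] = (70, 90, 185)
    fibrin_color: tuple[int, int, int] = (200, 85, 95)
    collagen_patch_fraction: float = 0.0
    n_fibrin_blobs: int = 2
    fibrin_blob_radius: int = 12
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.collagen_patch_fraction <= 0.9:
            raise ValueError(
                "collagen_patch_fraction must be in [0, 0.9]: a larger patch "
                "cannot be placed inside the lung"
            )
        for name in ("background_color", "airspace_color", "wall_color", "collagen_color", "fibrin_color"):
            c = getattr(self, name)
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]^3")
        for tissue in ("wall_color", "collagen_color", "fibrin_color"):
            c = getattr(self, tissue)
            if not all(b > t for b, t in zip(self.background_color, c)):
                raise ValueError(f"background_color must be brighter than {tissue} in every channel")
        if not self.collagen_color[2] > self.collagen_color[0]:
            raise ValueError("collagen_color must have blue > red")
        if not self.fibrin_color[0] > self.fibrin_color[2]:
            raise ValueError("fibrin_color must have red > blue")
        if self.wall_thickness < 1 or self.wall_spacing <= self.wall_thickness:
            raise ValueError("wall_spacing must exceed wall_thickness >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def dense_spacing(self) -> int:
        return self.collagen_wall_spacing or max(2, self.wall_spacing // 2)

    @property
    def dense_thickness(self) -> int:
        return self.collagen_wall_thickness or self.dense_spacing - 1


@dataclass
class MTGroundTruth:
    """Planted masks of one synthetic trichrome scene.

    ``planted_score`` is recomputed from the emitted masks, so
    ``|collagen_mask| / |lung_mask|`` holds exactly.
    """

    lung_mask: np.ndarray
    collagen_mask: np.ndarray
    planted_score: float
    wall_mask: np.ndarray  # every stained tissue pixel (walls, collagen, fibrin)
    fibrin_mask: np.ndarray


def _lattice(shape: tuple[int, int], spacing: int, thickness: int, offset: tuple[int, int]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy + offset[0]) % spacing < thickness) | ((xx + offset[1]) % spacing < thickness)


def generate_mt_image(params: MTSceneParams) -> tuple[np.ndarray, MTGroundTruth]:
    """Render one trichrome scene; returns (uint8 RGB image, ground truth)."""
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay = params.lung_axes[0] * h / 2.0
    ax = params.lung_axes[1] * w / 2.0
    yy, xx = np.ogrid[:h, :w]
    lung = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    lung_area = int(lung.sum())
    if lung_area == 0:
        raise ValueError("lung ellipse has zero area; enlarge image_size or lung_axes")

    sparse_off = tuple(rng.integers(0, params.wall_spacing, size=2))
    dense_off = tuple(rng.integers(0, params.dense_spacing, size=2))
    sparse = _lattice((h, w), params.wall_spacing, params.wall_thickness, sparse_off)
    dense = _lattice((h, w), params.dense_spacing, params.dense_thickness, dense_off)

    # pleural boundary closes the lung outline so the wall mask traces it
    boundary = lung & ~ndi.binary_erosion(lung, structure=disk_selem(params.wall_thickness), border_value=1)

    # collagen patch: disk around a jittered centre, radius solved so that
    # the dense-lattice pixels inside it occupy the requested lung fraction
    jitter = rng.uniform(-0.15, 0.15, size=2)
    pcy, pcx = cy + jitter[0] * ay, cx + jitter[1] * ax
    dist2 = (yy - pcy) ** 2 + (xx - pcx) ** 2
    target = int(round(params.collagen_patch_fraction * lung_area))
    if target > 0:
        dense_in_lung = dense & lung
        max_count = int(dense_in_lung.sum())
        if target > max_count:
            raise ValueError(
                f"collagen_patch_fraction {params.collagen_patch_fraction} not achievable: "
                f"at most {max_count / lung_area:.3f} of the lung can be collagen"
            )
        lo, hi = 0.0, float(np.hypot(h, w))
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if int((dense_in_lung & (dist2 <= mid * mid)).sum()) < target:
                lo = mid
            else:
                hi = mid
        patch_region = lung & (dist2 <= hi * hi)
        collagen = dense & patch_region
    else:
        patch_region = np.zeros((h, w), dtype=bool)
        collagen = patch_region

    # fibrin blobs: solid red disks inside the lung, clear of the patch
    fibrin = np.zeros((h, w), dtype=bool)
    r_blob = params.fibrin_blob_radius
    if params.n_fibrin_blobs > 0 and r_blob > 0:
        placed = 0
        patch_radius = float(np.sqrt(max(dist2[patch_region].max(), 0.0))) if patch_region.any() else 0.0
        for _ in range(200 * params.n_fibrin_blobs):
            if placed == params.n_fibrin_blobs:
                break
            by = rng.uniform(cy - ay, cy + ay)
            bx = rng.uniform(cx - ax, cx + ax)
            inside = ((by - cy) / ay) ** 2 + ((bx - cx) / ax) ** 2 <= (1 - (r_blob + 2) / min(ay, ax)) ** 2
            clear = np.hypot(by - pcy, bx - pcx) > patch_radius + r_blob + 4
            if inside and clear:
                fibrin |= (yy - by) ** 2 + (xx - bx) ** 2 <= r_blob * r_blob
                placed += 1
        fibrin &= lung & ~patch_region

    wall_sparse = ((sparse & lung) | boundary) & ~patch_region & ~fibrin
    tissue = wall_sparse | collagen | fibrin

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = params.background_color
    img[lung] = params.airspace_color
    img[wall_sparse] = params.wall_color
    img[fibrin] = params.fibrin_color
    img[collagen] = params.collagen_color
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = MTGroundTruth(
        lung_mask=lung,
        collagen_mask=collagen,
        planted_score=int(collagen.sum()) / lung_area,
        wall_mask=tissue,
        fibrin_mask=fibrin,
    )
    return img, truth


# --------------------------------------------------------------------------
# Immunofluorescence stacks
# --------------------------------------------------------------------------

@dataclass
class IFSceneParams:
    """A multi-channel IF field of bright disks on a dim noisy background."""

    image_size: tuple[int, int] = (256, 256)
    n_channels: int = 4
    objects_per_channel: int = 25
    object_radius: int = 5
    min_separation: int = 30
    peak_intensity: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 8.0
    seed: int = 0
    max_tries_per_object: int = 2000

    def __post_init__(self) -> None:
        if self.min_separation <= 2 * self.object_radius:
            raise ValueError("min_separation must exceed 2 * object_radius")
        if self.objects_per_channel < 0 or self.n_channels < 1:
            raise ValueError("objects_per_channel >= 0 and n_channels >= 1 required")
        margin = self.object_radius + 1
        if min(self.image_size) <= 2 * margin:
            raise ValueError("objects do not fit inside the frame")
        if self.peak_intensity <= self.background_level:
            raise ValueError("peak_intensity must exceed background_level")


def generate_if_stack(params: IFSceneParams) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render the stack; returns (channels x H x W float array, centre list).

    Centres are placed by dart throwing with a bounded number of retries;
    an infeasible packing raises RuntimeError.
    """
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    yy, xx = np.ogrid[:h, :w]
    margin = params.object_radius + 1
    stack = np.full((params.n_channels, h, w), params.background_level, dtype=np.float64)
    centers: list[np.ndarray] = []
    for c in range(params.n_channels):
        placed: list[tuple[int, int]] = []
        tries = 0
        budget = params.max_tries_per_object * max(1, params.objects_per_channel)
        while len(placed) < params.objects_per_channel:
            if tries >= budget:
                raise RuntimeError(
                    f"channel {c}: placed only {len(placed)}/{params.objects_per_channel} objects "
                    f"after {budget} tries; packing at min_separation={params.min_separation} "
                    "appears infeasible"
                )
            tries += 1
            py = int(rng.integers(margin, h - margin))
            px = int(rng.integers(margin, w - margin))
            if all(np.hypot(py - qy, px - qx) >= params.min_separation for qy, qx in placed):
                placed.append((py, px))
        for py, px in placed:
            stack[c][(yy - py) ** 2 + (xx - px) ** 2 <= params.object_radius ** 2] = params.peak_intensity
        centers.append(np.array(placed, dtype=np.int64).reshape(-1, 2))
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    return stack, centers


# --------------------------------------------------------------------------
# Count matrices
# --------------------------------------------------------------------------

@dataclass
class SynthCountParams:
    """A Poisson gene-by-cell matrix with planted QC-failing cells,
    a high-signature subpopulation and phase-dependent cluster frequencies.

    Per-gene baseline rates are exponential draws scaled by
    ``baseline_mean``; mitochondrial genes are rescaled so a normal cell's
    expected mito fraction is ``normal_mito_fraction``. Low-feature cells
    have their whole library scaled by ``low_feature_scale``; high-mito
    cells have mito rates boosted until the expected mito fraction is
    ``high_mito_fraction``; signature-positive cells have the signature
    genes multiplied by ``signature_fold``. The designated cluster is
    planted at exactly ``round(freq * n_phase)`` cells per phase.
    """

    n_genes: int = 2000
    n_cells: int = 600
    n_mito_genes: int = 13
    baseline_mean: float = 1.5
    frac_low_feature: float = 0.0
    frac_high_mito: float = 0.0
    frac_signature: float = 0.1
    low_feature_scale: float = 0.05
    normal_mito_fraction: float = 0.015
    high_mito_fraction: float = 0.15
    signature_genes: tuple[str, ...] | None = None
    signature_fold: float = 4.0
    n_signature_genes: int = 10
    phase_labels: tuple[str, ...] | None = None
    planted_cluster_freqs: dict = field(
        default_factory=lambda: {"intact": 0.01, "inflammatory": 0.04, "fibrotic": 0.04}
    )
    min_features: int = 200
    max_features: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito_genes > self.n_genes:
            raise ValueError("n_mito_genes must be <= n_genes")
        for name in ("frac_low_feature", "frac_high_mito", "frac_signature"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.high_mito_fraction <= 1.0 or not 0.0 < self.normal_mito_fraction < 1.0:
            raise ValueError("mito fractions must be in (0, 1]")
        if self.high_mito_fraction <= 0.05:
            raise ValueError("high_mito_fraction must exceed the 5% QC cutoff")
        for phase, f in self.planted_cluster_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"planted_cluster_freqs[{phase!r}] must be in [0, 1]")
        if self.phase_labels is not None and len(self.phase_labels) != self.n_cells:
            raise ValueError("phase_labels must have one entry per cell")
        if self.signature_fold <= 0:
            raise ValueError("signature_fold must be > 0")


def _gene_names(n_genes: int, n_mito: int) -> tuple[list[str], list[str]]:
    mito = list(_MOUSE_MITO_GENES[:n_mito])
    mito += [f"mt-X{i}" for i in range(len(mito) + 1, n_mito + 1)]
    body = [f"Gene{i:05d}" for i in range(1, n_genes - n_mito + 1)]
    return body + mito, mito


def generate_phase_labels(
    n_cells_per_phase: dict[str, int],
    cluster_freqs: dict[str, float],
    rng: np.random.Generator | int | None = 0,
    cluster_name: str = "planted",
    other_name: str = "other",
) -> pd.DataFrame:
    """Per-cell (cell, phase, cluster) labels with the designated cluster
    planted at exactly round(freq * n) cells per phase, in shuffled order."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    i = 0
    for phase, n in n_cells_per_phase.items():
        k = int(round(cluster_freqs.get(phase, 0.0) * n))
        members = np.zeros(n, dtype=bool)
        members[:k] = True
        rng.shuffle(members)
        for m in members:
            rows.append({"cell": f"cell{i:06d}", "phase": phase, "cluster": cluster_name if m else other_name})
            i += 1
    return pd.DataFrame(rows)


def generate_count_matrix(
    params: SynthCountParams,
) -> tuple[CountMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Draw the matrix; returns (CountMatrix, labels table, membership).

    The labels table has columns cell / cluster / phase / compartment; the
    membership dict names the planted ``low_feature`` / ``high_mito`` /
    ``signature`` / ``target_cluster`` cells.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    genes, mito = _gene_names(p.n_genes, p.n_mito_genes)
    n_body = p.n_genes - p.n_mito_genes

    rates = rng.exponential(1.0, size=p.n_genes) * p.baseline_mean
    if p.n_mito_genes > 0:
        body_total = rates[:n_body].sum()
        mito_target = body_total * p.normal_mito_fraction / (1.0 - p.normal_mito_fraction)
        cur = rates[n_body:].sum()
        if cur > 0:
            rates[n_body:] *= mito_target / cur

    # phases and planted-cluster membership (exact per-phase frequencies)
    if p.phase_labels is not None:
        phases = list(p.phase_labels)
    else:
        per = p.n_cells // 3
        phases = (
            ["intact"] * per
            + ["inflammatory"] * per
            + ["fibrotic"] * (p.n_cells - 2 * per)
        )
    phase_counts: dict[str, int] = {}
    for ph in phases:
        phase_counts[ph] = phase_counts.get(ph, 0) + 1
    cluster = np.empty(p.n_cells, dtype=object)
    for ph, n in phase_counts.items():
        idx = [i for i in range(p.n_cells) if phases[i] == ph]
        k = int(round(p.planted_cluster_freqs.get(ph, 0.0) * n))
        members = np.zeros(n, dtype=bool)
        members[:k] = True
        rng.shuffle(members)
        for j, i in enumerate(idx):
            cluster[i] = "planted" if members[j] else "other"

    # disjoint planted QC / signature groups
    n_low = int(round(p.frac_low_feature * p.n_cells))
    n_high = int(round(p.frac_high_mito * p.n_cells))
    n_sig = int(round(p.frac_signature * p.n_cells))
    if n_low + n_high + n_sig > p.n_cells:
        raise ValueError("planted fractions overlap: frac_low + frac_high_mito + frac_signature > 1")
    perm = rng.permutation(p.n_cells)
    low_idx = perm[:n_low]
    high_idx = perm[n_low : n_low + n_high]
    sig_idx = perm[n_low + n_high : n_low + n_high + n_sig]

    if p.signature_genes is None:
        sig_genes = genes[: p.n_signature_genes]
    else:
        sig_genes = list(p.signature_genes)
        missing = set(sig_genes) - set(genes)
        if missing:
            raise ValueError(f"signature_genes not in the gene list: {sorted(missing)}")
    gene_index = {g: i for i, g in enumerate(genes)}
    sig_rows = [gene_index[g] for g in sig_genes]

    # expected-value invariants of the planted groups
    exp_detected_low = float(np.sum(1.0 - np.exp(-rates * p.low_feature_scale)))
    if n_low > 0 and p.min_features <= exp_detected_low <= p.max_features:
        raise ValueError(
            f"planted low-feature cells expect {exp_detected_low:.0f} detected features, "
            f"inside the QC window [{p.min_features}, {p.max_features}]"
        )
    exp_detected_normal = float(np.sum(1.0 - np.exp(-rates)))
    if not p.min_features <= exp_detected_normal <= p.max_features:
        raise ValueError(
            f"normal cells expect {exp_detected_normal:.0f} detected features, "
            f"outside the QC window [{p.min_features}, {p.max_features}]"
        )

    lam = np.tile(rates[:, None], (1, p.n_cells))
    if len(low_idx):
        lam[:, low_idx] *= p.low_feature_scale
    if len(high_idx) and p.n_mito_genes > 0:
        m, hf = p.normal_mito_fraction, p.high_mito_fraction
        boost = hf * (1.0 - m) / (m * (1.0 - hf))
        lam[np.ix_(np.arange(n_body, p.n_genes), high_idx)] *= boost
    if len(sig_idx) and p.signature_fold != 1.0:
        lam[np.ix_(sig_rows, sig_idx)] *= p.signature_fold

    counts = rng.poisson(lam)
    cells = [f"cell{i:06d}" for i in range(p.n_cells)]
    matrix = CountMatrix(genes, cells, counts, frozenset(mito))
    labels = pd.DataFrame(
        {
            "cell": cells,
            "cluster": cluster,
            "phase": phases,
            "compartment": ["Ptprc+"] * p.n_cells,
        }
    )
    membership = {
        "low_feature": [cells[i] for i in sorted(low_idx)],
        "high_mito": [cells[i] for i in sorted(high_idx)],
        "signature": [cells[i] for i in sorted(sig_idx)],
        "target_cluster": [cells[i] for i in range(p.n_cells) if cluster[i] == "planted"],
        "signature_genes": sig_genes,
    }
    return matrix, labels, membership
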