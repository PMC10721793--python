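"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (double loops, BFS flood fill,
per-cell scans) kept free of the library code paths they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_density(mask: np.ndarray, window: int) -> np.ndarray:
    """Box moving average by an explicit double loop with zero padding."""
    mask = np.asarray(mask, dtype=np.int64)
    h, w = mask.shape
    r = window // 2
    padded = np.zeros((h + 2 * r, w + 2 * r), dtype=np.int64)
    padded[r : r + h, r : r + w] = mask
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + window, j : j + window].sum() / float(window * window)
    return out


def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask)
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    y, x = q.popleft()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
    return count


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Pixel sets of every connected component, by flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = {(i, j)}
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    y, x = q.popleft()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            comp.add((ny, nx))
                            q.append((ny, nx))
                comps.append(comp)
    return comps


def area_filter(mask: np.ndarray, min_area: int, connectivity: int) -> np.ndarray:
    """Per-component area filter built on the flood-fill oracle."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_area:
            for y, x in comp:
                out[y, x] = True
    return out


def qc_survivors(counts: np.ndarray, genes: list[str], mito_genes: set[str],
                 min_features: int = 200, max_features: int = 5000,
                 max_mito: float = 0.05) -> list[int]:
    """Cell indices passing QC, by an explicit per-cell scan."""
    mito_rows = [i for i, g in enumerate(genes) if g in mito_genes]
    keep = []
    for c in range(counts.shape[1]):
        col = counts[:, c]
        total = int(col.sum())
        if total == 0:
            continue
        nfeat = int((col > 0).sum())
        mito = sum(int(col[i]) for i in mito_rows) / total
        if min_features <= nfeat <= max_features and mito <= max_mito:
            keep.append(c)
    return keep


def crosstab_abundance(cell_types, phases, reference: str):
    """Hand-tabulated (type, phase) -> (frequency, log2FC) dictionary."""
    import math

    phases_u = sorted(set(phases))
    types_u = sorted(set(cell_types))
    table = {}
    totals = {ph: sum(1 for p in phases if p == ph) for ph in phases_u}
    freqs = {}
    for ph in phases_u:
        for t in types_u:
            n = sum(1 for ct, p in zip(cell_types, phases) if ct == t and p == ph)
            freqs[(t, ph)] = n / totals[ph]
    for (t, ph), f in freqs.items():
        ref = freqs[(t, reference)]
        l2 = math.log2(f / ref) if ref > 0 and f > 0 else (float("nan") if ref == 0 else float("-inf"))
        table[(t, ph)] = (f, l2)
    return table
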