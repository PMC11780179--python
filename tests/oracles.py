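"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage


def bfs_flood_fill(values, seed, threshold, connectivity=26, roi_slices=None):
    """Pure-python breadth-first flood fill (independent of ndimage.label)."""
    values = np.asarray(values)
    allowed = values <= threshold
    if roi_slices is not None:
        inroi = np.zeros_like(allowed)
        inroi[roi_slices] = True
        allowed &= inroi
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    mask = np.zeros_like(allowed)
    seed = tuple(int(v) for v in seed)
    if not allowed[seed]:
        raise ValueError("seed not allowed")
    mask[seed] = True
    q = deque([seed])
    shape = values.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if allowed[nz, ny, nx] and not mask[nz, ny, nx]:
                    mask[nz, ny, nx] = True
                    q.append((nz, ny, nx))
    return mask


def dilation_flood_fill(values, seed, threshold, connectivity=26, roi_slices=None):
    """Frontier expansion via repeated binary dilation until fixpoint."""
    values = np.asarray(values)
    allowed = values <= threshold
    if roi_slices is not None:
        inroi = np.zeros_like(allowed)
        inroi[roi_slices] = True
        allowed &= inroi
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    mask = np.zeros_like(allowed)
    mask[tuple(int(v) for v in seed)] = True
    while True:
        grown = ndimage.binary_dilation(mask, structure=structure) & allowed
        if (grown == mask).all():
            return mask
        mask = grown


def brute_force_bilateral(values, spacing, sigma_spatial_mm, sigma_range):
    """Triple-loop bilateral filter with symmetric padding, 3-sigma box."""
    values = np.asarray(values, float)
    sig_vox = [sigma_spatial_mm / s for s in spacing]
    radii = [max(1, int(np.ceil(3.0 * sv))) for sv in sig_vox]
    padded = np.pad(values, [(r, r) for r in radii], mode="symmetric")
    out = np.empty_like(values)
    nz, ny, nx = values.shape
    rz, ry, rx = radii
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                c = values[z, y, x]
                num = den = 0.0
                for dz in range(-rz, rz + 1):
                    for dy in range(-ry, ry + 1):
                        for dx in range(-rx, rx + 1):
                            v = padded[z + rz + dz, y + ry + dy, x + rx + dx]
                            w = np.exp(
                                -0.5
                                * (
                                    (dz / sig_vox[0]) ** 2
                                    + (dy / sig_vox[1]) ** 2
                                    + (dx / sig_vox[2]) ** 2
                                )
                            ) * np.exp(-((v - c) ** 2) / (2 * sigma_range**2))
                            num += w * v
                            den += w
                out[z, y, x] = num / den
    return out


def mc_studentized_range_sf(q, k, df, n_draws=1_000_000, seed=0):
    """Monte-Carlo survival function of the studentized range."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    rng_range = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return float(np.mean(rng_range / s >= q))
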