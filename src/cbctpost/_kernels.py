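"""Numba inner loops for the non-local-means weighting.

The kernels operate on mirror-padded arrays (padding margin =
search_radius + patch_radius) and a per-voxel h^2 map.  Loop order is
row-major over search offsets with the centre offset skipped, and row-major
over patch offsets inside the squared-distance accumulation; the brute-force
reference implementation in the test suite uses the same order, so the two
agree to floating-point round-off.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def nlm_2d(padded, h2, w_ori, search_radius, patch_radius, out):
    m = search_radius + patch_radius
    ny, nx = h2.shape
    for i in range(ny):
        for j in range(nx):
            ci = i + m
            cj = j + m
            h2v = h2[i, j]
            if h2v <= 0.0:
                out[i, j] = padded[ci, cj]
                continue
            acc = w_ori * padded[ci, cj]
            z = w_ori
            for di in range(-search_radius, search_radius + 1):
                for dj in range(-search_radius, search_radius + 1):
                    if di == 0 and dj == 0:
                        continue
                    ssd = 0.0
                    for pi in range(-patch_radius, patch_radius + 1):
                        for pj in range(-patch_radius, patch_radius + 1):
                            d = padded[ci + pi, cj + pj] - padded[ci + di + pi, cj + dj + pj]
                            ssd += d * d
                    w = math.exp(-ssd / h2v)
                    acc += w * padded[ci + di, cj + dj]
                    z += w
            out[i, j] = acc / z


@njit(cache=False)
def nlm_3d(padded, h2, w_ori, search_radius, patch_radius, out):
    m = search_radius + patch_radius
    nz, ny, nx = h2.shape
    for k in range(nz):
        for i in range(ny):
            for j in range(nx):
                ck = k + m
                ci = i + m
                cj = j + m
                h2v = h2[k, i, j]
                if h2v <= 0.0:
                    out[k, i, j] = padded[ck, ci, cj]
                    continue
                acc = w_ori * padded[ck, ci, cj]
                z = w_ori
                for dk in range(-search_radius, search_radius + 1):
                    for di in range(-search_radius, search_radius + 1):
                        for dj in range(-search_radius, search_radius + 1):
                            if dk == 0 and di == 0 and dj == 0:
                                continue
                            ssd = 0.0
                            for pk in range(-patch_radius, patch_radius + 1):
                                for pi in range(-patch_radius, patch_radius + 1):
                                    for pj in range(-patch_radius, patch_radius + 1):
                                        d = (
                                            padded[ck + pk, ci + pi, cj + pj]
                                            - padded[ck + dk + pk, ci + di + pi, cj + dj + pj]
                                        )
                                        ssd += d * d
                            w = math.exp(-ssd / h2v)
                            acc += w * padded[ck + dk, ci + di, cj + dj]
                            z += w
                out[k, i, j] = acc / z
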