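"""Numba kernels for the lattice-free Brownian dynamics update.

The kernels are deliberately free of Python objects: the caller pre-draws
all random variates with a seeded numpy Generator so that trajectories are
bit-reproducible regardless of numba version, and passes plain arrays.
Domain membership lookups go through a uniform spatial hash grid whose cell
size is at least one domain radius, so a particle can only be inside a
domain whose center lies in the 3x3 neighborhood of its own cell.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _min_image(d, box):
    if d > 0.5 * box:
        d -= box
    elif d < -0.5 * box:
        d += box
    return d


@njit(cache=True, inline="always")
def _locate(x, y, centers, r2, box, ncell, cell_size, grid_start, grid_items):
    """Index of the domain containing (x, y), or -1. Domains never overlap."""
    if centers.shape[0] == 0:
        return -1
    ix = int(x / cell_size)
    iy = int(y / cell_size)
    if ix >= ncell:
        ix = ncell - 1
    if iy >= ncell:
        iy = ncell - 1
    for di in range(-1, 2):
        for dj in range(-1, 2):
            ci = (ix + di) % ncell
            cj = (iy + dj) % ncell
            c = ci * ncell + cj
            for k in range(grid_start[c], grid_start[c + 1]):
                j = grid_items[k]
                dx = _min_image(x - centers[j, 0], box)
                dy = _min_image(y - centers[j, 1], box)
                if dx * dx + dy * dy <= r2:
                    return j
    return -1


@njit(cache=True)
def _advance(pos, dom, normals, unifs, sigma_out, sigma_in, p_enter, p_escape,
             box, centers, radius, ncell, cell_size, grid_start, grid_items,
             out_pos, out_in):
    """Advance all particles through normals.shape[0] steps, recording frames.

    pos (P,2) and dom (P,) are mutated in place and hold the final state on
    return.  A proposed step that changes domain membership is accepted with
    p_enter (outside->inside) or p_escape (inside->outside); a refused step
    is reflected radially off the circular domain boundary.
    """
    n_steps = normals.shape[0]
    n_part = pos.shape[0]
    r2 = radius * radius
    has_domains = centers.shape[0] > 0
    for s in range(n_steps):
        for i in range(n_part):
            cur = dom[i]
            sig = sigma_in if cur >= 0 else sigma_out
            x = pos[i, 0] + sig * normals[s, i, 0]
            y = pos[i, 1] + sig * normals[s, i, 1]
            if x >= box:
                x -= box
            elif x < 0.0:
                x += box
            if y >= box:
                y -= box
            elif y < 0.0:
                y += box
            if has_domains:
                nd = _locate(x, y, centers, r2, box, ncell, cell_size,
                             grid_start, grid_items)
            else:
                nd = -1
            if nd != cur:
                p = p_enter if cur < 0 else p_escape
                if unifs[s, i] < p:
                    dom[i] = nd
                    pos[i, 0] = x
                    pos[i, 1] = y
                else:
                    # reflect across the boundary circle of the domain the
                    # particle tried to enter (cur < 0) or leave (cur >= 0)
                    j = nd if cur < 0 else cur
                    dx = _min_image(x - centers[j, 0], box)
                    dy = _min_image(y - centers[j, 1], box)
                    d = (dx * dx + dy * dy) ** 0.5
                    if d > 1e-12:
                        scale = (2.0 * radius - d) / d
                        rx = centers[j, 0] + dx * scale
                        ry = centers[j, 1] + dy * scale
                        if rx >= box:
                            rx -= box
                        elif rx < 0.0:
                            rx += box
                        if ry >= box:
                            ry -= box
                        elif ry < 0.0:
                            ry += box
                        pos[i, 0] = rx
                        pos[i, 1] = ry
                    # membership unchanged
            else:
                pos[i, 0] = x
                pos[i, 1] = y
            out_pos[s, i, 0] = pos[i, 0]
            out_pos[s, i, 1] = pos[i, 1]
            out_in[s, i] = dom[i] >= 0


@njit(cache=True)
def _spot_signal(pos_frames, cx, cy, inv_w2_times2, box, out):
    """Sum of Gaussian detection weights per frame (minimum-image distances).

    pos_frames has shape (F, P, 2); out has shape (F,).
    """
    n_frames = pos_frames.shape[0]
    n_part = pos_frames.shape[1]
    for f in range(n_frames):
        acc = 0.0
        for i in range(n_part):
            dx = _min_image(pos_frames[f, i, 0] - cx, box)
            dy = _min_image(pos_frames[f, i, 1] - cy, box)
            acc += np.exp(-inv_w2_times2 * (dx * dx + dy * dy))
        out[f] = acc
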