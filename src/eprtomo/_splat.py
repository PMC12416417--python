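"""Numba kernels for area-weighted ray splatting.

Each wavefront pixel is a unit square whose four corners are ray-traced to
the detector plane; the pixel's intensity is distributed over the detector
cells its deformed quadrilateral overlaps, in proportion to exact overlap
area (Sutherland-Hodgman clipping against the axis-aligned cell).  The
gather kernel is the exact transpose.  Coordinates are 0-based with pixel
centers at integers and cell ownership [i-0.5, i+0.5).
"""

import numpy as np
from numba import njit

_AREA_EPS = 1e-12


@njit(cache=True, inline="always")
def _clip_axis(xs, ys, n, lo, hi, axis, ox, oy):
    """Clip polygon (xs, ys, n) to lo <= coord[axis] <= hi; result in (ox, oy)."""
    # first pass: coord >= lo
    m = 0
    for i in range(n):
        x0 = xs[i]
        y0 = ys[i]
        x1 = xs[(i + 1) % n]
        y1 = ys[(i + 1) % n]
        c0 = x0 if axis == 0 else y0
        c1 = x1 if axis == 0 else y1
        in0 = c0 >= lo
        in1 = c1 >= lo
        if in0:
            ox[m] = x0
            oy[m] = y0
            m += 1
        if in0 != in1:
            t = (lo - c0) / (c1 - c0)
            ox[m] = x0 + t * (x1 - x0)
            oy[m] = y0 + t * (y1 - y0)
            m += 1
    # second pass: coord <= hi, back into xs, ys
    n2 = 0
    for i in range(m):
        x0 = ox[i]
        y0 = oy[i]
        x1 = ox[(i + 1) % m]
        y1 = oy[(i + 1) % m]
        c0 = x0 if axis == 0 else y0
        c1 = x1 if axis == 0 else y1
        in0 = c0 <= hi
        in1 = c1 <= hi
        if in0:
            xs[n2] = x0
            ys[n2] = y0
            n2 += 1
        if in0 != in1:
            t = (hi - c0) / (c1 - c0)
            xs[n2] = x0 + t * (x1 - x0)
            ys[n2] = y0 + t * (y1 - y0)
            n2 += 1
    return n2


@njit(cache=True, inline="always")
def _poly_area(xs, ys, n):
    s = 0.0
    for i in range(n):
        j = (i + 1) % n
        s += xs[i] * ys[j] - xs[j] * ys[i]
    return 0.5 * s


@njit(cache=True, inline="always")
def _cell_overlap(qx, qy, c, r, bx, by, ox, oy):
    """Area of quad (qx, qy, 4 CCW vertices) clipped to cell (r, c)."""
    for t in range(4):
        bx[t] = qx[t]
        by[t] = qy[t]
    n = _clip_axis(bx, by, 4, c - 0.5, c + 0.5, 0, ox, oy)
    if n < 3:
        return 0.0
    n = _clip_axis(bx, by, n, r - 0.5, r + 0.5, 1, ox, oy)
    if n < 3:
        return 0.0
    return abs(_poly_area(bx, by, n))


@njit(cache=True)
def splat_scatter(intensity, cx, cy, out):
    """Scatter pixel intensities through the corner map (cx, cy).

    ``cx``, ``cy``: (H+1, W+1) ray-traced corner coordinates (x = column,
    y = row).  Accumulates into ``out`` (detector grid) and returns the total
    intensity that landed outside the grid.
    """
    H, W = intensity.shape
    Hd, Wd = out.shape
    escaped = 0.0
    qx = np.empty(4)
    qy = np.empty(4)
    bx = np.empty(16)
    by = np.empty(16)
    sx = np.empty(16)
    sy = np.empty(16)
    for i in range(H):
        for j in range(W):
            val = intensity[i, j]
            if val == 0.0:
                continue
            qx[0] = cx[i, j]
            qy[0] = cy[i, j]
            qx[1] = cx[i, j + 1]
            qy[1] = cy[i, j + 1]
            qx[2] = cx[i + 1, j + 1]
            qy[2] = cy[i + 1, j + 1]
            qx[3] = cx[i + 1, j]
            qy[3] = cy[i + 1, j]
            area = _poly_area(qx, qy, 4)
            if area < 0.0:
                # re-orient CCW (caustic folding flips orientation)
                qx[1], qx[3] = qx[3], qx[1]
                qy[1], qy[3] = qy[3], qy[1]
                area = -area
            if area < _AREA_EPS:
                # collapsed quad: deposit at the centroid cell
                ccx = 0.25 * (qx[0] + qx[1] + qx[2] + qx[3])
                ccy = 0.25 * (qy[0] + qy[1] + qy[2] + qy[3])
                c = int(np.floor(ccx + 0.5))
                r = int(np.floor(ccy + 0.5))
                if 0 <= r < Hd and 0 <= c < Wd:
                    out[r, c] += val
                else:
                    escaped += val
                continue
            xmin = min(min(qx[0], qx[1]), min(qx[2], qx[3]))
            xmax = max(max(qx[0], qx[1]), max(qx[2], qx[3]))
            ymin = min(min(qy[0], qy[1]), min(qy[2], qy[3]))
            ymax = max(max(qy[0], qy[1]), max(qy[2], qy[3]))
            c_lo = int(np.floor(xmin + 0.5))
            c_hi = int(np.floor(xmax + 0.5))
            r_lo = int(np.floor(ymin + 0.5))
            r_hi = int(np.floor(ymax + 0.5))
            w_in = 0.0
            for r in range(r_lo, r_hi + 1):
                if r < 0 or r >= Hd:
                    continue
                for c in range(c_lo, c_hi + 1):
                    if c < 0 or c >= Wd:
                        continue
                    w = _cell_overlap(qx, qy, c, r, bx, by, sx, sy)
                    if w > 0.0:
                        out[r, c] += val * (w / area)
                        w_in += w
            escaped += val * (1.0 - w_in / area)
    return escaped


@njit(cache=True)
def splat_gather(residual, cx, cy, out):
    """Exact transpose of :func:`splat_scatter` (escaped rays gather zero)."""
    H = cx.shape[0] - 1
    W = cx.shape[1] - 1
    Hd, Wd = residual.shape
    qx = np.empty(4)
    qy = np.empty(4)
    bx = np.empty(16)
    by = np.empty(16)
    sx = np.empty(16)
    sy = np.empty(16)
    for i in range(H):
        for j in range(W):
            qx[0] = cx[i, j]
            qy[0] = cy[i, j]
            qx[1] = cx[i, j + 1]
            qy[1] = cy[i, j + 1]
            qx[2] = cx[i + 1, j + 1]
            qy[2] = cy[i + 1, j + 1]
            qx[3] = cx[i + 1, j]
            qy[3] = cy[i + 1, j]
            area = _poly_area(qx, qy, 4)
            if area < 0.0:
                qx[1], qx[3] = qx[3], qx[1]
                qy[1], qy[3] = qy[3], qy[1]
                area = -area
            if area < _AREA_EPS:
                ccx = 0.25 * (qx[0] + qx[1] + qx[2] + qx[3])
                ccy = 0.25 * (qy[0] + qy[1] + qy[2] + qy[3])
                c = int(np.floor(ccx + 0.5))
                r = int(np.floor(ccy + 0.5))
                if 0 <= r < Hd and 0 <= c < Wd:
                    out[i, j] += residual[r, c]
                continue
            xmin = min(min(qx[0], qx[1]), min(qx[2], qx[3]))
            xmax = max(max(qx[0], qx[1]), max(qx[2], qx[3]))
            ymin = min(min(qy[0], qy[1]), min(qy[2], qy[3]))
            ymax = max(max(qy[0], qy[1]), max(qy[2], qy[3]))
            c_lo = int(np.floor(xmin + 0.5))
            c_hi = int(np.floor(xmax + 0.5))
            r_lo = int(np.floor(ymin + 0.5))
            r_hi = int(np.floor(ymax + 0.5))
            acc = 0.0
            for r in range(r_lo, r_hi + 1):
                if r < 0 or r >= Hd:
                    continue
                for c in range(c_lo, c_hi + 1):
                    if c < 0 or c >= Wd:
                        continue
                    w = _cell_overlap(qx, qy, c, r, bx, by, sx, sy)
                    if w > 0.0:
                        acc += residual[r, c] * (w / area)
            out[i, j] += acc
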