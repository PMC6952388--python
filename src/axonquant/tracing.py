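"""Greedy ridge-following tracer for bright axons in 2D images.

A convenience replacement for manual tracing. The image is first blurred
on the scale of the puncta spacing so a beaded axon becomes a continuous
ridge, then the tracer walks outward from a seed point in both
directions, recentring on the ridge crest after every step. Quality is
not guaranteed on low-SNR or crossing structures — callers may always
supply an explicit trace instead.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import TracingFailedError
from .geometry import AxonTrace
from .profiles import ImageFrame


def _interp(img, pts):
    return ndimage.map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")


def trace_from_ridge(frame: ImageFrame, seed_point, smooth_um: float = 0.5,
                     step_px: float = 2.0, max_turn_deg: float = 50.0) -> AxonTrace:
    """Trace the bright ridge passing near ``seed_point`` (x_um, y_um).

    Raises :class:`TracingFailedError` when no ridge stands above
    background near the seed.
    """
    px = frame.pixel_size_xy
    img = ndimage.gaussian_filter(frame.pixels, smooth_um / px)
    bg = float(np.median(img))
    contrast = float(img.max() - bg)
    if contrast <= 0 or contrast < 1e-6 * max(1.0, bg):
        raise TracingFailedError("no ridge above background")

    nr, nc = img.shape
    sr, sc = seed_point[1] / px, seed_point[0] / px
    # refine seed to the local maximum in a small window
    win = 10
    r0, r1 = int(max(0, sr - win)), int(min(nr, sr + win + 1))
    c0, c1 = int(max(0, sc - win)), int(min(nc, sc + win + 1))
    local = img[r0:r1, c0:c1]
    rr, cc = np.unravel_index(np.argmax(local), local.shape)
    start = np.array([r0 + rr, c0 + cc], dtype=float)
    peak = img[int(start[0]), int(start[1])]
    if peak - bg < 0.5 * contrast:
        raise TracingFailedError("seed point not on a bright ridge")
    stop_level = bg + 0.25 * (peak - bg)
    # revisit-exclusion radius: wide enough to span the smoothed ridge so a
    # U-turn cannot find a parallel return lane
    forbid_px = max(2.0 * step_px, 2.0 * smooth_um / px)

    def recenter(p, d):
        """Shift p along the normal of d onto the ridge crest (px grid, 0.25 px)."""
        nrm = np.array([-d[1], d[0]])
        offs = np.arange(-2.0, 2.01, 0.25)
        cand = p[None, :] + offs[:, None] * nrm[None, :]
        ok = ((cand[:, 0] >= 0) & (cand[:, 0] <= nr - 1)
              & (cand[:, 1] >= 0) & (cand[:, 1] <= nc - 1))
        cand, offs = cand[ok], offs[ok]
        vals = _interp(img, cand)
        i = int(np.argmax(vals))
        # parabolic sub-pixel refinement on the offset axis
        if 0 < i < len(offs) - 1:
            y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                return p + (offs[i] + np.clip(shift, -0.5, 0.5) * 0.25) * nrm
        return cand[i]

    def walk(d0):
        pts = []
        p, d = start.copy(), d0 / np.linalg.norm(d0)
        angles = np.deg2rad(np.linspace(-max_turn_deg, max_turn_deg, 21))
        for _ in range(int(4 * (nr + nc))):
            base = np.arctan2(d[0], d[1])
            cand_dir = np.stack([np.sin(base + angles), np.cos(base + angles)], axis=1)
            cand = p[None, :] + step_px * cand_dir
            ok = ((cand[:, 0] >= 1) & (cand[:, 0] <= nr - 2)
                  & (cand[:, 1] >= 1) & (cand[:, 1] <= nc - 2))
            # forbid stepping back onto already-walked ground (prevents
            # U-turns inside bright terminal blobs)
            lookback = int(np.ceil(forbid_px / step_px)) + 4
            if len(pts) > lookback:
                old = np.asarray(pts[:-lookback])
                for j in np.nonzero(ok)[0]:
                    if np.min(np.linalg.norm(old - cand[j], axis=1)) < forbid_px:
                        ok[j] = False
            if not ok.any():
                break
            vals = _interp(img, cand[ok])
            i = int(np.argmax(vals))
            if vals[i] < stop_level:
                break
            nxt = recenter(cand[ok][i], cand_dir[ok][i])
            # heading follows the chosen step direction, not the recentring
            # shift, so the walk cannot reverse along the ridge
            d = cand_dir[ok][i]
            p = nxt
            pts.append(p.copy())
        return pts

    # initial direction: brightest bearing at radius step_px from the seed
    bearings = np.deg2rad(np.arange(0, 360, 10))
    dirs = np.stack([np.sin(bearings), np.cos(bearings)], axis=1)
    probe = start[None, :] + 3.0 * dirs
    ok = ((probe[:, 0] >= 0) & (probe[:, 0] <= nr - 1)
          & (probe[:, 1] >= 0) & (probe[:, 1] <= nc - 1))
    vals = np.where(ok, _interp(img, np.clip(probe, 0, [[nr - 1, nc - 1]])), -np.inf)
    d1 = dirs[int(np.argmax(vals))]
    fwd = walk(d1)
    back = walk(-d1)
    path = back[::-1] + [start] + fwd
    if len(path) < 3:
        raise TracingFailedError("ridge too short to trace")
    path = np.asarray(path)
    # keep every other point to damp step zigzag, preserving the endpoints
    keep = np.unique(np.r_[np.arange(0, len(path), 2), len(path) - 1])
    path = path[keep]
    xy = np.stack([path[:, 1] * px, path[:, 0] * px], axis=1)  # (x, y) µm
    dedup = [xy[0]]
    for q in xy[1:]:
        if np.linalg.norm(q - dedup[-1]) > 1e-9:
            dedup.append(q)
    return AxonTrace(np.asarray(dedup))
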