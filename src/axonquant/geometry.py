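"""Axon traces as polylines in physical (µm) coordinates.

Coordinate convention, used throughout the package: positions are physical
micrometres with the origin at the centre of image pixel (row 0, col 0);
``x`` runs along columns and ``y`` along rows, so a point (x, y) sits at
fractional pixel (row = y / pixel_size, col = x / pixel_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class AxonTrace:
    """Ordered polyline along an axon, in µm.

    Parameters
    ----------
    vertices
        Array of shape (n, 2) holding (x_um, y_um) pairs, n >= 2.
        Consecutive vertices must be distinct.
    """

    vertices: np.ndarray
    _cumlen: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidInputError("trace needs an (n>=2, 2) array of (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("trace vertices must be finite")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg == 0):
            raise InvalidInputError("consecutive trace vertices must be distinct")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_cumlen", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def total_length(self) -> float:
        """Arc length of the polyline in µm."""
        return float(self._cumlen[-1])

    def point_at(self, s) -> np.ndarray:
        """Interpolate (x, y) at arc length ``s`` (µm, scalar or array).

        Values outside [0, total_length] raise.
        """
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-9) or np.any(s > self.total_length + 1e-9):
            raise InvalidInputError("arc length outside trace")
        s = np.clip(s, 0.0, self.total_length)
        x = np.interp(s, self._cumlen, self.vertices[:, 0])
        y = np.interp(s, self._cumlen, self.vertices[:, 1])
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent vector(s) of the segment containing arc length ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self._cumlen, s, side="right") - 1,
                      0, len(self.vertices) - 2)
        d = self.vertices[idx + 1] - self.vertices[idx]
        return d / np.linalg.norm(d, axis=-1, keepdims=True)


def straight_trace(start_xy, end_xy) -> AxonTrace:
    """Two-vertex trace from ``start_xy`` to ``end_xy`` (µm)."""
    return AxonTrace(np.array([start_xy, end_xy], dtype=float))
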