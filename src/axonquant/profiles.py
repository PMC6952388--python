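"""Images, maximum projection, line-scan extraction, and normalization.

The measurement chain mirrors standard confocal quantification of
fluorescence along a traced neurite: a deconvolved z-stack is reduced to a
maximum projection over a window of slices centred on the axon, intensity
is sampled at uniform arc-length steps along the trace, and the resulting
profile is normalized to the pooled mean of a reference condition
(wild-type L4-stage controls), giving intensities in arbitrary units (a.u.)
where the reference average is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    InvalidRegionError,
    OutOfBoundsError,
)
from .geometry import AxonTrace

log = logging.getLogger(__name__)

#: Default arc-length sampling step, µm (63 nm xy pixel pitch of the
#: acquisition this pipeline was designed around).
DEFAULT_SAMPLING_UM = 0.063

#: Default analysis region: the first 50 µm of the traced axon.
DEFAULT_REGION_UM = (0.0, 50.0)


@dataclass(frozen=True)
class ImageFrame:
    """Single-plane grayscale image with physical pixel size.

    ``pixels`` is a 2D float array (row-major); ``pixel_size_xy`` is the
    pitch in µm/pixel, identical in x and y.
    """

    pixels: np.ndarray
    pixel_size_xy: float

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise InvalidInputError("frame pixels must be 2D")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise InvalidInputError("frame pixels must be finite and nonnegative")
        if self.pixel_size_xy <= 0:
            raise InvalidParameterError("pixel_size_xy must be > 0")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class ImageStack:
    """Ordered z-stack of same-shape planes with physical voxel sizes."""

    planes: np.ndarray  # (z, rows, cols)
    pixel_size_xy: float
    plane_spacing_z: float = 0.130

    def __post_init__(self):
        p = np.asarray(self.planes, dtype=float)
        if p.ndim != 3 or p.shape[0] < 1:
            raise InvalidInputError("stack needs a (z, rows, cols) array with z >= 1")
        if self.pixel_size_xy <= 0:
            raise InvalidParameterError("pixel_size_xy must be > 0")
        object.__setattr__(self, "planes", p)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]


@dataclass(frozen=True)
class LineProfile:
    """Uniform arc-length-sampled intensity profile along an axon.

    ``arc_positions`` are strictly increasing with constant step
    ``sampling_interval`` (µm). ``raw`` holds the extracted intensities;
    ``normalized`` is populated by :func:`normalize_profile` and equals
    ``raw / reference_mean``. ``exclusion_mask`` marks samples excluded
    from every downstream statistic (True = excluded), e.g. the anus
    region where attachment is absent in all animals.
    """

    sampling_interval: float
    arc_positions: np.ndarray
    raw: np.ndarray
    exclusion_mask: np.ndarray = None
    normalized: np.ndarray = None
    reference_mean: float = None

    def __post_init__(self):
        x = np.asarray(self.arc_positions, dtype=float)
        r = np.asarray(self.raw, dtype=float)
        if x.shape != r.shape or x.ndim != 1:
            raise InvalidInputError("arc_positions and raw must be equal-length 1D arrays")
        if self.sampling_interval <= 0:
            raise InvalidParameterError("sampling_interval must be > 0")
        m = self.exclusion_mask
        m = np.zeros(x.shape, bool) if m is None else np.asarray(m, bool)
        if m.shape != x.shape:
            raise InvalidInputError("exclusion_mask length must match raw")
        object.__setattr__(self, "arc_positions", x)
        object.__setattr__(self, "raw", r)
        object.__setattr__(self, "exclusion_mask", m)
        if self.normalized is not None:
            n = np.asarray(self.normalized, dtype=float)
            if n.shape != x.shape:
                raise InvalidInputError("normalized length must match raw")
            object.__setattr__(self, "normalized", n)

    def __len__(self) -> int:
        return self.arc_positions.size

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of samples that enter the analysis."""
        return ~self.exclusion_mask

    def values(self) -> np.ndarray:
        """Normalized values if available, otherwise raw."""
        return self.raw if self.normalized is None else self.normalized

    def with_exclusion(self, intervals) -> "LineProfile":
        """Return a copy with arc-length ``intervals`` [(start, end), ...] excluded."""
        mask = self.exclusion_mask.copy()
        for a, b in intervals:
            mask |= (self.arc_positions >= a) & (self.arc_positions <= b)
        return replace(self, exclusion_mask=mask)


def n_samples_for_region(length_um: float, sampling_um: float) -> int:
    """Sample count for a line scan over ``length_um`` at step ``sampling_um``.

    The count n satisfies n·sampling <= length < (n+1)·sampling, i.e.
    samples sit at k·sampling for k = 0..n-1 measured from the region
    start. A 50 µm region at 0.063 µm yields 793 samples.
    """
    if length_um <= 0 or sampling_um <= 0:
        raise InvalidParameterError("length and sampling must be > 0")
    # epsilon guards against 50/0.05 -> 999.9999…
    return int(np.floor(length_um / sampling_um + 1e-9))


def max_project(stack: ImageStack, center_plane: int = None, window: int = 21) -> ImageFrame:
    """Maximum-intensity projection over ``window`` slices centred on the axon.

    ``window`` must be odd; the slice range is clipped to the stack. A
    window larger than the stack projects over all planes (logged).
    """
    if stack.n_planes == 0:
        raise InvalidInputError("empty stack")
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    if center_plane is None:
        center_plane = stack.n_planes // 2
    if not 0 <= center_plane < stack.n_planes:
        raise InvalidParameterError("center_plane outside stack")
    half = window // 2
    lo, hi = max(0, center_plane - half), min(stack.n_planes, center_plane + half + 1)
    if window > stack.n_planes:
        log.warning("projection window %d exceeds stack depth %d; using all planes",
                    window, stack.n_planes)
        lo, hi = 0, stack.n_planes
    return ImageFrame(stack.planes[lo:hi].max(axis=0), stack.pixel_size_xy)


def extract_line_profile(
    frame: ImageFrame,
    trace: AxonTrace,
    sampling: float = DEFAULT_SAMPLING_UM,
    region: tuple = DEFAULT_REGION_UM,
    interpolation: str = "bilinear",
    line_width: int = 1,
) -> LineProfile:
    """Uniform arc-length line scan of ``frame`` along ``trace``.

    Samples are placed every ``sampling`` µm of arc length from
    ``region[0]`` (µm along the trace); intensity is read by bilinear
    interpolation at each sub-pixel point (``interpolation="nearest"``
    reads the nearest pixel instead). ``line_width`` > 1 averages over
    that many parallel sample lines spaced one sampling step apart,
    perpendicular to the trace.
    """
    start, end = region
    if sampling <= 0:
        raise InvalidParameterError("sampling must be > 0")
    if not 0 <= start < end:
        raise InvalidRegionError("region must satisfy 0 <= start < end")
    if end > trace.total_length + 1e-9:
        raise InvalidRegionError(
            f"region end {end} µm exceeds trace length {trace.total_length:.3f} µm")
    if line_width < 1 or line_width % 2 == 0:
        raise InvalidParameterError("line_width must be odd and >= 1")

    n = n_samples_for_region(end - start, sampling)
    s = start + np.arange(n) * sampling
    pts = trace.point_at(s)  # (n, 2) of (x, y) µm

    offsets = (np.arange(line_width) - line_width // 2) * sampling
    if line_width > 1:
        t = trace.tangent_at(s)
        normal = np.stack([-t[:, 1], t[:, 0]], axis=-1)
        all_pts = pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    else:
        all_pts = pts[None, :, :]

    rows = all_pts[..., 1] / frame.pixel_size_xy
    cols = all_pts[..., 0] / frame.pixel_size_xy
    nr, nc = frame.shape
    if rows.min() < -1e-6 or rows.max() > nr - 1 + 1e-6 \
            or cols.min() < -1e-6 or cols.max() > nc - 1 + 1e-6:
        raise OutOfBoundsError("line-scan sample falls outside the image")

    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    vals = ndimage.map_coordinates(frame.pixels, [rows.ravel(), cols.ravel()],
                                   order=order, mode="nearest")
    raw = vals.reshape(line_width, n).mean(axis=0)
    return LineProfile(sampling_interval=sampling, arc_positions=s, raw=raw)


def compute_reference_mean(profiles) -> float:
    """Pooled mean raw intensity over reference-condition profiles.

    Excluded samples are ignored; all included samples are pooled with
    equal weight across profiles.
    """
    if not profiles:
        raise InvalidInputError("need at least one reference profile")
    pooled = np.concatenate([p.raw[p.included] for p in profiles])
    if pooled.size == 0:
        raise InvalidInputError("all reference samples are excluded")
    return float(pooled.mean())


def normalize_profile(profile: LineProfile, reference_mean: float) -> LineProfile:
    """Divide raw intensities by the reference mean; raw is retained."""
    if reference_mean <= 0:
        raise InvalidParameterError("reference_mean must be > 0")
    return replace(profile, normalized=profile.raw / reference_mean,
                   reference_mean=float(reference_mean))
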