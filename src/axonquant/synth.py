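"""Synthetic fluorescence data with known ground truth.

Generates the three kinds of object the analysis consumes — 1D intensity
line profiles, 2D axon images, and scored-animal penetrance tables — with
every ground-truth element recorded, so each pipeline stage can be
validated without microscope data.

The signal model emulates hemidesmosome labelling along a touch-receptor
axon: Gaussian puncta on a near-regular ~1 µm grid (the larval-stage
"periodic" pattern), an optional continuous plateau component (the
adult-stage "remodelled" pattern), epidermal background, configurable gap
regions where attachment is lost, and camera noise. The plateau level is
the arc-length mean of the periodic train, amplitude·σ·√(2π)/spacing, so
``continuous_fraction`` interpolates between the two patterns at constant
integrated intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, OutOfBoundsError
from .geometry import AxonTrace, straight_trace
from .profiles import DEFAULT_SAMPLING_UM, ImageFrame, LineProfile

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class PunctaModel:
    """Phenomenological model of punctate attachment-protein fluorescence.

    Parameters
    ----------
    spacing_d
        Centre-to-centre puncta spacing, µm (> 0). ~1 µm for
        hemidesmosome stripes.
    puncta_sigma
        Gaussian width (PSF-convolved) of a punctum, µm.
    puncta_amplitude
        Peak intensity of a punctum above background, a.u.
    background
        Diffuse epidermal background level, a.u.
    jitter_sd
        SD of positional jitter applied to each punctum, µm.
    amplitude_cv
        Coefficient of variation of per-punctum brightness.
    continuous_fraction
        0 = fully periodic (L4-like), 1 = fully continuous (adult-like).
    """

    spacing_d: float = 1.0
    puncta_sigma: float = 0.15
    puncta_amplitude: float = 1.0
    background: float = 0.05
    jitter_sd: float = 0.0
    amplitude_cv: float = 0.0
    continuous_fraction: float = 0.0

    def __post_init__(self):
        if self.spacing_d <= 0 or self.puncta_sigma <= 0:
            raise InvalidParameterError("spacing_d and puncta_sigma must be > 0")
        if min(self.puncta_amplitude, self.background,
               self.jitter_sd, self.amplitude_cv) < 0:
            raise InvalidParameterError("intensities, jitter_sd and amplitude_cv must be >= 0")
        if not 0 <= self.continuous_fraction <= 1:
            raise InvalidParameterError("continuous_fraction must be in [0, 1]")

    @property
    def plateau_level(self) -> float:
        """Mean of the periodic Gaussian train; level of the continuous component."""
        return self.puncta_amplitude * self.puncta_sigma * _SQRT2PI / self.spacing_d


@dataclass(frozen=True)
class GapSpec:
    """Arc-length intervals where attachment signal is deleted.

    ``residual_fraction`` is the fraction of above-background signal that
    survives inside a gap (0 = complete loss).
    """

    intervals: tuple = ()
    residual_fraction: float = 0.0

    def __post_init__(self):
        if not 0 <= self.residual_fraction <= 1:
            raise InvalidParameterError("residual_fraction must be in [0, 1]")
        ivals = [(float(a), float(b)) for a, b in self.intervals]
        if any(b <= a for a, b in ivals):
            raise InvalidParameterError("gap intervals need start < end")
        object.__setattr__(self, "intervals", tuple(ivals))

    def canonical(self, length: float) -> tuple:
        """Intervals clipped to [0, length], sorted, overlaps merged."""
        clipped = sorted((max(0.0, a), min(length, b))
                         for a, b in self.intervals if a < length and b > 0)
        merged = []
        for a, b in clipped:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return tuple(merged)

    def contains(self, s, length: float) -> np.ndarray:
        """Boolean: which arc positions ``s`` fall inside a gap."""
        s = np.asarray(s, dtype=float)
        inside = np.zeros(s.shape, bool)
        for a, b in self.canonical(length):
            inside |= (s >= a) & (s <= b)
        return inside


@dataclass(frozen=True)
class NoiseModel:
    """Camera-noise emulation: shot noise and/or additive Gaussian read noise."""

    kind: str = "none"  # none | gaussian | poisson | poisson+gaussian
    gaussian_sd: float = 0.05
    photon_scale: float = 100.0  # photon counts per a.u.

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson", "poisson+gaussian"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.gaussian_sd < 0 or self.photon_scale <= 0:
            raise InvalidParameterError("gaussian_sd >= 0 and photon_scale > 0 required")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(clean, dtype=float)
        if "poisson" in self.kind:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale) / self.photon_scale
        if "gaussian" in self.kind:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one synthetic axon."""

    puncta_positions: np.ndarray  # arc-length µm of surviving puncta
    gap_intervals: tuple  # canonical (start, end) µm
    true_spacing: float
    true_label_l4: str  # "gaps" | "continuous"
    true_label_adult: str
    trace: AxonTrace = None
    puncta_amplitudes: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "puncta_positions_um": list(map(float, self.puncta_positions)),
            "gap_intervals_um": [list(iv) for iv in self.gap_intervals],
            "true_spacing_um": self.true_spacing,
            "true_label_l4": self.true_label_l4,
            "true_label_adult": self.true_label_adult,
            "trace_vertices_um": None if self.trace is None
            else self.trace.vertices.tolist(),
        }


NO_GAPS = GapSpec()
NO_NOISE = NoiseModel("none")


def _sample_puncta(model: PunctaModel, length: float, rng: np.random.Generator):
    """Puncta centres k·d (k = 0..floor(L/d), endpoint-inclusive) plus jitter,
    with per-punctum amplitudes."""
    k = np.arange(int(np.floor(length / model.spacing_d + 1e-9)) + 1)
    pos = k * model.spacing_d
    if model.jitter_sd > 0:
        pos = pos + rng.normal(0.0, model.jitter_sd, size=pos.shape)
        pos = np.clip(pos, 0.0, length)
    amps = np.full(pos.shape, model.puncta_amplitude)
    if model.amplitude_cv > 0:
        amps = amps * np.clip(1.0 + model.amplitude_cv * rng.normal(size=pos.shape), 0.0, None)
    return pos, amps


def _clean_signal(x: np.ndarray, pos: np.ndarray, amps: np.ndarray,
                  model: PunctaModel, gaps: GapSpec, length: float) -> np.ndarray:
    """Noiseless above-background signal at arc positions ``x``."""
    f = model.continuous_fraction
    sig = np.zeros_like(x)
    if f < 1 and pos.size:
        d2 = (x[:, None] - pos[None, :]) ** 2
        sig = (1.0 - f) * (np.exp(-d2 / (2.0 * model.puncta_sigma ** 2)) * amps[None, :]).sum(axis=1)
    sig = sig + f * model.plateau_level
    in_gap = gaps.contains(x, length)
    sig[in_gap] *= gaps.residual_fraction
    return sig


def _truth_labels(model: PunctaModel, gaps: GapSpec, length: float,
                  sampling: float, pos: np.ndarray, amps: np.ndarray):
    """Stage labels from the classifiers run on the noiseless, gap-faithful
    profile, normalized against the gap-free version of the same model."""
    from .classify import classify_adult, classify_l4  # cycle guard
    from .profiles import normalize_profile

    x = np.arange(int(np.floor(length / sampling + 1e-9)) + 1) * sampling
    clean = model.background + _clean_signal(x, pos, amps, model, gaps, length)
    ref = model.background + _clean_signal(x, pos, amps, model, NO_GAPS, length)
    prof = LineProfile(sampling, x, clean)
    prof = normalize_profile(prof, float(ref.mean()))
    l4 = classify_l4(prof, expected_spacing=model.spacing_d)
    adult = classify_adult(prof)
    return l4.label, adult.label


def generate_profile(
    model: PunctaModel,
    gaps: GapSpec = NO_GAPS,
    noise: NoiseModel = NO_NOISE,
    length: float = 50.0,
    sampling: float = DEFAULT_SAMPLING_UM,
    seed: int = 0,
    n_samples: int = None,
) -> tuple:
    """Simulate one intensity line profile with ground truth.

    The profile has floor(length/sampling)+1 samples at k·sampling
    (endpoint-inclusive) unless ``n_samples`` overrides the count. All
    randomness (jitter, brightness variation, noise) is driven by ``seed``.
    """
    if length <= 0 or sampling <= 0:
        raise InvalidParameterError("length and sampling must be > 0")
    rng = np.random.default_rng(seed)
    n = int(np.floor(length / sampling + 1e-9)) + 1 if n_samples is None else int(n_samples)
    x = np.arange(n) * sampling

    pos, amps = _sample_puncta(model, length, rng)
    raw = model.background + _clean_signal(x, pos, amps, model, gaps, length)
    raw = noise.apply(raw, rng)
    profile = LineProfile(sampling_interval=sampling, arc_positions=x, raw=raw)

    gap_ivals = gaps.canonical(length)
    deleted = gaps.contains(pos, length) & (gaps.residual_fraction < 1)
    l4, adult = _truth_labels(model, gaps, length, sampling, pos, amps)
    truth = GroundTruth(
        puncta_positions=pos[~deleted],
        puncta_amplitudes=amps[~deleted],
        gap_intervals=gap_ivals,
        true_spacing=model.spacing_d,
        true_label_l4=l4,
        true_label_adult=adult,
        trace=straight_trace((0.0, 0.0), (length, 0.0)),
    )
    return profile, truth


def generate_axon_image(
    model: PunctaModel,
    gaps: GapSpec = NO_GAPS,
    noise: NoiseModel = NO_NOISE,
    trace: AxonTrace = None,
    pixel_size: float = DEFAULT_SAMPLING_UM,
    shape: tuple = None,
    seed: int = 0,
) -> tuple:
    """Render a synthetic axon image: isotropic 2D Gaussians at each punctum
    centre along the trace, plus background and noise.

    The continuous component is rendered as a Gaussian ridge along the
    trace whose peak matches the 1D plateau level, so line-scan extraction
    along the true trace reproduces :func:`generate_profile` output.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    if trace is None:
        trace = straight_trace((2.0, 2.0), (52.0, 2.0))
    length = trace.total_length
    if shape is None:
        hi = trace.vertices.max(axis=0)
        shape = (int(np.ceil(hi[1] / pixel_size)) + 33,
                 int(np.ceil(hi[0] / pixel_size)) + 33)
    nr, nc = shape
    lo, hi = trace.vertices.min(axis=0), trace.vertices.max(axis=0)
    if lo[0] < 0 or lo[1] < 0 or hi[0] > (nc - 1) * pixel_size or hi[1] > (nr - 1) * pixel_size:
        raise OutOfBoundsError("trace outside image bounds")

    rng = np.random.default_rng(seed)
    pos, amps = _sample_puncta(model, length, rng)
    f = model.continuous_fraction

    # render sources: discrete puncta (scaled by 1-f) plus a dense line of
    # sub-puncta approximating the continuous ridge (peak = f * plateau)
    src_s = [pos]
    src_a = [(1.0 - f) * amps]
    if f > 0:
        step = model.puncta_sigma / 4.0
        dense = np.arange(0.0, length + step / 2, step)
        src_s.append(dense)
        src_a.append(np.full(dense.shape,
                             f * model.plateau_level * step / (model.puncta_sigma * _SQRT2PI)))
    src_s = np.concatenate(src_s)
    src_a = np.concatenate(src_a).astype(float)
    in_gap = gaps.contains(src_s, length)
    src_a[in_gap] *= gaps.residual_fraction

    img = np.full((nr, nc), float(model.background))
    if src_s.size:
        xy = trace.point_at(src_s)
        sig_px = model.puncta_sigma / pixel_size
        half = max(1, int(np.ceil(4 * sig_px)))
        for (px, py), a in zip(xy, src_a):
            if a == 0:
                continue
            c0, r0 = px / pixel_size, py / pixel_size
            cmin, cmax = max(0, int(c0) - half), min(nc, int(c0) + half + 1)
            rmin, rmax = max(0, int(r0) - half), min(nr, int(r0) + half + 1)
            rr = np.arange(rmin, rmax)[:, None] - r0
            cc = np.arange(cmin, cmax)[None, :] - c0
            img[rmin:rmax, cmin:cmax] += a * np.exp(-(rr ** 2 + cc ** 2) / (2 * sig_px ** 2))
    img = noise.apply(img, rng)
    frame = ImageFrame(img, pixel_size)

    deleted = gaps.contains(pos, length) & (gaps.residual_fraction < 1)
    l4, adult = _truth_labels(model, gaps, length, pixel_size, pos, amps)
    truth = GroundTruth(
        puncta_positions=pos[~deleted],
        puncta_amplitudes=amps[~deleted],
        gap_intervals=gaps.canonical(length),
        true_spacing=model.spacing_d,
        true_label_l4=l4,
        true_label_adult=adult,
        trace=trace,
    )
    return frame, truth


def generate_penetrance_table(true_p, n, seed: int = 0, conditions=None) -> pd.DataFrame:
    """Scored-animal table: per condition, broken count x ~ Binomial(n, p).

    Returns a DataFrame with columns (condition, n, x, true_p).
    """
    true_p = np.asarray(true_p, dtype=float)
    n = np.asarray(n, dtype=int)
    if true_p.shape != n.shape:
        raise InvalidParameterError("true_p and n must have equal length")
    if np.any((true_p < 0) | (true_p > 1)):
        raise InvalidParameterError("probabilities must be in [0, 1]")
    if np.any(n <= 0):
        raise InvalidParameterError("n must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.binomial(n, true_p)
    if conditions is None:
        conditions = [f"condition_{i}" for i in range(len(n))]
    return pd.DataFrame({"condition": conditions, "n": n, "x": x, "true_p": true_p})
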