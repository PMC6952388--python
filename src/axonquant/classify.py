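"""Stage-specific attachment classification along a normalized profile.

Two scoring rules, applied at different developmental stages:

* L4 (larval, periodic pattern): the profile is scored on a grid of
  expected punctum positions (one per mean spacing). A position whose
  local maximum, within ±half a spacing, falls below an intensity
  threshold (default 0.2 a.u.) counts as a missing punctum. More than 5
  missing puncta labels the axon "gaps", otherwise "continuous".
  Exactly 5 is labelled "continuous" under the literal > rule; this
  boundary case is logged whenever it occurs, since the complementary
  "< 5" wording leaves it undefined.

* Adult (1-day-old, continuous pattern): the longest contiguous run of
  samples below the threshold is measured in µm; a run longer than 10 µm
  labels the axon "gaps".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ReconciliationError
from .profiles import LineProfile
from .stats import agresti_coull_interval

log = logging.getLogger(__name__)

DEFAULT_INTENSITY_THRESHOLD = 0.2  # a.u., normalized scale
DEFAULT_COUNT_RULE = 5             # L4: gaps iff > 5 missing puncta
DEFAULT_GAP_RULE_UM = 10.0         # adult: gaps iff a > 10 µm run of no signal

LABEL_GAPS = "gaps"
LABEL_CONTINUOUS = "continuous"


@dataclass(frozen=True)
class L4GapCall:
    n_subthreshold_puncta: int
    threshold: float
    count_rule: int
    label: str


@dataclass(frozen=True)
class AdultGapCall:
    longest_gap: float  # µm
    gap_rule: float
    label: str
    break_status: str = "unknown"  # intact | broken | unknown


def _smoothed(values: np.ndarray, smooth_um: float, sampling: float) -> np.ndarray:
    if smooth_um <= 0:
        return values
    from scipy.ndimage import gaussian_filter1d
    return gaussian_filter1d(values, smooth_um / sampling)


def classify_l4(profile: LineProfile, puncta=None, expected_spacing: float = None,
                threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                count_rule: int = DEFAULT_COUNT_RULE,
                smooth_um: float = 0.0,
                peak_prominence: float = None) -> L4GapCall:
    """Score an L4-stage profile by counting missing expected puncta.

    The expected-position grid steps by ``expected_spacing`` (µm) from the
    first to the last included sample; if not given, the spacing is taken
    from ``puncta.mean_spacing`` (a detected-peak set from the same
    profile or the reference condition). By default each expected position
    is scored by its local intensity maximum within ±half a spacing over
    included samples; positions whose entire window is excluded are
    skipped.

    On noisy profiles the bare window maximum is upward-biased (any noise
    excursion reads as signal). ``smooth_um`` applies PSF-scale Gaussian
    smoothing first, and setting ``peak_prominence`` switches to
    peak-qualified scoring: a position counts as present only when a
    local maximum with at least that prominence and height >= threshold
    lies in its window.
    """
    if profile.normalized is None:
        raise InvalidInputError("profile must be normalized first")
    if expected_spacing is None:
        if puncta is None or not np.isfinite(puncta.mean_spacing):
            raise InvalidInputError("need expected_spacing or a PunctaSet with >= 2 peaks")
        expected_spacing = float(puncta.mean_spacing)
    if expected_spacing <= 0:
        raise InvalidInputError("expected_spacing must be > 0")

    x = profile.arc_positions[profile.included]
    y = _smoothed(profile.normalized, smooth_um, profile.sampling_interval)[profile.included]
    if x.size == 0:
        raise InvalidInputError("fully excluded profile")
    span = x[-1] - x[0]
    if span < expected_spacing:
        raise InvalidInputError("profile shorter than one expected spacing")

    grid = x[0] + np.arange(int(np.floor(span / expected_spacing + 1e-9)) + 1) * expected_spacing
    half = expected_spacing / 2.0

    if peak_prominence is not None:
        from scipy.signal import find_peaks
        # pad so maxima at the profile ends still register as peaks
        padded = np.r_[y.min() - 1.0, y, y.min() - 1.0]
        idx, _ = find_peaks(padded, prominence=peak_prominence)
        peak_x = x[idx - 1]
        peak_h = y[idx - 1]

        def score(g):
            sel = (peak_x >= g - half) & (peak_x <= g + half)
            return peak_h[sel].max() if sel.any() else 0.0
    else:
        def score(g):
            win = y[(x >= g - half) & (x <= g + half)]
            return win.max() if win.size else None

    n_sub = 0
    for g in grid:
        s = score(g)
        if s is not None and s < threshold:
            n_sub += 1
    label = LABEL_GAPS if n_sub > count_rule else LABEL_CONTINUOUS
    if n_sub == count_rule:
        log.warning("boundary case: exactly %d sub-threshold puncta; "
                    "labelled %s under the literal > rule", count_rule, label)
    return L4GapCall(n_subthreshold_puncta=n_sub, threshold=threshold,
                     count_rule=count_rule, label=label)


def classify_adult(profile: LineProfile,
                   threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                   gap_rule: float = DEFAULT_GAP_RULE_UM,
                   break_status: str = "unknown",
                   smooth_um: float = 0.0,
                   median_um: float = 0.0,
                   close_um: float = 0.0) -> AdultGapCall:
    """Score an adult-stage profile by its longest run of absent signal.

    Run length is the count of consecutive included sub-threshold samples
    times the sampling interval; excluded samples terminate runs.

    On noisy profiles, single-sample noise excursions artificially break
    long gaps. ``median_um`` applies a running median of that window
    (edge positions of real gaps shift by at most half the window;
    punctum-width signal islands are preserved); ``smooth_um`` applies
    Gaussian smoothing; ``close_um`` then removes above-threshold islands
    shorter than that length (morphological closing of the sub-threshold
    mask) before runs are measured — genuine puncta span more than
    ~0.6 µm above threshold and survive the closing.
    """
    if profile.normalized is None:
        raise InvalidInputError("profile must be normalized first")
    inc = profile.included
    if not inc.any():
        raise InvalidInputError("fully excluded profile")
    y = _smoothed(profile.normalized, smooth_um, profile.sampling_interval)
    if median_um > 0:
        from scipy.ndimage import median_filter
        size = max(1, int(round(median_um / profile.sampling_interval)))
        y = median_filter(y, size=size, mode="nearest")
    below = (y < threshold) & inc
    if close_um > 0:
        min_island = int(round(close_um / profile.sampling_interval))
        # drop above-threshold islands shorter than min_island samples
        i = 0
        n = below.size
        while i < n:
            if not below[i] and inc[i]:
                j = i
                while j < n and not below[j] and inc[j]:
                    j += 1
                if j - i < min_island:
                    below[i:j] = True
                i = j
            else:
                i += 1
    # split runs wherever a sample is excluded or above threshold
    longest = best = 0
    for b, i in zip(below, inc):
        best = best + 1 if (b and i) else 0
        longest = max(longest, best)
    longest_um = longest * profile.sampling_interval
    label = LABEL_GAPS if longest_um > gap_rule else LABEL_CONTINUOUS
    return AdultGapCall(longest_gap=float(longest_um), gap_rule=gap_rule,
                        label=label, break_status=break_status)


def crosstab_attachment_breakage(calls) -> pd.DataFrame:
    """2x2 contingency of attachment label vs axonal breakage.

    Calls with unknown break status are excluded with a warning. Returns a
    DataFrame with counts and within-label proportions; empty input yields
    an empty table.
    """
    rows = [(c.label, c.break_status) for c in calls]
    unknown = sum(1 for _, b in rows if b not in ("intact", "broken"))
    if unknown:
        log.warning("%d calls with unknown break status excluded", unknown)
    rows = [(l, b) for l, b in rows if b in ("intact", "broken")]
    if not rows:
        return pd.DataFrame(columns=["label", "break_status", "count", "proportion_within_label"])
    df = pd.DataFrame(rows, columns=["label", "break_status"])
    counts = (df.groupby(["label", "break_status"]).size()
              .rename("count").reset_index())
    totals = counts.groupby("label")["count"].transform("sum")
    counts["proportion_within_label"] = counts["count"] / totals
    return counts


def predictive_linkage(l4_calls: dict, later_breaks: dict,
                       confidence: float = 0.95) -> pd.DataFrame:
    """Association between L4 attachment label and later breakage.

    ``l4_calls`` maps animal id -> :class:`L4GapCall` (or label string);
    ``later_breaks`` maps animal id -> bool (broken later). Identifiers
    must match exactly. Per label arm: broken proportion with an
    Agresti–Coull interval; empty arms are reported as not estimable
    (NaN).
    """
    a, b = set(l4_calls), set(later_breaks)
    if a != b:
        off = sorted(a.symmetric_difference(b))
        raise ReconciliationError(f"unmatched animal identifiers: {off}", offenders=off)
    rows = []
    for label in (LABEL_GAPS, LABEL_CONTINUOUS):
        ids = [i for i in l4_calls
               if (l4_calls[i].label if hasattr(l4_calls[i], "label") else l4_calls[i]) == label]
        n = len(ids)
        if n == 0:
            rows.append({"label": label, "n": 0, "x_broken": 0,
                         "p_broken": float("nan"),
                         "ac_lower": float("nan"), "ac_upper": float("nan")})
            continue
        x = sum(bool(later_breaks[i]) for i in ids)
        lo, hi = agresti_coull_interval(x, n, confidence)
        rows.append({"label": label, "n": n, "x_broken": x,
                     "p_broken": x / n, "ac_lower": lo, "ac_upper": hi})
    return pd.DataFrame(rows)
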