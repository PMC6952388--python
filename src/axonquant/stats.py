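"""Penetrance statistics: Agresti–Coull intervals, Tukey-corrected
comparison of proportions, and ordinal degeneration-score summaries.

Penetrance — the fraction of scored animals with a broken axon — is a
binomial proportion x/n. Its 95% confidence interval uses the
Agresti–Coull construction: with z the standard-normal quantile at
(1 + confidence)/2,

    ñ = n + z²,  p̃ = (x + z²/2) / ñ,  p̃ ± z·sqrt(p̃(1 − p̃)/ñ),

clipped to [0, 1]. Multi-group comparisons use pairwise two-proportion
z-statistics computed on the same adjusted counts, with family-wise
control via the studentized-range (Tukey) critical value for k groups:
a pair is significant when |z|·√2 exceeds q(1 − α; k, ∞). For k = 2 this
reduces to the ordinary two-sided z-test. The "ANOVA of proportions"
reported in the source field literature is not a uniquely defined
procedure; this is the closest standard construction, and a Bonferroni
adjustment is available as a sensitivity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError


@dataclass(frozen=True)
class PenetranceRecord:
    """Per-condition binomial breakage count with its Agresti–Coull interval."""

    condition: str
    n: int
    x: int
    confidence: float = 0.95

    def __post_init__(self):
        if self.n <= 0:
            raise InvalidInputError("n must be > 0")
        if not 0 <= self.x <= self.n:
            raise InvalidInputError("x must be in [0, n]")

    @property
    def p_hat(self) -> float:
        return self.x / self.n

    @property
    def interval(self) -> tuple:
        return agresti_coull_interval(self.x, self.n, self.confidence)

    @property
    def ac_lower(self) -> float:
        return self.interval[0]

    @property
    def ac_upper(self) -> float:
        return self.interval[1]


@dataclass(frozen=True)
class PairwiseComparison:
    condition_a: str
    condition_b: str
    diff: float  # p̃_a − p̃_b on the adjusted scale
    z: float
    adjusted_p: float
    significant: bool


def agresti_coull_interval(x, n, confidence: float = 0.95):
    """Agresti–Coull interval for a binomial proportion.

    Accepts scalars or arrays for ``x`` and ``n``; returns (lower, upper)
    clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise InvalidInputError("n must be > 0")
    if np.any((x < 0) | (x > n)):
        raise InvalidInputError("x must be in [0, n]")
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    z = sps.norm.ppf(0.5 * (1.0 + confidence))
    n_t = n + z * z
    p_t = (x + z * z / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    lower = np.clip(p_t - half, 0.0, 1.0)
    upper = np.clip(p_t + half, 0.0, 1.0)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def _adjusted(x, n, confidence):
    z = sps.norm.ppf(0.5 * (1.0 + confidence))
    return (x + z * z / 2.0), (n + z * z)


def compare_proportions(records, family_alpha: float = 0.05,
                        method: str = "tukey", confidence: float = 0.95):
    """All pairwise comparisons of binomial proportions with family-wise control.

    ``records`` is a list of :class:`PenetranceRecord` (or any objects with
    ``condition``, ``x``, ``n``). Each pair gets a two-proportion
    z-statistic on Agresti–Coull-adjusted counts; ``method="tukey"``
    controls the family-wise error via the studentized-range distribution
    for k groups, ``method="bonferroni"`` multiplies the two-sided normal
    p-value by the number of pairs.
    """
    records = list(records)
    if len(records) < 2:
        raise InvalidInputError("need at least two records to compare")
    if method not in ("tukey", "bonferroni"):
        raise InvalidInputError(f"unknown adjustment {method!r}")
    k = len(records)
    n_pairs = k * (k - 1) // 2
    out = []
    for ra, rb in combinations(records, 2):
        xa, na = _adjusted(ra.x, ra.n, confidence)
        xb, nb = _adjusted(rb.x, rb.n, confidence)
        pa, pb = xa / na, xb / nb
        se = np.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb)
        z = (pa - pb) / se if se > 0 else 0.0
        if method == "tukey":
            q = abs(z) * np.sqrt(2.0)
            adj_p = float(sps.studentized_range.sf(q, k, np.inf))
        else:
            adj_p = float(min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs))
        out.append(PairwiseComparison(
            condition_a=ra.condition, condition_b=rb.condition,
            diff=float(pa - pb), z=float(z), adjusted_p=adj_p,
            significant=bool(adj_p < family_alpha)))
    return out


def simulate_familywise_error(k: int, p: float, n: int, n_sim: int = 5000,
                              family_alpha: float = 0.05, confidence: float = 0.95,
                              seed: int = 0) -> float:
    """Empirical family-wise type-I error of :func:`compare_proportions`.

    Draws ``n_sim`` experiments of ``k`` groups with identical true
    proportion ``p`` and sample size ``n``, applies the Tukey-corrected
    pairwise rule (|z|·√2 against the studentized-range quantile — the
    same decision rule ``compare_proportions`` evaluates through the
    survival function), and returns the fraction of experiments with at
    least one significant pair.
    """
    rng = np.random.default_rng(seed)
    q_crit = sps.studentized_range.ppf(1.0 - family_alpha, k, np.inf)
    x = rng.binomial(n, p, size=(n_sim, k)).astype(float)
    xt, nt = _adjusted(x, float(n), confidence)
    pt = xt / nt
    var = pt * (1 - pt) / nt
    any_sig = np.zeros(n_sim, bool)
    for i, j in combinations(range(k), 2):
        z = np.abs(pt[:, i] - pt[:, j]) / np.sqrt(var[:, i] + var[:, j])
        any_sig |= z * np.sqrt(2.0) > q_crit
    return float(any_sig.mean())


def penetrance_table(records, confidence: float = 0.95) -> pd.DataFrame:
    """DataFrame of penetrance records with p̂ and Agresti–Coull bounds."""
    rows = []
    for r in records:
        lo, hi = agresti_coull_interval(r.x, r.n, confidence)
        rows.append({"condition": r.condition, "n": r.n, "x": r.x,
                     "p_hat": r.x / r.n, "ac_lower": lo, "ac_upper": hi,
                     "confidence": confidence})
    return pd.DataFrame(rows)


#: Ordinal axotomy degeneration scale: 1 = fully cleared axon,
#: 2 = multiple breaks, 3 = one break, 4 = beading and thinning,
#: 5 = intact axon.
DEGENERATION_CATEGORIES = (1, 2, 3, 4, 5)


def summarize_degeneration(scores, conditions) -> dict:
    """Per-condition summary of ordinal degeneration scores.

    ``scores`` and ``conditions`` are parallel sequences; scores must lie
    in 1..5. Returns a dict with a per-condition category-count table
    (including medians) and, when exactly two conditions are present, a
    rank-based two-group comparison (Mann–Whitney U, two-sided).
    """
    scores = np.asarray(scores, dtype=int)
    conditions = np.asarray(conditions)
    if scores.shape != conditions.shape:
        raise InvalidInputError("scores and conditions must have equal length")
    if np.any((scores < 1) | (scores > 5)):
        raise InvalidInputError("degeneration scores must be in 1..5")
    rows = []
    for cond in pd.unique(conditions):
        s = scores[conditions == cond]
        row = {"condition": cond, "n": s.size, "median": float(np.median(s))}
        for c in DEGENERATION_CATEGORIES:
            row[f"count_{c}"] = int((s == c).sum())
        rows.append(row)
    summary = pd.DataFrame(rows)
    result = {"summary": summary, "test": None}
    uniq = list(pd.unique(conditions))
    if len(uniq) == 2:
        a = scores[conditions == uniq[0]]
        b = scores[conditions == uniq[1]]
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        result["test"] = {"method": "mann-whitney-u", "groups": uniq,
                          "statistic": float(stat), "p_value": float(p)}
    return result
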