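"""Uplift evaluation: cumulative gain curves and normalized AUUC.

A causal model cannot be scored directly on observational data (no row
reveals both potential outcomes), so ranking quality is used instead:
sort members by predicted benefit and watch how fast the treated-minus-
control outcome contrast accumulates.

Conventions, fixed throughout:

* ``scores``: higher = ranked earlier. Callers rank by predicted benefit
  by passing ``-tau_hat`` (the most negative predicted effect first).
* uplift at fraction q = mean(-Y | treated) - mean(-Y | control) within
  the top q of the ranking — the outcome sign is flipped so that a drop
  in estimated A1c counts as positive gain.
* cumulative gain at q = uplift(q) * q * n (uplift scaled by the number
  of members covered); the curve starts at (0, 0).
* AUUC = trapezoidal area under the gain curve over q in [0, 1], divided
  by the total gain (the area of the [0,1] x [0, total gain] box). A
  uniformly random ranking's gain curve is the straight line from (0, 0)
  to (1, total gain) in expectation, giving AUUC 0.5 under this
  normalization; a model that front-loads the uplift scores above 0.5
  (and can exceed 1 when the curve peaks above the total gain). The value
  is invariant to strictly monotone transformations of the scores.

Quantile bins whose top-q subset lacks one cohort have undefined uplift;
those points are recorded, skipped in the curve, and linearly
interpolated across when integrating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import default_config

__all__ = [
    "UpliftCurve",
    "UndefinedUpliftError",
    "NormalizationError",
    "uplift_at_fraction",
    "cumulative_gain_curve",
    "auuc",
    "random_auuc_baseline",
]

_EVAL_CFG = default_config()["evaluation"]


class UndefinedUpliftError(ValueError):
    """The top-fraction subset contains only one cohort."""


class NormalizationError(ValueError):
    """Total gain is zero; normalized AUUC is undefined."""


@dataclass
class UpliftCurve:
    fractions: np.ndarray  # strictly increasing, ends at 1.0
    gains: np.ndarray      # cumulative gain; NaN where undefined
    n: int
    auuc: float = float("nan")
    area: float = float("nan")        # unnormalized trapezoidal area
    total_gain: float = float("nan")  # gain at fraction 1.0
    undefined_fractions: list[float] = field(default_factory=list)


def _ranked(scores, T, Y):
    scores = np.asarray(scores, dtype=float)
    T = np.asarray(T, dtype=int)
    Y = np.asarray(Y, dtype=float)
    if not len(scores) == len(T) == len(Y):
        raise ValueError("scores, T and Y must be aligned")
    # Stable sort: ties keep input order.
    order = np.argsort(-scores, kind="stable")
    return T[order], Y[order]


def uplift_at_fraction(scores, T, Y, fraction: float) -> float:
    """Uplift of -Y within the top ``fraction`` of the score ranking."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    T_r, Y_r = _ranked(scores, T, Y)
    k = int(np.ceil(fraction * len(T_r)))
    t, y = T_r[:k], -Y_r[:k]
    if t.sum() == 0 or t.sum() == k:
        raise UndefinedUpliftError(
            f"top {fraction:.3f} subset has a single cohort (k={k})"
        )
    return float(y[t == 1].mean() - y[t == 0].mean())


def cumulative_gain_curve(scores, T, Y, n_quantiles: int | None = None) -> UpliftCurve:
    """Cumulative gain at q = k/n_quantiles, with (0, 0) prepended."""
    if n_quantiles is None:
        n_quantiles = int(_EVAL_CFG["n_quantiles"])
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    n = len(np.asarray(Y))
    fractions = np.arange(1, n_quantiles + 1) / n_quantiles
    gains = np.full(n_quantiles, np.nan)
    undefined = []
    for i, q in enumerate(fractions):
        try:
            gains[i] = uplift_at_fraction(scores, T, Y, q) * q * n
        except UndefinedUpliftError:
            undefined.append(float(q))
    curve = UpliftCurve(
        fractions=fractions, gains=gains, n=n, undefined_fractions=undefined
    )
    if np.isfinite(gains[-1]):
        curve.total_gain = float(gains[-1])
        try:
            curve.auuc = auuc(curve)
        except NormalizationError:
            pass  # total gain exactly zero: auuc stays NaN, caller decides
    return curve


def _filled_curve(curve: UpliftCurve) -> tuple[np.ndarray, np.ndarray]:
    """(fractions, gains) with (0,0) prepended and NaN gains interpolated."""
    q = np.concatenate([[0.0], curve.fractions])
    g = np.concatenate([[0.0], curve.gains])
    bad = ~np.isfinite(g)
    if bad.any():
        g[bad] = np.interp(q[bad], q[~bad], g[~bad])
    return q, g


def auuc(curve: UpliftCurve) -> float:
    """Normalized area under the gain curve (random ranking -> 0.5)."""
    q, g = _filled_curve(curve)
    if len(q) < 2:
        raise ValueError("curve needs at least 2 points")
    total = g[-1]
    if total == 0.0:
        raise NormalizationError("total gain is zero; cannot normalize AUUC")
    area = float(np.trapezoid(g, q))
    curve.area = area
    return area / total


def random_auuc_baseline(
    T,
    Y,
    n_quantiles: int | None = None,
    n_permutations: int | None = None,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of AUUC over uniformly random rankings.

    Returns (mean, sd, all values). Permutations where the AUUC is
    undefined (should not happen with both cohorts present) are skipped.
    """
    if n_permutations is None:
        n_permutations = int(_EVAL_CFG["n_permutations"])
    rng = np.random.default_rng(seed)
    n = len(np.asarray(Y))
    values = []
    for _ in range(n_permutations):
        scores = rng.permutation(n).astype(float)
        curve = cumulative_gain_curve(scores, T, Y, n_quantiles)
        if np.isfinite(curve.auuc):
            values.append(curve.auuc)
    values = np.asarray(values)
    return float(values.mean()), float(values.std(ddof=1)), values
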