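"""Point estimation of the Youden Index from two-group diagnostic data.

The Youden Index of a continuous or ordinal diagnostic marker is

    J = max_c [ Sen(c) + Spe(c) - 1 ] = max_c [ P(X <= c) - P(Y < c) ],

where X is the marker in the non-diseased group and Y in the diseased
group (assumed stochastically larger).  The empirical estimator replaces
the two probabilities by sample proportions and maximises the resulting
step function over cut points.  The Agresti-Coull (AC) adjusted estimator
shrinks each proportion by adding z^2/2 pseudo-successes and z^2
pseudo-trials (roughly "two successes and two failures" at the 95% level)
before maximising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "TwoGroupSample",
    "YoudenEstimate",
    "candidate_cutpoints",
    "empirical_youden",
    "ac_adjusted_youden",
]

logger = logging.getLogger(__name__)

# Below this the diseased group barely exceeds the non-diseased one and the
# marker orientation (diseased = larger) deserves a second look.
ORIENTATION_WARN_THRESHOLD = 0.05


@dataclass(frozen=True)
class TwoGroupSample:
    """Measurements for the non-diseased group ``x`` and diseased group ``y``.

    Values may contain ties within and across groups; no ordering is
    assumed.  Both groups must be non-empty and all values finite.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size == 0 or y.size == 0:
            raise ValueError("both groups must contain at least one observation")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all measurements must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def m(self) -> int:
        """Size of the non-diseased group."""
        return self.x.size

    @property
    def n(self) -> int:
        """Size of the diseased group."""
        return self.y.size


@dataclass(frozen=True)
class YoudenEstimate:
    """A point estimate of the Youden Index.

    Attributes
    ----------
    j_hat : float
        The estimate, ``p1_hat - p2_hat``.
    cut : float
        The optimal cut point (smallest maximiser when ties occur).
    p1_hat : float
        Estimated specificity component P(X <= cut).
    p2_hat : float
        Estimated 1 - sensitivity component P(Y < cut).
    estimator : str
        ``"empirical"`` or ``"ac_adjusted"``.
    alpha : float or None
        Significance level whose normal quantile drives the AC
        adjustment; ``None`` for the empirical estimator.
    """

    j_hat: float
    cut: float
    p1_hat: float
    p2_hat: float
    estimator: str
    alpha: float | None = field(default=None)


def candidate_cutpoints(sample: TwoGroupSample) -> np.ndarray:
    """Finite cut-point set realising the maximum over all real cuts.

    The objective c -> #{x_i <= c}/m - #{y_j < c}/n is a step function
    that only changes value at observed data points, so its maximum over
    the real line is attained on the sorted unique pooled values.  A
    sentinel strictly below the pooled minimum is prepended; there both
    counts are zero, which guarantees the value 0 is attainable and hence
    the estimate is never negative.
    """
    pooled = np.unique(np.concatenate([sample.x, sample.y]))
    return np.concatenate([[pooled[0] - 1.0], pooled])


def _cut_counts(sample: TwoGroupSample, cuts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts #{x <= c} and #{y < c} at each cut (vectorised).

    Ties at the cut count toward specificity (inclusive for x) and not
    against sensitivity (strict for y), matching the indicator
    conventions of the estimator.
    """
    cx = np.searchsorted(np.sort(sample.x), cuts, side="right")
    cy = np.searchsorted(np.sort(sample.y), cuts, side="left")
    return cx, cy


def empirical_youden(sample: TwoGroupSample) -> YoudenEstimate:
    """Empirical (nonparametric) Youden Index estimate.

    Evaluates D(c) = #{x_i <= c}/m - #{y_j < c}/n on the candidate cut
    set and returns the maximum, breaking ties toward the smallest cut.
    """
    cuts = candidate_cutpoints(sample)
    cx, cy = _cut_counts(sample, cuts)
    # integer numerator of D(c) over the common denominator m*n: exact
    # arithmetic, so ties break at the smallest cut without float noise
    d_num = cx * sample.n - cy * sample.m
    k = int(np.argmax(d_num))  # argmax returns the first (smallest) maximiser
    est = YoudenEstimate(
        j_hat=float(d_num[k] / (sample.m * sample.n)),
        cut=float(cuts[k]),
        p1_hat=float(cx[k] / sample.m),
        p2_hat=float(cy[k] / sample.n),
        estimator="empirical",
    )
    if est.j_hat < ORIENTATION_WARN_THRESHOLD:
        logger.warning(
            "estimated Youden Index %.3f is near zero; check that the "
            "diseased group is the stochastically larger one",
            est.j_hat,
        )
    return est


def _check_alpha(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return float(norm.ppf(1.0 - alpha / 2.0))


def ac_adjusted_youden(sample: TwoGroupSample, alpha: float = 0.05) -> YoudenEstimate:
    """Agresti-Coull-adjusted Youden Index estimate.

    With z the 1 - alpha/2 standard-normal quantile, each count gains
    z^2/2 pseudo-successes and each denominator z^2 pseudo-trials:

        D_AC(c) = (#{x<=c} + z^2/2)/(m + z^2) - (#{y<c} + z^2/2)/(n + z^2).

    The maximum is taken over the same candidate set as the empirical
    estimator, independently of the empirical maximiser (the two cuts may
    differ).
    """
    z = _check_alpha(alpha)
    z2 = z * z
    cuts = candidate_cutpoints(sample)
    cx, cy = _cut_counts(sample, cuts)
    # maximise via the rescaled score cx*(n+z^2) - cy*(m+z^2), which drops
    # a constant offset; with m == n this is an exact integer multiple, so
    # ties again break at the smallest cut
    score = cx * (sample.n + z2) - cy * (sample.m + z2)
    k = int(np.argmax(score))
    p1 = float((cx[k] + z2 / 2.0) / (sample.m + z2))
    p2 = float((cy[k] + z2 / 2.0) / (sample.n + z2))
    return YoudenEstimate(
        j_hat=p1 - p2,
        cut=float(cuts[k]),
        p1_hat=p1,
        p2_hat=p2,
        estimator="ac_adjusted",
        alpha=alpha,
    )
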