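"""Mixture decomposition of delayed-response error histograms.

Responses on a 20-position circular grid are modelled as a mixture of
uniform random guessing (probability ``p``) and a "true working memory"
distribution ``d`` confined to within ``a = 2`` positions of the target::

    D(n) = p / N + (1 - p) * d(n),      d(n) = 0 for |n| > a

The guess rate is estimated from the mean of the histogram outside the
region of correct responding (where memory contributes nothing), the
residual distribution inside it gives ``d``, and memory precision is the
standard deviation of ``d`` (1 position = 18 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseHistogram",
    "MixtureEstimate",
    "GuessingMixtureModel",
    "MixtureResults",
    "estimate_guess_rate",
    "estimate_true_distribution",
    "precision",
    "rate_correct",
    "eligibility_chi2",
    "histogram_from_trials",
    "DEGREES_PER_POSITION",
]

DEGREES_PER_POSITION = 18.0
#: Minimum trials per cell for a histogram to be considered interpretable.
MIN_TRIALS = 5


class PureGuessingError(ValueError):
    """Raised when the guess rate is ~1 and the memory distribution (and
    hence precision) is undefined."""


@dataclass(frozen=True)
class ResponseHistogram:
    """Counts of signed position offsets (wrapped response minus target).

    ``counts[i]`` is the number of trials with offset ``offsets[i]``, the
    offsets running over the 20 bins ``-10 .. +9``.
    """

    counts: np.ndarray
    n_positions: int = 20
    tolerance_a: int = 2

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.n_positions,):
            raise ValueError(
                f"expected {self.n_positions} offset bins, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def offsets(self) -> np.ndarray:
        half = self.n_positions // 2
        return np.arange(-half, self.n_positions - half)

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.n_trials
        if total == 0:
            raise ValueError("empty histogram: no trials")
        return self.counts / total

    def inside_mask(self) -> np.ndarray:
        return np.abs(self.offsets) <= self.tolerance_a

    @classmethod
    def from_offsets(cls, offsets, n_positions: int = 20,
                     tolerance_a: int = 2) -> "ResponseHistogram":
        half = n_positions // 2
        idx = (np.asarray(offsets, dtype=int) + half) % n_positions
        return cls(np.bincount(idx, minlength=n_positions),
                   n_positions=n_positions, tolerance_a=tolerance_a)


def histogram_from_trials(trials: pd.DataFrame, target_col: str = "target_pos",
                          response_col: str = "response_pos",
                          n_positions: int = 20) -> ResponseHistogram:
    """Build an offset histogram from a trial table with 1-based positions."""
    t = trials[target_col].to_numpy(dtype=int)
    r = trials[response_col].to_numpy(dtype=int)
    half = n_positions // 2
    offsets = (r - t + half) % n_positions - half
    return ResponseHistogram.from_offsets(offsets, n_positions)


def estimate_guess_rate(hist: ResponseHistogram) -> float:
    """Guess-rate estimate from the histogram mass outside ``[-a, a]``.

    ``p_hat = mean(D outside) * N``, i.e. the total outside mass divided by
    the ``N - 2a - 1`` outside bins, rescaled so a uniform histogram gives
    exactly 1 and a histogram confined to the correct region gives 0.
    Finite-sample noise can push the raw estimate slightly past the unit
    interval; the returned value is clamped to [0, 1].
    """
    D = hist.probabilities
    outside = ~hist.inside_mask()
    n_outside = hist.n_positions - 2 * hist.tolerance_a - 1
    raw = D[outside].sum() / n_outside * hist.n_positions
    return float(np.clip(raw, 0.0, 1.0))


def estimate_true_distribution(hist: ResponseHistogram,
                               p_hat: float | None = None,
                               eps: float = 1e-9) -> np.ndarray:
    """Memory-response distribution over offsets ``-a .. +a``.

    Subtracts the uniform guessing floor, ``delta(n) = (D(n) - p/N)/(1-p)``,
    restricts to the correct-response region, zeroes residual negative mass
    and renormalizes to 1.
    """
    if p_hat is None:
        p_hat = estimate_guess_rate(hist)
    if p_hat >= 1.0 - eps:
        raise PureGuessingError(
            "guess rate ~ 1: memory distribution undefined (pure guessing)")
    D = hist.probabilities
    delta = (D - p_hat / hist.n_positions) / (1.0 - p_hat)
    d = np.where(hist.inside_mask(), np.maximum(delta, 0.0), 0.0)
    total = d.sum()
    if total <= 0:
        raise PureGuessingError(
            "no positive mass inside the correct-response region")
    return d[hist.inside_mask()] / total


def precision(d_hat: np.ndarray, tolerance_a: int = 2,
              degrees: bool = False) -> float:
    """Standard deviation of the memory distribution, in positions.

    ``d_hat`` holds probabilities over offsets ``-a .. +a``.  One position
    equals 18 degrees on the 20-position circle.
    """
    d_hat = np.asarray(d_hat, dtype=float)
    support = np.arange(-tolerance_a, tolerance_a + 1)
    if d_hat.shape != support.shape:
        raise ValueError(f"d_hat must have {len(support)} entries")
    mean = float(np.sum(support * d_hat))
    var = float(np.sum((support - mean) ** 2 * d_hat))
    sd = np.sqrt(max(var, 0.0))
    return sd * DEGREES_PER_POSITION if degrees else sd


def rate_correct(hist: ResponseHistogram) -> float:
    """Proportion of responses within ±a positions of the target.

    With ``a = 2`` this counts 5 of 20 positions as correct, so chance is
    25%.
    """
    return float(hist.probabilities[hist.inside_mask()].sum())


def eligibility_chi2(n_correct: int, n_trials: int,
                     chance: float = 0.25,
                     alpha: float = 0.05) -> tuple[bool, float]:
    """Chi-square test of above-chance correct responding.

    Pearson chi-square of the observed correct/incorrect split against the
    chance split (1 df).  Eligible only when p < alpha AND the observed
    rate exceeds chance (one-direction guard: performing significantly
    *below* chance does not qualify).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    observed = np.array([n_correct, n_trials - n_correct], dtype=float)
    expected = np.array([chance, 1 - chance]) * n_trials
    if expected.min() < 1:
        import warnings
        warnings.warn("expected cell count below 1; chi-square unreliable")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    eligible = p_value < alpha and (n_correct / n_trials) > chance
    return eligible, p_value


@dataclass(frozen=True)
class MixtureEstimate:
    p_hat: float
    d_hat: np.ndarray | None
    precision_sd: float | None     # positions; None when pure guessing
    rate_correct: float
    n_trials: float

    @property
    def precision_degrees(self) -> float | None:
        if self.precision_sd is None:
            return None
        return self.precision_sd * DEGREES_PER_POSITION


class GuessingMixtureModel:
    """Guessing/memory mixture fitted to a response-offset histogram.

    Statsmodels-style entry point: build from a histogram or a trial table
    and call :meth:`fit` for a :class:`MixtureResults`.
    """

    def __init__(self, hist: ResponseHistogram):
        self.hist = hist

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame,
                       target_col: str = "target_pos",
                       response_col: str = "response_pos"
                       ) -> "GuessingMixtureModel":
        return cls(histogram_from_trials(trials, target_col, response_col))

    def fit(self) -> "MixtureResults":
        hist = self.hist
        if hist.n_trials < MIN_TRIALS:
            raise ValueError(
                f"need at least {MIN_TRIALS} trials, got {hist.n_trials:g}")
        p_hat = estimate_guess_rate(hist)
        try:
            d_hat = estimate_true_distribution(hist, p_hat)
            sd = precision(d_hat, hist.tolerance_a)
        except PureGuessingError:
            d_hat, sd = None, None
        est = MixtureEstimate(p_hat=p_hat, d_hat=d_hat, precision_sd=sd,
                              rate_correct=rate_correct(hist),
                              n_trials=hist.n_trials)
        return MixtureResults(self, est)


class MixtureResults:
    """Fitted mixture decomposition with eligibility diagnostics."""

    def __init__(self, model: GuessingMixtureModel, estimate: MixtureEstimate):
        self.model = model
        self.estimate = estimate
        hist = model.hist
        n_correct = int(round(hist.probabilities[hist.inside_mask()].sum()
                              * hist.n_trials))
        self.eligible, self.chi2_pvalue = eligibility_chi2(
            n_correct, int(hist.n_trials))

    @property
    def p_hat(self) -> float:
        return self.estimate.p_hat

    @property
    def d_hat(self):
        return self.estimate.d_hat

    @property
    def precision_sd(self):
        return self.estimate.precision_sd

    @property
    def rate_correct(self) -> float:
        return self.estimate.rate_correct

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Guessing/memory mixture fit",
            "===========================",
            f"trials                 {e.n_trials:.0f}",
            f"guess rate p_hat       {e.p_hat:.4f}",
            f"rate correct (+-2)     {e.rate_correct:.4f}  (chance 0.25)",
            f"chi2 p-value           {self.chi2_pvalue:.4g}"
            f"  -> {'eligible' if self.eligible else 'not eligible'}",
        ]
        if e.precision_sd is not None:
            lines.append(f"precision SD           {e.precision_sd:.4f} positions"
                         f" ({e.precision_degrees:.2f} deg)")
        else:
            lines.append("precision SD           undefined (pure guessing)")
        return "\n".join(lines)
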