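"""Circular-linear correlation maps with a label-shuffling empirical null.

For each channel and time sample the association between a scalar signal
``x`` and a circular label ``theta`` (stimulus or response angle) is the
multiple correlation of ``x`` on ``(sin theta, cos theta)``::

    rho^2 = (r_xs^2 + r_xc^2 - 2 r_xs r_xc r_sc) / (1 - r_sc^2)

An empirical baseline is obtained by recomputing the map under random
permutations of the angle labels and averaging; ``delta_rho`` is the map
minus this null mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpochSet",
    "CorrelationMap",
    "circ_linear_r",
    "correlation_map",
    "permutation_null",
    "window_average",
    "ANALYSIS_WINDOWS",
    "BASELINE_WINDOW",
]

#: A-priori analysis windows (seconds relative to stimulus onset).
ANALYSIS_WINDOWS = {
    "early": (0.100, 0.300),
    "p3b": (0.300, 0.600),
    "delay1": (0.600, 1.550),
    "delay2": (1.550, 2.530),
}

BASELINE_WINDOW = (-0.200, -0.050)


@dataclass
class EpochSet:
    """Trials x channels x time array with per-trial labels."""

    data: np.ndarray                 # (n_trials, n_channels, n_times)
    times: np.ndarray                # (n_times,) seconds
    angle_labels: np.ndarray | None = None      # (n_trials,) radians
    category_labels: np.ndarray | None = None   # (n_trials,)
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch between data and times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("angle_labels", "category_labels"):
            lab = getattr(self, name)
            if lab is not None and len(lab) != self.data.shape[0]:
                raise ValueError(f"{name} length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def baseline_correct(self) -> "EpochSet":
        """Subtract the per-trial, per-channel mean over the baseline window."""
        lo, hi = self.baseline_window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        base = self.data[:, :, mask].mean(axis=2, keepdims=True)
        return EpochSet(self.data - base, self.times, self.angle_labels,
                        self.category_labels, self.baseline_window,
                        dict(self.meta))


@dataclass
class CorrelationMap:
    rho: np.ndarray                  # (n_channels, n_times) in [0, 1]
    times: np.ndarray
    null_mean: np.ndarray | None = None

    @property
    def delta_rho(self) -> np.ndarray:
        if self.null_mean is None:
            raise ValueError("no permutation null attached to this map")
        return self.rho - self.null_mean


def circ_linear_r(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Circular-linear correlation of signal(s) ``x`` with angles ``theta``.

    ``x`` may carry trailing feature axes; trials are axis 0.  The result
    equals the multiple correlation coefficient of a least-squares fit of
    ``x`` on sine and cosine of ``theta``, and so lies in [0, 1].  It is
    invariant to affine transforms of ``x`` and to global rotation of the
    angles.  Degenerate inputs (zero-variance ``x``) yield NaN.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    if n < 3:
        raise ValueError("need at least 3 trials")
    if x.shape[0] != n:
        raise ValueError("x and theta must agree on the trial axis")
    s = np.sin(theta)
    c = np.cos(theta)

    def corr(a, b):
        # a: (n, ...), b: (n,)
        a0 = a - a.mean(axis=0)
        b0 = (b - b.mean())[(...,) + (None,) * (a.ndim - 1)]
        denom = np.sqrt((a0 ** 2).sum(axis=0) * (b0 ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (a0 * b0).sum(axis=0) / denom

    r_xs = corr(x, s)
    r_xc = corr(x, c)
    s0, c0 = s - s.mean(), c - c.mean()
    denom_sc = np.sqrt((s0 ** 2).sum() * (c0 ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_sc = float((s0 * c0).sum() / denom_sc) if denom_sc > 0 else np.nan
    if not np.isfinite(r_sc) or abs(r_sc) >= 1 - 1e-12:
        raise ValueError("degenerate angle set: sin and cos are collinear")
    with np.errstate(invalid="ignore"):
        rho2 = (r_xs ** 2 + r_xc ** 2 - 2 * r_xs * r_xc * r_sc) / (1 - r_sc ** 2)
        rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
    return rho if rho.ndim else float(rho)


def correlation_map(epochs: EpochSet, labels: np.ndarray | None = None
                    ) -> CorrelationMap:
    """Per-channel, per-time circular-linear correlation with the angles."""
    if labels is None:
        labels = epochs.angle_labels
    if labels is None:
        raise ValueError("no angle labels provided")
    rho = circ_linear_r(epochs.data, np.asarray(labels))
    return CorrelationMap(rho=rho, times=epochs.times)


def permutation_null(epochs: EpochSet, n_perm: int = 1000,
                     seed: int | None = None,
                     labels: np.ndarray | None = None,
                     permutations=None) -> CorrelationMap:
    """Correlation map with its label-shuffling empirical null attached.

    Each permutation shuffles the trial-to-angle assignment once and reuses
    it across all channels and time points, preserving the spatial and
    temporal covariance of the null maps.  ``null_mean`` is the average of
    ``n_perm`` shuffled maps.  Explicit ``permutations`` (a sequence of
    trial-index arrays) override the seeded shuffles.
    """
    if labels is None:
        labels = epochs.angle_labels
    labels = np.asarray(labels, dtype=float)
    observed = circ_linear_r(epochs.data, labels)
    if permutations is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(labels)) for _ in range(n_perm)]
    null_acc = np.zeros_like(observed)
    for perm in permutations:
        null_acc += circ_linear_r(epochs.data, labels[np.asarray(perm)])
    return CorrelationMap(rho=observed, times=epochs.times,
                          null_mean=null_acc / len(permutations))


def window_average(cmap: CorrelationMap,
                   windows: dict[str, tuple[float, float]] | None = None,
                   channels: np.ndarray | slice | None = None,
                   use_delta: bool = True) -> dict[str, float]:
    """Mean (delta-)rho per named time window over a channel group."""
    windows = ANALYSIS_WINDOWS if windows is None else windows
    values = cmap.delta_rho if use_delta else cmap.rho
    if channels is not None:
        values = values[channels]
    out = {}
    for name, (lo, hi) in windows.items():
        mask = (cmap.times >= lo) & (cmap.times <= hi)
        if not mask.any():
            raise ValueError(f"window {name} = ({lo}, {hi}) is empty")
        out[name] = float(values[..., mask].mean())
    return out
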