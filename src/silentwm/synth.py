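"""Synthetic behavioral trial tables and sensor-level epochs.

Two generators provide ground-truth-known inputs for every analysis stage:

* :func:`gen_behavior` samples delayed-response trials from the guessing/
  memory mixture family — target position uniform over 20 locations, the
  response either a uniform guess (probability ``p_guess``) or the target
  plus a small error drawn from a discretized truncated Gaussian confined
  to ±2 positions — together with a visibility rating (4-point scale).

* :func:`gen_epochs` builds trials x channels x time arrays carrying a
  linear sine/cosine code for the stimulus angle and a categorical
  "visibility" effect, each confined to configurable time windows, plus
  Gaussian sensor noise.  Ground-truth windows and loadings are recorded in
  the epoch metadata so tests can assert where information should (not) be
  decodable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import EpochSet

__all__ = [
    "BehaviorGenSpec",
    "EpochGenSpec",
    "gen_behavior",
    "gen_epochs",
    "truncated_gaussian_offsets",
]

N_POSITIONS = 20


def truncated_gaussian_offsets(sd_positions: float, a: int = 2
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Discretized zero-mean Gaussian over offsets ``-a .. +a``.

    Returns (offsets, probabilities).  ``sd_positions = 0`` degenerates to
    a point mass at 0.  Note the truncation shrinks the realized SD below
    the nominal parameter for large ``sd_positions``.
    """
    if sd_positions < 0:
        raise ValueError("sd_positions must be >= 0")
    offsets = np.arange(-a, a + 1)
    if sd_positions == 0:
        probs = (offsets == 0).astype(float)
    else:
        w = np.exp(-0.5 * (offsets / sd_positions) ** 2)
        probs = w / w.sum()
    return offsets, probs


@dataclass(frozen=True)
class BehaviorGenSpec:
    """Generator settings for mixture-family behavioral trials.

    Per-visibility guess rates default to a steep visibility gradient:
    unseen (rating 1) trials are mostly guesses, clearly seen (rating 4)
    trials almost never are — the qualitative pattern of threshold-masked
    targets.
    """

    n_trials: int = 1000
    p_guess: tuple[float, ...] = (0.8, 0.45, 0.15, 0.05)   # per rating 1-4
    sd_positions: tuple[float, ...] = (1.0, 0.9, 0.7, 0.5)  # per rating 1-4
    visibility_probs: tuple[float, ...] = (0.45, 0.2, 0.2, 0.15)
    n_positions: int = N_POSITIONS
    tolerance_a: int = 2
    with_distractor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        vp = np.asarray(self.visibility_probs, dtype=float)
        if (vp < 0).any() or not np.isclose(vp.sum(), 1.0):
            raise ValueError("visibility_probs must be nonnegative and sum to 1")
        for p in self.p_guess:
            if not 0 <= p <= 1:
                raise ValueError("p_guess entries must lie in [0, 1]")
        for s in self.sd_positions:
            if s < 0:
                raise ValueError("sd_positions entries must be >= 0")
        if not (len(self.p_guess) == len(self.sd_positions)
                == len(self.visibility_probs)):
            raise ValueError("per-visibility settings must have equal length")


def gen_behavior(spec: BehaviorGenSpec) -> pd.DataFrame:
    """Sample a behavioral trial table from the mixture model family.

    Columns: ``target_pos`` and ``response_pos`` (1-based, 1..20),
    ``visibility`` (1..4), ``guessed`` (ground truth), ``distractor``.
    Bit-reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    n_pos = spec.n_positions
    vis = rng.choice(len(spec.visibility_probs), size=n,
                     p=spec.visibility_probs)  # 0-based rating index
    target = rng.integers(0, n_pos, size=n)
    p_guess = np.asarray(spec.p_guess)[vis]
    guessed = rng.random(n) < p_guess
    response = np.empty(n, dtype=int)
    response[guessed] = rng.integers(0, n_pos, size=int(guessed.sum()))
    for k, sd in enumerate(spec.sd_positions):
        sel = (~guessed) & (vis == k)
        if not sel.any():
            continue
        offs, probs = truncated_gaussian_offsets(sd, spec.tolerance_a)
        draw = rng.choice(offs, size=int(sel.sum()), p=probs)
        response[sel] = (target[sel] + draw) % n_pos
    return pd.DataFrame({
        "target_pos": target + 1,
        "response_pos": response + 1,
        "visibility": vis + 1,
        "guessed": guessed,
        "distractor": spec.with_distractor,
    })


@dataclass(frozen=True)
class EpochGenSpec:
    """Generator settings for angle- and category-coded sensor epochs.

    The angle code writes ``amp * (L_s(ch) sin(theta) + L_c(ch) cos(theta))``
    into a random subset of channels inside ``angle_window``; the category
    code adds a fixed topography to class-1 trials inside ``cat_window``.
    Default windows mimic a transient stimulus code (0.12–0.9 s) and a
    sustained condition effect (0.3–2.5 s).
    """

    n_trials: int = 200
    n_channels: int = 30
    t_start: float = -0.2
    t_end: float = 2.5
    sfreq: float = 250.0                    # Hz
    angle_amp: float = 1.0
    angle_window: tuple[float, float] = (0.12, 0.9)
    n_angle_channels: int = 8
    cat_amp: float = 1.0
    cat_window: tuple[float, float] = (0.3, 2.5)
    n_cat_channels: int = 8
    cat_probs: tuple[float, float] = (0.5, 0.5)
    noise_sd: float = 1.0
    amp_jitter: float = 0.2                 # trial-to-trial multiplicative SD
    n_positions: int = N_POSITIONS
    seed: int = 0
    #: separate seed for the planted channel loadings/topography; lets two
    #: independently sampled epoch sets share the same neural code
    code_seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("angle_window", "cat_window"):
            lo, hi = getattr(self, name)
            if not (self.t_start <= lo < hi <= self.t_end + 1e-9):
                raise ValueError(f"{name} must lie within the epoch times")


def _envelope(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Smooth on/off envelope: raised cosine ramps over 10% of the window."""
    lo, hi = window
    ramp = 0.1 * (hi - lo)
    env = np.zeros_like(times)
    inside = (times >= lo) & (times <= hi)
    env[inside] = 1.0
    rise = inside & (times < lo + ramp)
    fall = inside & (times > hi - ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - lo) / ramp))
    env[fall] = 0.5 * (1 - np.cos(np.pi * (hi - times[fall]) / ramp))
    return env


def gen_epochs(spec: EpochGenSpec) -> EpochSet:
    """Generate an :class:`EpochSet` with planted angle and category codes.

    Ground truth (channel loadings, windows, class assignment) is stored in
    ``epochs.meta``.  Bit-reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rng_code = np.random.default_rng(
        spec.seed if spec.code_seed is None else spec.code_seed)
    n_times = int(round((spec.t_end - spec.t_start) * spec.sfreq)) + 1
    times = spec.t_start + np.arange(n_times) / spec.sfreq
    n, n_ch = spec.n_trials, spec.n_channels

    positions = rng.integers(0, spec.n_positions, size=n)
    theta = -np.pi + positions * (2 * np.pi / spec.n_positions)
    category = rng.choice(len(spec.cat_probs), size=n, p=np.asarray(spec.cat_probs))

    data = rng.normal(0.0, spec.noise_sd, size=(n, n_ch, n_times))

    angle_ch = rng_code.choice(n_ch, size=min(spec.n_angle_channels, n_ch),
                               replace=False)
    L_s = np.zeros(n_ch)
    L_c = np.zeros(n_ch)
    L_s[angle_ch] = rng_code.normal(0, 1, size=len(angle_ch))
    L_c[angle_ch] = rng_code.normal(0, 1, size=len(angle_ch))
    env_a = _envelope(times, spec.angle_window)
    jitter = 1.0 + spec.amp_jitter * rng.standard_normal(n)
    angle_signal = (np.sin(theta)[:, None] * L_s[None, :]
                    + np.cos(theta)[:, None] * L_c[None, :])
    data += (spec.angle_amp * jitter[:, None, None]
             * angle_signal[:, :, None] * env_a[None, None, :])

    cat_ch = rng_code.choice(n_ch, size=min(spec.n_cat_channels, n_ch),
                             replace=False)
    topo = np.zeros(n_ch)
    topo[cat_ch] = rng_code.normal(0, 1, size=len(cat_ch))
    env_c = _envelope(times, spec.cat_window)
    jitter_c = 1.0 + spec.amp_jitter * rng.standard_normal(n)
    data += (spec.cat_amp * (category == 1)[:, None, None]
             * jitter_c[:, None, None] * topo[None, :, None]
             * env_c[None, None, :])

    return EpochSet(
        data=data, times=times, angle_labels=theta,
        category_labels=category,
        meta={
            "angle_window": spec.angle_window,
            "cat_window": spec.cat_window,
            "angle_channels": np.sort(angle_ch),
            "cat_channels": np.sort(cat_ch),
            "positions": positions,
            "spec": spec,
        },
    )
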