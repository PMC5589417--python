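"""One-dimensional continuous attractor network with short-term synaptic plasticity.

The model is a ring of rate neurons labelled by preferred angle
``theta in [-pi, pi)``.  Recurrent excitation is translation invariant
(a truncated-cosine kernel), inhibition is a single global pool, and every
excitatory synapse carries short-term facilitation ``u`` (release probability,
decaying to baseline ``U`` with time constant ``tau_f``) and short-term
depression ``x`` (available resources, recovering to 1 with ``tau_d``).
Effective synaptic efficacy is proportional to ``u * x``, so a transiently
active assembly leaves a slowly decaying synaptic trace even after firing
returns to baseline -- the substrate of "activity-silent" memory.

State variables evolve as (Euler--Maruyama discretization)::

    tau  dh_E/dt = -h_E + rho * integral J(th,th') u x R_E dth'
                   - J_EI * R_I + I_b + I_e + noise
         du/dt   = (U - u)/tau_f + U (1 - u) R_E
         dx/dt   = (1 - x)/tau_d - u x R_E
    tau  dh_I/dt = -h_I + J_IE * integral R_E dth

with the smoothed threshold-linear gain ``R(h) = alpha * log(1 + exp(h/alpha))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NetworkParams",
    "NetworkState",
    "TrialTrace",
    "gain",
    "preferred_angles",
    "connectivity_kernel",
    "kernel_matrix",
    "RingNetwork",
    "step",
    "run_network",
]


#: Calibrated scaling of the neuronal density: ``rho = RHO_SCALE * N/(2*pi)``,
#: equivalently ``rho * dtheta = RHO_SCALE``.  The density only enters the
#: dynamics jointly with the synaptic amplitudes, so it is not identifiable
#: from the printed parameters; this value places the noiseless critical mask
#: amplitude separating the reactivating and silent maintenance regimes near
#: 62 Hz (with the default stimulus protocol), the published operating point.
RHO_SCALE = 0.0716


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the ring attractor with short-term plasticity.

    Defaults are the published operating point of the model: a 100-neuron
    ring with an 8 ms current time constant, facilitation decaying over 4 s
    and depression recovering over 0.3 s.  ``rho`` (neuronal density per
    radian) is not separately identifiable from the synaptic amplitudes;
    its default is calibrated (see :data:`RHO_SCALE`) so the critical mask
    amplitude of the delayed-response protocol falls near 62 Hz.
    """

    n_neurons: int = 100
    tau: float = 0.008          # s, firing-rate time constant
    rho: float | None = None    # neurons per radian; None -> calibrated default
    J1: float = 12.0            # excitatory kernel amplitude
    J0: float = 1.0             # uniform inhibitory part of the kernel
    B: float = 2.2              # kernel width factor
    J_EI: float = 1.9           # inhibitory -> excitatory coupling
    J_IE: float = 1.8           # excitatory -> inhibitory coupling
    I_b: float = -0.1           # Hz, background current
    delta1: float = 0.3         # background noise amplitude
    delta2: float = 9.0         # stimulus noise amplitude
    U: float = 0.3              # baseline release probability
    tau_f: float = 4.0          # s, facilitation time constant
    tau_d: float = 0.3          # s, depression time constant
    alpha: float = 1.5          # gain smoothing
    dt: float = 0.001           # s, integration step
    noise_dt: float = 0.001     # s, correlation (hold) time of noise currents

    def __post_init__(self) -> None:
        if self.n_neurons < 3:
            raise ValueError("n_neurons must be >= 3")
        for name in ("tau", "tau_f", "tau_d", "dt", "noise_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt >= self.tau:
            raise ValueError("dt must be smaller than tau for stability")
        if not (0 < self.U <= 1):
            raise ValueError("U must lie in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (self.J1 > self.J0 >= 0):
            raise ValueError("require J1 > J0 >= 0")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rho must be > 0")

    @property
    def density(self) -> float:
        """Neuronal density per radian (``rho``), resolved from the default."""
        if self.rho is None:
            return RHO_SCALE * self.n_neurons / (2.0 * np.pi)
        return self.rho

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.n_neurons

    def with_overrides(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass
class NetworkState:
    """Instantaneous state of the network (supports a leading batch axis)."""

    h_E: np.ndarray   # (..., N) synaptic current of excitatory neurons
    u: np.ndarray     # (..., N) release probability
    x: np.ndarray     # (..., N) available neurotransmitter fraction
    h_I: np.ndarray   # (...,)   inhibitory-pool current
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.h_E.copy(), self.u.copy(), self.x.copy(),
                            np.array(self.h_I, copy=True), self.t)


@dataclass
class TrialTrace:
    """Time-sampled record of one simulated trial."""

    times: np.ndarray        # (T,) s, decimated sample times
    raster: np.ndarray       # (T, N) firing rates in Hz
    u: np.ndarray            # (T, N) facilitation snapshots
    x: np.ndarray            # (T, N) depression snapshots
    h_I: np.ndarray          # (T,) inhibitory current
    events: dict             # event name -> (onset, offset) in s
    target_angle: float | None = None
    params: NetworkParams | None = None

    def rate_in_window(self, window: tuple[float, float]) -> np.ndarray:
        """Time-averaged firing-rate profile within ``window`` (inclusive)."""
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        return self.raster[mask].mean(axis=0)


def gain(h, alpha: float = 1.5):
    """Smoothed threshold-linear gain ``R(h) = alpha * log(1 + exp(h/alpha))``.

    Stable for large ``|h|``: reduces to ``h`` as ``h -> +inf`` and to 0 as
    ``h -> -inf``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite synaptic current passed to gain()")
    # softplus with overflow guard: for z > 0, log(1+e^z) = z + log1p(e^-z)
    z = h / alpha
    out = alpha * (np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z))))
    return out if out.ndim else float(out)


def preferred_angles(n_neurons: int) -> np.ndarray:
    """Equally spaced preferred angles on ``[-pi, pi)``."""
    return -np.pi + np.arange(n_neurons) * (2.0 * np.pi / n_neurons)


def wrap_angle(a):
    """Wrap angles to ``(-pi, pi]``."""
    return -np.remainder(-np.asarray(a, dtype=float) + np.pi, 2 * np.pi) + np.pi


def connectivity_kernel(theta_i, theta_j, params: NetworkParams):
    """Translation-invariant interaction strength between preferred angles.

    ``J1*cos(B*d) - J0`` while ``B*d`` lies within ``[-arccos(-J0/J1),
    arccos(-J0/J1)]`` of zero (``d`` the wrapped angular difference), and the
    uniform inhibitory floor ``-J0`` outside.
    """
    if params.J0 / params.J1 > 1:
        raise ValueError("J0/J1 > 1: kernel cutoff arccos(-J0/J1) undefined")
    d = wrap_angle(np.asarray(theta_i, dtype=float) - np.asarray(theta_j, dtype=float))
    cutoff = np.arccos(-params.J0 / params.J1)
    inside = np.abs(params.B * d) <= cutoff
    out = np.where(inside, params.J1 * np.cos(params.B * d) - params.J0, -params.J0)
    return out if out.ndim else float(out)


def kernel_matrix(params: NetworkParams) -> np.ndarray:
    """Full ``N x N`` connectivity matrix over the preferred-angle grid."""
    th = preferred_angles(params.n_neurons)
    return connectivity_kernel(th[:, None], th[None, :], params)


class RingNetwork:
    """Integrator for the ring attractor; holds precomputed geometry.

    The heavy per-step work is a single matrix product, vectorized over an
    optional batch of independent trials, so thousands of trials run in
    minutes on one CPU.
    """

    def __init__(self, params: NetworkParams):
        self.params = params
        self.thetas = preferred_angles(params.n_neurons)
        self.J = kernel_matrix(params)
        # rho * dtheta premultiplies the recurrent sum; J_IE * dtheta the
        # inhibitory-pool integral.
        self._rec_scale = params.density * params.dtheta
        self._inh_scale = params.J_IE * params.dtheta

    def initial_state(self, batch: int | None = None, t: float = 0.0) -> NetworkState:
        """Rest state: ``h_E = I_b``, ``u = U``, ``x = 1``, ``h_I = 0``."""
        p = self.params
        shape = (p.n_neurons,) if batch is None else (batch, p.n_neurons)
        return NetworkState(
            h_E=np.full(shape, p.I_b, dtype=float),
            u=np.full(shape, p.U, dtype=float),
            x=np.ones(shape, dtype=float),
            h_I=np.zeros(shape[:-1], dtype=float),
            t=t,
        )

    def step(self, state: NetworkState, external_input,
             noise_draws: tuple[np.ndarray, np.ndarray] | None = None,
             stimulus_on: bool = False,
             noise_mode: str = "continuous") -> NetworkState:
        """Advance the state by one Euler--Maruyama step of size ``dt``.

        ``noise_draws`` are two standard-normal arrays shaped like ``h_E``;
        background noise ``delta1`` enters every step in ``continuous``
        mode, stimulus noise ``delta2`` only while ``stimulus_on``.  Noise
        is a fluctuating input current in the same units as the external
        stimuli, entering the update like ``I_e``; the run loops hold each
        draw for ``noise_dt`` so the noise process (and hence the dynamics)
        is independent of the integration step.
        """
        p = self.params
        dt = p.dt
        # overflow here is caught by the finiteness check below; silence
        # the intermediate warnings
        with np.errstate(over="ignore", invalid="ignore"):
            R_E = gain(state.h_E, p.alpha)
            R_I = gain(state.h_I, p.alpha)
            recurrent = self._rec_scale * ((state.u * state.x * R_E) @ self.J)
            drive = (-state.h_E + recurrent + p.I_b + external_input
                     - p.J_EI * np.expand_dims(R_I, -1))
            if noise_draws is not None:
                xi1, xi2 = noise_draws
                if noise_mode == "continuous":
                    drive = drive + p.delta1 * xi1
                elif noise_mode != "input_only":
                    raise ValueError(f"unknown noise_mode {noise_mode!r}")
                if stimulus_on:
                    drive = drive + p.delta2 * xi2
            h_E = state.h_E + (dt / p.tau) * drive
            # The STP equations are linear in u (resp. x) given the rate,
            # but stiff during population spikes (u*R*dt ~ 1); exponential-
            # Euler integrates the conditionally linear part exactly and
            # keeps u in [U, 1] and x in (0, 1] without overshoot.
            B_u = 1.0 / p.tau_f + p.U * R_E
            u_inf = (p.U / p.tau_f + p.U * R_E) / B_u
            u = u_inf + (state.u - u_inf) * np.exp(-dt * B_u)
            B_x = 1.0 / p.tau_d + state.u * R_E
            x_inf = (1.0 / p.tau_d) / B_x
            x = x_inf + (state.x - x_inf) * np.exp(-dt * B_x)
            h_I = state.h_I + (dt / p.tau) * (
                -state.h_I + self._inh_scale * R_E.sum(axis=-1))
        new = NetworkState(h_E, u, x, h_I, state.t + dt)
        for name, arr in (("h_E", h_E), ("u", u), ("x", x), ("h_I", h_I)):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"state component {name} diverged at t={new.t:.4f}s "
                    "(integration step dt may be too large)")
        return new

    def run(self, schedule, seed: int | None = None,
            noise_mode: str = "continuous", noise: bool = True,
            decimate: int = 4, record: bool = True,
            target_angle: float | None = None) -> TrialTrace:
        """Integrate one trial over a stimulus schedule.

        ``schedule`` provides ``t_start``, ``t_end``, ``segments()`` (see
        :mod:`silentwm.protocol`) and event markers.  Deterministic given
        ``seed``; ``noise=False`` disables both noise sources.
        """
        p = self.params
        rng = np.random.default_rng(seed)
        angle = schedule.target_angle if target_angle is None else target_angle
        state = self.initial_state(t=schedule.t_start)
        n_steps = int(round((schedule.t_end - schedule.t_start) / p.dt))
        seg_input, seg_stim = _segment_arrays(schedule, self.thetas, p,
                                              n_steps, angle)
        times, rasters, us, xs, h_Is = [], [], [], [], []
        hold = max(1, int(round(p.noise_dt / p.dt)))
        draws = None
        for k in range(n_steps):
            if noise and k % hold == 0:
                draws = (rng.standard_normal(p.n_neurons),
                         rng.standard_normal(p.n_neurons))
            state = self.step(state, seg_input[k], draws, bool(seg_stim[k]),
                              noise_mode)
            if record and ((k + 1) % decimate == 0 or k == n_steps - 1):
                times.append(state.t)
                rasters.append(gain(state.h_E, p.alpha))
                us.append(state.u.copy())
                xs.append(state.x.copy())
                h_Is.append(float(state.h_I))
        return TrialTrace(
            times=np.asarray(times),
            raster=np.asarray(rasters),
            u=np.asarray(us),
            x=np.asarray(xs),
            h_I=np.asarray(h_Is),
            events=dict(schedule.events()),
            target_angle=angle,
            params=p,
        )


def _segment_arrays(schedule, thetas: np.ndarray, params: NetworkParams,
                    n_steps: int, target_angle) -> tuple[np.ndarray, np.ndarray]:
    """Precompute per-step external input (n_steps x N) and stimulus flags.

    ``target_angle`` may be a scalar or a batch of angles; in the batched
    case the input array has shape (n_steps, batch, N).
    """
    angles = np.atleast_1d(np.asarray(target_angle, dtype=float))
    batched = np.ndim(target_angle) > 0
    shape = ((n_steps, len(angles), params.n_neurons) if batched
             else (n_steps, params.n_neurons))
    inputs = np.zeros(shape)
    stim_on = np.zeros(n_steps, dtype=bool)
    t_grid = schedule.t_start + params.dt * np.arange(n_steps)
    for seg in schedule.segments():
        mask = (t_grid >= seg.onset - 1e-12) & (t_grid < seg.offset - 1e-12)
        if not mask.any():
            continue
        profile = seg.profile(thetas, angles if batched else angles[0])
        inputs[mask] += profile
        stim_on |= mask
    return inputs, stim_on


# -- functional wrappers -----------------------------------------------------

def step(state: NetworkState, external_input, params: NetworkParams,
         noise_draws=None, stimulus_on: bool = False,
         noise_mode: str = "continuous") -> NetworkState:
    """One integration step (functional form of :meth:`RingNetwork.step`)."""
    return RingNetwork(params).step(state, external_input, noise_draws,
                                    stimulus_on, noise_mode)


def run_network(schedule, params: NetworkParams, seed: int | None = None,
                noise_mode: str = "continuous", noise: bool = True,
                decimate: int = 4) -> TrialTrace:
    """Simulate one trial (functional form of :meth:`RingNetwork.run`)."""
    return RingNetwork(params).run(schedule, seed=seed, noise_mode=noise_mode,
                                   noise=noise, decimate=decimate)
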