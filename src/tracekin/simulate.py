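"""Stochastic simulation of single-molecule intensity trajectories.

The generator mirrors a TIRF single-molecule experiment: each immobilised
molecule follows a continuous-time Markov chain over the chemical states of a
:class:`~tracekin.scheme.KineticScheme` (simulated exactly, Gillespie-style),
and a camera integrates its state-dependent fluorescence over fixed frames.
Within a frame the noiseless level is the time-weighted mean of the state
emission means (exposure integration); Gaussian read-out noise with the sd of
the frame's majority state is added on top.  Photobleaching, when enabled, is
an extra first-order decay channel from every emitting state into an
absorbing dark state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import Condition, KineticScheme, effective_rates

__all__ = [
    "SimulationConfig",
    "StatePath",
    "IntensityTrace",
    "simulate_state_path",
    "render_trace",
    "generate_ensemble",
]

#: Default emission means (arbitrary units).  The product emits at the level
#: of IM1: the two are optically indistinguishable in this assay.
DEFAULT_EMISSION_MEANS = {
    "S": 1.00,
    "IM1": 0.60,
    "IM2": 0.25,
    "P": 0.60,
    "BLEACHED": 0.05,
}
DEFAULT_EMISSION_SD = 0.08


def _default_means() -> dict[str, float]:
    return dict(DEFAULT_EMISSION_MEANS)


def _default_sds() -> dict[str, float]:
    return {s: DEFAULT_EMISSION_SD for s in DEFAULT_EMISSION_MEANS}


@dataclass
class SimulationConfig:
    """Imaging and ensemble parameters.

    Defaults follow the imaging conditions of the experiment being emulated:
    ~100 ms frames and observation windows of up to one minute (600 frames),
    about 200 trajectories per condition.
    """

    frame_period: float = 0.1
    n_frames: int = 600
    n_traces: int = 200
    emission_means: dict[str, float] = field(default_factory=_default_means)
    emission_sds: dict[str, float] = field(default_factory=_default_sds)
    bleach_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        for s, sd in self.emission_sds.items():
            if sd <= 0:
                raise ValueError(f"emission sd for {s} must be > 0")

    @property
    def duration(self) -> float:
        return self.frame_period * self.n_frames


@dataclass
class StatePath:
    """Ground-truth jump path: epoch start times (s, first is 0) and states."""

    jump_times: np.ndarray
    states: list[str]

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        if self.jump_times.ndim != 1 or len(self.jump_times) != len(self.states):
            raise ValueError("jump_times and states must have equal length")
        if len(self.jump_times) == 0 or self.jump_times[0] != 0.0:
            raise ValueError("path must start at time 0")
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("consecutive states must differ")

    def state_at_frames(self, times: np.ndarray) -> list[str]:
        """State occupied at each (frame-start) time."""
        idx = np.searchsorted(self.jump_times, times, side="right") - 1
        return [self.states[i] for i in idx]


@dataclass
class IntensityTrace:
    """One molecule's observed intensity trajectory plus condition metadata."""

    trace_id: str
    condition: Condition
    times: np.ndarray
    intensities: np.ndarray
    truth: StatePath | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.times)


def simulate_state_path(
    scheme: KineticScheme,
    cond: Condition,
    duration: float,
    rng: np.random.Generator,
    *,
    initial_state: str = "S",
    bleach_rate: float = 0.0,
) -> StatePath:
    """Exact stochastic simulation of the chain until *duration* or absorption.

    Waiting time in a state is exponential with the total exit rate; the
    destination is drawn proportionally to the branch rates.  A state with no
    exits yields a single-epoch path.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial_state not in scheme.states:
        raise ValueError(f"initial state {initial_state!r} not in scheme")
    rates = effective_rates(scheme, cond)
    exits: dict[str, tuple[list[str], np.ndarray]] = {}
    for state in scheme.states:
        dests = [d for (s, d), k in rates.items() if s == state and k > 0]
        ks = np.array([rates[(state, d)] for d in dests], dtype=float)
        if bleach_rate > 0 and state != "BLEACHED":
            dests = dests + ["BLEACHED"]
            ks = np.append(ks, bleach_rate)
        exits[state] = (dests, ks)

    t = 0.0
    state = initial_state
    jump_times = [0.0]
    states = [state]
    while True:
        # The bleach sink may be absent from the declared states; it is
        # terminal either way.
        dests, ks = exits.get(state, ([], np.array([])))
        total = ks.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        state = dests[int(rng.choice(len(dests), p=ks / total))]
        jump_times.append(t)
        states.append(state)
    return StatePath(np.array(jump_times), states)


def render_trace(
    path: StatePath,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    trace_id: str = "trace",
    condition: Condition | None = None,
) -> IntensityTrace:
    """Camera model: integrate *path* over frames and add Gaussian noise.

    The noiseless level of a frame is the occupancy-time-weighted mean of the
    emission means of the states visited during that frame; the noise sd is
    that of the state occupying the frame longest (ties go to the earlier
    state within the frame).
    """
    dt = config.frame_period
    n = config.n_frames
    means = config.emission_means
    sds = config.emission_sds
    # Epoch boundaries clipped to the trace window.
    starts = path.jump_times
    ends = np.append(path.jump_times[1:], config.duration)
    if starts[-1] > config.duration:
        raise ValueError("path extends beyond the trace duration")

    levels = np.zeros(n)
    noise_sd = np.zeros(n)
    frame_starts = np.arange(n) * dt
    frame_ends = frame_starts + dt
    # Occupancy of each epoch within each frame; epochs are few, frames many.
    occ = np.zeros(n)
    major = np.zeros(n)  # best occupancy seen so far per frame
    levels_acc = np.zeros(n)
    sd_choice = np.full(n, -1, dtype=int)
    for i, (s, t0, t1) in enumerate(zip(path.states, starts, ends)):
        lo = max(0, int(np.floor(t0 / dt)))
        hi = min(n, int(np.ceil(t1 / dt)))
        if hi <= lo:
            continue
        overlap = np.minimum(frame_ends[lo:hi], t1) - np.maximum(frame_starts[lo:hi], t0)
        overlap = np.clip(overlap, 0.0, None)
        levels_acc[lo:hi] += overlap * means[s]
        occ[lo:hi] += overlap
        better = overlap > major[lo:hi]  # strict: ties keep the earlier state
        major[lo:hi] = np.where(better, overlap, major[lo:hi])
        sd_choice[lo:hi] = np.where(better, i, sd_choice[lo:hi])
    levels = levels_acc / np.maximum(occ, 1e-300)
    noise_sd = np.array([sds[path.states[j]] for j in sd_choice])
    intensities = levels + rng.normal(0.0, 1.0, size=n) * noise_sd
    times = frame_starts
    return IntensityTrace(
        trace_id=trace_id,
        condition=condition or Condition(),
        times=times,
        intensities=intensities,
        truth=path,
    )


def generate_ensemble(
    scheme: KineticScheme,
    conditions: list[Condition],
    config: SimulationConfig,
) -> list[IntensityTrace]:
    """Simulate ``config.n_traces`` trajectories per condition, reproducibly.

    Each trace gets an independent child RNG stream spawned from
    ``config.rng_seed``, so the ensemble is bit-reproducible for a fixed seed
    and does not depend on generation order.
    """
    if not conditions:
        raise ValueError("conditions list is empty")
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(len(conditions) * config.n_traces)
    traces: list[IntensityTrace] = []
    idx = 0
    for ci, cond in enumerate(conditions):
        for ti in range(config.n_traces):
            rng = np.random.Generator(np.random.PCG64(children[idx]))
            idx += 1
            path = simulate_state_path(
                scheme,
                cond,
                config.duration,
                rng,
                bleach_rate=config.bleach_rate,
            )
            traces.append(
                render_trace(
                    path,
                    config,
                    rng,
                    trace_id=f"c{ci}_t{ti}",
                    condition=cond,
                )
            )
    return traces
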