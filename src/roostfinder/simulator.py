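"""Agent-based simulator of nightly bat dispersal and acoustic detection.

Each simulated bat starts the night at the roost and performs planar Brownian
motion, the stochastic counterpart of the diffusion forward model: per axis,

    x <- x + sqrt(2 D dt) * xi,    xi ~ N(0, 1),

so the position at time t is exactly Gaussian with mean-squared displacement
4 D t for any step size (the Euler-Maruyama scheme is exact in distribution
for pure diffusion; the step size only affects how finely disk crossings are
resolved).  A detector registers one *pass* per entry event — the agent moves
from outside to inside its circular footprint — subject to a refractory
window that stops boundary jitter being double-counted.

Nightly pass counts aggregated over a survey produce exactly the CSV schema
the estimator consumes, with the ground-truth roost retained for validation.
A geometric detector-failure model emulates the mid-survey dropouts seen in
real deployments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import DiffusionParams
from .survey_io import Detector, SurveySet

#: Diffusion rate (m^2/s) used for simulated validation surveys.  Slightly
#: different from the inference default (80) on purpose: the estimator is
#: never handed the exact generating parameter.
SIM_DEFAULT_D = 81.7


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one synthetic survey."""

    roost: tuple[float, float]
    detector_positions: np.ndarray  # (N, 2)
    n_agents: int = 600
    n_nights: int = 5
    params: DiffusionParams = field(
        default_factory=lambda: DiffusionParams(D=SIM_DEFAULT_D)
    )
    step_dt: float = 1.0
    refractory: float = 30.0
    seed: int = 0
    record_trajectories: bool = False
    trajectory_thin: int = 60  # store every k-th step when recording

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "detector_positions",
            np.atleast_2d(np.asarray(self.detector_positions, dtype=float)),
        )
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if not (0 < self.step_dt <= self.params.T):
            raise ValueError("step_dt must be in (0, T]")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.params.T / self.step_dt))

    @property
    def n_detectors(self) -> int:
        return self.detector_positions.shape[0]


@dataclass
class NightResult:
    counts: np.ndarray  # (N,) passes per detector
    msd: np.ndarray  # (n_steps,) mean squared displacement from the roost
    final_positions: np.ndarray | None = None  # (n_agents, 2) at t = T
    trajectories: np.ndarray | None = None  # (n_agents, n_kept, 2)


@dataclass
class SimResult:
    """Aggregated synthetic survey with its ground truth."""

    scenario: SimScenario
    nightly_counts: np.ndarray  # (n_nights, N)
    nights_active: np.ndarray  # (N,) ints
    msd: np.ndarray  # mean over nights
    trajectories: list[np.ndarray] = field(default_factory=list)

    @property
    def total_counts(self) -> np.ndarray:
        """Per-detector totals over each detector's active nights."""
        active = np.arange(self.nightly_counts.shape[0])[:, None] < self.nights_active
        return (self.nightly_counts * active).sum(axis=0)

    def to_survey(self) -> SurveySet:
        totals = self.total_counts
        detectors = [
            Detector(
                id=f"d{i + 1:03d}",
                easting=float(x),
                northing=float(y),
                nights_active=int(self.nights_active[i]),
                total_calls=int(totals[i]),
            )
            for i, (x, y) in enumerate(self.scenario.detector_positions)
        ]
        return SurveySet(detectors=detectors, roost_known=self.scenario.roost)


def _night_rng(seed: int, night_index: int) -> np.random.Generator:
    # (seed, night) pair fully determines the stream: nights are independent
    # and reproducible individually.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(night_index)]))


def _thin_refractory(
    agents: np.ndarray, dets: np.ndarray, times: np.ndarray, refractory: float
) -> np.ndarray:
    """Keep entry events at least ``refractory`` seconds after the previous
    *kept* event of the same (agent, detector).  Returns kept detector ids."""
    if refractory <= 0 or len(times) == 0:
        return dets
    order = np.lexsort((times, dets, agents))
    kept = []
    last_key = None
    last_t = -np.inf
    for k in order:
        key = (agents[k], dets[k])
        if key != last_key or times[k] - last_t >= refractory:
            kept.append(dets[k])
            last_key = key
            last_t = times[k]
    return np.asarray(kept, dtype=int)


def simulate_night(scenario: SimScenario, night_index: int) -> NightResult:
    """Simulate one night of dispersal; fully determined by (seed, night)."""
    rng = _night_rng(scenario.seed, night_index)
    n, N = scenario.n_agents, scenario.n_detectors
    n_steps = scenario.n_steps
    sigma = np.sqrt(2.0 * scenario.params.D * scenario.step_dt)
    r2 = scenario.params.detector_radius**2
    X = scenario.detector_positions
    roost = np.asarray(scenario.roost, dtype=float)

    pos = np.tile(roost, (n, 1))
    prev_inside = ((roost - X) ** 2).sum(axis=1) <= r2  # same for all agents
    prev_inside = np.tile(prev_inside, (n, 1))
    msd = np.empty(n_steps)
    ev_agents: list[np.ndarray] = []
    ev_dets: list[np.ndarray] = []
    ev_times: list[np.ndarray] = []
    traj_chunks: list[np.ndarray] = []

    block = max(1, min(n_steps, 4_000_000 // max(1, n * N)))
    step = 0
    while step < n_steps:
        b = min(block, n_steps - step)
        incr = rng.normal(0.0, sigma, size=(n, b, 2))
        traj = pos[:, None, :] + np.cumsum(incr, axis=1)  # (n, b, 2)
        pos = traj[:, -1, :].copy()
        d2 = ((traj[:, :, None, :] - X[None, None, :, :]) ** 2).sum(-1)  # (n, b, N)
        inside = d2 <= r2
        prev = np.concatenate([prev_inside[:, None, :], inside[:, :-1, :]], axis=1)
        entries = inside & ~prev
        if entries.any():
            ai, si, di = np.nonzero(entries)
            ev_agents.append(ai)
            ev_dets.append(di)
            ev_times.append((step + si + 1) * scenario.step_dt)
        prev_inside = inside[:, -1, :]
        msd[step : step + b] = ((traj - roost) ** 2).sum(-1).mean(axis=0)
        if scenario.record_trajectories:
            sel = np.arange(step, step + b) % scenario.trajectory_thin == 0
            if sel.any():
                traj_chunks.append(traj[:, sel, :])
        step += b

    if ev_agents:
        agents = np.concatenate(ev_agents)
        dets = np.concatenate(ev_dets)
        times = np.concatenate(ev_times)
        kept = _thin_refractory(agents, dets, times, scenario.refractory)
        counts = np.bincount(kept, minlength=N)
    else:
        counts = np.zeros(N, dtype=int)
    traj = np.concatenate(traj_chunks, axis=1) if traj_chunks else None
    return NightResult(counts=counts, msd=msd, final_positions=pos, trajectories=traj)


def simulate_survey(scenario: SimScenario) -> tuple[SurveySet, SimResult]:
    """Run every night of the scenario and aggregate into a survey table."""
    nightly = np.zeros((scenario.n_nights, scenario.n_detectors), dtype=int)
    msd = np.zeros(scenario.n_steps)
    trajectories: list[np.ndarray] = []
    for night in range(scenario.n_nights):
        res = simulate_night(scenario, night)
        nightly[night] = res.counts
        msd += res.msd
        if res.trajectories is not None:
            trajectories.append(res.trajectories)
    result = SimResult(
        scenario=scenario,
        nightly_counts=nightly,
        nights_active=np.full(scenario.n_detectors, scenario.n_nights, dtype=int),
        msd=msd / scenario.n_nights,
        trajectories=trajectories,
    )
    return result.to_survey(), result


def apply_failures(
    result: SimResult, survival_prob: float, seed: int
) -> SimResult:
    """Truncate each detector's record by a nightly geometric failure draw.

    Each detector independently survives each night with probability
    ``survival_prob``; once it fails it stays silent.  A detector can fail
    before its first night (zero active nights), in which case survey loading
    drops it downstream.
    """
    if not (0 < survival_prob <= 1):
        raise ValueError("survival probability must be in (0, 1]")
    if survival_prob == 1.0:
        return result
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n_nights, N = result.nightly_counts.shape
    # geometric(p_fail) = nights until first failure, >= 1; survived nights
    # before the failure = draw - 1, capped at the survey length
    draws = rng.geometric(1.0 - survival_prob, size=N) - 1
    nights_active = np.minimum(draws, result.nights_active)
    return replace(result, nights_active=nights_active)


def save_trajectories(result: SimResult, path) -> None:
    """Thinned trajectories as CSV: night, agent_id, t, x, y."""
    import pandas as pd

    rows = []
    thin = result.scenario.trajectory_thin * result.scenario.step_dt
    for night, traj in enumerate(result.trajectories):
        n_agents, n_kept, _ = traj.shape
        t = np.arange(n_kept) * thin
        for a in range(n_agents):
            rows.append(
                pd.DataFrame(
                    {
                        "night": night,
                        "agent_id": a,
                        "t": t,
                        "x": traj[a, :, 0],
                        "y": traj[a, :, 1],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
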