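"""Closed-loop simulation: episodes, training schedule and probing.

One iteration = one emitted call, one received echo and one head-pose
update.  The target sits at a fixed 1 m distance; its direction is held
for 20 iterations (one episode), then redrawn uniformly over the
horizontal x elevation target region.  Per iteration the loop is:

  roll sample -> Fick head pose (Listing torsion + roll) -> target
  direction in head coordinates -> call synthesis -> binaural echo
  through the HRTFs -> windowing + GASSOM encoding -> pooled feature
  f(t) and reward r(t) -> policy action (dyaw, dpitch) -> head update.

In train mode the GASSOM dictionaries and the actor-critic learn online
from the same stream; in greedy mode (testing) nothing learns and the
policy mean is used.  Head rolls are applied in every mode.

Two profiles are provided: a scaled-down ``ci`` profile (64-unit
GASSOMs on an 8x8 grid, 100 hidden policy units, coarse HRTF grid) used
throughout the test battery, and the ``full`` profile (400-unit GASSOMs
on a 20x20 grid, 500 hidden units) matching the model at full scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import acoustics, control, gassom, kinematics, roll_model

__all__ = [
    "PROFILES",
    "EpisodeConfig",
    "EpisodeTrace",
    "AgentState",
    "init_agent",
    "run_episode",
    "train",
    "evaluate_grid",
    "error_surface",
    "reconstruction_error_at",
    "save_checkpoint",
    "load_checkpoint",
]

PROFILES = {
    "ci": {
        "n_units": 64,
        "grid_shape": (8, 8),
        "hidden": 100,
        "radius_start": 1.0,
        "hrtf_step_deg": 10.0,
        "default_train_targets": 600,
    },
    "full": {
        "n_units": 400,
        "grid_shape": (20, 20),
        "hidden": 500,
        "radius_start": 2.5,
        "hrtf_step_deg": 5.0,
        "default_train_targets": 10000,
    },
}


@dataclass(frozen=True)
class EpisodeConfig:
    """Conditions of one simulated localization episode."""

    iterations: int = 20
    sigma_roll: float = 10.0
    target_region: tuple = (-60.0, 60.0, -60.0, 60.0)  # h_lo, h_hi, e_lo, e_hi
    call_duration_ms: float | None = None  # None: drawn from the gamma law
    target_distance_m: float = 1.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sigma_roll < 0:
            raise ValueError("sigma_roll must be >= 0")


@dataclass
class EpisodeTrace:
    """Per-iteration record of one episode."""

    target_body: np.ndarray  # fixed target direction, body frame
    sigma_roll: float
    seed: object
    iterations: list = field(default_factory=list)  # iteration numbers (1-based)
    yaw: list = field(default_factory=list)
    pitch: list = field(default_factory=list)
    torsion: list = field(default_factory=list)
    roll: list = field(default_factory=list)
    target_horizontal: list = field(default_factory=list)
    target_elevation: list = field(default_factory=list)
    dyaw: list = field(default_factory=list)
    dpitch: list = field(default_factory=list)
    reward: list = field(default_factory=list)
    call_duration_ms: list = field(default_factory=list)
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "yaw": self.yaw,
                "pitch": self.pitch,
                "torsion": self.torsion,
                "roll": self.roll,
                "target_horizontal": self.target_horizontal,
                "target_elevation": self.target_elevation,
                "dyaw": self.dyaw,
                "dpitch": self.dpitch,
                "reward": self.reward,
                "call_duration_ms": self.call_duration_ms,
            }
        )

    @property
    def final_direction(self) -> tuple[float, float]:
        return (self.target_horizontal[-1], self.target_elevation[-1])


@dataclass
class AgentState:
    """All learned components plus the HRTF set they were trained with."""

    hrtf: acoustics.HRTFSet
    gassoms: dict
    policy: control.PolicyNet
    critic: control.CriticNet
    profile: str = "ci"
    episodes_trained: int = 0
    train_seed: object = None

    @property
    def feature_dim(self) -> int:
        return sum(g.config.n_units for g in self.gassoms.values())


def _profile_hrtf(profile: str) -> acoustics.HRTFSet:
    step = PROFILES[profile]["hrtf_step_deg"]
    cfg = acoustics.SyntheticHrtfConfig(
        horizontal_deg=(-85.0, 85.0, step), elevation_deg=(-85.0, 85.0, step)
    )
    return acoustics.make_synthetic_hrtf(cfg)


def init_agent(
    profile: str = "ci",
    seed=0,
    hrtf: acoustics.HRTFSet | None = None,
    total_steps: int | None = None,
    nac_overrides: dict | None = None,
) -> AgentState:
    """Fresh untrained agent under a profile.

    ``total_steps`` sets the annealing horizon (number of closed-loop
    iterations the agent will be trained for); ``nac_overrides`` replaces
    individual :class:`~echoroll.control.NacConfig` fields.
    """
    p = PROFILES[profile]
    if hrtf is None:
        hrtf = _profile_hrtf(profile)
    if total_steps is None:
        total_steps = p["default_train_targets"] * 20
    gassoms = {}
    for k, stream in enumerate(gassom.STREAMS):
        dim = 100 if stream[1] == "binaural" else 50
        cfg = gassom.GassomConfig(
            n_units=p["n_units"], dim=dim, grid_shape=tuple(p["grid_shape"]),
            radius_start=p["radius_start"], total_steps=total_steps,
        )
        gassoms[stream] = gassom.GassomDictionary(cfg, seed=[seed, 100 + k])
    nac_cfg = control.NacConfig(total_steps=total_steps,
                                **(nac_overrides or {}))
    feature_dim = p["n_units"] * len(gassom.STREAMS)
    policy = control.PolicyNet(feature_dim, hidden=p["hidden"],
                               seed=[seed, 7], config=nac_cfg)
    critic = control.CriticNet(feature_dim, config=nac_cfg)
    return AgentState(hrtf, gassoms, policy, critic, profile, 0, seed)


def _feasible(h_deg: float, e_deg: float, min_x: float = 0.15) -> bool:
    """(horizontal, elevation) pairs must satisfy sin^2 h + sin^2 e < 1
    (they parametrize the frontal hemisphere); additionally keep a margin
    off the lateral great circle where the forward component vanishes."""
    y = np.sin(np.deg2rad(h_deg))
    z = np.sin(np.deg2rad(e_deg))
    return bool(1.0 - y * y - z * z >= min_x**2)


def _draw_target(cfg: EpisodeConfig, rng) -> np.ndarray:
    h_lo, h_hi, e_lo, e_hi = cfg.target_region
    while True:  # rejection sampling keeps the draw uniform on the region
        h = rng.uniform(h_lo, h_hi)
        e = rng.uniform(e_lo, e_hi)
        if _feasible(h, e):
            return kinematics.direction_from_horizontal(h, e)


def _net_features(f: np.ndarray) -> np.ndarray:
    """Standardized feature vector fed to the actor and critic.

    Pooled responses live on a small positive scale (mean ~ 2/dim); the
    nets see the pattern standardized per vector so that hidden units
    operate in their sensitive range.
    """
    mu = f.mean()
    sd = f.std()
    return (f - mu) / (sd + 1e-12)


def _observe(state: AgentState, horizontal: float, elevation: float,
             duration_ms: float, call_seed) -> tuple[float, np.ndarray, dict, dict]:
    """Render and encode one echo; returns (reward, feature, windows, encodings)."""
    call = acoustics.synthesize_call(duration_ms, seed=call_seed)
    echo = acoustics.render_echo(call, state.hrtf, horizontal=horizontal,
                                 elevation=elevation)
    windows = gassom.extract_windows(echo)
    encodings = {s: state.gassoms[s].encode(w) for s, w in windows.items()}
    reward = control.compute_reward(
        {s: enc.window_errors for s, enc in encodings.items()}
    )
    feature = gassom.pool_features(encodings)
    return reward, feature, windows, encodings


def run_episode(
    state: AgentState,
    cfg: EpisodeConfig,
    mode: str = "greedy",
    seed=0,
    target_direction: np.ndarray | None = None,
    rolls: np.ndarray | None = None,
    oracle: bool = False,
    freeze_gassom: bool = False,
) -> EpisodeTrace:
    """Run one episode (20 iterations against a fixed target).

    ``mode`` is ``"train"`` (stochastic policy, online learning) or
    ``"greedy"`` (deterministic policy, no learning).  ``oracle``
    replaces the policy by the exact kinematic controller (a sanity
    device, not a model component).  The episode is truncated with
    ``trace.truncated = True`` if the target leaves the HRTF hull.
    """
    rng = np.random.default_rng(seed)
    if target_direction is None:
        target_direction = _draw_target(cfg, rng)
    s_B = np.asarray(target_direction, dtype=float)
    s_B = s_B / np.linalg.norm(s_B)
    if rolls is None:
        rolls = roll_model.roll_stream(cfg.sigma_roll, cfg.iterations, rng)
    trace = EpisodeTrace(s_B, cfg.sigma_roll, seed)
    R = np.eye(3)  # accumulated body-to-head yaw/pitch matrix
    pending = None  # (feature, action) awaiting its consequence
    for t in range(1, cfg.iterations + 1):
        head = R.T @ np.array([1.0, 0.0, 0.0])
        head_ang = kinematics.angles_from_direction(head)
        fick, R_HB = kinematics.head_pose_with_roll(
            head_ang.azimuth, head_ang.elevation, float(rolls[t - 1])
        )
        s_H, t_ang = kinematics.target_in_head_coords(R_HB.T, s_B)
        t_h, t_e = t_ang.horizontal, t_ang.elevation
        if s_H[0] <= 0.0 or not state.hrtf.contains(t_h, t_e):
            trace.truncated = True
            break
        duration = cfg.call_duration_ms
        if duration is None:
            duration = float(np.clip(
                rng.gamma(*acoustics.CALL_DURATION_GAMMA), 0.51, 9.99))
        reward, feature, windows, encodings = _observe(
            state, t_h, t_e, duration, call_seed=rng)
        f_net = _net_features(feature)
        if mode == "train":
            if pending is not None:
                control.nac_update(
                    state.policy, state.critic,
                    (pending[0], pending[1], reward, f_net), done=False,
                )
            if not freeze_gassom:
                for s, w in windows.items():
                    state.gassoms[s].update(w, encodings[s])
        if oracle:
            aim = kinematics.angles_from_direction(R @ s_B)
            action = control.Action(aim.azimuth, aim.elevation)
        else:
            action = control.act(state.policy, f_net, mode=mode, rng=rng)
        if mode == "train":
            pending = (f_net, action)
        trace.iterations.append(t)
        trace.yaw.append(fick.yaw)
        trace.pitch.append(fick.pitch)
        trace.torsion.append(fick.torsion)
        trace.roll.append(float(rolls[t - 1]))
        trace.target_horizontal.append(t_h)
        trace.target_elevation.append(t_e)
        trace.dyaw.append(action.dyaw)
        trace.dpitch.append(action.dpitch)
        trace.reward.append(reward)
        trace.call_duration_ms.append(duration)
        R, _ = kinematics.update_head_rotation(R, action.dyaw, action.dpitch)
    return trace


def train(
    n_targets: int,
    sigma_roll: float,
    seed=0,
    profile: str = "ci",
    cfg: EpisodeConfig | None = None,
    hrtf: acoustics.HRTFSet | None = None,
    state: AgentState | None = None,
    freeze_gassom: bool = False,
    log_path=None,
) -> tuple[AgentState, pd.DataFrame]:
    """Train an agent over successive randomly-targeted episodes.

    Episode k derives all of its randomness from SeedSequence([seed, k]),
    so training resumed from a checkpoint at episode k under the same
    master seed reproduces the uninterrupted run bit for bit.

    Returns the trained state and a per-episode curve (episode, mean
    reward, final distance to (0,0)).
    """
    if cfg is None:
        cfg = EpisodeConfig(sigma_roll=sigma_roll)
    elif cfg.sigma_roll != sigma_roll:
        raise ValueError("cfg.sigma_roll disagrees with sigma_roll")
    if state is None:
        state = init_agent(profile, seed=seed, hrtf=hrtf,
                           total_steps=n_targets * cfg.iterations)
    rows = []
    logf = open(log_path, "a") if log_path is not None else None
    try:
        if logf:
            logf.write(json.dumps({
                "event": "train_start", "config": config_hash(cfg),
                "sigma_roll": sigma_roll, "seed": seed, "n_targets": n_targets,
            }) + "\n")
        for ep in range(state.episodes_trained, n_targets):
            trace = run_episode(
                state, cfg, mode="train",
                seed=np.random.SeedSequence([_as_int_seed(seed), ep]),
                freeze_gassom=freeze_gassom,
            )
            state.episodes_trained = ep + 1
            final = trace.final_direction if trace.iterations else (np.nan, np.nan)
            row = {
                "episode": ep,
                "mean_reward": float(np.mean(trace.reward)) if trace.reward else np.nan,
                "final_distance": float(np.hypot(*final)),
                "truncated": trace.truncated,
            }
            rows.append(row)
            if logf:
                logf.write(json.dumps({"event": "episode", **row}) + "\n")
    finally:
        if logf:
            logf.close()
    return state, pd.DataFrame(rows)


def _as_int_seed(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def evaluate_grid(
    state: AgentState,
    sigma_roll: float,
    initial_directions,
    call_durations=(2.0,),
    seed=0,
    iterations: int = 20,
) -> list[EpisodeTrace]:
    """Greedy evaluation episodes from given initial target directions.

    ``initial_directions`` is an iterable of (horizontal, elevation) deg.
    Rolls are still applied (they are part of the behavior, not of the
    exploration).  Returns one trace per (direction, duration).
    """
    if state.episodes_trained == 0:
        import warnings

        warnings.warn("evaluating an untrained agent")
    traces = []
    for di, (h, e) in enumerate(initial_directions):
        for ci, dur in enumerate(call_durations):
            cfg = EpisodeConfig(iterations=iterations, sigma_roll=sigma_roll,
                                call_duration_ms=float(dur))
            trace = run_episode(
                state, cfg, mode="greedy",
                seed=np.random.SeedSequence([_as_int_seed(seed), di, ci]),
                target_direction=kinematics.direction_from_horizontal(h, e),
            )
            traces.append(trace)
    return traces


def reconstruction_error_at(
    state: AgentState,
    directions,
    rolls,
    durations,
    seed=0,
) -> np.ndarray:
    """Mean reconstruction error for each (horizontal, elevation) direction.

    For every direction the error is averaged over the given roll angles
    and call durations; a roll gamma maps the nominal direction d to
    R_X(gamma)^T d before rendering (the head rolls, the world does not).
    Directions whose rolled image leaves the HRTF hull contribute only
    their in-hull samples; an all-out direction yields NaN.
    """
    rng = np.random.default_rng(seed)
    call_seeds = [rng.integers(2**31) for _ in durations]
    out = np.full(len(directions), np.nan)
    for i, (h, e) in enumerate(directions):
        if not _feasible(h, e):
            continue
        d = kinematics.direction_from_horizontal(h, e)
        vals = []
        for gamma in rolls:
            dr = kinematics.elementary_rotation("X", float(gamma)).T @ d
            ang = kinematics.angles_from_direction(dr)
            th, te = ang.horizontal, ang.elevation
            if dr[0] <= 0 or not state.hrtf.contains(th, te):
                continue
            for dur, cs in zip(durations, call_seeds):
                r, _, _, _ = _observe(state, th, te, float(dur), call_seed=cs)
                vals.append(-r)  # reward is negative mean error
        if vals:
            out[i] = float(np.mean(vals))
    return out


def error_surface(
    state: AgentState,
    sigma_roll: float | None = None,
    fixed_roll: float | None = None,
    grid=(-80.0, 80.0, 2.0),
    n_calls: int = 30,
    n_rolls: int = 100,
    seed=0,
):
    """Mean reconstruction-error surface over a direction grid.

    Rolls are either ``n_rolls`` samples from the AR stream at
    ``sigma_roll`` or the single ``fixed_roll`` angle.  Call durations
    are drawn from the gamma law (``n_calls`` of them).  Returns
    (horizontal_axis, elevation_axis, surface, argmin) with the surface
    indexed [horizontal, elevation] and argmin the (horizontal,
    elevation) of the minimum.  Grid points outside the hull are NaN.
    """
    if (sigma_roll is None) == (fixed_roll is None):
        raise ValueError("give exactly one of sigma_roll or fixed_roll")
    rng = np.random.default_rng(seed)
    if fixed_roll is not None:
        rolls = np.array([float(fixed_roll)])
    else:
        rolls = roll_model.roll_stream(sigma_roll, n_rolls, rng)
    durations = np.clip(rng.gamma(*acoustics.CALL_DURATION_GAMMA, size=n_calls),
                        0.51, 9.99)
    lo, hi, step = grid
    axis = np.arange(lo, hi + 1e-9, step)
    dirs = [(h, e) for h in axis for e in axis]
    flat = reconstruction_error_at(state, dirs, rolls, durations, seed=rng)
    surface = flat.reshape(len(axis), len(axis))
    k = np.nanargmin(surface)
    i, j = np.unravel_index(k, surface.shape)
    return axis, axis, surface, (float(axis[i]), float(axis[j]))


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: AgentState, path) -> None:
    """Write the full agent state (GASSOMs, nets, HRTF) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["profile"] = state.profile
        f.attrs["episodes_trained"] = state.episodes_trained
        f.attrs["train_seed"] = json.dumps(state.train_seed)
        gg = f.create_group("gassoms")
        for stream, d in state.gassoms.items():
            d.save(gg.create_group(f"{stream[0]}_{stream[1]}"))
        pg = f.create_group("policy")
        for k, v in state.policy.state_arrays().items():
            pg.create_dataset(k, data=v)
        pg.attrs["step"] = state.policy.step
        pg.attrs["config"] = json.dumps(asdict(state.policy.config))
        cg = f.create_group("critic")
        for k, v in state.critic.state_arrays().items():
            cg.create_dataset(k, data=v)
        cg.attrs["step"] = state.critic.step
        hg = f.create_group("hrtf")
        hg.create_dataset("horizontal_deg", data=state.hrtf.horizontal_grid)
        hg.create_dataset("elevation_deg", data=state.hrtf.elevation_grid)
        hg.create_dataset("impulse_responses", data=state.hrtf.impulse_responses)
        hg.attrs["sample_rate"] = state.hrtf.sample_rate
        hg.attrs["provenance"] = state.hrtf.provenance


def load_checkpoint(path) -> AgentState:
    import h5py

    with h5py.File(path, "r") as f:
        gassoms = {}
        for name, grp in f["gassoms"].items():
            scale, stream = name.split("_")
            gassoms[(scale, stream)] = gassom.GassomDictionary.load(grp)
        nac_cfg = control.NacConfig(**json.loads(f["policy"].attrs["config"]))
        W1 = f["policy/W1"][()]
        policy = control.PolicyNet(W1.shape[1], hidden=W1.shape[0],
                                   config=nac_cfg)
        policy.W1 = W1
        policy.b1 = f["policy/b1"][()]
        policy.W2 = f["policy/W2"][()]
        policy.b2 = f["policy/b2"][()]
        if "nat_P" in f["policy"]:
            policy._nat_P = f["policy/nat_P"][()]
            policy._nat_w = f["policy/nat_w"][()]
        policy.step = int(f["policy"].attrs["step"])
        critic = control.CriticNet(W1.shape[1], config=nac_cfg)
        critic.w = f["critic/w"][()]
        critic.b = float(f["critic/b"][()][0])
        if "P" in f["critic"]:
            critic.P = f["critic/P"][()]
        critic.step = int(f["critic"].attrs["step"])
        hrtf = acoustics.HRTFSet(
            f["hrtf/horizontal_deg"][()], f["hrtf/elevation_deg"][()],
            f["hrtf/impulse_responses"][()],
            int(f["hrtf"].attrs["sample_rate"]),
            str(f["hrtf"].attrs["provenance"]),
        )
        return AgentState(
            hrtf, gassoms, policy, critic,
            profile=str(f.attrs["profile"]),
            episodes_trained=int(f.attrs["episodes_trained"]),
            train_seed=json.loads(f.attrs["train_seed"]),
        )
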