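"""Agent-based simulator of the desert-herding containment game.

Three embodied ground players corral evasive target agents (TAs) into a
central containment area on a flat 500 x 500 m field.  TAs are unit-mass
particles driven by a 1 Hz zero-order-hold Brownian force (magnitude uniform
on [0, 60] N, direction uniform) plus a capped inverse-distance repulsion
from any player avatar inside their 10 m threat radius.  Velocities are
clamped at 10 m/s; there is no drag.  A trial ends in success once every TA
has been inside the containment circle for 5 continuous seconds, or in
failure at the 300 s ceiling.

Everything is deterministic given ``(design, params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimParams",
    "ConditionDesign",
    "TAState",
    "TrialRecord",
    "repulsion_force",
    "step_ta",
    "run_trial",
]

# integer status codes used in recorded status series
STATUS_UNSPAWNED = -1
STATUS_IDLE = 0
STATUS_FLEEING = 1
STATUS_CONTAINED = 2
STATUS_ALL_CONTAINED = 3

STATUS_NAMES = {
    STATUS_UNSPAWNED: "unspawned",
    STATUS_IDLE: "idle",
    STATUS_FLEEING: "fleeing",
    STATUS_CONTAINED: "contained",
    STATUS_ALL_CONTAINED: "all_contained",
}

_VALID_TARGET_NUMBERS = (9, 18)
_VALID_VISIBILITY = ("clear", "fog")
_VALID_PERTURBATION = ("none", "late_spawn")


@dataclass(frozen=True)
class SimParams:
    """Physical and procedural constants of the game server.

    Distances in meters, forces in newtons, rates in hertz, times in seconds.

    ``contained_dynamics`` controls what a TA does inside the containment
    circle: ``"calm"`` (default) freezes an *unthreatened* contained TA in
    place (no Brownian kick, velocity zeroed) while a threatened one still
    flees; ``"full"`` applies the open-field dynamics everywhere.
    """

    field_size: float = 500.0
    containment_radius: float = 5.0
    ta_spawn_radius: float = 180.0
    player_spawn_radius: float = 100.0
    threat_radius: float = 10.0
    brownian_force_max: float = 60.0
    brownian_rate: float = 1.0
    repulsion_force_max: float = 450.0
    repulsion_k: float = 450.0  # N*m; F(d) = min(f_max, k/d)
    ta_mass: float = 1.0
    ta_speed_max: float = 10.0
    player_speed: float = 10.0
    player_speed_slow: float = 5.0
    tick_rate: int = 90
    trial_max: float = 300.0
    success_dwell: float = 5.0
    perturb_window: float = 90.0
    contained_dynamics: str = "calm"

    def __post_init__(self) -> None:
        positive = (
            "field_size containment_radius ta_spawn_radius player_spawn_radius "
            "threat_radius brownian_rate repulsion_force_max repulsion_k ta_mass "
            "ta_speed_max player_speed player_speed_slow tick_rate trial_max "
            "success_dwell perturb_window"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be > 0")
        if self.brownian_force_max < 0:
            raise ValueError("SimParams.brownian_force_max must be >= 0")
        if not (
            self.containment_radius
            < self.player_spawn_radius
            < self.ta_spawn_radius
            <= self.field_size / 2
        ):
            raise ValueError(
                "require containment_radius < player_spawn_radius < "
                "ta_spawn_radius <= field_size/2"
            )
        if self.success_dwell >= self.trial_max:
            raise ValueError("SimParams.success_dwell must be < trial_max")
        if self.contained_dynamics not in ("calm", "full"):
            raise ValueError("SimParams.contained_dynamics must be 'calm' or 'full'")

    @property
    def dt(self) -> float:
        return 1.0 / self.tick_rate

    @property
    def field_half(self) -> float:
        return self.field_size / 2.0

    @property
    def brownian_interval_ticks(self) -> int:
        return max(1, int(round(self.tick_rate / self.brownian_rate)))


@dataclass(frozen=True)
class ConditionDesign:
    """One cell of the 2 (targets) x 2 (visibility) x 2 (perturbation) design."""

    target_number: int
    visibility: str = "clear"
    perturbation: str = "none"
    trial_id: int | str = 0
    team_id: int | str = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.target_number not in _VALID_TARGET_NUMBERS:
            raise ValueError(
                f"target_number must be one of {_VALID_TARGET_NUMBERS}, "
                f"got {self.target_number!r}"
            )
        if self.visibility not in _VALID_VISIBILITY:
            raise ValueError(f"visibility must be one of {_VALID_VISIBILITY}")
        if self.perturbation not in _VALID_PERTURBATION:
            raise ValueError(f"perturbation must be one of {_VALID_PERTURBATION}")


@dataclass
class TAState:
    """Single target-agent state (used by the one-agent stepping API)."""

    position: np.ndarray
    velocity: np.ndarray
    status: str = "idle"
    brownian_force: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.brownian_force = np.asarray(self.brownian_force, dtype=float)


@dataclass
class TrialRecord:
    """Full telemetry of one simulated trial.

    ``player_traj`` has shape (3, T, 2) and ``ta_traj`` (n_ta, T, 2), both
    sampled at ``params.tick_rate`` after each physics tick.  ``ta_status``
    (n_ta, T, int8) uses the STATUS_* codes; unspawned late TAs are -1.
    """

    design: ConditionDesign
    params: SimParams
    seed: int
    duration: float
    success: bool
    contained_at_end: int
    player_traj: np.ndarray
    ta_traj: np.ndarray
    ta_status: np.ndarray
    ta_spawn_tick: np.ndarray  # tick index at which each TA became active

    @property
    def n_ticks(self) -> int:
        return self.player_traj.shape[1]

    @property
    def n_tas(self) -> int:
        return self.ta_traj.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time stamp of each recorded tick (state after the tick)."""
        return (np.arange(self.n_ticks) + 1) * self.params.dt


# ---------------------------------------------------------------------------
# forces and single-step dynamics
# ---------------------------------------------------------------------------


def repulsion_force(
    offset: Sequence[float],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Repulsive force on a TA from one player.

    ``offset`` points from the player to the TA; the force acts along it
    ("directly away from the participant's avatar") with magnitude
    ``min(f_max, k/d)`` for ``d <= threat_radius`` and zero beyond.  A
    zero-length offset (coincident positions) gets a direction drawn
    uniformly from ``rng``.
    """
    o = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(o)):
        raise ValueError("offset must be finite")
    d = float(np.hypot(o[0], o[1]))
    if d > params.threat_radius:
        return np.zeros(2)
    if d == 0.0:
        if rng is None:
            raise ValueError("zero-length offset needs an rng to draw a direction")
        theta = rng.uniform(0.0, 2.0 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        return params.repulsion_force_max * direction
    mag = min(params.repulsion_force_max, params.repulsion_k / d)
    return mag * (o / d)


def sample_brownian(
    n: int, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` Brownian forcing vectors: magnitude U(0, f_max), angle U(0, 2pi)."""
    mag = rng.uniform(0.0, params.brownian_force_max, size=n)
    ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])


def _reflect(pos: np.ndarray, vel: np.ndarray, half: float) -> None:
    """Reflective field boundary at +/- half, in place."""
    if np.abs(pos).max(initial=0.0) <= half:
        return
    for axis in (0, 1):
        hi = pos[..., axis] > half
        if np.any(hi):
            pos[hi, axis] = 2 * half - pos[hi, axis]
            vel[hi, axis] *= -1.0
        lo = pos[..., axis] < -half
        if np.any(lo):
            pos[lo, axis] = -2 * half - pos[lo, axis]
            vel[lo, axis] *= -1.0


try:  # jitted inner loop; the numpy path below is the reference fallback
    import math as _math

    from numba import njit as _njit

    @_njit(cache=True)
    def _step_kernel(pos, vel, brown, players, dt, mass, threat2, fmax, kk, rc2, vmax2, half, calm_mode):  # pragma: no cover - exercised via _step_ta_arrays
        n = pos.shape[0]
        m = players.shape[0]
        contained = np.zeros(n, np.bool_)
        threatened = np.zeros(n, np.bool_)
        coincident = 0
        for i in range(n):
            fx = brown[i, 0]
            fy = brown[i, 1]
            thr = False
            for j in range(m):
                dx = pos[i, 0] - players[j, 0]
                dy = pos[i, 1] - players[j, 1]
                d2 = dx * dx + dy * dy
                if d2 <= threat2:
                    thr = True
                    d = _math.sqrt(d2)
                    if d < 1e-12:
                        coincident += 1
                    else:
                        mag = kk / d
                        if mag > fmax:
                            mag = fmax
                        fx += mag * dx / d
                        fy += mag * dy / d
            threatened[i] = thr
            r2 = pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
            if calm_mode and r2 <= rc2 and not thr:
                vx = 0.0
                vy = 0.0
            else:
                vx = vel[i, 0] + fx * dt / mass
                vy = vel[i, 1] + fy * dt / mass
                s2 = vx * vx + vy * vy
                if s2 > vmax2:
                    sc = _math.sqrt(vmax2 / s2)
                    vx *= sc
                    vy *= sc
            x = pos[i, 0] + vx * dt
            y = pos[i, 1] + vy * dt
            if x > half:
                x = 2 * half - x
                vx = -vx
            elif x < -half:
                x = -2 * half - x
                vx = -vx
            if y > half:
                y = 2 * half - y
                vy = -vy
            elif y < -half:
                y = -2 * half - y
                vy = -vy
            pos[i, 0] = x
            pos[i, 1] = y
            vel[i, 0] = vx
            vel[i, 1] = vy
            contained[i] = x * x + y * y <= rc2
        return contained, threatened, coincident

except Exception:  # numba unavailable: stay on the numpy path
    _step_kernel = None


def _step_ta_arrays(
    pos: np.ndarray,
    vel: np.ndarray,
    brown: np.ndarray,
    player_pos: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One semi-implicit Euler tick for an array of TAs.

    Returns (pos, vel, contained, threatened) after the tick.  Dispatches to
    the jitted kernel when available; coincident player/TA positions (which
    need the trial RNG for a random push direction) are handled by the
    reference path.
    """
    if _step_kernel is not None and len(pos):
        new_pos = np.ascontiguousarray(pos, dtype=np.float64)
        if new_pos is pos:
            new_pos = pos.copy()
        new_vel = np.ascontiguousarray(vel, dtype=np.float64)
        if new_vel is vel:
            new_vel = vel.copy()
        contained, threatened, coincident = _step_kernel(
            new_pos,
            new_vel,
            np.ascontiguousarray(brown, dtype=np.float64),
            np.ascontiguousarray(player_pos, dtype=np.float64),
            params.dt,
            params.ta_mass,
            params.threat_radius**2,
            params.repulsion_force_max,
            params.repulsion_k,
            params.containment_radius**2,
            params.ta_speed_max**2,
            params.field_half,
            params.contained_dynamics == "calm",
        )
        if coincident == 0:
            return new_pos, new_vel, contained, threatened
    return _step_ta_arrays_numpy(pos, vel, brown, player_pos, params, rng)


def _step_ta_arrays_numpy(
    pos: np.ndarray,
    vel: np.ndarray,
    brown: np.ndarray,
    player_pos: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reference numpy implementation of the TA tick."""
    dt = params.dt
    n = len(pos)
    fx = brown[:, 0].copy()
    fy = brown[:, 1].copy()
    if len(player_pos) and n:
        dx = pos[:, 0, None] - player_pos[None, :, 0]
        dy = pos[:, 1, None] - player_pos[None, :, 1]
        d2 = dx * dx + dy * dy
        within = d2 <= params.threat_radius**2
        threatened = within.any(axis=1)
        if threatened.any():
            d = np.sqrt(d2)
            safe = np.maximum(d, 1e-12)
            coef = np.where(
                within,
                np.minimum(params.repulsion_force_max, params.repulsion_k / safe)
                / safe,
                0.0,
            )
            zero = within & (d < 1e-12)
            if zero.any():
                idx = np.argwhere(zero)
                theta = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
                coef[idx[:, 0], idx[:, 1]] = 0.0
                fx[idx[:, 0]] += params.repulsion_force_max * np.cos(theta)
                fy[idx[:, 0]] += params.repulsion_force_max * np.sin(theta)
            fx += (coef * dx).sum(axis=1)
            fy += (coef * dy).sum(axis=1)
    else:
        threatened = np.zeros(n, dtype=bool)

    rc2 = params.containment_radius**2
    calm = None
    if params.contained_dynamics == "calm":
        contained_before = pos[:, 0] ** 2 + pos[:, 1] ** 2 <= rc2
        calm = contained_before & ~threatened
        if calm.any():
            fx[calm] = 0.0
            fy[calm] = 0.0

    scale = dt / params.ta_mass
    vx = vel[:, 0] + fx * scale
    vy = vel[:, 1] + fy * scale
    s2 = vx * vx + vy * vy
    over = s2 > params.ta_speed_max**2
    if over.any():
        shrink = params.ta_speed_max / np.sqrt(s2[over])
        vx[over] *= shrink
        vy[over] *= shrink
    if calm is not None and calm.any():
        vx[calm] = 0.0
        vy[calm] = 0.0

    new_pos = np.empty_like(pos)
    new_pos[:, 0] = pos[:, 0] + vx * dt
    new_pos[:, 1] = pos[:, 1] + vy * dt
    new_vel = np.empty_like(vel)
    new_vel[:, 0] = vx
    new_vel[:, 1] = vy
    _reflect(new_pos, new_vel, params.field_half)
    contained = new_pos[:, 0] ** 2 + new_pos[:, 1] ** 2 <= rc2
    return new_pos, new_vel, contained, threatened


def step_ta(
    ta: TAState,
    player_positions: Sequence[Sequence[float]],
    t: float,
    params: SimParams,
    rng: np.random.Generator,
) -> TAState:
    """Advance one TA by a single tick starting at time ``t``.

    The Brownian force is a zero-order hold: it is resampled only when ``t``
    falls on a 1/brownian_rate boundary (tick grid) and held otherwise.
    """
    players = np.atleast_2d(np.asarray(player_positions, dtype=float)) if len(
        player_positions
    ) else np.zeros((0, 2))
    tick = int(round(t * params.tick_rate))
    brown = ta.brownian_force
    if tick % params.brownian_interval_ticks == 0:
        brown = sample_brownian(1, params, rng)[0]
    pos, vel, contained, threatened = _step_ta_arrays(
        ta.position[None, :].copy(),
        ta.velocity[None, :].copy(),
        brown[None, :].copy(),
        players,
        params,
        rng,
    )
    if contained[0]:
        status = "contained"
    elif threatened[0]:
        status = "fleeing"
    else:
        status = "idle"
    return TAState(pos[0], vel[0], status=status, brownian_force=brown)


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------


def _spawn_disk(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def run_trial(
    design: ConditionDesign,
    policy=None,
    params: Optional[SimParams] = None,
    seed: Optional[int] = None,
    initial_ta_positions: Optional[np.ndarray] = None,
    initial_player_positions: Optional[np.ndarray] = None,
) -> TrialRecord:
    """Simulate one trial and return its full telemetry.

    ``policy`` must expose ``reset(design, sim_params, player_positions, rng)``
    and ``step(t, player_pos, ta_pos, active, contained) -> (3, 2) velocity``;
    the default is :class:`herdlab.policy.ScriptedPolicy`.  The trial is fully
    reproducible from ``seed`` (defaulting to ``design.seed``).

    ``initial_*_positions`` override the random spawns (useful for probing
    the termination rules under controlled geometry).
    """
    params = params or SimParams()
    if seed is None:
        seed = design.seed if design.seed is not None else 0
    rng = np.random.default_rng(seed)

    if policy is None:
        from .policy import ScriptedPolicy

        policy = ScriptedPolicy()

    n_base = design.target_number
    perturbed = design.perturbation == "late_spawn"
    n_total = n_base + (1 if perturbed else 0)

    if initial_ta_positions is not None:
        ta_pos = np.array(initial_ta_positions, dtype=float)
        if ta_pos.shape != (n_base, 2):
            raise ValueError(
                f"initial_ta_positions must have shape ({n_base}, 2)"
            )
        ta_pos = np.vstack([ta_pos, np.zeros((n_total - n_base, 2))])
    else:
        ta_pos = np.vstack(
            [
                _spawn_disk(rng, params.ta_spawn_radius, n_base),
                np.zeros((n_total - n_base, 2)),
            ]
        )
    if initial_player_positions is not None:
        player_pos = np.array(initial_player_positions, dtype=float)
        if player_pos.shape != (3, 2):
            raise ValueError("initial_player_positions must have shape (3, 2)")
    else:
        player_pos = _spawn_disk(rng, params.player_spawn_radius, 3)

    ta_vel = np.zeros((n_total, 2))
    brown = np.zeros((n_total, 2))
    active = np.zeros(n_total, dtype=bool)
    active[:n_base] = True
    spawn_tick = np.full(n_total, -1, dtype=np.int64)
    spawn_tick[:n_base] = 0

    # the late TA appears at a uniform time in the final perturb_window, or as
    # soon as all base TAs are contained, whichever comes first
    spawn_deadline = np.inf
    if perturbed:
        spawn_deadline = rng.uniform(
            params.trial_max - params.perturb_window, params.trial_max
        )

    n_ticks_max = int(round(params.trial_max * params.tick_rate))
    dwell_ticks_needed = int(round(params.success_dwell * params.tick_rate))
    control_interval = max(1, int(round(params.tick_rate / getattr(policy, "control_rate", 10.0))))

    player_traj = np.empty((3, n_ticks_max, 2))
    ta_traj = np.empty((n_total, n_ticks_max, 2))
    ta_status = np.full((n_total, n_ticks_max), STATUS_UNSPAWNED, dtype=np.int8)

    policy.reset(design, params, player_pos.copy(), rng)

    dt = params.dt
    dwell = 0
    success = False
    controls = np.zeros((3, 2))
    contained = np.hypot(ta_pos[:, 0], ta_pos[:, 1]) <= params.containment_radius
    n_used = n_ticks_max

    idx = np.flatnonzero(active)
    n_active = len(idx)
    pending_spawn = perturbed

    for k in range(n_ticks_max):
        t = k * dt
        if k % params.brownian_interval_ticks == 0:
            brown[idx] = sample_brownian(n_active, params, rng)
        if k % control_interval == 0:
            controls = np.asarray(
                policy.step(t, player_pos, ta_pos, active, contained), dtype=float
            )
        player_pos = player_pos + controls * dt
        if np.abs(player_pos).max() > params.field_half:
            np.clip(player_pos, -params.field_half, params.field_half, out=player_pos)

        idx_step = idx
        pos_a, vel_a, cont_a, threat_a = _step_ta_arrays(
            ta_pos[idx], ta_vel[idx], brown[idx], player_pos, params, rng
        )
        ta_pos[idx] = pos_a
        ta_vel[idx] = vel_a
        contained[:] = False
        contained[idx] = cont_a
        all_contained = int(cont_a.sum()) == n_active

        # late-spawn trigger
        spawned_now = False
        if pending_spawn and ((t + dt >= spawn_deadline) or all_contained):
            ta_pos[n_base] = _spawn_disk(rng, params.ta_spawn_radius, 1)[0]
            ta_vel[n_base] = 0.0
            brown[n_base] = sample_brownian(1, params, rng)[0]
            active[n_base] = True
            spawn_tick[n_base] = k
            contained[n_base] = (
                np.hypot(*ta_pos[n_base]) <= params.containment_radius
            )
            idx = np.flatnonzero(active)
            n_active = len(idx)
            all_contained = bool(contained[idx].all())
            pending_spawn = False
            spawned_now = True

        # record state after the tick
        player_traj[:, k] = player_pos
        ta_traj[:, k] = ta_pos
        cont_code = STATUS_ALL_CONTAINED if all_contained else STATUS_CONTAINED
        ta_status[idx_step, k] = np.where(
            cont_a, cont_code, np.where(threat_a, STATUS_FLEEING, STATUS_IDLE)
        ).astype(np.int8)
        if spawned_now:
            ta_status[n_base, k] = cont_code if contained[n_base] else STATUS_IDLE

        if all_contained and not pending_spawn:
            dwell += 1
        else:
            dwell = 0
        if dwell >= dwell_ticks_needed:
            success = True
            n_used = k + 1
            break

    duration = n_used * dt
    return TrialRecord(
        design=design,
        params=params,
        seed=int(seed),
        duration=float(duration),
        success=success,
        contained_at_end=int(contained[active].sum()),
        player_traj=player_traj[:, :n_used].copy(),
        ta_traj=ta_traj[:, :n_used].copy(),
        ta_status=ta_status[:, :n_used].copy(),
        ta_spawn_tick=spawn_tick,
    )
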