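"""Scripted stand-ins for the human ground players.

The study's players were people; synthesis needs a reproducible policy.  The
default policy searches until a TA is visible, then drives it home by sitting
just inside the TA's threat radius on the side opposite the containment
center, so the flee response pushes the TA inward.

Visibility is the key manipulation: with clear skies a player senses TAs out
to 150 m and works its own 120-degree sector of the field; under fog sensing
collapses to 10 m and the player has no landmarks with which to maintain a
partition, so it wanders between uniformly random waypoints and chases
whatever it stumbles into.  That difference is what makes fog trials slower
and the players' search polygons more overlapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sim import ConditionDesign, SimParams

__all__ = [
    "PolicyParams",
    "Control",
    "Observation",
    "PlayerState",
    "scripted_policy_step",
    "ScriptedPolicy",
    "IdlePolicy",
    "observe",
]


@dataclass(frozen=True)
class PolicyParams:
    """Tunables of the scripted ground-player controller (meters, m/s, Hz)."""

    sense_clear: float = 150.0
    sense_fog: float = 10.0
    drive_offset: float = 5.0  # standoff behind the TA, inside its threat radius
    lead_time: float = 0.4  # aim ahead of the TA's estimated velocity
    deep_radius: float = 2.5  # push a contained TA this deep before releasing
    waypoint_tolerance: float = 10.0
    retreat_distance: float = 25.0
    slow_radius: float = 3.0
    control_rate: float = 10.0  # re-planning rate; controls held between updates
    target_memory_radius: float = 20.0  # hysteresis for re-acquiring the same TA
    sweep_radii: tuple[float, ...] = (150.0, 110.0, 70.0, 40.0)
    # geometry mirrored from SimParams at reset
    containment_radius: float = 5.0
    threat_radius: float = 10.0
    search_radius: float = 180.0
    player_speed: float = 10.0
    player_speed_slow: float = 5.0

    @property
    def center_avoid_radius(self) -> float:
        # transit keeps clear of contained TAs: containment + threat + margin
        return self.containment_radius + self.threat_radius + 3.0


@dataclass
class Control:
    """Heading (radians) plus a speed from the avatar's {0, 5, 10} m/s gears."""

    heading: float
    speed: float

    @property
    def velocity(self) -> np.ndarray:
        return self.speed * np.array([math.cos(self.heading), math.sin(self.heading)])


@dataclass
class Observation:
    """What one player can currently sense."""

    position: np.ndarray
    ta_positions: np.ndarray  # visible, active, un-contained TAs (k, 2)
    contained_positions: np.ndarray  # visible contained TAs (ring light blue)
    teammate_positions: np.ndarray
    sense_radius: float


@dataclass
class PlayerState:
    """Per-player persistent controller state."""

    index: int
    sector_center: float  # azimuth of the assigned sector (radians)
    sector_halfwidth: float
    fog: bool
    rng: np.random.Generator
    waypoints: list = field(default_factory=list)
    waypoint_idx: int = 0
    last_target: Optional[np.ndarray] = None
    prev_target: Optional[np.ndarray] = None  # for velocity estimation
    retreat_goal: Optional[np.ndarray] = None


def observe(
    own: np.ndarray,
    teammates: np.ndarray,
    ta_pos: np.ndarray,
    active: np.ndarray,
    contained: np.ndarray,
    sense_radius: float,
) -> Observation:
    """Restrict the world state to what a player at ``own`` can sense."""
    def _visible(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.zeros((0, 2))
        cand = ta_pos[mask]
        d = np.hypot(cand[:, 0] - own[0], cand[:, 1] - own[1])
        return cand[d <= sense_radius]

    return Observation(
        position=np.asarray(own, float),
        ta_positions=_visible(active & ~contained),
        contained_positions=_visible(active & contained),
        teammate_positions=np.asarray(teammates, float),
        sense_radius=sense_radius,
    )


def _sweep_waypoints(center: float, halfwidth: float, radii) -> list[np.ndarray]:
    """Boustrophedon sweep of one sector: alternate across-sector passes."""
    pts = []
    offsets = np.linspace(-0.7, 0.7, 3) * halfwidth
    for i, r in enumerate(radii):
        row = offsets if i % 2 == 0 else offsets[::-1]
        for a in row:
            theta = center + a
            pts.append(r * np.array([math.cos(theta), math.sin(theta)]))
    return pts


def _segment_blocked(p: np.ndarray, g: np.ndarray, c: np.ndarray, r: float) -> bool:
    """Does segment p->g pass within r of c (with p itself outside r)?"""
    if np.hypot(*(p - c)) <= r:
        return False
    v = g - p
    L2 = float(v @ v)
    if L2 == 0.0:
        return False
    s = float(np.clip((c - p) @ v / L2, 0.0, 1.0))
    closest = p + s * v
    return bool(np.hypot(*(closest - c)) < r)


def _tangent_heading(p: np.ndarray, g: np.ndarray, c: np.ndarray, r: float) -> float:
    """Heading along the tangent of circle (c, r) closest to the direct course."""
    to_c = c - p
    d = float(np.hypot(*to_c))
    base = math.atan2(to_c[1], to_c[0])
    spread = math.asin(min(1.0, r / max(d, 1e-9)))
    direct = math.atan2(g[1] - p[1], g[0] - p[0])
    cands = (base + spread, base - spread)
    return min(cands, key=lambda h: abs(_wrap(h - direct)))


def _wrap(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def _in_sector(pos: np.ndarray, center: float, halfwidth: float) -> bool:
    return abs(_wrap(math.atan2(pos[1], pos[0]) - center)) <= halfwidth + 0.2


def _select_target(
    state: PlayerState, own: np.ndarray, visible: np.ndarray, params: PolicyParams
) -> np.ndarray:
    p = None
    # hysteresis: keep driving the TA we were driving if it is still around
    if state.last_target is not None and len(visible):
        d_prev = np.hypot(
            visible[:, 0] - state.last_target[0], visible[:, 1] - state.last_target[1]
        )
        j = int(np.argmin(d_prev))
        if d_prev[j] <= params.target_memory_radius:
            p = visible[j]
    if p is None:
        pool = visible
        if not state.fog:
            in_own = np.array(
                [
                    _in_sector(v, state.sector_center, state.sector_halfwidth)
                    for v in visible
                ]
            )
            if in_own.any():
                pool = visible[in_own]
        d = np.hypot(pool[:, 0] - own[0], pool[:, 1] - own[1])
        p = pool[int(np.argmin(d))]
    return np.asarray(p, float)


def _next_waypoint(state: PlayerState, params: PolicyParams) -> np.ndarray:
    if state.fog:
        if not state.waypoints:
            state.waypoints.append(_random_waypoint(state, params))
        return state.waypoints[-1]
    return state.waypoints[state.waypoint_idx % len(state.waypoints)]


def _random_waypoint(state: PlayerState, params: PolicyParams) -> np.ndarray:
    r = params.search_radius * math.sqrt(state.rng.uniform())
    theta = state.rng.uniform(0.0, 2.0 * math.pi)
    return r * np.array([math.cos(theta), math.sin(theta)])


def _advance_waypoint(state: PlayerState, params: PolicyParams) -> None:
    if state.fog:
        state.waypoints = [_random_waypoint(state, params)]
    else:
        state.waypoint_idx += 1


def scripted_policy_step(
    player_state: PlayerState, observation: Observation, params: PolicyParams
) -> Control:
    """One control decision for one ground player.

    Search the assigned waypoints until a TA is visible; then move to the
    point ``drive_offset`` meters directly behind the TA (relative to the
    containment center) so the flee response drives it inward.  Transit
    routes detour around the containment area (to avoid scattering contained
    TAs) and around the targeted TA's threat circle when repositioning, so a
    TA sitting between the player and the center is flanked rather than
    pushed outward.
    """
    p = observation.position
    r_p = float(np.hypot(*p))

    target = None
    visible = observation.ta_positions
    if len(visible):
        target = _select_target(player_state, p, visible, params)
    elif (
        player_state.last_target is not None
        and len(observation.contained_positions)
    ):
        # the TA just crossed the containment rim: keep pushing it deep so a
        # passing teammate cannot immediately knock it back out
        cand = observation.contained_positions
        d_prev = np.hypot(
            cand[:, 0] - player_state.last_target[0],
            cand[:, 1] - player_state.last_target[1],
        )
        j = int(np.argmin(d_prev))
        if (
            d_prev[j] <= params.target_memory_radius
            and np.hypot(*cand[j]) > params.deep_radius
        ):
            target = cand[j]

    if target is not None:
        player_state.prev_target = player_state.last_target
        player_state.last_target = target.copy()
    else:
        player_state.prev_target = None
        player_state.last_target = None

    # after a delivery (or any drift into the guarded zone with nothing to
    # drive), back out radially so contained TAs stay calm
    in_guard = r_p < params.center_avoid_radius
    driving_close = target is not None and np.hypot(*(p - target)) <= params.threat_radius
    if in_guard and not driving_close:
        direction = p / max(r_p, 1e-9) if r_p > 1e-9 else np.array([1.0, 0.0])
        player_state.retreat_goal = direction * params.retreat_distance
    if player_state.retreat_goal is not None:
        goal = player_state.retreat_goal
        if np.hypot(*(p - goal)) < params.slow_radius or r_p >= params.retreat_distance:
            player_state.retreat_goal = None
        else:
            heading = math.atan2(goal[1] - p[1], goal[0] - p[0])
            return Control(heading, params.player_speed)

    if target is not None:
        r_t = float(np.hypot(*target))
        goal = target * (1.0 + params.drive_offset / max(r_t, 1e-9))
        if (
            player_state.prev_target is not None
            and np.hypot(*(player_state.prev_target - target))
            <= params.target_memory_radius
        ):
            # lead the chase with the TA's velocity estimated across updates
            v_est = (target - player_state.prev_target) * params.control_rate
            goal = goal + params.lead_time * v_est
        obstacles = []
        if np.hypot(*(p - target)) > params.threat_radius:
            # repositioning: do not barge through the TA's threat circle
            obstacles.append((target, params.threat_radius * 0.95))
        if float(np.hypot(*goal)) > params.center_avoid_radius:
            obstacles.append((np.zeros(2), params.center_avoid_radius))
    else:
        goal = _next_waypoint(player_state, params)
        if np.hypot(*(p - goal)) <= params.waypoint_tolerance:
            _advance_waypoint(player_state, params)
            goal = _next_waypoint(player_state, params)
        obstacles = [(np.zeros(2), params.center_avoid_radius)]

    heading = math.atan2(goal[1] - p[1], goal[0] - p[0])
    for c, r in obstacles:
        if _segment_blocked(p, goal, c, r):
            heading = _tangent_heading(p, goal, c, r * 1.1)
            break

    dist = float(np.hypot(*(goal - p)))
    if dist < 1e-6:
        return Control(heading, 0.0)
    speed = params.player_speed_slow if dist < params.slow_radius else params.player_speed
    return Control(heading, speed)


class ScriptedPolicy:
    """Default three-player controller used by :func:`herdlab.sim.run_trial`."""

    def __init__(self, params: Optional[PolicyParams] = None):
        self.params = params or PolicyParams()
        self.states: list[PlayerState] = []
        self.sense_radius = self.params.sense_clear

    @property
    def control_rate(self) -> float:
        return self.params.control_rate

    def reset(
        self,
        design: ConditionDesign,
        sim_params: SimParams,
        player_positions: np.ndarray,
        rng: np.random.Generator,
    ) -> None:
        import dataclasses

        self.params = dataclasses.replace(
            self.params,
            containment_radius=sim_params.containment_radius,
            threat_radius=sim_params.threat_radius,
            search_radius=sim_params.ta_spawn_radius,
            player_speed=sim_params.player_speed,
            player_speed_slow=sim_params.player_speed_slow,
        )
        fog = design.visibility == "fog"
        self.sense_radius = self.params.sense_fog if fog else self.params.sense_clear
        # contiguous sectors ordered by spawn azimuth
        azimuth = np.arctan2(player_positions[:, 1], player_positions[:, 0])
        order = np.argsort(azimuth)
        halfwidth = math.pi / 3.0
        self.states = [None] * len(player_positions)  # type: ignore[list-item]
        for rank, i in enumerate(order):
            center = -math.pi + (2 * rank + 1) * halfwidth
            st = PlayerState(
                index=int(i),
                sector_center=center,
                sector_halfwidth=halfwidth,
                fog=fog,
                rng=np.random.default_rng(rng.integers(0, 2**31)),
            )
            if fog:
                st.waypoints = [_random_waypoint(st, self.params)]
            else:
                st.waypoints = _sweep_waypoints(
                    center, halfwidth, self.params.sweep_radii
                )
            self.states[int(i)] = st

    def step(
        self,
        t: float,
        player_pos: np.ndarray,
        ta_pos: np.ndarray,
        active: np.ndarray,
        contained: np.ndarray,
    ) -> np.ndarray:
        vel = np.zeros((len(player_pos), 2))
        for i, st in enumerate(self.states):
            others = np.delete(player_pos, i, axis=0)
            obs = observe(
                player_pos[i], others, ta_pos, active, contained, self.sense_radius
            )
            vel[i] = scripted_policy_step(st, obs, self.params).velocity
        return vel


class IdlePolicy:
    """Players stand still (used to probe the pure TA dynamics and rules)."""

    control_rate = 1.0

    def reset(self, design, sim_params, player_positions, rng) -> None:
        self.n = len(player_positions)

    def step(self, t, player_pos, ta_pos, active, contained) -> np.ndarray:
        return np.zeros((self.n, 2))
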