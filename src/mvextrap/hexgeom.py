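"""Stimulus geometry: hexagonal position grid, straight motion trajectories, trial schedules.

The experiment presents a black disc either flashed at one of the positions of a
centred hexagonal grid (static trials) or moving on a straight line through the
grid along one of its three lattice axes (motion trials).  This module builds
the grid, enumerates every straight trajectory together with the times at which
the moving disc is centred on each grid position ("crossings"), and produces
randomised session schedules with the trial counts of the original design.

Coordinates are degrees of visual angle (dva), origin at fixation, x rightward,
y upward.  Position ids are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: default stimulus speed (dva/s)
DEFAULT_VELOCITY_DVA_S = 10.36
#: time for the moving disc to travel between adjacent grid positions (s)
CROSSING_INTERVAL_S = 0.400
#: grid spacing is not an independent quantity: it is fixed so that at the
#: default speed the disc takes exactly 400 ms between adjacent positions.
DEFAULT_SPACING_DVA = DEFAULT_VELOCITY_DVA_S * CROSSING_INTERVAL_S  # 4.144
#: motion paths start/end this far beyond the grid (dva), plus one grid spacing
DEFAULT_LEAD_DVA = 7.0

_SQRT3 = math.sqrt(3.0)

# axial-coordinate steps of the six grid directions, counterclockwise from +x
_AXIAL_DIRECTIONS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def _axial_to_xy(q: np.ndarray, r: np.ndarray, spacing: float) -> np.ndarray:
    x = spacing * (q + 0.5 * r)
    y = spacing * (_SQRT3 / 2.0) * r
    return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class GridSpec:
    """Hexagonal grid of stimulus positions.

    ``axial`` holds integer axial coordinates (q, r); ``xy`` the Cartesian
    centre of each position in dva.  Positions are ordered ring-major and,
    within a ring, by increasing polar angle (angle-minor), so ids are
    deterministic.
    """

    ring_count: int
    spacing_dva: float
    axial: np.ndarray
    xy: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.xy.shape[0]

    def distances(self) -> np.ndarray:
        """Pairwise centre-to-centre distance matrix in dva."""
        d = self.xy[:, None, :] - self.xy[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])

    def positions(self) -> list[dict]:
        """Positions as records {id, q, r, x, y} (convenience/export form)."""
        return [
            {"id": i, "q": int(q), "r": int(r), "x": float(x), "y": float(y)}
            for i, ((q, r), (x, y)) in enumerate(zip(self.axial, self.xy))
        ]


def build_grid(ring_count: int = 3, spacing_dva: float = DEFAULT_SPACING_DVA) -> GridSpec:
    """Build the centred hexagonal grid of stimulus positions.

    Parameters
    ----------
    ring_count
        Number of rings around the central position.  ``ring_count=3`` gives
        the 37-position layout of the experiment (centred hexagonal number
        ``1 + sum(6k, k=1..rings)``).
    spacing_dva
        Centre-to-centre distance between adjacent positions, in dva.
    """
    if ring_count < 0:
        raise ValueError("ring_count must be >= 0")
    if not spacing_dva > 0:
        raise ValueError("spacing_dva must be positive")
    coords = []
    for q in range(-ring_count, ring_count + 1):
        for r in range(-ring_count, ring_count + 1):
            ring = (abs(q) + abs(r) + abs(q + r)) // 2
            if ring <= ring_count:
                coords.append((q, r, ring))
    axial = np.array([(q, r) for q, r, _ in coords], dtype=int).reshape(-1, 2)
    rings = np.array([k for _, _, k in coords])
    xy = _axial_to_xy(axial[:, 0].astype(float), axial[:, 1].astype(float), spacing_dva)
    ang = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * np.pi)
    ang[rings == 0] = 0.0
    order = np.lexsort((ang, rings))
    return GridSpec(ring_count, spacing_dva, axial[order], xy[order])


@dataclass(frozen=True)
class TrajectorySpec:
    """One straight motion path through the grid.

    ``crossings`` lists ``(position_id, t_ms)`` pairs giving the time, relative
    to motion onset, at which the disc centre coincides with each grid position
    on the line, in traversal order.
    """

    traj_id: int
    direction_index: int  # 1..6, counterclockwise from +x
    offset_index: int  # 1..(2*rings+1), by signed perpendicular distance
    velocity_dva_s: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    crossings: tuple[tuple[int, float], ...]
    duration_ms: float

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)

    @property
    def crossing_ids(self) -> np.ndarray:
        return np.array([c[0] for c in self.crossings], dtype=int)

    @property
    def crossing_times_ms(self) -> np.ndarray:
        return np.array([c[1] for c in self.crossings], dtype=float)

    @property
    def unit_vector(self) -> np.ndarray:
        d = np.asarray(self.end_xy, dtype=float) - np.asarray(self.start_xy, dtype=float)
        return d / np.hypot(*d)

    def position_at(self, t_ms) -> np.ndarray:
        """Disc centre (dva) at time ``t_ms`` after motion onset (no clamping)."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        p = np.asarray(self.start_xy) + self.unit_vector * (self.velocity_dva_s * t[:, None] / 1000.0)
        return p


def crossing_times(traj: TrajectorySpec) -> list[tuple[int, float]]:
    """Return the ordered (position_id, t_ms) crossings of a trajectory."""
    if traj.velocity_dva_s <= 0:
        raise ValueError("velocity must be positive")
    return list(traj.crossings)


def enumerate_trajectories(
    grid: GridSpec,
    velocity_dva_s: float = DEFAULT_VELOCITY_DVA_S,
    lead_dva: float = DEFAULT_LEAD_DVA,
) -> list[TrajectorySpec]:
    """Enumerate every straight trajectory along the grid axes.

    Each of the six directed grid-axis directions is combined with every line
    of positions perpendicular-offset from the centre, giving
    ``6 * (2*rings + 1)`` trajectories (42 for the 3-ring grid).  Paths start
    and end ``lead_dva`` plus one grid spacing beyond the outermost crossed
    position, which at the defaults reproduces motion durations between
    roughly 3350 and 4550 ms.
    """
    if grid.n_positions == 0:
        raise ValueError("grid has no positions")
    if velocity_dva_s <= 0:
        raise ValueError("velocity must be positive")
    if lead_dva < 0:
        raise ValueError("lead_dva must be >= 0")

    spacing = grid.spacing_dva
    margin = lead_dva + spacing
    trajs: list[TrajectorySpec] = []
    tid = 0
    for d_idx, (dq, dr) in enumerate(_AXIAL_DIRECTIONS, start=1):
        u = _axial_to_xy(np.array(float(dq)), np.array(float(dr)), spacing)
        u = u / np.hypot(*u)
        perp = np.array([-u[1], u[0]])
        offs = grid.xy @ perp
        proj = grid.xy @ u
        # group positions into parallel lines by perpendicular offset
        key = np.round(offs / spacing, 6)
        lines = sorted(set(key.tolist()))
        for o_idx, line_key in enumerate(lines, start=1):
            sel = np.flatnonzero(key == line_key)
            sel = sel[np.argsort(proj[sel])]
            first, last = grid.xy[sel[0]], grid.xy[sel[-1]]
            start = first - margin * u
            end = last + margin * u
            length = float(np.hypot(*(end - start)))
            t0 = margin / velocity_dva_s * 1000.0
            gap = spacing / velocity_dva_s * 1000.0
            crossings = tuple(
                (int(p), t0 + i * gap) for i, p in enumerate(sel)
            )
            trajs.append(
                TrajectorySpec(
                    traj_id=tid,
                    direction_index=d_idx,
                    offset_index=o_idx,
                    velocity_dva_s=velocity_dva_s,
                    start_xy=(float(start[0]), float(start[1])),
                    end_xy=(float(end[0]), float(end[1])),
                    crossings=crossings,
                    duration_ms=length / velocity_dva_s * 1000.0,
                )
            )
            tid += 1
    return trajs


@dataclass(frozen=True)
class ScheduleEntry:
    kind: str  # "static" | "motion"
    stim_id: int  # position_id for static, traj_id for motion
    session: int  # 1-based
    block: int  # 1-based within session
    onset_ms: float
    isi_ms: float
    duration_ms: float


@dataclass(frozen=True)
class TrialSchedule:
    entries: tuple[ScheduleEntry, ...]
    seed: int
    n_sessions: int
    static_reps: int
    motion_reps: int

    def counts(self) -> tuple[dict[int, int], dict[int, int]]:
        """Total repetitions per static position and per motion trajectory."""
        stat: dict[int, int] = {}
        mot: dict[int, int] = {}
        for e in self.entries:
            tgt = stat if e.kind == "static" else mot
            tgt[e.stim_id] = tgt.get(e.stim_id, 0) + 1
        return stat, mot


STATIC_DURATION_MS = 250.0
_BLOCKS_PER_SESSION = 7


def build_schedule(
    grid: GridSpec,
    trajectories: list[TrajectorySpec],
    n_sessions: int,
    static_reps: int,
    motion_reps: int,
    isi_range_ms: tuple[float, float] = (350.0, 450.0),
    seed: int = 0,
) -> TrialSchedule:
    """Randomised trial schedule reproducing the session structure.

    Per session every position is flashed ``static_reps`` times and every
    trajectory presented ``motion_reps`` times, in shuffled order, with
    inter-stimulus intervals drawn uniformly from ``isi_range_ms``.  The
    shuffle and ISIs are reproducible under ``seed``.
    """
    if n_sessions < 1 or static_reps < 0 or motion_reps < 0:
        raise ValueError("n_sessions must be >= 1 and repetition counts >= 0")
    if static_reps == 0 and motion_reps == 0:
        raise ValueError("schedule would be empty")
    lo, hi = isi_range_ms
    if not (0 <= lo <= hi):
        raise ValueError("invalid isi range")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C4ED]))
    dur_by_traj = {t.traj_id: t.duration_ms for t in trajectories}
    entries: list[ScheduleEntry] = []
    for sess in range(1, n_sessions + 1):
        items: list[tuple[str, int]] = []
        items += [("static", p) for p in range(grid.n_positions) for _ in range(static_reps)]
        items += [("motion", t.traj_id) for t in trajectories for _ in range(motion_reps)]
        idx = rng.permutation(len(items))
        items = [items[i] for i in idx]
        bounds = np.linspace(0, len(items), _BLOCKS_PER_SESSION + 1).astype(int)
        t = 0.0
        for b in range(_BLOCKS_PER_SESSION):
            for kind, sid in items[bounds[b] : bounds[b + 1]]:
                isi = float(rng.uniform(lo, hi))
                dur = STATIC_DURATION_MS if kind == "static" else dur_by_traj[sid]
                entries.append(ScheduleEntry(kind, sid, sess, b + 1, t, isi, dur))
                t += dur + isi
    return TrialSchedule(tuple(entries), int(seed), n_sessions, static_reps, motion_reps)
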