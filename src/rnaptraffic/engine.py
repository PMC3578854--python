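"""Event-driven stochastic simulation of transcription elongation.

Two simulation modes are provided:

* **SRA** (single-round approach): one polymerase per template, plain
  Gillespie first-reaction dynamics over the sequence-dependent rates.
* **MRA** (multiple-round approach): up to ``n_rnap_max`` polymerases
  initiate from the same promoter at a fixed attempt interval; between
  molecular events every polymerase moves linearly from its current
  position toward the target of its pending reaction, and the engine
  solves for the earliest pairwise contact time.  Collisions are
  resolved according to the states of the trailing (T) and leading (L)
  molecules:

  - T elongating, L elongating or forwardtracking: the pair enters
    *contact*; while in contact the trailer pushes with force F (its
    forward channels are blocked, its backward channels feel −F) and the
    leader's forward channels are accelerated by +F while its backward
    channels are blocked (the trailing RNAP is a roadblock).
  - T elongating, L backtracking backwards: the leader's backward hop is
    cancelled and replaced by a pushed forward hop.
  - both molecules backtracking: a perfectly elastic exchange — the two
    intended step directions and completion times are swapped, positions
    unchanged.

  A translocation step interrupted mid-flight by a collision does not
  commit: both molecules are repositioned to their last discrete
  positions at the contact time.  This keeps the piecewise-linear
  trajectories inside the hard-core exclusion constraint at all times.

Per-polymerase random streams are derived as
``SeedSequence([seed, replicate, rnap_index])`` so that an MRA run with
one polymerase reproduces the SRA trajectory bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import EnergyModel, TECGeometry, Template
from .kinetics import KineticParams, RateTable

__all__ = [
    "RunConfig",
    "Trajectory",
    "CollisionCase",
    "StalledStateError",
    "LivelockError",
    "gillespie_step",
    "collision_time",
    "simulate_sra",
    "simulate_mra",
    "run_replicates",
    "validate_trajectory",
    "validate_exclusion",
]

_TIE_EPS = 1e-12


class StalledStateError(RuntimeError):
    """Raised when a polymerase has no reaction channel with positive rate."""


class LivelockError(RuntimeError):
    """Raised when collision resolutions repeat without the clock advancing."""


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one simulation run."""

    template: Template
    params: KineticParams
    n_rnap_max: int = 1
    initiation_interval: float = 0.5
    n_replicates: int = 1
    seed: int = 0
    t_max: float = 1.0e4
    start_position: int = 1
    backtracking: bool = True
    geometry: TECGeometry = field(default_factory=TECGeometry)

    def __post_init__(self) -> None:
        if self.n_rnap_max < 1:
            raise ValueError("n_rnap_max must be >= 1")
        if self.initiation_interval <= 0:
            raise ValueError("initiation_interval must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.template.length < self.geometry.min_template_length:
            raise ValueError(
                f"template {self.template.name!r} ({self.template.length} nt) shorter "
                f"than minimum TEC span ({self.geometry.min_template_length} nt)"
            )
        if self.start_position >= self.termination_position:
            raise ValueError("template leaves no room between start and termination")

    @property
    def termination_position(self) -> int:
        """RNA 3'-end position at which the leading edge reaches the last base."""
        return self.template.length - self.geometry.d1

    def energy_model(self) -> EnergyModel:
        return EnergyModel(temperature=self.params.temperature, geometry=self.geometry)

    def rate_table(self) -> RateTable:
        return RateTable(self.energy_model().landscape(self.template), self.params)


@dataclass
class Trajectory:
    """Piecewise-linear record of one polymerase's movement.

    ``breakpoints`` are ``(time, active_site_position)`` pairs; the
    position function is the linear interpolation between them.
    ``events`` are ``(time, kind, position)`` with kind in
    {initiation, incorporation, backtrack_step, forward_step, collision,
    termination}.
    """

    rnap_index: int
    t_init: float
    breakpoints: list[tuple[float, float]] = field(default_factory=list)
    events: list[tuple[float, str, int]] = field(default_factory=list)
    terminated: bool = False
    t_term: float = math.nan
    truncated: bool = False

    def position_at(self, t: float) -> float:
        times = [b[0] for b in self.breakpoints]
        pos = [b[1] for b in self.breakpoints]
        return float(np.interp(t, times, pos))

    @property
    def completion_time(self) -> float:
        """Elapsed time from initiation to termination (nan if truncated)."""
        return self.t_term - self.t_init if self.terminated else math.nan

    def incorporation_times(self) -> list[tuple[float, int]]:
        return [(t, p) for t, kind, p in self.events if kind == "incorporation"]


@dataclass(frozen=True)
class CollisionCase:
    """Fig.-4-style classification of a collision.

    ``trailing_mode`` in {TN, TBb, TBf}; ``leading_mode`` in
    {LN, LBb, LBf}: N = normal elongation, Bb/Bf = backtracked moving
    backward/forward.
    """

    trailing_mode: str
    leading_mode: str

    def __post_init__(self) -> None:
        if self.trailing_mode not in ("TN", "TBb", "TBf"):
            raise ValueError(f"bad trailing mode {self.trailing_mode!r}")
        if self.leading_mode not in ("LN", "LBb", "LBf"):
            raise ValueError(f"bad leading mode {self.leading_mode!r}")


def classify_collision(
    trailing_state: str, trailing_dir: int, leading_state: str, leading_dir: int
) -> CollisionCase:
    """Map (mode, pending direction) of the two molecules to a CollisionCase."""
    t = "TN" if trailing_state == "elongating" else ("TBf" if trailing_dir > 0 else "TBb")
    l = "LN" if leading_state == "elongating" else ("LBf" if leading_dir >= 0 else "LBb")
    return CollisionCase(t, l)


# ----------------------------------------------------------------------
# Gillespie first-reaction draws


def _first_reaction(
    channels: list[tuple[str, int, float]], rng: np.random.Generator
) -> tuple[float, str, int] | None:
    """First-reaction step over ``(kind, direction, rate)`` channels.

    Draws one exponential waiting time per positive-rate channel and
    returns ``(dt, kind, direction)`` for the earliest, or None if no
    channel has positive rate.  One rng draw is consumed per positive
    channel, in list order.
    """
    best = None
    for kind, direction, rate in channels:
        if rate <= 0.0:
            continue
        dt = rng.exponential(1.0 / rate)
        if best is None or dt < best[0]:
            best = (dt, kind, direction)
    return best


def gillespie_step(
    rates: dict[str, float], rng: np.random.Generator
) -> tuple[float, str]:
    """Public first-reaction step over a channel → rate mapping.

    Returns ``(dt, channel)``; raises :class:`StalledStateError` when no
    channel has positive rate.
    """
    channels = [(name, 0, rate) for name, rate in rates.items()]
    best = _first_reaction(channels, rng)
    if best is None:
        raise StalledStateError("all reaction channels have zero rate")
    dt, name, _ = best
    return dt, name


# ----------------------------------------------------------------------
# Collision-time solving


def collision_time(
    seg_trailing: tuple[float, float, float],
    seg_leading: tuple[float, float, float],
    exclusion: float,
    t_lo: float,
    t_hi: float,
) -> float | None:
    """Earliest contact time of two linearly moving molecules, or None.

    Each segment is ``(t0, x0, v)``: position ``x(t) = x0 + v (t − t0)``
    of the active site.  Contact means the gap
    ``x_L(t) − x_T(t)`` equals *exclusion* (= d1_T + d2_L).  The search
    window is ``[t_lo, t_hi]``; contact after ``t_hi`` (the next
    scheduled molecular event) is not a collision.
    """
    tT, xT, vT = seg_trailing
    tL, xL, vL = seg_leading
    gap0 = (xL + vL * (t_lo - tL)) - (xT + vT * (t_lo - tT)) - exclusion
    if gap0 < -1e-9:
        raise RuntimeError(
            f"exclusion invariant already violated at t={t_lo}: gap {gap0:.3g}"
        )
    dv = vL - vT  # gap slope
    if dv >= -1e-300:
        return None  # not approaching
    tc = t_lo + max(0.0, gap0) / (-dv)
    if tc > t_hi + _TIE_EPS:
        return None
    return tc


# ----------------------------------------------------------------------
# Engine internals


class _Rnap:
    __slots__ = (
        "idx", "rng", "mode", "pos", "offset",
        "seg_t0", "ev_t", "ev_kind", "ev_dir",
        "contact_front", "contact_back", "front_force", "back_force",
        "traj", "active",
    )

    def __init__(self, idx: int, rng: np.random.Generator, pos: int, t: float) -> None:
        self.idx = idx
        self.rng = rng
        self.mode = "elongating"
        self.pos = pos          # RNA 3' end (frozen while backtracked)
        self.offset = 0         # backtrack offset; active site = pos - offset
        self.seg_t0 = t
        self.ev_t = math.inf
        self.ev_kind: str | None = None
        self.ev_dir = 0
        self.contact_front = False
        self.contact_back = False
        self.front_force = 0.0
        self.back_force = 0.0
        self.active = True
        self.traj = Trajectory(rnap_index=idx, t_init=t)
        self.traj.breakpoints.append((t, float(pos)))
        self.traj.events.append((t, "initiation", pos))

    @property
    def x(self) -> int:
        """Discrete active-site position."""
        return self.pos - self.offset

    def velocity(self) -> float:
        if not math.isfinite(self.ev_t) or self.ev_t <= self.seg_t0:
            return 0.0
        return self.ev_dir / (self.ev_t - self.seg_t0)

    def segment(self) -> tuple[float, float, float]:
        return (self.seg_t0, float(self.x), self.velocity())


def _channels_for(
    r: _Rnap, rt: RateTable, cfg: RunConfig
) -> list[tuple[str, int, float]]:
    """Reaction channels of one polymerase given its contact status."""
    p = rt.params
    plain = not (r.contact_front or r.contact_back)
    force = p.force - (r.front_force if r.contact_front else 0.0) + (
        r.back_force if r.contact_back else 0.0
    )
    ch: list[tuple[str, int, float]] = []
    if r.mode == "elongating":
        e = r.pos
        if not r.contact_front:
            k = float(rt.k_inc[e]) if plain else rt.k_inc_at_force(e, force)
            ch.append(("incorporation", +1, k))
        if cfg.backtracking and not r.contact_back:
            k = float(rt.k_hop_back[e]) if plain else rt.k_hop_back_at_force(e, force)
            ch.append(("backtrack_step", -1, k))
    else:  # backtracked
        x = r.x
        if not r.contact_front:
            k = float(rt.k_hop_fwd[x]) if plain else rt.k_hop_fwd_at_force(x, force)
            ch.append(("forward_step", +1, k))
        if not r.contact_back:
            k = float(rt.k_hop_back[x]) if plain else rt.k_hop_back_at_force(x, force)
            ch.append(("backtrack_step", -1, k))
    return ch


def _redraw(r: _Rnap, rt: RateTable, cfg: RunConfig, t: float, *, strict: bool) -> None:
    r.seg_t0 = t
    # a new linear segment starts here; anchor it in the recorded path
    if r.traj.breakpoints[-1][0] < t:
        r.traj.breakpoints.append((t, float(r.x)))
    best = _first_reaction(_channels_for(r, rt, cfg), r.rng)
    if best is None:
        if strict:
            raise StalledStateError(
                f"RNAP {r.idx} stalled at position {r.x} with no open channel"
            )
        r.ev_t, r.ev_kind, r.ev_dir = math.inf, None, 0
        return
    dt, kind, direction = best
    r.ev_t = t + dt
    r.ev_kind = kind
    r.ev_dir = direction


def _apply_move(r: _Rnap, t: float, cfg: RunConfig) -> None:
    """Commit the pending ±1 move of *r* at time *t*."""
    kind = r.ev_kind
    if kind == "incorporation":
        r.pos += 1
    elif kind == "backtrack_step":
        if r.mode == "elongating":
            r.mode = "backtracked"
            r.offset = 1
        else:
            r.offset += 1
    elif kind == "forward_step":
        r.offset -= 1
        if r.offset == 0:
            r.mode = "elongating"
    else:  # pragma: no cover - guarded by callers
        raise RuntimeError(f"cannot apply move of kind {kind!r}")
    r.traj.breakpoints.append((t, float(r.x)))
    r.traj.events.append((t, kind, r.x))
    if r.mode == "elongating" and r.pos >= cfg.termination_position:
        r.traj.events.append((t, "termination", r.x))
        r.traj.terminated = True
        r.traj.t_term = t
        r.active = False


def _flatten(r: _Rnap, t: float) -> None:
    """Interrupt the pending step: reposition at the discrete position."""
    r.traj.breakpoints.append((t, float(r.x)))
    r.traj.events.append((t, "collision", r.x))
    r.seg_t0 = t
    r.ev_t, r.ev_kind, r.ev_dir = math.inf, None, 0


def _mapped_kind(r: _Rnap, direction: int) -> str | None:
    """Move kind realising *direction* for r's mode, or None if undefined."""
    if direction > 0:
        return "incorporation" if r.mode == "elongating" else "forward_step"
    if direction < 0:
        if r.mode == "elongating" or r.x > 1:
            return "backtrack_step"
        return None  # reflecting boundary
    return None


def _elastic_swap(T: _Rnap, L: _Rnap, rt, cfg, tc: float,
                  dirs: tuple[int, int], times: tuple[float, float]) -> None:
    """Perfectly elastic collision: exchange intended step directions/times."""
    dT, dL = dirs
    tT, tL = times
    for r, d, te in ((T, dL, tL), (L, dT, tT)):
        kind = _mapped_kind(r, d)
        blocked = (d > 0 and r.contact_front) or (d < 0 and r.contact_back)
        if kind is None or blocked or not math.isfinite(te) or te <= tc:
            _redraw(r, rt, cfg, tc, strict=False)
        else:
            r.ev_t, r.ev_kind, r.ev_dir = te, kind, d


def _position_at(r: _Rnap, t: float) -> float:
    t0, x0, v = r.segment()
    return x0 + v * (t - t0)


def _cascade_flatten(
    chain: list[_Rnap], i_leading: int, rt: RateTable, cfg: RunConfig, tc: float
) -> None:
    """Interrupt neighbours whose fractional progress now violates exclusion.

    *chain* is the active molecules leader-first; the colliding pair sits
    at indices ``i_leading``/``i_leading + 1`` and has already been
    repositioned to its discrete coordinates.  Any committed discrete
    configuration satisfies the exclusion constraint, so snapping a
    neighbour back to its discrete position is always safe; the cascade
    stops at the first pair with room to spare.
    """
    D = cfg.geometry.exclusion_distance
    # rearward: trailers that borrowed space from the trailing molecule
    for j in range(i_leading + 2, len(chain)):
        front, rear = chain[j - 1], chain[j]
        if front.x - _position_at(rear, tc) - D < -1e-12:
            _flatten(rear, tc)
            _redraw(rear, rt, cfg, tc, strict=False)
        else:
            break
    # forward: leaders that borrowed space from the leading molecule
    for j in range(i_leading - 1, -1, -1):
        front, rear = chain[j], chain[j + 1]
        if _position_at(front, tc) - rear.x - D < -1e-12:
            _flatten(front, tc)
            _redraw(front, rt, cfg, tc, strict=False)
        else:
            break


def _resolve_collision(
    T: _Rnap,
    L: _Rnap,
    rt: RateTable,
    cfg: RunConfig,
    tc: float,
    leader_of_L: _Rnap | None = None,
) -> CollisionCase:
    """Resolve a contact between trailing *T* and leading *L* at time *tc*."""
    case = classify_collision(T.mode, T.ev_dir, L.mode, L.ev_dir)
    dirs = (T.ev_dir, L.ev_dir)
    times = (T.ev_t, L.ev_t)
    _flatten(T, tc)
    _flatten(L, tc)

    if case.trailing_mode == "TN":
        room_ahead = not L.contact_front and (
            leader_of_L is None
            or leader_of_L.x - (L.x + 1) >= cfg.geometry.exclusion_distance
        )
        if case.leading_mode == "LBb" and room_ahead:
            # pushed forward hop: trailing in forward motion pushes the leader
            L.ev_kind, L.ev_dir = "forward_step", +1
            _apply_move(L, tc, cfg)
            _redraw(T, rt, cfg, tc, strict=False)
            if L.active:
                _redraw(L, rt, cfg, tc, strict=False)
        else:
            # LN / LBf (or stalled leader): contact-scoped force transmission
            fc = rt.params.transmitted_force
            T.contact_front = True
            T.front_force = fc
            L.contact_back = True
            L.back_force = fc
            _redraw(T, rt, cfg, tc, strict=False)
            _redraw(L, rt, cfg, tc, strict=False)
    else:
        # at least the trailing molecule is backtracked (or moving backward):
        # perfectly elastic exchange of intended steps
        _elastic_swap(T, L, rt, cfg, tc, dirs, times)
    return case


def _clear_contact_after_move(
    r: _Rnap, order: list[_Rnap], rt: RateTable, cfg: RunConfig, t: float
) -> None:
    """Open contacts adjacent to *r* after it moved (or terminated)."""
    i = order.index(r)
    trailer = order[i + 1] if i + 1 < len(order) else None
    leader = order[i - 1] if i > 0 else None
    moved_fwd = r.ev_dir > 0 or not r.active
    if r.contact_back and trailer is not None and (moved_fwd or not r.active):
        r.contact_back = False
        trailer.contact_front = False
        _redraw(trailer, rt, cfg, t, strict=False)
    if r.contact_front and leader is not None and r.ev_dir < 0:
        r.contact_front = False
        leader.contact_back = False
        _redraw(leader, rt, cfg, t, strict=False)
    if not r.active and r.contact_front and leader is not None:
        # terminated molecule leaves; its leader loses the rear contact
        r.contact_front = False
        leader.contact_back = False
        _redraw(leader, rt, cfg, t, strict=False)


# ----------------------------------------------------------------------
# Public simulation entry points


def _rnap_rng(seed: int, replicate: int, rnap_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, rnap_index]))


def simulate_sra(config: RunConfig, replicate: int = 0, rate_table: RateTable | None = None) -> Trajectory:
    """Single-round simulation: one polymerase, Gillespie first-reaction."""
    rt = rate_table if rate_table is not None else config.rate_table()
    r = _Rnap(0, _rnap_rng(config.seed, replicate, 0), config.start_position, 0.0)
    t = 0.0
    while r.active:
        _redraw(r, rt, config, t, strict=True)
        if r.ev_t > config.t_max:
            r.traj.truncated = True
            r.traj.breakpoints.append((config.t_max, r.traj.breakpoints[-1][1]))
            break
        t = r.ev_t
        _apply_move(r, t, config)
    return r.traj


def simulate_mra(
    config: RunConfig, replicate: int = 0, rate_table: RateTable | None = None
) -> list[Trajectory]:
    """Multiple-round simulation with collision detection and resolution.

    Returns one trajectory per initiated polymerase, in binding order.
    """
    rt = rate_table if rate_table is not None else config.rate_table()
    N = config.n_rnap_max
    D = config.geometry.exclusion_distance
    start = config.start_position
    order: list[_Rnap] = []  # binding order == spatial order, leader first
    all_rnaps: list[_Rnap] = []
    n_started = 0
    next_init = 0.0
    t = 0.0
    collisions_since_event = 0

    while True:
        active = [r for r in order if r.active]
        t_init = next_init if n_started < N else math.inf
        t_mol = math.inf
        r_mol = None
        for r in active:
            if r.ev_t < t_mol:
                t_mol = r.ev_t
                r_mol = r
        t_coll = math.inf
        pair = None
        for i in range(len(active) - 1):
            L_, T_ = active[i], active[i + 1]
            if T_.contact_front:
                continue
            tc = collision_time(
                T_.segment(), L_.segment(), float(D), t, min(T_.ev_t, L_.ev_t)
            )
            if tc is not None and tc < t_coll:
                t_coll = tc
                pair = (T_, L_)

        t_next = min(t_init, t_mol, t_coll)
        if not math.isfinite(t_next):
            if n_started >= N and not active:
                break
            raise StalledStateError("simulation deadlocked: no finite next event")
        if t_next > config.t_max:
            for r in active:
                r.traj.truncated = True
                r.traj.breakpoints.append(
                    (config.t_max, r.traj.position_at(min(config.t_max, r.ev_t)))
                )
            break

        if pair is not None and t_coll <= t_mol + _TIE_EPS and t_coll <= t_init + _TIE_EPS:
            t = t_coll
            collisions_since_event += 1
            if collisions_since_event > 10_000:
                raise LivelockError(
                    f"more than 10000 collision resolutions without a molecular "
                    f"event near t={t:.6g}"
                )
            T_, L_ = pair
            i = active.index(L_)
            leader_of_L = active[i - 1] if i > 0 else None
            _resolve_collision(T_, L_, rt, config, t, leader_of_L)
            _cascade_flatten(active, i, rt, config, t)
            continue

        if t_init <= t_mol:
            t = t_init
            next_init += config.initiation_interval
            promoter_clear = all(r.x > start + D for r in active)
            if promoter_clear and n_started < N:
                r = _Rnap(n_started, _rnap_rng(config.seed, replicate, n_started), start, t)
                order.append(r)
                all_rnaps.append(r)
                n_started += 1
                _redraw(r, rt, config, t, strict=False)
            collisions_since_event = 0
            continue

        # molecular event
        t = t_mol
        collisions_since_event = 0
        _apply_move(r_mol, t, config)
        _clear_contact_after_move(r_mol, order, rt, config, t)
        if r_mol.active:
            _redraw(r_mol, rt, config, t, strict=False)
        else:
            order.remove(r_mol)

    return [r.traj for r in all_rnaps]


def run_replicates(
    config: RunConfig,
    mode: str = "mra",
    n_replicates: int | None = None,
    rate_table: RateTable | None = None,
):
    """Yield per-replicate results (Trajectory for sra, list for mra)."""
    n = config.n_replicates if n_replicates is None else n_replicates
    rt = rate_table if rate_table is not None else config.rate_table()
    for rep in range(n):
        if mode == "sra":
            yield simulate_sra(config, replicate=rep, rate_table=rt)
        elif mode == "mra":
            yield simulate_mra(config, replicate=rep, rate_table=rt)
        else:
            raise ValueError(f"unknown mode {mode!r}; expected 'sra' or 'mra'")


# ----------------------------------------------------------------------
# Validators (also applied to hand-scripted fixtures)


def validate_trajectory(traj: Trajectory) -> None:
    """Check time monotonicity and ±1 discrete steps; raise on violation."""
    times = [b[0] for b in traj.breakpoints]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError(f"RNAP {traj.rnap_index}: breakpoint times decrease")
    move_kinds = {"incorporation", "backtrack_step", "forward_step"}
    last_pos = None
    for t, kind, pos in traj.events:
        if kind in move_kinds and last_pos is not None:
            if abs(pos - last_pos) != 1:
                raise ValueError(
                    f"RNAP {traj.rnap_index}: {kind} at t={t} moved "
                    f"{pos - last_pos} nt (expected ±1)"
                )
        if kind in move_kinds or kind == "initiation":
            last_pos = pos


def validate_exclusion(trajs: list[Trajectory], geometry: TECGeometry) -> None:
    """Check the hard-core exclusion between all adjacent pairs.

    The gap of the piecewise-linear position functions is itself
    piecewise linear, so it suffices to test it at every breakpoint time
    of either trajectory within the overlap of their lifetimes.
    """
    D = geometry.exclusion_distance
    by_index = sorted(trajs, key=lambda tr: tr.rnap_index)
    arrays = [np.asarray(tr.breakpoints, dtype=float).T for tr in by_index]
    for (lead, trail), (al, at) in zip(
        zip(by_index, by_index[1:]), zip(arrays, arrays[1:])
    ):
        t0 = max(al[0][0], at[0][0])
        t1 = min(al[0][-1], at[0][-1])
        checks = np.concatenate([al[0], at[0]])
        checks = np.sort(checks[(checks >= t0) & (checks <= t1)])
        gap = np.interp(checks, al[0], al[1]) - np.interp(checks, at[0], at[1]) - D
        if len(gap) and gap.min() < -1e-6:
            i = int(np.argmin(gap))
            raise ValueError(
                f"exclusion violated between RNAP {trail.rnap_index} and "
                f"{lead.rnap_index} at t={checks[i]:.6g}: gap {gap.min():.3g}"
            )
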