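"""Gillespie draws, single- and multi-polymerase simulation, collisions."""

import math

import numpy as np
import pytest

from rnaptraffic.energetics import Template
from rnaptraffic.engine import (
    RunConfig,
    StalledStateError,
    _Rnap,
    _channels_for,
    _resolve_collision,
    classify_collision,
    collision_time,
    gillespie_step,
    simulate_mra,
    simulate_sra,
    validate_exclusion,
    validate_trajectory,
)
from rnaptraffic.kinetics import KineticParams


def make_params(**kw):
    base = dict(ntp_conc={b: 25.0 for b in "ACGU"})
    base.update(kw)
    return KineticParams(**base)


# ----------------------------------------------------------------------
# first-reaction draws


def test_gillespie_step_deterministic_given_seed():
    rates = {"a": 1.0, "b": 2.5}
    out1 = [gillespie_step(rates, np.random.default_rng(42)) for _ in range(5)]
    out2 = [gillespie_step(rates, np.random.default_rng(42)) for _ in range(5)]
    assert out1[0] == out2[0]


def test_gillespie_step_all_zero_rates_raises():
    with pytest.raises(StalledStateError):
        gillespie_step({"a": 0.0}, np.random.default_rng(0))


def test_gillespie_single_channel_waiting_time():
    rng = np.random.default_rng(7)
    k = 3.0
    dts = [gillespie_step({"only": k}, rng)[0] for _ in range(10_000)]
    mean = np.mean(dts)
    se = np.std(dts, ddof=1) / math.sqrt(len(dts))
    assert abs(mean - 1.0 / k) < 3 * se


def test_gillespie_two_equal_channels_symmetric():
    rng = np.random.default_rng(8)
    picks = [gillespie_step({"a": 2.0, "b": 2.0}, rng)[1] for _ in range(20_000)]
    frac = np.mean([p == "a" for p in picks])
    assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 20_000)


# ----------------------------------------------------------------------
# collision-time solving


def test_collision_time_linear_example():
    """x_T = 10 + 2t against x_L = 30 + t with zero footprints meets at t = 20."""
    tc = collision_time((0.0, 10.0, 2.0), (0.0, 30.0, 1.0), 0.0, 0.0, math.inf)
    assert tc == pytest.approx(20.0)


def test_collision_time_non_approaching_is_none():
    assert collision_time((0.0, 10.0, 1.0), (0.0, 30.0, 1.0), 0.0, 0.0, math.inf) is None
    assert collision_time((0.0, 10.0, 0.5), (0.0, 30.0, 1.0), 0.0, 0.0, math.inf) is None


def test_collision_time_respects_event_window():
    tc = collision_time((0.0, 10.0, 2.0), (0.0, 30.0, 1.0), 0.0, 0.0, 5.0)
    assert tc is None


def test_collision_time_overlap_is_internal_error():
    with pytest.raises(RuntimeError, match="exclusion"):
        collision_time((0.0, 10.0, 1.0), (0.0, 11.0, 1.0), 5.0, 0.0, math.inf)


def test_collision_solver_matches_time_stepping_oracle():
    """Analytic contact time vs dt = 1e-4 brute-force scan, 1000 random pairs."""
    rng = np.random.default_rng(99)
    checked = 0
    for _ in range(1000):
        xT = rng.uniform(0, 50)
        gap = rng.uniform(0.0, 30.0)
        vT = rng.uniform(-5, 5)
        vL = rng.uniform(-5, 5)
        D = rng.uniform(0, 10)
        xL = xT + D + gap
        t_hi = rng.uniform(0.5, 10.0)
        tc = collision_time((0.0, xT, vT), (0.0, xL, vL), D, 0.0, t_hi)
        ts = np.arange(0.0, t_hi, 1e-4)
        gaps = (xL + vL * ts) - (xT + vT * ts) - D
        hit = np.nonzero(gaps <= 0.0)[0]
        oracle = ts[hit[0]] if len(hit) else None
        if tc is None:
            assert oracle is None or oracle == pytest.approx(t_hi, abs=1e-3)
        else:
            assert oracle is not None
            assert abs(tc - oracle) < 1e-3
            checked += 1
    assert checked > 100  # the random mix must actually exercise contacts


# ----------------------------------------------------------------------
# single-round simulation


def test_sra_deterministic_given_seed(pause_template, params, pause_rate_table):
    cfg = RunConfig(template=pause_template, params=params, seed=5)
    t1 = simulate_sra(cfg, rate_table=pause_rate_table)
    t2 = simulate_sra(cfg, rate_table=pause_rate_table)
    assert t1.events == t2.events
    assert t1.breakpoints == t2.breakpoints


def test_sra_homopolymer_completion_time_closed_form(params):
    """Without backtracking the total time is a sum of exponentials whose
    mean and variance follow from the per-position rates."""
    tpl = Template("homo", "G" * 60)
    cfg = RunConfig(template=tpl, params=params, backtracking=False, seed=0)
    rt = cfg.rate_table()
    ks = rt.k_inc[cfg.start_position : cfg.termination_position]
    expected = float(np.sum(1.0 / ks))
    var = float(np.sum(1.0 / ks**2))
    n = 100
    times = [
        simulate_sra(cfg, replicate=r, rate_table=rt).completion_time for r in range(n)
    ]
    se = math.sqrt(var / n)
    assert abs(np.mean(times) - expected) < 3 * se


def test_tenfold_ntp_never_slows_transcription(pause_template):
    """Median completion time at 10x [NTP] <= at 1x (paired seeds)."""
    lo = RunConfig(template=pause_template, params=make_params(), seed=2)
    hi = RunConfig(
        template=pause_template,
        params=make_params(ntp_conc={b: 250.0 for b in "ACGU"}),
        seed=2,
    )
    rt_lo, rt_hi = lo.rate_table(), hi.rate_table()
    t_lo = [simulate_sra(lo, replicate=r, rate_table=rt_lo).completion_time for r in range(100)]
    t_hi = [simulate_sra(hi, replicate=r, rate_table=rt_hi).completion_time for r in range(100)]
    assert np.median(t_hi) <= np.median(t_lo)


def test_sra_trajectory_valid(pause_template, params, pause_rate_table):
    cfg = RunConfig(template=pause_template, params=params, seed=9)
    traj = simulate_sra(cfg, rate_table=pause_rate_table)
    validate_trajectory(traj)
    assert traj.terminated
    assert traj.events[-1][0] == pytest.approx(traj.t_term)


# ----------------------------------------------------------------------
# multi-round simulation


def test_mra_single_polymerase_bit_identical_to_sra(
    pause_template, params, pause_rate_table
):
    cfg = RunConfig(template=pause_template, params=params, n_rnap_max=1, seed=31)
    sra = simulate_sra(cfg, rate_table=pause_rate_table)
    (mra,) = simulate_mra(cfg, rate_table=pause_rate_table)
    assert sra.events == mra.events
    assert sra.breakpoints == mra.breakpoints


def test_mra_exclusion_and_order(study_mra_ensemble, study_template):
    geometry = RunConfig(
        template=study_template, params=make_params()
    ).geometry
    for rep in study_mra_ensemble[:25]:
        validate_exclusion(rep, geometry)
        for traj in rep:
            validate_trajectory(traj)
        # binding order equals spatial order at every shared breakpoint time
        for lead, trail in zip(rep, rep[1:]):
            t = max(lead.t_init, trail.t_init)
            assert lead.position_at(t) >= trail.position_at(t)


def test_mra_initiation_interval_and_promoter_clearance(
    study_template, params, study_rate_table
):
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=10, seed=17)
    trajs = simulate_mra(cfg, rate_table=study_rate_table)
    t_inits = [tr.t_init for tr in trajs]
    assert t_inits == sorted(t_inits)
    D = cfg.geometry.exclusion_distance
    for prev, nxt in zip(trajs, trajs[1:]):
        # initiation times fall on the attempt grid
        assert (nxt.t_init / cfg.initiation_interval) == pytest.approx(
            round(nxt.t_init / cfg.initiation_interval), abs=1e-9
        )
        # at the moment of initiation the predecessor has cleared the promoter
        assert prev.position_at(nxt.t_init) > cfg.start_position + D


def test_mra_seed_reproducibility(study_template, params, study_rate_table):
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=4, seed=23)
    a = simulate_mra(cfg, rate_table=study_rate_table)
    b = simulate_mra(cfg, rate_table=study_rate_table)
    for ta, tb in zip(a, b):
        assert ta.events == tb.events


# ----------------------------------------------------------------------
# collision resolution unit behaviour


def _contact_pair(rt, cfg, t=0.0, x_t=100, gap=0):
    """Two polymerases with L exactly `gap` nt beyond contact with T."""
    D = cfg.geometry.exclusion_distance
    rng = np.random.default_rng
    L = _Rnap(0, rng(1), x_t + D + gap, t)
    T = _Rnap(1, rng(2), x_t, t)
    return T, L


def test_resolve_normal_normal_transmits_force(study_rate_table, study_template, params):
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=2, seed=0)
    rt = study_rate_table
    T, L = _contact_pair(rt, cfg)
    for r, dirn in ((T, +1), (L, +1)):
        r.ev_t, r.ev_kind, r.ev_dir = 1.0, "incorporation", dirn
    case = _resolve_collision(T, L, rt, cfg, 0.5)
    assert (case.trailing_mode, case.leading_mode) == ("TN", "LN")
    assert T.contact_front and L.contact_back
    # leader's forward rate is boosted, trailer can only go backward
    ch_L = dict((k, v) for k, _, v in _channels_for(L, rt, cfg))
    ch_T = dict((k, v) for k, _, v in _channels_for(T, rt, cfg))
    e = L.pos
    assert ch_L["incorporation"] > float(rt.k_inc[e])
    # the trailer's forward channel is blocked outright (rate 0 < before),
    # and the opposing load it feels makes its backward hops easier
    assert "incorporation" not in ch_T
    assert ch_T["backtrack_step"] > float(rt.k_hop_back[T.pos])


def test_resolve_push_moves_backtracking_leader_forward(
    study_rate_table, study_template, params
):
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=2, seed=0)
    rt = study_rate_table
    T, L = _contact_pair(rt, cfg, gap=1)
    T.ev_t, T.ev_kind, T.ev_dir = 1.0, "incorporation", +1
    L.mode, L.offset = "backtracked", 3
    x_before = L.x
    L.ev_t, L.ev_kind, L.ev_dir = 1.0, "backtrack_step", -1
    case = _resolve_collision(T, L, rt, cfg, 0.5)
    assert case.leading_mode == "LBb"
    assert L.x == x_before + 1          # pushed one position forward
    assert L.offset == 2                # by a forwardtracking hop
    assert not T.contact_front


def test_resolve_elastic_exchanges_step_intentions(
    study_rate_table, study_template, params
):
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=2, seed=0)
    rt = study_rate_table
    T, L = _contact_pair(rt, cfg, gap=1)
    T.mode, T.offset = "backtracked", 2
    L.mode, L.offset = "backtracked", 2
    T.ev_t, T.ev_kind, T.ev_dir = 2.0, "forward_step", +1
    L.ev_t, L.ev_kind, L.ev_dir = 3.0, "backtrack_step", -1
    dirs_before = T.ev_dir + L.ev_dir
    case = _resolve_collision(T, L, rt, cfg, 1.0)
    assert case.trailing_mode == "TBf" and case.leading_mode == "LBb"
    # intended displacements conserved, directions swapped
    assert T.ev_dir + L.ev_dir == dirs_before
    assert (T.ev_dir, L.ev_dir) == (-1, +1)
    assert (T.ev_t, L.ev_t) == (3.0, 2.0)


def test_classify_collision_covers_six_cases():
    assert classify_collision("elongating", 1, "elongating", 1).leading_mode == "LN"
    assert classify_collision("elongating", 1, "backtracked", -1).leading_mode == "LBb"
    assert classify_collision("elongating", 1, "backtracked", 1).leading_mode == "LBf"
    assert classify_collision("backtracked", 1, "backtracked", -1).trailing_mode == "TBf"
    assert classify_collision("backtracked", -1, "backtracked", -1).trailing_mode == "TBb"
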