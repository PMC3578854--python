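"""Synthetic templates and scripted trajectories with known structure.

Real pause-mapping studies use specific phage templates that are not
bundled here; this module generates random templates with *planted*
motifs so that every stage of the simulator and analysis layer can be
exercised against known ground truth:

* ``strong_pause`` — a window whose pre-translocated register is
  strongly stabilised relative to post, which inflates the
  translocation-equilibrium factor and slows incorporation there;
* ``backtrack_trap`` — a window upstream of which the backtracked
  landscape runs downhill, so excursions launched there run deep.

Motifs are planted by greedy local search against the *actual*
energetics model (not hard-coded base runs), so fixtures stay valid if
the nearest-neighbor parameter sets are swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import EnergyModel, Template
from .engine import Trajectory

__all__ = ["MotifSpec", "MotifPlantingError", "make_template", "make_trajectory_fixture"]

_BASES = "ACGT"

# per-hop descent (kcal/mol) beyond which a trap step earns no extra credit;
# chosen near the default-force tilt F·Δ so trap interiors are close to a
# neutral random walk (deep excursions without effectively irreversible wells)
_STEP_CAP = 1.3


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: kind in {strong_pause, backtrack_trap, neutral}."""

    kind: str
    position: int
    length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("strong_pause", "backtrack_trap", "neutral"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.position < 1 or self.length < 1:
            raise ValueError("motif position/length must be positive")


class MotifPlantingError(RuntimeError):
    def __init__(self, spec: MotifSpec, achieved: float, target: float) -> None:
        super().__init__(
            f"could not plant {spec.kind} at {spec.position}: achieved energy gap "
            f"{achieved:.2f} kcal/mol < target {target:.2f}"
        )
        self.achieved = achieved
        self.target = target


def _g_pre(model: EnergyModel, template: Template, e: int) -> float:
    from .energetics import TECState

    return model.tec_free_energy(TECState(m=e, n=e, register="pre"), template)


def _g_post(model: EnergyModel, template: Template, e: int) -> float:
    from .energetics import TECState

    return model.tec_free_energy(TECState(m=e + 1, n=e, register="post"), template)


def _bias_score(model: EnergyModel, template: Template, pos: int) -> float:
    """ΔG°(post) − ΔG°(pre) at the RNA 3' end *pos* (large = slow incorporation)."""
    return _g_post(model, template, pos) - _g_pre(model, template, pos)


def _pause_score(model: EnergyModel, template: Template, pos: int) -> float:
    """Pause strength at *pos*: translocation bias plus backtrack stabilisation.

    In this model long pauses are backtracking-mediated: a strong pause
    site couples a pre-translocated register that is stable against
    forward translocation with an upstream backtracked landscape running
    downhill, so excursions launched at the site are deep and slow to
    return.  Both ingredients are summed (kcal/mol).
    """
    return _bias_score(model, template, pos) + _trap_score(model, template, pos, 8)


def _trap_score(model: EnergyModel, template: Template, pos: int, depth: int) -> float:
    """Guaranteed monotone descent of the backtracked landscape behind *pos*.

    Sums the per-step energy drops over the *depth* upstream hops, each
    clamped at ``_STEP_CAP`` kcal/mol, so the search is rewarded for a
    gradual downhill staircase rather than a single cliff — excursions
    launched at *pos* then wander deep instead of sticking at one edge.
    """
    lo = max(model.geometry.hybrid_len_pre, pos - depth)
    gs = [_g_pre(model, template, p) for p in range(lo, pos + 1)]
    steps = [g1 - g0 for g0, g1 in zip(gs, gs[1:])]  # drop per backward hop
    return sum(min(s, _STEP_CAP) for s in steps)


def _local_search(
    seq: list[str],
    model: EnergyModel,
    score: callable,
    window: range,
    target: float,
    passes: int = 3,
) -> float:
    """Greedy coordinate ascent of *score* over the bases in *window*."""
    best = score(Template("work", "".join(seq)))
    for _ in range(passes):
        improved = False
        for i in window:
            if best >= target:  # planted exactly as strong as requested
                return best
            current = seq[i]
            for base in _BASES:
                if base == current:
                    continue
                seq[i] = base
                s = score(Template("work", "".join(seq)))
                if s > best + 1e-12:
                    best = s
                    current = base
                    improved = True
                else:
                    seq[i] = current
        if not improved:
            break
    return best


#: Default energy separation (kcal/mol) the local search must achieve.
DEFAULT_TARGET_GAP = {"strong_pause": 6.0, "backtrack_trap": 4.5}


def make_template(
    length: int,
    motifs: list[MotifSpec] | None = None,
    seed: int = 0,
    model: EnergyModel | None = None,
    target_gap: float | None = None,
    name: str | None = None,
) -> Template:
    """Random background sequence with planted motifs; deterministic in *seed*.

    *target_gap* (kcal/mol) is the energy separation the local search
    must achieve for each motif (per-kind defaults when omitted); an
    infeasible motif raises :class:`MotifPlantingError` carrying the
    achieved gap.
    """
    motifs = motifs or []
    model = model if model is not None else EnergyModel()
    geom = model.geometry
    rng = np.random.default_rng(np.random.SeedSequence([seed, length]))
    seq = list(rng.choice(list(_BASES), size=length))

    spans = []
    for spec in motifs:
        if spec.position + spec.length - 1 > length:
            raise ValueError(f"motif {spec} extends past template end")
        # bases influencing the TEC energy at the motif: one hybrid span each side
        margin = geom.hybrid_len_pre + geom.bubble_len
        span = (max(0, spec.position - margin), min(length, spec.position + spec.length + 4))
        for other in spans:
            if span[0] < other[1] and other[0] < span[1]:
                raise ValueError("motif influence regions overlap")
        spans.append(span)

    for spec, span in zip(motifs, spans):
        if spec.kind == "neutral":
            continue
        window = range(*span)
        if spec.kind == "strong_pause":
            score = lambda t, p=spec.position: _pause_score(model, t, p)
        else:
            score = lambda t, p=spec.position, d=spec.length: _trap_score(model, t, p, max(d, 8))
        target = target_gap if target_gap is not None else DEFAULT_TARGET_GAP[spec.kind]
        achieved = _local_search(seq, model, score, window, target)
        if achieved < target:
            raise MotifPlantingError(spec, achieved, target)

    tname = name if name is not None else f"synthetic-L{length}-s{seed}"
    return Template(tname, "".join(seq))


def make_trajectory_fixture(
    steps: list[tuple[float, str, int]],
    rnap_index: int = 0,
    t_init: float = 0.0,
    terminated: bool = False,
) -> Trajectory:
    """Hand-scripted trajectory for analysis-layer unit tests.

    *steps* is a list of ``(time, kind, position)`` events (kinds as in
    :class:`~rnaptraffic.engine.Trajectory`), excluding the implicit
    initiation event, which is added at ``t_init`` using the first
    step's starting position.
    """
    if not steps:
        raise ValueError("scripted trajectory needs at least one step")
    first_pos = steps[0][2]
    start = first_pos - (1 if steps[0][1] == "incorporation" else -1) \
        if steps[0][1] in ("incorporation", "backtrack_step") else first_pos
    traj = Trajectory(rnap_index=rnap_index, t_init=t_init)
    traj.events.append((t_init, "initiation", start))
    traj.breakpoints.append((t_init, float(start)))
    for t, kind, pos in steps:
        traj.events.append((t, kind, pos))
        if kind in ("incorporation", "backtrack_step", "forward_step", "collision"):
            traj.breakpoints.append((t, float(pos)))
        if kind == "termination":
            traj.terminated = True
            traj.t_term = t
    if terminated and not traj.terminated:
        t_last, _, p_last = steps[-1]
        traj.events.append((t_last, "termination", p_last))
        traj.terminated = True
        traj.t_term = t_last
    return traj
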