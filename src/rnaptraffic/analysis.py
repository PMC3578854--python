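"""Trajectory ensemble statistics: pauses, gels, efficiency, prediction quality.

All quantile computations in this module go through one shared helper
(:func:`third_quartile`, linear-interpolation quantiles) so that dwell
profiles, backtracking distances, completion-time boxes and the derived
pause thresholds agree on the same definition.

Pause criterion.  For each template position ``i`` the dwell time is the
interval between the incorporation that brings the RNA 3' end to ``i``
and the incorporation that advances it past ``i``; backtracking
excursions that start at ``i`` are charged to ``i``.  With ``τ_TQ(i)``
the third quartile of the dwell-time distribution across replicates and
``τ_min`` the smallest ``τ_TQ`` on the template, position ``i`` is
called a pause when

    τ_TQ(i) > τ_min / α ,

so a larger ``α`` implies a larger absolute dwell threshold.  Calls
within 3 bp are merged into clusters; a predicted cluster matches an
experimental cluster when any members lie within 3 bp, and the
prediction quality is summarised as ``Q = TP / (TP + FP + FN)``
(configurable form), with bootstrap-over-sequences error bars.

Transcription efficiency.  With ``median_j`` the median time for the
``j``-th initiated polymerase to complete the template under a maximum
of ``N`` molecules, the average transcription time is
``T_avg(N) = (1/N) Σ_{j≤N} median_j`` and the relative efficiency
``ε(N) = T_avg(1) / T_avg(N)``; ``ε > 1`` means that collisions speed
transcription up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .engine import Trajectory

__all__ = [
    "DwellProfile",
    "PauseReport",
    "EfficiencyCurve",
    "QualityResult",
    "GelImage",
    "third_quartile",
    "dwell_profile",
    "pause_threshold",
    "call_pauses",
    "cluster_positions",
    "tune_alpha",
    "backtrack_distances",
    "completion_times",
    "efficiency_curve",
    "simulated_gel",
    "match_clusters",
    "quality_metric",
    "bootstrap_quality",
]

CLUSTER_BP = 3  # pauses within 3 bp form a single cluster


def third_quartile(samples: Sequence[float]) -> float:
    """Third quartile with linear interpolation (shared by all analyses)."""
    return float(np.quantile(np.asarray(samples, dtype=float), 0.75, method="linear"))


# ----------------------------------------------------------------------
# Dwell profiles and pause calling


@dataclass
class DwellProfile:
    """Per-position dwell-time samples and their third-quartile statistic."""

    samples: dict[int, list[float]]
    tq: dict[int, float]
    tau_min: float
    n_traces: int
    missing: list[int] = field(default_factory=list)

    def positions(self) -> list[int]:
        return sorted(self.tq)


def dwell_profile(trajs: Iterable[Trajectory]) -> DwellProfile:
    """Dwell-time distribution per template position over an ensemble.

    The dwell at position ``i`` runs from the incorporation completing
    ``i`` (or initiation, for the start position) to the incorporation
    completing ``i+1``; time spent in backtracking excursions launched
    from ``i`` therefore counts toward ``i``.
    """
    samples: dict[int, list[float]] = {}
    n_traces = 0
    max_count = 0
    for traj in trajs:
        n_traces += 1
        arrivals = [(traj.t_init, traj.events[0][2])]
        arrivals += traj.incorporation_times()
        for (t0, p0), (t1, _p1) in zip(arrivals, arrivals[1:]):
            samples.setdefault(p0, []).append(t1 - t0)
    if n_traces == 0:
        raise ValueError("dwell_profile needs at least one trajectory")
    max_count = max((len(v) for v in samples.values()), default=0)
    tq = {pos: third_quartile(v) for pos, v in samples.items()}
    # positions not visited by every trace are flagged and excluded from tau_min
    full = [pos for pos, v in samples.items() if len(v) == max_count]
    missing = sorted(set(samples) - set(full))
    tau_min = min(tq[pos] for pos in full)
    return DwellProfile(samples=samples, tq=tq, tau_min=tau_min,
                        n_traces=n_traces, missing=missing)


def pause_threshold(tau_min: float, alpha: float) -> float:
    """Absolute dwell threshold implied by the pause criterion: τ_min/α.

    Isolated in one function so the comparison form of the criterion can
    be corrected in a single place.
    """
    if alpha <= 0:
        raise ValueError("pause-criterion parameter alpha must be positive")
    return tau_min / alpha


@dataclass
class PauseReport:
    positions: list[int]
    tq: dict[int, float]
    alpha: float
    threshold: float
    clusters: list[list[int]]


def cluster_positions(positions: Sequence[int], max_gap: int = CLUSTER_BP) -> list[list[int]]:
    """Maximal groups of positions with inter-member distance <= max_gap."""
    out: list[list[int]] = []
    for pos in sorted(positions):
        if out and pos - out[-1][-1] <= max_gap:
            out[-1].append(pos)
        else:
            out.append([pos])
    return out


def call_pauses(profile: DwellProfile, alpha: float) -> PauseReport:
    """Call pause sites on a dwell profile at criterion parameter *alpha*."""
    thr = pause_threshold(profile.tau_min, alpha)
    calls = sorted(pos for pos, tq in profile.tq.items() if tq > thr)
    return PauseReport(
        positions=calls,
        tq={p: profile.tq[p] for p in calls},
        alpha=alpha,
        threshold=thr,
        clusters=cluster_positions(calls),
    )


# ----------------------------------------------------------------------
# Prediction quality


def match_clusters(
    predicted: list[list[int]], truth: list[list[int]], tol: int = CLUSTER_BP
) -> tuple[int, int, int]:
    """(TP, FP, FN) cluster counts under one-to-one matching.

    A truth cluster is detected when any predicted member lies within
    *tol* bp of any of its members; matching is one-to-one (greedy, in
    genomic order), so a single sprawling predicted cluster cannot claim
    several truth clusters.  Unmatched predicted clusters are false
    positives, unmatched truth clusters false negatives.
    """

    def near(c1: list[int], c2: list[int]) -> bool:
        return any(abs(a - b) <= tol for a in c1 for b in c2)

    used: set[int] = set()
    tp = 0
    for tc in sorted(truth):
        for i, pc in enumerate(predicted):
            if i not in used and near(pc, tc):
                used.add(i)
                tp += 1
                break
    fn = len(truth) - tp
    fp = len(predicted) - len(used)
    return tp, fp, fn


@dataclass
class QualityResult:
    tp: int
    fp: int
    fn: int
    q: float
    bootstrap_sd: float = math.nan


def _default_q(tp: int, fp: int, fn: int) -> float:
    denom = tp + fp + fn
    return tp / denom if denom else math.nan


def quality_metric(
    predicted: list[list[int]],
    truth: list[list[int]],
    q_form: Callable[[int, int, int], float] = _default_q,
) -> QualityResult:
    """Cluster-level pause-prediction quality for one sequence."""
    if not truth:
        raise ValueError("quality metric undefined for an empty truth set")
    tp, fp, fn = match_clusters(predicted, truth)
    return QualityResult(tp=tp, fp=fp, fn=fn, q=q_form(tp, fp, fn))


def bootstrap_quality(
    per_sequence: Mapping[str, tuple[list[list[int]], list[list[int]]]],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    q_form: Callable[[int, int, int], float] = _default_q,
) -> QualityResult:
    """Pooled quality over sequences with a bootstrap-over-sequences sd.

    *per_sequence* maps sequence name to (predicted clusters, truth
    clusters).  Counts are pooled across sequences before computing Q;
    the bootstrap resamples whole sequences with replacement.
    """
    names = sorted(per_sequence)
    if not names:
        raise ValueError("no sequences supplied")
    counts = {name: match_clusters(*per_sequence[name]) for name in names}
    tp, fp, fn = (sum(c[i] for c in counts.values()) for i in range(3))
    q = q_form(tp, fp, fn)
    rng = rng if rng is not None else np.random.default_rng()
    qs = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(names), size=len(names))
        t = sum(counts[names[i]][0] for i in pick)
        f = sum(counts[names[i]][1] for i in pick)
        n = sum(counts[names[i]][2] for i in pick)
        qi = q_form(t, f, n)
        if not math.isnan(qi):
            qs.append(qi)
    sd = float(np.std(qs, ddof=1)) if len(qs) > 1 else math.nan
    return QualityResult(tp=tp, fp=fp, fn=fn, q=q, bootstrap_sd=sd)


def tune_alpha(
    profiles: Mapping[str, DwellProfile],
    truth: Mapping[str, Sequence[int]],
    grid: Sequence[float] | None = None,
) -> float:
    """Grid-search α minimising (FP + FN)/TP pooled over sequences.

    Ties resolve to the smallest α.  Raises if TP = 0 at every grid
    point (the objective is then undefined everywhere).
    """
    if grid is None:
        grid = np.round(np.arange(0.01, 1.001, 0.01), 4)
    truth_clusters = {name: cluster_positions(list(pos)) for name, pos in truth.items()}
    best_alpha = None
    best_obj = math.inf
    for alpha in sorted(grid):
        tp = fp = fn = 0
        for name, profile in profiles.items():
            report = call_pauses(profile, float(alpha))
            t, f, n = match_clusters(report.clusters, truth_clusters[name])
            tp += t
            fp += f
            fn += n
        if tp == 0:
            continue
        obj = (fp + fn) / tp
        if obj < best_obj:
            best_obj = obj
            best_alpha = float(alpha)
    if best_alpha is None:
        raise ValueError("objective undefined: TP = 0 at every grid point")
    return best_alpha


# ----------------------------------------------------------------------
# Backtracking, completion times, efficiency


def backtrack_distances(trajs: Iterable[Trajectory]) -> list[int]:
    """Maximum upstream distance (nt) of each backtracking excursion."""
    out: list[int] = []
    for traj in trajs:
        depth = 0
        max_depth = 0
        in_excursion = False
        for _t, kind, _pos in traj.events:
            if kind == "backtrack_step":
                depth += 1
                max_depth = max(max_depth, depth)
                in_excursion = True
            elif kind == "forward_step":
                depth -= 1
                if depth == 0 and in_excursion:
                    out.append(max_depth)
                    max_depth = 0
                    in_excursion = False
        if in_excursion:  # trajectory ended mid-excursion (truncation)
            out.append(max_depth)
    return out


def completion_times(replicates: Iterable[list[Trajectory]]) -> dict[int, list[float]]:
    """Per-binding-order completion-time samples over MRA replicates."""
    out: dict[int, list[float]] = {}
    for trajs in replicates:
        for traj in trajs:
            if traj.terminated:
                out.setdefault(traj.rnap_index, []).append(traj.completion_time)
    return out


@dataclass
class EfficiencyCurve:
    n_values: list[int]
    t_avg: dict[int, float]
    epsilon: dict[int, float]


def efficiency_curve(medians_by_n: Mapping[int, Sequence[float]]) -> EfficiencyCurve:
    """Average transcription time and relative efficiency per RNAP cap N.

    *medians_by_n* maps the maximum polymerase count N to the per-index
    median completion times ``[median_1, …, median_N]`` from runs capped
    at N.  ``T_avg(N)`` is their mean; ``ε(N) = T_avg(1)/T_avg(N)``.
    """
    if 1 not in medians_by_n:
        raise ValueError("need N = 1 medians to normalise the efficiency")
    t_avg: dict[int, float] = {}
    for n_cap, medians in medians_by_n.items():
        medians = list(medians)
        if len(medians) != n_cap:
            raise ValueError(
                f"N = {n_cap}: expected {n_cap} per-index medians, got {len(medians)}"
            )
        if any(math.isnan(m) for m in medians):
            raise ValueError(f"N = {n_cap}: missing per-index median")
        t_avg[n_cap] = float(np.mean(medians))
    eps = {n_cap: t_avg[1] / t for n_cap, t in t_avg.items()}
    return EfficiencyCurve(
        n_values=sorted(t_avg), t_avg=t_avg, epsilon=eps
    )


# ----------------------------------------------------------------------
# Simulated gels


@dataclass
class GelImage:
    """Counts of transcripts per (length, timepoint); lanes are timepoints."""

    lengths: np.ndarray       # row labels, nt
    timepoints: list[float]   # lane labels, s
    counts: np.ndarray        # shape (len(lengths), len(timepoints))

    def lane(self, j: int) -> np.ndarray:
        return self.counts[:, j]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.counts,
            index=self.lengths,
            columns=[f"t={t:g}s" for t in self.timepoints],
        )
        df.index.name = "transcript_length"
        df.to_csv(path, sep="\t")


def simulated_gel(
    trajs: Iterable[Trajectory], timepoints: Sequence[float], start_position: int | None = None
) -> GelImage:
    """Transcript-length histogram per timepoint (a simulated gel).

    Each trajectory contributes one transcript per lane whose length is
    the number of incorporated nucleotides at that time (full length
    after termination).  Band intensity is the transcript count.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories supplied")
    timepoints = sorted(timepoints)
    origin = start_position if start_position is not None else min(
        tr.events[0][2] for tr in trajs
    )
    rows: dict[int, np.ndarray] = {}
    for traj in trajs:
        final_pos = traj.events[-1][2]
        incs = traj.incorporation_times()
        for j, t in enumerate(timepoints):
            if t < traj.t_init:
                continue
            if traj.terminated and t >= traj.t_term:
                length = final_pos - origin
            else:
                # transcript length never shrinks during backtracking:
                # it is the count of incorporations up to time t
                done = [p for ti, p in incs if ti <= t]
                length = (done[-1] - origin) if done else 0
            if length not in rows:
                rows[length] = np.zeros(len(timepoints), dtype=int)
            rows[length][j] += 1
    lengths = np.array(sorted(rows))
    counts = np.vstack([rows[l] for l in lengths]) if len(lengths) else np.zeros((0, len(timepoints)), int)
    return GelImage(lengths=lengths, timepoints=list(timepoints), counts=counts)
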