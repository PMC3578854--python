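# rnaptraffic

Stochastic, sequence-dependent simulation of transcription elongation by
one or many RNA polymerases (RNAPs) on the same DNA template — including
the traffic: collisions between polymerases are detected and resolved,
and the analysis layer quantifies what the resulting cooperation does to
pauses, backtracking and overall transcription speed.

The package is aimed at people studying transcription kinetics at the
single-molecule level: it predicts where an RNAP pauses on a given
sequence, how trailing polymerases push a paused or backtracked leader,
and how the speed-up scales with the number of polymerases loaded from
one promoter.

## The model

The stability of the transcription elongation complex (TEC) at
active-site position *m* is a standard Gibbs free energy built from
nearest-neighbor thermodynamics:

    ΔG°(m) = ΔG_bubble(m)  +  ΔG_hybrid(m)  +  0

— the cost of the melted 12-bp transcription bubble (unified DNA/DNA
parameters), the stabilisation of the 8/9-bp RNA/DNA hybrid (hybrid
parameters), and a sequence-independent RNAP interaction term set to
zero.  Kinetics on this landscape:

* pre/post translocation equilibrium
  `q = exp((ΔG°(post) − ΔG°(pre) − F·Δ)/kBT)` under external force `F`,
* nucleotide incorporation `k = Vmax·[NTP]/([NTP] + Km·(1 + q))` with
  NTP-specific Vmax/Km,
* backtracking/forwardtracking hops
  `k = k0·exp(−(max(0, ΔΔG°) + ΔG0 ∓ F·Δ/2)/kBT)`, detailed-balanced
  against the landscape.

A single polymerase is simulated with the Gillespie first-reaction
method (**SRA**, single-round approach).  With several polymerases
(**MRA**, multiple-round approach), each molecule moves linearly between
its stochastic steps, the engine solves for pairwise contact times, and
collisions are resolved by case: a trailing elongating RNAP transmits
its force to the leader and acts as a roadblock against the leader's
backtracking, a backtracking-backwards leader is pushed forward, and two
backtracked molecules collide elastically.  Hard-core exclusion
(34-nt footprint) is enforced exactly.

The analysis layer computes per-position dwell-time distributions and
their third quartile (TQDT), calls pause sites via the criterion
`τ_TQ(i) > τ_min/α` with 3-bp clustering, tunes α against a reference
pause list by minimising (FP+FN)/TP, builds simulated transcription
gels, backtracking-distance distributions, per-binding-order completion
times, the relative transcription efficiency
`ε(N) = T_avg(1)/T_avg(N)`, and a clustered prediction-quality metric
`Q = TP/(TP+FP+FN)` with bootstrap error bars.

## Worked example

```python
import numpy as np
from rnaptraffic import (
    KineticParams, MotifSpec, RunConfig, make_template,
    simulate_sra, simulate_mra, dwell_profile, call_pauses,
    completion_times, efficiency_curve,
)

# 300-nt random template with one engineered pause site near position 150
template = make_template(300, [MotifSpec("strong_pause", 150)], seed=1)
params = KineticParams(ntp_conc={b: 25.0 for b in "ACGU"}, force=25.0)

cfg1 = RunConfig(template=template, params=params, n_rnap_max=1, seed=0)
rt = cfg1.rate_table()
sra = [simulate_sra(cfg1, replicate=r, rate_table=rt) for r in range(100)]

cfg10 = RunConfig(template=template, params=params, n_rnap_max=10, seed=0)
mra = [simulate_mra(cfg10, replicate=r, rate_table=rt) for r in range(100)]

prof = dwell_profile(sra)
report = call_pauses(prof, alpha=0.02)
print("pause clusters:", report.clusters)
print(f"dwell threshold: {report.threshold:.2f} s")

planted = max(range(130, 171), key=lambda p: prof.tq[p])
prof_m = dwell_profile(t for rep in mra for t in rep)
print(f"planted pause at {planted}: "
      f"TQ dwell {prof.tq[planted]:.1f} s alone, "
      f"{prof_m.tq[planted]:.1f} s with traffic")

ct = completion_times(mra)
medians = {1: [float(np.median([t.completion_time for t in sra]))],
           10: [float(np.median(ct[j])) for j in range(10)]}
curve = efficiency_curve(medians)
print(f"epsilon(10) = {curve.epsilon[10]:.2f}")
```

Output:

```
pause clusters: [[9, 10], [113], [146, 148], [174, 175], [194], [215], [223]]
dwell threshold: 2.34 s
planted pause at 148: TQ dwell 11.9 s alone, 3.6 s with traffic
epsilon(10) = 1.37
```

The pause caller finds the engineered site (cluster 146–148) among the
natural pauses of the random background; polymerase traffic cuts its
third-quartile dwell from 11.9 s to 3.6 s, and loading up to ten
polymerases makes transcription 1.37× faster per molecule on average
(ε > 1 = cooperation).  Note the cluster at 9–10: a pause right at the
start is *not* relieved, because no polymerase can bind behind it while
it occupies the promoter — the same position effect seen in the
multi-round experiments the model describes.

A command-line interface mirrors the library
(`rnaptraffic simulate | pauses | gel | efficiency | quality |
fixtures make-template`); `simulate` writes one event-stream TSV per
replicate plus a JSON manifest of the full configuration.

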