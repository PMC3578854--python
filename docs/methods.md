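# Methods

`rnaptraffic` simulates sequence-dependent transcription elongation by
one or many RNA polymerases (RNAPs) on a shared DNA template, resolves
collisions between them, and turns the resulting trajectory ensembles
into pause, gel, efficiency and prediction-quality statistics.  This
note records the model, its assumptions, the parameter choices made
where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The free-energy landscape of the elongation complex

The transcription elongation complex (TEC) is described by the position
`m` of the active site on the template (1-based, sense strand 5'→3'),
the transcript length, a translocation register (pre/post) and a
backtrack offset.  Its standard Gibbs free energy is the sum of three
terms: the cost of keeping the 12-bp transcription bubble melted, the
stabilisation from the RNA/DNA hybrid inside the bubble (8 bp in the
post-translocated register, 9 bp in the pre-translocated one), and an
RNAP–nucleic-acid interaction term taken as sequence-independent and set
to zero.  Both duplex terms use the nearest-neighbor model: the unified
DNA/DNA parameter set (SantaLucia) for the bubble and the RNA/DNA hybrid
set (Sugimoto) for the hybrid.  ΔG(T) is always recomputed as ΔH − TΔS
at the configured temperature (default 297.15 K = 24 °C), not taken from
the 37 °C table column.

Data curation: the published one-decimal ΔS entries reproduce the
published ΔG°37 only to ~0.02 kcal/mol because of rounding.  The shipped
TSV tables therefore carry ΔS at two decimals, computed as
(ΔH − ΔG°37)/310.15 K — thermodynamically consistent with the published
ΔH and ΔG°37 triplets and inside the rounding of the published ΔS.  A
test asserts the 0.01 kcal/mol round trip for all 16 steps of both
tables.

Geometry conventions (configurable through `TECGeometry`): the hybrid
occupies the upstream part of the bubble and the remaining bubble base
pairs lie downstream of the active site.  Only energy *differences*
between adjacent configurations enter the kinetics, which makes this
partition immaterial away from the template ends.  Windows that would
extend past a template end are clamped; transcription terminates when
the RNAP's leading edge (`d1` = 17 nt ahead of the active site) reaches
the last base.  The RNAP footprint is `d1 + d2` = 34 nt, split
symmetrically about the active site.

Backtracked configurations live on the pre-register landscape shifted
upstream by the offset.  Backward hops whose target could not hold a
full upstream hybrid (the first `hybrid_len_pre` = 9 template positions)
have rate zero.  This generalises the reflecting boundary at the
template start; without it the clamped windows near position 1 form a
spurious low-energy region that acts as a strong artificial trap.

## Kinetics

Three reaction families drive the Gillespie dynamics.

**Translocation equilibrium.**  Pre/post interconversion is fast
compared to nucleotide turnover, so it enters as the occupancy ratio

    q = [pre]/[post] = exp((ΔG°(post) − ΔG°(pre) − F·Δ) / kBT),

with `F` the external force on the polymerase (positive assisting,
default 25 pN — the scale of the RNAP stalling force) acting over the
inter-nucleotide distance Δ = 0.34 nm (F·Δ = 1.223 kcal/mol at 25 pN;
1 kcal/mol = 6.9477 pN·nm).  The sign is fixed by Boltzmann statistics:
a sequence that stabilises the pre register (lower ΔG°) increases q and
slows incorporation; an assisting force drives q → 0.

**Incorporation** is an effective Michaelis–Menten step in which only
the post-translocated state binds substrate:

    k = Vmax·[NTP] / ([NTP] + Km·(1 + q)),

with the NTP-specific constants Vmax = 50/18/36/33 s⁻¹ and
Km = 38/24/62/7 µM for ATP/UTP/GTP/CTP.  NTP concentrations are a
mandatory configuration input — there is no hidden default; the
package's own study runs use 25 µM per NTP for pause analyses and
250 µM for simulated gels (single-molecule pause assays use low µM
substrate to lengthen pauses; gel assays run near saturation).

**Backtracking / forwardtracking** hops are thermally activated moves on
the same landscape:

    k_hop = k0 · exp(−(max(0, ΔG°(target) − ΔG°(current)) + ΔG0 ∓ F·Δ/2) / kBT).

The asymmetric `max(0, ·)` barrier plus a symmetric intrinsic offset
ΔG0 satisfies detailed balance against the landscape exactly at F = 0
(property-tested).  The defaults k0 = 1000 s⁻¹ and ΔG0 = 4.0 kcal/mol
were chosen once so that the entry rate into backtracking on a flat
landscape at 25 pN is ≈ 0.4 s⁻¹ against incorporation rates of
5–15 s⁻¹ — a few percent pause entry per position, the order observed
in single-molecule records — and excursion returns are force-biased.
Both are configurable.

## The event engine

**Single-round approach (SRA).**  One polymerase; at each state the open
channels (incorporation and backtrack entry while elongating; forward
and backward hops while backtracked) receive independent exponential
waiting times (first-reaction method) and the earliest executes.  All
randomness flows from `SeedSequence([seed, replicate, rnap_index])`.

**Multiple-round approach (MRA).**  Initiation is attempted every 0.5 s
(deterministic interval) and succeeds if the promoter footprint is clear
and fewer than N polymerases have initiated.  Between molecular events
each polymerase moves linearly from its current position to the target
of its pending reaction; the engine solves the linear contact condition
`x_T(t) + d1 = x_L(t) − d2` for every adjacent pair and executes the
earliest of {molecular event, collision, initiation attempt}.  When a
collision and a molecular event coincide within 1e−12 s the collision
resolves first, preserving the exclusion invariant.

Collision resolution by the states of trailing (T) and leading (L)
molecules:

* **T elongating × L elongating or forwardtracking** — contact-scoped
  force transmission: while the pair touches, the leader's forward
  channels run at force F + F_c and its backward channels are blocked
  (the trailer is a roadblock); the trailer's forward channels are
  blocked and its backward channels run at F − F_c.  F_c defaults to
  the configured applied force.  Contact ends as soon as either
  molecule's next committed step opens the gap, upon which both revert
  to unmodified rates.
* **T elongating × L backtracking backwards** — the leader's backward
  hop is cancelled and replaced by an immediate pushed forward hop
  (possibly re-entering elongation).  If the leader has no room ahead,
  the case degrades to the roadblock contact above.
* **both backtracked** — perfectly elastic: the two intended step
  directions and completion times are exchanged, positions unchanged
  (the 1-D equal-mass elastic exchange; it always separates the pair).
  The residual combination "trailing backtracked, leading elongating,
  trailing faster" is not enumerated in the six canonical cases and is
  resolved by the same exchange.

A step interrupted mid-flight by a collision does not commit: the
affected molecules are repositioned at their last discrete coordinates.
Because every *committed* discrete configuration respects the exclusion
distance, this snap is always safe for the colliding pair; if a third
molecule had fractionally advanced into the space being vacated, the
snap cascades outward until a pair with slack is found.  Every segment
start is recorded as a trajectory breakpoint, so the emitted
piecewise-linear paths are exactly the paths the engine integrated, and
a validator checks `x_L(t) − x_T(t) ≥ d1 + d2` at all breakpoints of
every adjacent pair.

With N = 1 the MRA event loop reduces to the SRA draw sequence and the
two produce bit-identical trajectories at a shared seed; this is tested,
and it is a genuine test because the SRA is implemented as its own
simple loop that shares only the channel/draw helpers.

## Analysis layer

The dwell time at position i runs from the incorporation that brings the
RNA 3' end to i until the incorporation that advances it past i;
backtracking excursions launched at i are charged to i (gel-band
persistence semantics).  τ_TQ(i) is the third quartile of the dwell
distribution across replicates; all quantiles package-wide use linear
interpolation (numpy's default, "type 7") through one shared helper.
Position i is called a pause when τ_TQ(i) > τ_min/α, where τ_min is the
smallest τ_TQ on the template, so larger α means a larger absolute dwell
threshold.  The comparison form lives in one function
(`pause_threshold`) for easy correction.  α has no default; `tune_alpha`
grid-searches it to minimise (FP + FN)/TP pooled over sequences after
3-bp clustering, ties resolving to the smallest α.

Pause calls within 3 bp merge into clusters.  Predicted and truth
clusters match when any members are within 3 bp; matching is one-to-one
(greedy in genomic order).  The one-to-one restriction matters: with
many-to-many matching a dense call set merges into giant clusters that
trivially cover every truth cluster and drive Q to 1, and the α tuner
exploits exactly that degeneracy.  The quality statistic defaults to
Q = TP/(TP + FP + FN) (configurable), with a bootstrap-over-sequences
standard deviation.

Transcription efficiency: with `median_j` the median completion time of
the j-th initiated polymerase under a cap of N molecules,
T_avg(N) = (1/N)·Σ_{j≤N} median_j and ε(N) = T_avg(1)/T_avg(N); ε(1) = 1
by construction and ε > 1 means collisions accelerate transcription.

Simulated gels count, per timepoint, the replicates whose transcript
has a given length (the number of incorporated nucleotides at that
time; full length after termination — transcript length never shrinks
during backtracking).  Lane sums equal the replicate count.

## Synthetic templates

Real pause-mapping experiments use specific phage templates that are not
bundled here.  The `fixtures` module generates random backgrounds with
*planted* motifs by greedy local search against the actual energy model,
so fixtures remain valid if parameter tables are swapped:

* `strong_pause` — maximises the sum of the translocation-bias gap
  ΔG°(post) − ΔG°(pre) at the site and a *gradual* downhill staircase of
  the backtracked landscape behind it.  The staircase term is included
  deliberately: in this parameterisation long pauses are
  backtracking-mediated, and a bias-only site cannot dominate a random
  background that already contains natural traps.
* `backtrack_trap` — the staircase term alone.

Per-step staircase drops are only credited up to 1.3 kcal/mol, near the
force tilt F·Δ at the default load, so trap interiors behave as roughly
neutral random walks: excursions run deep, yet escape in tens of
seconds rather than becoming irreversible wells.  The search stops as
soon as the requested energy gap is reached (defaults: 6.0 kcal/mol for
pauses, 4.5 for traps), and raises with the achieved gap when a motif is
infeasible in its window.

What the generator emulates: sequence-dependent pause sites of tunable
strength, backtracking traps, and neutral backgrounds on which the
cooperative effects of polymerase traffic are measurable.  What it does
not emulate: real promoter/terminator context, RNA secondary structure
(out of scope for the model as a whole), abortive initiation, and the
specific pause maps of natural templates — so green tests demonstrate
the machinery and the qualitative cooperative phenomenology, not
quantitative agreement with any particular natural sequence.

## Study conditions and problem sizes

The standard study set, used by the test suite and by
`scripts/acceptance.py`, is: a 500-nt template with five planted motifs
(pauses near 120 and 330; traps near 190, 260, 400; background seed 11)
and a 300-nt template with one pause near 150 (seed 1); 25 µM per NTP,
25 pN assisting force, 24 °C, initiation every 0.5 s, up to 10
polymerases, 200 replicates per ensemble (150 per point of the ε(N)
sweep over N ∈ {1, 2, 4, 10}).  These sizes give stable medians and
quartiles while keeping a full run in tens of seconds.  Ground truth
for the prediction-quality statistic is the realised dwell peak inside
each planted-motif window — the synthetic analogue of an experimentally
mapped pause list.

Under these conditions the package reproduces the qualitative signatures
of cooperative transcription (each computed afresh by the acceptance
script and asserted by the test suite): ε(N) ≥ 1, increasing and
saturating in N; planted-pause dwell times sharply reduced by collisions;
deep backtracking excursions suppressed (paired-seed sign test on
per-replicate third-quartile distances); and a last polymerase that is
slower than a lone one, since it is never pushed but still blocked.

## Numerical choices and limitations

* Times are float64 seconds; collision ties break toward the collision
  within 1e−12 s; a livelock guard raises after 10,000 collision
  resolutions without a molecular event.
* The exclusion validator tolerates −1e−6 nt of numerical slack.
* `t_max` (default 10⁴ s) truncates pathological replicates and flags
  the trajectory rather than discarding it.
* Initiation is strictly periodic; an exponential-interval variant would
  change burst statistics but not the steady-state traffic behaviour.
* Elastic exchange is an interpretation of "perfectly elastic" between
  two backtracked molecules; reflection (velocity reversal without
  exchange) is the alternative reading.  Exchange was chosen because it
  conserves the pair's intended displacement and always separates the
  molecules.
* The force transmitted through a contact equals the configured applied
  force by default; no independent measurement constrains it.
* Pause thresholds and tuned α values on synthetic templates are not
  comparable in absolute value to any natural-template figures; only
  their SRA-vs-MRA ordering and the machinery that produces them carry
  over.
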