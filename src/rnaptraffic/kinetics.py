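"""Stochastic reaction rates for transcription elongation.

Three reaction families drive the simulator:

* **Translocation equilibrium.**  The pre- and post-translocated
  registers of the TEC interconvert much faster than NTP turnover, so
  the occupancy ratio ``q = [pre]/[post]`` enters the incorporation rate
  as an equilibrium factor,

      q = exp((ΔG°(post) − ΔG°(pre) − F·Δ) / kBT),

  with ``F`` the external force on the polymerase (positive = assisting
  forward motion), acting over the inter-nucleotide distance ``Δ``.

* **NTP incorporation** follows effective Michaelis–Menten kinetics in
  which only the post-translocated state binds substrate:

      k = Vmax·[NTP] / ([NTP] + Km·(1 + q)).

  Vmax and Km are NTP-specific, experimentally determined constants.

* **Backtracking / forwardtracking** hops are thermally activated moves
  on the same free-energy landscape:

      k_hop = k0 · exp(−(max(0, ΔG°(target) − ΔG°(current)) + ΔG0 ∓ F·Δ/2) / kBT),

  with a configurable attempt prefactor ``k0`` and intrinsic barrier
  ``ΔG0``; the force tilts the barrier by ``−F·Δ/2`` for forward hops
  and ``+F·Δ/2`` for backward hops.  The asymmetric ``max(0, ·)`` form
  satisfies detailed balance against the landscape exactly at F = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import (
    PN_NM_PER_KCAL_MOL,
    EnergyModel,
    Landscape,
    TECState,
    Template,
    kbt_kcal,
)

__all__ = [
    "TABLE1_VMAX",
    "TABLE1_KM",
    "KineticParams",
    "translocation_bias",
    "incorporation_rate",
    "backtrack_rates",
    "RateTable",
]

#: Maximal single-nucleotide incorporation rates, s^-1 (NTP-specific).
TABLE1_VMAX = {"A": 50.0, "U": 18.0, "G": 36.0, "C": 33.0}

#: Michaelis constants for incorporation, uM (NTP-specific).
TABLE1_KM = {"A": 38.0, "U": 24.0, "G": 62.0, "C": 7.0}


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set for one simulation condition.

    ``ntp_conc`` (uM, keyed by RNA base A/C/G/U) is a mandatory input:
    the incorporation rates depend on it everywhere and no biological
    default exists.  ``force`` is the external load on each polymerase
    in pN, positive when assisting forward translocation.
    ``collision_force`` is the force transmitted between two RNAPs in
    contact; ``None`` means "same magnitude as ``force``".
    """

    ntp_conc: dict[str, float]
    vmax: dict[str, float] = field(default_factory=lambda: dict(TABLE1_VMAX))
    km: dict[str, float] = field(default_factory=lambda: dict(TABLE1_KM))
    k0: float = 1000.0
    dg0: float = 4.0
    force: float = 25.0
    collision_force: float | None = None
    temperature: float = 297.15

    def __post_init__(self) -> None:
        for name, mapping in (("vmax", self.vmax), ("km", self.km), ("ntp_conc", self.ntp_conc)):
            missing = set("ACGU") - set(mapping)
            if missing:
                raise ValueError(f"{name} missing NTP entries: {sorted(missing)}")
            if any(v <= 0 for v in mapping.values()):
                raise ValueError(f"all {name} values must be positive")
        if self.k0 <= 0:
            raise ValueError("backtrack prefactor k0 must be positive")

    @property
    def kbt(self) -> float:
        return kbt_kcal(self.temperature)

    @property
    def transmitted_force(self) -> float:
        return self.force if self.collision_force is None else self.collision_force

    def with_force(self, force: float) -> "KineticParams":
        return replace(self, force=force)


def force_term_kcal(force: float, delta: float) -> float:
    """Mechanical work F·Δ converted from pN·nm to kcal/mol."""
    return force * delta / PN_NM_PER_KCAL_MOL


def translocation_bias_from_energies(
    g_pre: float, g_post: float, force: float, delta: float, kbt: float
) -> float:
    """Pre/post occupancy ratio q for given register energies (kcal/mol)."""
    return math.exp((g_post - g_pre - force_term_kcal(force, delta)) / kbt)


def translocation_bias(
    state: TECState,
    template: Template,
    model: EnergyModel,
    force: float,
) -> float:
    """Equilibrium factor q = [pre]/[post] for the TEC at *state*.

    Assisting force (F > 0) shrinks the factor, favouring the
    post-translocated register; a pre register stabilised by the
    sequence (lower ΔG°) grows it, slowing incorporation.
    """
    if state.mode != "elongating":
        raise ValueError("translocation bias is defined for elongating TECs only")
    e = state.m if state.register == "pre" else state.m - 1  # RNA 3' end
    g_pre = model.tec_free_energy(TECState(m=e, n=state.n, register="pre"), template)
    g_post = model.tec_free_energy(
        TECState(m=e + 1, n=state.n, register="post"), template
    )
    return translocation_bias_from_energies(
        g_pre, g_post, force, model.geometry.delta, model.kbt
    )


def incorporation_rate(
    next_base: str, params: KineticParams, bias: float
) -> float:
    """Effective Michaelis–Menten incorporation rate, s^-1.

    *next_base* is the RNA nucleotide to be added (A/C/G/U, i.e. the
    sense-strand template base with T read as U); *bias* the pre/post
    occupancy ratio q.
    """
    base = next_base.upper().replace("T", "U")
    if base not in "ACGU":
        raise ValueError(f"unknown nucleotide {next_base!r}")
    conc = params.ntp_conc[base]
    return params.vmax[base] * conc / (conc + params.km[base] * (1.0 + bias))


def _hop_rate(dg_step: float, params: KineticParams, tilt: float) -> float:
    """k0·exp(−(max(0, ΔG_step) + ΔG0 + tilt)/kBT); *tilt* in kcal/mol."""
    barrier = max(0.0, dg_step) + params.dg0 + tilt
    return params.k0 * math.exp(-barrier / params.kbt)


def backtrack_rates(
    state: TECState,
    template: Template,
    model: EnergyModel,
    params: KineticParams,
    force: float | None = None,
) -> tuple[float, float]:
    """(k_backward, k_forward) hop rates for the TEC at *state*, s^-1.

    Backtracked states live on the pre-register landscape shifted
    upstream by the backtrack offset.  A backward hop past the template
    start has rate 0 (reflecting boundary).  For an elongating TEC the
    backward rate is the entry into backtracking and the forward rate is
    0 (re-entry to elongation is only defined from offset 1).
    """
    F = params.force if force is None else force
    delta = model.geometry.delta
    half = force_term_kcal(F, delta) / 2.0
    if state.mode == "elongating":
        # RNA 3' end is the position on the pre-register landscape
        pos = state.m if state.register == "pre" else state.m - 1
        offset = 0
    elif state.mode == "backtracked":
        pos = state.m - state.backtrack_offset
        offset = state.backtrack_offset
    else:
        raise ValueError("terminated TEC has no hop rates")

    def g_at(p: int) -> float:
        return model.tec_free_energy(TECState(m=p, n=state.n, register="pre"), template)

    g_here = g_at(pos)
    # backward hop: pos -> pos - 1; requires an intact upstream hybrid,
    # so excursions cannot slide off the template start (reflecting boundary)
    if pos - 1 >= model.geometry.hybrid_len_pre:
        k_back = _hop_rate(g_at(pos - 1) - g_here, params, +half)
    else:
        k_back = 0.0
    # forward hop: pos -> pos + 1 (only meaningful when backtracked)
    if offset >= 1:
        k_fwd = _hop_rate(g_at(pos + 1) - g_here, params, -half)
    else:
        k_fwd = 0.0
    return k_back, k_fwd


class RateTable:
    """Per-template cache of all position-dependent rates.

    Precomputes, for each RNA 3'-end position ``e`` on the template at
    the configured external force:

    * ``q[e]`` — translocation equilibrium factor,
    * ``k_inc[e]`` — incorporation rate for the step e → e+1,
    * ``k_hop_back[p]`` / ``k_hop_fwd[p]`` — hop rates on the
      pre-register (backtracking) landscape at active-site position p.

    ``*_at_force`` methods recompute individual entries under a
    collision-modified force without touching the cache.
    """

    def __init__(self, landscape: Landscape, params: KineticParams) -> None:
        self.landscape = landscape
        self.params = params
        self.template = landscape.template
        self.delta = landscape.model.geometry.delta
        kbt = params.kbt
        L = self.template.length
        g_pre = landscape.g_pre
        g_post = landscape.g_post
        fterm = force_term_kcal(params.force, self.delta)
        half = fterm / 2.0

        seq = self.template.seq
        self.q = np.full(L + 1, np.nan)
        self.k_inc = np.zeros(L + 1)
        with np.errstate(invalid="ignore"):
            self.q[1:L] = np.exp((g_post[1:L] - g_pre[1:L] - fterm) / kbt)
        for e in range(1, L):
            base = seq[e].replace("T", "U")  # template base at e+1 (0-based e)
            self.k_inc[e] = incorporation_rate(base, params, float(self.q[e]))

        # hop barriers on the pre-register landscape; backward hops need an
        # intact upstream hybrid (reflecting boundary at the template start)
        hmin = landscape.model.geometry.hybrid_len_pre
        self._hmin = hmin
        self.k_hop_back = np.zeros(L + 1)
        self.k_hop_fwd = np.zeros(L + 1)
        for p in range(hmin + 1, L + 1):
            self.k_hop_back[p] = _hop_rate(g_pre[p - 1] - g_pre[p], params, +half)
        for p in range(1, L):
            self.k_hop_fwd[p] = _hop_rate(g_pre[p + 1] - g_pre[p], params, -half)

    # -- force-modified lookups (used while two RNAPs are in contact) ---

    def k_inc_at_force(self, e: int, force: float) -> float:
        p = self.params
        scale = math.exp(-force_term_kcal(force - p.force, self.delta) / p.kbt)
        q = float(self.q[e]) * scale
        base = self.template.seq[e].replace("T", "U")
        return incorporation_rate(base, p, q)

    def k_hop_back_at_force(self, pos: int, force: float) -> float:
        if pos - 1 < self._hmin:
            return 0.0
        g = self.landscape.g_pre
        half = force_term_kcal(force, self.delta) / 2.0
        return _hop_rate(float(g[pos - 1] - g[pos]), self.params, +half)

    def k_hop_fwd_at_force(self, pos: int, force: float) -> float:
        if pos + 1 > self.template.length:
            return 0.0
        g = self.landscape.g_pre
        half = force_term_kcal(force, self.delta) / 2.0
        return _hop_rate(float(g[pos + 1] - g[pos]), self.params, -half)
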