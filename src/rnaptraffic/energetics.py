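"""Free-energy model of the transcription elongation complex (TEC).

The stability of a TEC on a given DNA template is written as the sum of
three sequence-dependent contributions:

* the cost of holding the transcription bubble open (melting of the
  DNA/DNA duplex over the bubble window),
* the stabilisation gained from the RNA/DNA hybrid inside the bubble,
* an RNAP/nucleic-acid interaction term, taken as sequence-independent
  and set to zero.

Both duplex terms use the nearest-neighbor model: unified DNA/DNA
parameters (SantaLucia) for the bubble and RNA/DNA hybrid parameters
(Sugimoto) for the hybrid, recomputed at the configured temperature from
the tabulated ΔH/ΔS entries.

Geometry convention (documented, configurable through
:class:`TECGeometry`): the RNA/DNA hybrid occupies the upstream part of
the 12-bp bubble and the remaining bubble base pairs lie downstream of
the active site.  In the post-translocated register the hybrid is 8 bp,
in the pre-translocated register 9 bp.  Windows are clamped at template
ends; only energy *differences* between adjacent states drive the
kinetics, which makes the bubble-partition convention immaterial away
from the ends.

Coordinates are 1-based template positions; windows are half-open
``[start, stop)`` intervals of positions on the sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "PN_NM_PER_KCAL_MOL",
    "kbt_kcal",
    "Template",
    "TECGeometry",
    "NNTables",
    "TECState",
    "EnergyModel",
    "duplex_dna_energy",
    "hybrid_energy",
    "tec_free_energy",
    "read_templates_fasta",
]

#: Boltzmann constant expressed per mole (gas constant) in kcal/(mol K).
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Mechanical-unit conversion: 1 kcal/mol per molecule = 6.9477 pN nm.
PN_NM_PER_KCAL_MOL = 6.9477

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def kbt_kcal(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol at *temperature* (kelvin)."""
    return KB_KCAL_PER_MOL_K * temperature


@dataclass(frozen=True)
class Template:
    """A DNA template: the sense strand, 5'->3', over {A,C,G,T}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"template {self.name!r} contains invalid characters {sorted(bad)}; "
                "only A/C/G/T are accepted (ambiguity codes rejected)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Sense-strand base at 1-based position *pos*."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside template [1, {self.length}]")
        return self.seq[pos - 1]


@dataclass(frozen=True)
class TECGeometry:
    """Geometric parameters of the elongation complex.

    ``hybrid_len_post``/``hybrid_len_pre`` are the RNA/DNA hybrid lengths
    in the post-/pre-translocated registers; ``bubble_len`` the open
    transcription bubble; ``delta`` the distance between adjacent
    template nucleotides (nm); ``d1``/``d2`` the distances (nt) from the
    active site to the leading/trailing edge of the RNAP footprint.
    """

    hybrid_len_post: int = 8
    hybrid_len_pre: int = 9
    bubble_len: int = 12
    delta: float = 0.34
    d1: int = 17
    d2: int = 17

    def __post_init__(self) -> None:
        if self.hybrid_len_pre != self.hybrid_len_post + 1:
            raise ValueError("pre-translocated hybrid must be one bp longer than post")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("footprint distances d1, d2 must be positive")
        if self.d1 + self.d2 < self.bubble_len:
            raise ValueError("RNAP footprint cannot be smaller than the bubble")

    @property
    def min_template_length(self) -> int:
        # bubble + one hybrid-length margin; shorter templates cannot host a TEC
        return self.bubble_len + self.hybrid_len_pre

    @property
    def exclusion_distance(self) -> int:
        """Minimum active-site separation of two RNAPs on the same template."""
        return self.d1 + self.d2


class NNTables:
    """Nearest-neighbor ΔH/ΔS tables for one duplex type.

    ``steps`` maps a 5'->3' dinucleotide (of the strand named by
    ``strand``) to ``(dH kcal/mol, dS cal/(mol K))``; ``dg37`` carries
    the source's published ΔG° at 310.15 K for round-trip checks;
    ``initiation`` holds the published duplex-initiation terms (not used
    for the internal windows of a TEC, kept for completeness).
    """

    REFERENCE_TEMPERATURE = 310.15

    def __init__(
        self,
        steps: dict[str, tuple[float, float]],
        dg37: dict[str, float],
        initiation: dict[str, tuple[float, float]],
        source: str,
        alphabet: str,
    ) -> None:
        expected = {a + b for a in alphabet for b in alphabet}
        missing = expected - set(steps)
        if missing:
            raise ValueError(f"NN table {source!r} missing steps: {sorted(missing)}")
        self.steps = dict(steps)
        self.dg37 = dict(dg37)
        self.initiation = dict(initiation)
        self.source = source
        self.alphabet = alphabet

    def dg(self, step: str, temperature: float) -> float:
        """ΔG(T) = ΔH − T·ΔS for one dinucleotide step, kcal/mol."""
        try:
            dh, ds = self.steps[step]
        except KeyError:
            raise KeyError(f"unknown dinucleotide step {step!r} in {self.source}") from None
        return dh - temperature * ds / 1000.0

    @classmethod
    def from_tsv(cls, path: str | Path, source: str, alphabet: str) -> "NNTables":
        steps: dict[str, tuple[float, float]] = {}
        dg37: dict[str, float] = {}
        initiation: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("step\t"):
                continue
            key, dh, ds, g37 = line.split("\t")
            if key.startswith("init"):
                initiation[key] = (float(dh), float(ds))
            else:
                steps[key] = (float(dh), float(ds))
                dg37[key] = float(g37)
        return cls(steps, dg37, initiation, source, alphabet)


_DATA_DIR = resources.files("rnaptraffic") / "data"


@lru_cache(maxsize=None)
def load_dna_dna_table() -> NNTables:
    """Unified DNA/DNA nearest-neighbor parameters (SantaLucia 1998)."""
    with resources.as_file(_DATA_DIR / "dna_dna_santalucia1998.tsv") as p:
        return NNTables.from_tsv(p, "SantaLucia1998-DNA/DNA", "ACGT")


@lru_cache(maxsize=None)
def load_rna_dna_table() -> NNTables:
    """RNA/DNA hybrid nearest-neighbor parameters (Sugimoto et al. 1995)."""
    with resources.as_file(_DATA_DIR / "rna_dna_sugimoto1995.tsv") as p:
        return NNTables.from_tsv(p, "Sugimoto1995-RNA/DNA", "ACGU")


@dataclass
class TECState:
    """Instantaneous configuration of one polymerase.

    ``m`` is the 1-based active-site template position: in the *pre*
    register the active site holds the just-incorporated 3' nucleotide
    (RNA 3' end at ``m``); in the *post* register the active site is
    free, awaiting the NTP templated by position ``m`` (RNA 3' end at
    ``m − 1``).  ``backtrack_offset`` is how far the RNAP has slid
    upstream of the frozen RNA 3' end.
    """

    m: int
    n: int
    register: Literal["pre", "post"] = "pre"
    backtrack_offset: int = 0
    mode: Literal["elongating", "backtracked", "terminated"] = "elongating"

    def __post_init__(self) -> None:
        if self.mode == "elongating" and self.backtrack_offset != 0:
            raise ValueError("elongating TEC cannot carry a backtrack offset")
        if self.mode == "backtracked" and self.backtrack_offset < 1:
            raise ValueError("backtracked TEC needs backtrack_offset >= 1")


def _clamp_window(start: int, stop: int, length: int) -> tuple[int, int]:
    return max(1, start), min(length + 1, stop)


def duplex_dna_energy(
    template: Template,
    window: tuple[int, int],
    temperature: float,
    table: NNTables | None = None,
) -> float:
    """Nearest-neighbor formation ΔG of the DNA/DNA duplex over *window*.

    *window* is a half-open 1-based interval ``[start, stop)`` of
    sense-strand positions; the sum runs over its ``stop − start − 1``
    dinucleotide steps.  The value returned is the (negative,
    stabilising) formation free energy; melting the window — opening the
    transcription bubble — costs its negation.
    """
    start, stop = window
    if not (1 <= start and stop <= template.length + 1):
        raise IndexError(f"window {window} outside template [1, {template.length}]")
    if stop - start < 2:
        raise ValueError(f"window {window} is degenerate: need length >= 2")
    table = table if table is not None else load_dna_dna_table()
    seq = template.seq
    return sum(table.dg(seq[i - 1 : i + 1], temperature) for i in range(start, stop - 1))


def hybrid_energy(
    template: Template,
    rna_3p_end: int,
    hybrid_len: int,
    temperature: float,
    table: NNTables | None = None,
) -> float:
    """Nearest-neighbor formation ΔG of the RNA/DNA hybrid, kcal/mol.

    The hybrid covers sense-strand positions
    ``[rna_3p_end − hybrid_len + 1, rna_3p_end]``; the RNA strand is the
    transcript of the template strand, i.e. the sense sequence with T→U.
    Negative (stabilising) values lower the TEC free energy.
    """
    start = rna_3p_end - hybrid_len + 1
    stop = rna_3p_end + 1
    if not (1 <= start and stop <= template.length + 1):
        raise IndexError(
            f"hybrid window [{start}, {stop}) outside template [1, {template.length}]"
        )
    if hybrid_len < 2:
        raise ValueError("hybrid window must span at least 2 bp")
    table = table if table is not None else load_rna_dna_table()
    rna = template.seq[start - 1 : stop - 1].replace("T", "U")
    return sum(table.dg(rna[i : i + 2], temperature) for i in range(len(rna) - 1))


class EnergyModel:
    """TEC free-energy evaluator: NN tables + geometry + temperature."""

    def __init__(
        self,
        temperature: float = 297.15,
        geometry: TECGeometry | None = None,
        dna_table: NNTables | None = None,
        rna_table: NNTables | None = None,
    ) -> None:
        self.temperature = float(temperature)
        self.geometry = geometry if geometry is not None else TECGeometry()
        self.dna_table = dna_table if dna_table is not None else load_dna_dna_table()
        self.rna_table = rna_table if rna_table is not None else load_rna_dna_table()

    @property
    def kbt(self) -> float:
        return kbt_kcal(self.temperature)

    # -- window layout -------------------------------------------------

    def _windows(
        self, m: int, register: str
    ) -> tuple[tuple[int, int], tuple[int, int]]:
        """(bubble, hybrid) half-open windows for an active site at *m*."""
        g = self.geometry
        if register == "pre":
            # RNA 3' end at m, hybrid_len_pre bp upstream-inclusive
            hyb = (m - g.hybrid_len_pre + 1, m + 1)
            bubble = (hyb[0], hyb[0] + g.bubble_len)
        elif register == "post":
            # active site free at m, RNA 3' end at m-1, hybrid_len_post bp
            hyb = (m - g.hybrid_len_post, m)
            bubble = (hyb[0], hyb[0] + g.bubble_len)
        else:
            raise ValueError(f"unknown register {register!r}")
        return bubble, hyb

    def _window_energy(self, template: Template, window: tuple[int, int], table, rna: bool) -> float:
        start, stop = _clamp_window(*window, template.length)
        if stop - start < 2:
            return 0.0
        if rna:
            return hybrid_energy(template, stop - 1, stop - start, self.temperature, table)
        return duplex_dna_energy(template, (start, stop), self.temperature, table)

    def tec_free_energy(self, state: TECState, template: Template) -> float:
        """Standard Gibbs free energy ΔG° of a TEC configuration, kcal/mol.

        ΔG° = (bubble melting cost, positive) + (hybrid formation,
        negative) + 0 (sequence-independent RNAP/nucleic-acid term).
        Windows truncated by template ends are clamped.
        """
        if template.length < self.geometry.min_template_length:
            raise ValueError(
                f"template {template.name!r} shorter than minimum TEC span "
                f"({self.geometry.min_template_length} nt)"
            )
        if state.mode == "backtracked":
            m = state.m - state.backtrack_offset
            register = "pre"
        else:
            m, register = state.m, state.register
        if not 1 <= m <= template.length:
            raise IndexError(f"active site {m} outside template [1, {template.length}]")
        bubble, hyb = self._windows(m, register)
        g_bubble = -self._window_energy(template, bubble, self.dna_table, rna=False)
        g_hybrid = self._window_energy(template, hyb, self.rna_table, rna=True)
        return g_bubble + g_hybrid

    # -- cached landscape ----------------------------------------------

    def landscape(self, template: Template) -> "Landscape":
        return Landscape(self, template)


def tec_free_energy(state: TECState, template: Template, model: EnergyModel) -> float:
    """Module-level convenience wrapper around :meth:`EnergyModel.tec_free_energy`."""
    return model.tec_free_energy(state, template)


@dataclass
class Landscape:
    """Per-template cache of pre/post-register TEC free energies.

    ``g_pre[e]`` / ``g_post[e]`` are ΔG° for the TEC whose RNA 3' end sits
    at template position ``e`` in the pre-/post-translocated register
    (index 0 unused).  Computed once per template; the engine reads
    energies in O(1).
    """

    model: EnergyModel
    template: Template
    g_pre: np.ndarray = field(init=False)
    g_post: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        L = self.template.length
        g_pre = np.empty(L + 1)
        g_post = np.empty(L + 1)
        g_pre[0] = g_post[0] = np.nan
        for e in range(1, L + 1):
            g_pre[e] = self.model.tec_free_energy(
                TECState(m=e, n=e, register="pre"), self.template
            )
            # post register with RNA 3' end at e => active site at e+1
            if e + 1 <= L:
                g_post[e] = self.model.tec_free_energy(
                    TECState(m=e + 1, n=e, register="post"), self.template
                )
            else:
                g_post[e] = np.nan
        self.g_pre = g_pre
        self.g_post = g_post


def read_templates_fasta(path: str | Path) -> list[Template]:
    """Read templates from a FASTA file (record id becomes the name)."""
    from Bio import SeqIO

    return [Template(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
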