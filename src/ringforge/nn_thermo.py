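"""Nearest-neighbor thermodynamics for DNA hairpin stems and loops.

This module evaluates the folding energetics of perfect Watson-Crick
hairpins in single-stranded DNA with the unified nearest-neighbor (NN)
model: each stacked dinucleotide step contributes a (ΔH, ΔS) pair, helix
termini carry small initiation-like penalties, and the unpaired hairpin
loop is charged an entropic penalty that grows with loop length.  Free
energy at temperature T follows ΔG(T) = ΔH − T·ΔS/1000 (ΔH in kcal/mol,
ΔS in cal/(mol·K)), and the unimolecular melting temperature is
Tm = 1000·ΔH/ΔS (no concentration term, unlike duplex hybridization).

Only perfect stems are modeled: no wobble pairs, mismatches, bulges or
dangling ends.  Salt is handled with an entropic correction at the
divalent-dominated condition of a typical ligase buffer (10 mM Mg²⁺),
folded into ΔS via a monovalent-equivalent concentration.

The parameter table ships as a versioned JSON resource
(``ringforge/data/nn_params.json``) and can be overridden by file path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "EnergyTriple",
    "ThermoParams",
    "StemError",
    "UndefinedTmError",
    "SequenceError",
    "revcomp",
    "is_complement",
    "validate_sequence",
    "stem_energy",
    "hairpin_energy",
    "hairpin_tm",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT = 1.987e-3

#: 0 °C in kelvin.
CELSIUS_OFFSET = 273.15

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_TRANSLATE = str.maketrans(_COMPLEMENT)


class SequenceError(ValueError):
    """A sequence contains characters outside the DNA alphabet ACGT."""


class StemError(ValueError):
    """Two strands do not form a valid perfect Watson-Crick stem."""


class UndefinedTmError(ValueError):
    """The two-state melting temperature is undefined (ΔS ≥ 0)."""


def validate_sequence(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise :class:`SequenceError` naming the
    first offending 1-based position."""
    s = seq.upper()
    for i, base in enumerate(s):
        if base not in _COMPLEMENT:
            if base == "U":
                raise SequenceError(
                    f"{what}: RNA base 'U' at position {i + 1}; this is a DNA tool"
                )
            raise SequenceError(f"{what}: invalid base {base!r} at position {i + 1}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (5'→3' in, 5'→3' out)."""
    return seq.translate(_TRANSLATE)[::-1]


def is_complement(a: str, b: str) -> bool:
    """True if bases ``a`` and ``b`` form a Watson-Crick pair."""
    return _COMPLEMENT.get(a.upper()) == b.upper()


@dataclass(frozen=True)
class EnergyTriple:
    """ΔH / ΔS / ΔG(T) of a folding transition.

    Units: ``dH`` kcal/mol, ``dS`` cal/(mol·K), ``dG_at_T`` kcal/mol at
    ``temperature`` kelvin.  ``dG_at_T`` is always derived from dH and dS so
    the triple stays internally consistent.
    """

    dH: float
    dS: float
    temperature: float
    dG_at_T: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dG_at_T", self.dH - self.temperature * self.dS / 1000.0
        )

    def __add__(self, other: "EnergyTriple") -> "EnergyTriple":
        if abs(self.temperature - other.temperature) > 1e-9:
            raise ValueError("cannot add EnergyTriples at different temperatures")
        return EnergyTriple(self.dH + other.dH, self.dS + other.dS, self.temperature)

    def at(self, temperature: float) -> "EnergyTriple":
        """Re-evaluate ΔG at another temperature (ΔH, ΔS assumed constant)."""
        return EnergyTriple(self.dH, self.dS, temperature)


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor parameter set with loop table and salt condition.

    ``stack_dH``/``stack_dS`` are keyed by the 5'→3' dinucleotide of the top
    strand.  ``loop_dG37`` holds hairpin-loop free-energy increments
    (kcal/mol at ``loop_ref_temperature``) for loop lengths 3..30; longer
    loops are extrapolated logarithmically (Jacobson-Stockmayer form) with
    coefficient ``loop_extrapolation_coeff``.  Salt enters as an entropy
    correction per stack using the monovalent-equivalent of Na⁺ + Mg²⁺.
    """

    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    terminal_dH: dict[str, float]
    terminal_dS: dict[str, float]
    at_closing_dG37: float
    loop_dG37: dict[int, float]
    loop_ref_temperature: float
    loop_extrapolation_coeff: float
    na_molar: float
    mg_molar: float
    salt_entropy_coeff: float
    ref_temperature: float
    gas_constant: float = GAS_CONSTANT
    name: str = "unnamed"
    version: str = ""

    def __post_init__(self) -> None:
        for step in ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG",
                     "TT", "TG", "AC", "AG", "TC", "CC"):
            if step not in self.stack_dH or step not in self.stack_dS:
                raise ValueError(f"NN table missing Watson-Crick step {step}")
        for length, dg in self.loop_dG37.items():
            if length < 3:
                raise ValueError("loop table defined only for loop lengths >= 3")
            if dg <= 0:
                raise ValueError("loop penalties must be positive (destabilizing)")

    @staticmethod
    def from_json(path: str | Path) -> "ThermoParams":
        with open(path) as fh:
            return ThermoParams._from_dict(json.load(fh))

    @staticmethod
    def _from_dict(raw: dict) -> "ThermoParams":
        return ThermoParams(
            stack_dH=dict(raw["stack_dH"]),
            stack_dS=dict(raw["stack_dS"]),
            terminal_dH=dict(raw["terminal_dH"]),
            terminal_dS=dict(raw["terminal_dS"]),
            at_closing_dG37=float(raw["at_closing_dG37"]),
            loop_dG37={int(k): float(v) for k, v in raw["loop_dG37"].items()},
            loop_ref_temperature=float(raw["loop_ref_temperature_K"]),
            loop_extrapolation_coeff=float(raw["loop_extrapolation_coeff"]),
            na_molar=float(raw["salt"]["na_molar"]),
            mg_molar=float(raw["salt"]["mg_molar"]),
            salt_entropy_coeff=float(raw["salt_entropy_coeff"]),
            ref_temperature=float(raw["ref_temperature_K"]),
            name=raw.get("name", "unnamed"),
            version=raw.get("version", ""),
        )

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "ThermoParams":
        """The shipped SantaLucia unified table at 10 mM Mg²⁺."""
        raw = json.loads(
            resources.files("ringforge").joinpath("data/nn_params.json").read_text()
        )
        return ThermoParams._from_dict(raw)

    def with_salt(self, na_molar: float, mg_molar: float) -> "ThermoParams":
        return replace(self, na_molar=na_molar, mg_molar=mg_molar)

    @property
    def monovalent_equivalent(self) -> float:
        """Monovalent-equivalent cation concentration in mol/L.

        Mg²⁺ is converted with the 120·√[Mg²⁺ (mM)] mM rule commonly used
        for PCR-buffer Tm corrections.
        """
        return self.na_molar + 120.0 * math.sqrt(self.mg_molar * 1000.0) / 1000.0

    def salt_dS_per_stack(self) -> float:
        """Entropy correction (cal/mol·K) per stacked step for the configured
        salt; zero when no salt is configured (1 M NaCl reference)."""
        mon = self.monovalent_equivalent
        if mon <= 0:
            return 0.0
        return self.salt_entropy_coeff * math.log(mon)

    def loop_penalty_dG(self, loop_len: int) -> float:
        """Hairpin-loop free-energy increment (kcal/mol) at the loop
        reference temperature, extrapolated for loops beyond the table."""
        if loop_len < 3:
            raise ValueError("hairpin loops shorter than 3 nt are sterically impossible")
        table_max = max(self.loop_dG37)
        if loop_len in self.loop_dG37:
            return self.loop_dG37[loop_len]
        if loop_len > table_max:
            return self.loop_dG37[table_max] + (
                self.loop_extrapolation_coeff
                * self.gas_constant
                * self.loop_ref_temperature
                * math.log(loop_len / table_max)
            )
        # interior gaps: linear interpolation between flanking entries
        below = max(k for k in self.loop_dG37 if k < loop_len)
        above = min(k for k in self.loop_dG37 if k > loop_len)
        frac = (loop_len - below) / (above - below)
        return self.loop_dG37[below] + frac * (self.loop_dG37[above] - self.loop_dG37[below])


def _terminal_class(base: str) -> str:
    return "GC" if base in "GC" else "AT"


def stem_energy(
    stem_top: str,
    stem_bottom: str,
    temperature: float = 298.15,
    params: ThermoParams | None = None,
) -> EnergyTriple:
    """Energy of a perfect Watson-Crick stem (both strands 5'→3').

    Sums the NN stacking terms along the top strand, adds terminal penalties
    for the two closing pairs and the salt-entropy correction, and evaluates
    ΔG at ``temperature`` (kelvin).

    Raises :class:`StemError` if the strands are not exact reverse
    complements or are shorter than 2 bp (a single pair has no stack).
    """
    params = params or ThermoParams.default()
    top = validate_sequence(stem_top, what="stem_top")
    bottom = validate_sequence(stem_bottom, what="stem_bottom")
    if len(top) != len(bottom):
        raise StemError("not a valid stem: strands differ in length")
    if len(top) < 2:
        raise StemError("not a valid stem: need >= 2 bp (no dinucleotide step in 1 bp)")
    if bottom != revcomp(top):
        raise StemError("not a valid stem: strands are not reverse complements")

    dH = 0.0
    dS = 0.0
    for i in range(len(top) - 1):
        step = top[i : i + 2]
        dH += params.stack_dH[step]
        dS += params.stack_dS[step]
    for base in (top[0], top[-1]):
        cls = _terminal_class(base)
        dH += params.terminal_dH[cls]
        dS += params.terminal_dS[cls]
    dS += params.salt_dS_per_stack() * (len(top) - 1)
    return EnergyTriple(dH, dS, temperature)


def hairpin_energy(
    seq: str,
    stem_len: int,
    loop_len: int,
    temperature: float = 298.15,
    params: ThermoParams | None = None,
) -> EnergyTriple:
    """Folding energy of a hairpin: perfect stem + unpaired loop.

    ``seq`` must be exactly ``2·stem_len + loop_len`` nt with the two arms
    being reverse complements.  The loop contributes a purely entropic
    penalty taken from the loop table (logarithmically extrapolated past
    30 nt); an A·T loop-closing pair carries an extra destabilization.

    The returned ΔG is the free energy of *folding*: negative for a stable
    hairpin.
    """
    params = params or ThermoParams.default()
    s = validate_sequence(seq)
    if loop_len < 3:
        raise ValueError("loop_len < 3: sterically impossible loop")
    if len(s) != 2 * stem_len + loop_len:
        raise ValueError(
            f"sequence length {len(s)} != 2*{stem_len} + {loop_len}"
        )
    arm5 = s[:stem_len]
    arm3 = s[stem_len + loop_len :]
    stem = stem_energy(arm5, arm3, temperature, params)  # raises on mismatched arms

    t_loop = params.loop_ref_temperature
    loop_dS = -1000.0 * params.loop_penalty_dG(loop_len) / t_loop
    dH = stem.dH
    dS = stem.dS + loop_dS
    # closing pair adjacent to the loop: extra penalty if A·T
    if _terminal_class(arm5[-1]) == "AT":
        dS += -1000.0 * params.at_closing_dG37 / t_loop
    return EnergyTriple(dH, dS, temperature)


def hairpin_tm(e: EnergyTriple) -> float:
    """Two-state unimolecular melting temperature in °C.

    For a hairpin there is no strand-concentration term; the midpoint is
    where ΔG(T) = 0, i.e. Tm = 1000·ΔH/ΔS kelvin.  Undefined when ΔS ≥ 0
    (no entropy loss on folding → no finite melting point).
    """
    if e.dS >= 0:
        raise UndefinedTmError("Tm undefined for dS >= 0 (no two-state midpoint)")
    return 1000.0 * e.dH / e.dS - CELSIUS_OFFSET
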