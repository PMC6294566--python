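"""Enumeration of perfect-stem hairpins in a linear DNA sequence.

A hairpin here is a maximal perfect Watson-Crick stem of >= 3 bp closing a
loop of 3-30 unpaired nucleotides.  "Maximal" means the stem can be
extended neither outward (adding a pair on the open side) nor inward
(stealing two loop bases) with a valid Watson-Crick pair, so nested
sub-stems of one helix are not double-reported.  Coordinates are 1-based
and inclusive, with ``start`` on the 5'-most paired base — the convention
used when saying a hairpin "starts at the 3rd nt" of a precursor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .nn_thermo import (
    CELSIUS_OFFSET,
    EnergyTriple,
    ThermoParams,
    UndefinedTmError,
    hairpin_energy,
    hairpin_tm,
    is_complement,
    validate_sequence,
)

__all__ = ["Hairpin", "find_hairpins", "assign_structure"]


@dataclass(frozen=True)
class Hairpin:
    """A detected stem-loop.

    ``start``/``end`` are 1-based inclusive indices of the outermost paired
    bases; ``end = start + 2·stem_len + loop_len − 1``.  ``energy`` is the
    folding EnergyTriple at the scan temperature; ``tm`` is the two-state
    melting temperature in °C (None in the degenerate ΔS ≥ 0 case).
    """

    start: int
    stem_len: int
    loop_len: int
    end: int
    seq: str
    energy: EnergyTriple
    tm: float | None

    @property
    def dG(self) -> float:
        return self.energy.dG_at_T

    @property
    def arm5(self) -> str:
        return self.seq[: self.stem_len]

    @property
    def arm3(self) -> str:
        return self.seq[self.stem_len + self.loop_len :]

    def geometry(self) -> tuple[int, int, int]:
        return (self.start, self.stem_len, self.loop_len)


def _maximal_geometries(
    seq: str, min_stem: int, min_loop: int, max_loop: int
) -> Iterator[tuple[int, int, int]]:
    """Yield (start0, stem_len, loop_len) of every maximal hairpin.

    Anchored on the outermost pair (a, b): an anchor that can be extended
    outward is skipped (the larger hairpin is found at its own anchor); the
    stem is then grown inward greedily until a mismatch or the loop floor.
    """
    n = len(seq)
    for a in range(n):
        b_lo = a + 2 * min_stem + min_loop - 1
        for b in range(b_lo, n):
            if not is_complement(seq[a], seq[b]):
                continue
            if 0 < a and b < n - 1 and is_complement(seq[a - 1], seq[b + 1]):
                continue  # outward-extendable: not maximal
            s = 1
            while True:
                loop = b - a + 1 - 2 * s
                if loop - 2 >= min_loop and is_complement(seq[a + s], seq[b - s]):
                    s += 1
                else:
                    break
            loop = b - a + 1 - 2 * s
            if s >= min_stem and min_loop <= loop <= max_loop:
                yield (a, s, loop)


def find_hairpins(
    seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    max_loop: int = 30,
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> list[Hairpin]:
    """All maximal perfect-stem hairpins in ``seq``, most stable first.

    Sorted by ascending ΔG at ``temperature_c``, ties broken by
    (start, stem_len) for a fully deterministic order.  Raises
    :class:`~ringforge.nn_thermo.SequenceError` on non-ACGT input, naming
    the offending position.
    """
    s = validate_sequence(seq)
    if len(s) < 2 * min_stem + min_loop:
        return []
    params = params or ThermoParams.default()
    t_kelvin = temperature_c + CELSIUS_OFFSET
    out: list[Hairpin] = []
    for a, stem, loop in _maximal_geometries(s, min_stem, min_loop, max_loop):
        sub = s[a : a + 2 * stem + loop]
        e = hairpin_energy(sub, stem, loop, t_kelvin, params)
        try:
            tm = hairpin_tm(e)
        except UndefinedTmError:
            tm = None
        out.append(
            Hairpin(
                start=a + 1,
                stem_len=stem,
                loop_len=loop,
                end=a + 2 * stem + loop,
                seq=sub,
                energy=e,
                tm=tm,
            )
        )
    out.sort(key=lambda h: (h.dG, h.start, h.stem_len))
    return out


def assign_structure(
    seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    max_loop: int = 30,
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> list[Hairpin]:
    """Greedy non-overlapping secondary-structure assignment.

    Walks the hairpin list in ascending-ΔG order and keeps each hairpin
    whose [start, end] span does not overlap an already-kept one — a
    deterministic stand-in for a full minimum-free-energy fold, adequate
    for multi-hairpin precursors whose helices are disjoint.  Returned in
    5'→3' order of position.
    """
    kept: list[Hairpin] = []
    for h in find_hairpins(seq, min_stem, min_loop, max_loop, temperature_c, params):
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept
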