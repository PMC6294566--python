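"""Fragment screening: how many sequences carry a usable stable hairpin?

The terminal-hairpin strategy is broadly applicable only if arbitrary
sequences tend to contain at least one sufficiently stable hairpin
somewhere (position is irrelevant here — the ring can always be rotated to
put an existing hairpin at a terminus).  This module classifies fragments
by the existence of a hairpin with Tm > 50 °C and −ΔG > 3 kcal/mol (strict
inequalities) and aggregates the positive fraction over a fragment set.

A seedable random-fragment generator is included so the screen runs
without any genome download; random uniform-composition fragments are a
stand-in for genomic sequence and fractions on them are indicative, not
equivalent to genomic figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hairpin_scan import Hairpin, find_hairpins
from .nn_thermo import ThermoParams, validate_sequence

__all__ = ["ScreenReport", "classify_fragment", "screen_records", "screen_fasta",
           "random_fragments"]


@dataclass(frozen=True)
class ScreenReport:
    """Aggregate of a fragment screen."""

    n_fragments: int
    fragment_length: int  # 0 when lengths are mixed
    n_positive: int
    tm_floor: float
    dG_ceiling: float
    per_fragment: tuple[tuple[str, Hairpin | None], ...]

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_fragments if self.n_fragments else 0.0


def classify_fragment(
    seq: str,
    tm_floor: float = 50.0,
    dG_ceiling: float = -3.0,
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> tuple[bool, Hairpin | None]:
    """Does the fragment carry >= 1 stable hairpin?

    Stable means Tm strictly above ``tm_floor`` AND ΔG strictly below
    ``dG_ceiling``.  Returns (positive, best qualifying hairpin or None),
    best = lowest ΔG.
    """
    hps = find_hairpins(seq, temperature_c=temperature_c, params=params)
    qualifiers = [
        h for h in hps
        if h.tm is not None and h.tm > tm_floor and h.dG < dG_ceiling
    ]
    if not qualifiers:
        return False, None
    return True, min(qualifiers, key=lambda h: (h.dG, h.start, h.stem_len))


def screen_records(
    records: list[tuple[str, str]],
    tm_floor: float = 50.0,
    dG_ceiling: float = -3.0,
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> ScreenReport:
    """Classify a list of (id, sequence) records and aggregate."""
    if not records:
        raise ValueError("no fragments to screen")
    per: list[tuple[str, Hairpin | None]] = []
    n_pos = 0
    for rid, seq in records:
        ok, best = classify_fragment(seq, tm_floor, dG_ceiling, temperature_c, params)
        n_pos += ok
        per.append((rid, best))
    lengths = {len(seq) for _, seq in records}
    return ScreenReport(
        n_fragments=len(records),
        fragment_length=lengths.pop() if len(lengths) == 1 else 0,
        n_positive=n_pos,
        tm_floor=tm_floor,
        dG_ceiling=dG_ceiling,
        per_fragment=tuple(per),
    )


def screen_fasta(
    path,
    tm_floor: float = 50.0,
    dG_ceiling: float = -3.0,
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> ScreenReport:
    """Screen every record of a multi-FASTA file."""
    from .io_cli import read_fasta

    return screen_records(read_fasta(path), tm_floor, dG_ceiling, temperature_c, params)


def random_fragments(
    n: int, length: int, gc: float = 0.5, seed: int = 0
) -> list[tuple[str, str]]:
    """``n`` i.i.d. random fragments with per-base GC probability ``gc``.

    Reproducible per seed (numpy PCG64).  Returns (id, sequence) records;
    write with :func:`ringforge.io_cli.write_fasta` for a FASTA file.
    """
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    half = gc / 2.0
    p = [half, half, (1.0 - gc) / 2.0, (1.0 - gc) / 2.0]
    bases = np.array(list("GCAT"))
    draws = rng.choice(bases, size=(n, length), p=p)
    return [
        (f"frag_{i + 1:04d}", "".join(row)) for i, row in enumerate(draws)
    ]
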