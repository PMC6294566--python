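"""Conversion, selectivity and yield from gel band intensities.

After a cyclization reaction the denaturing gel shows three classes of
band: the circular monomer (C), polymeric byproducts — linear and
multi-cyclic pooled together (P) — and unreacted linear substrate (R).
From their intensities:

    conversion  (%) = (1 − R/(C+P+R)) · 100     fraction of substrate consumed
    selectivity (%) = C/(C+P) · 100             ring fraction of ligated product
    yield       (%) = C/(C+P+R) · 100           ring fraction of everything

so yield = selectivity · conversion / 100 holds as an exact identity, and
all three are invariant to overall intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GelLane",
    "SelectivityUndefinedError",
    "conversion",
    "selectivity",
    "yield_pct",
    "quantify_table",
]


class SelectivityUndefinedError(ZeroDivisionError):
    """No ligated product at all (C + P = 0): selectivity has no value,
    which is distinct from a selectivity of 0%."""


@dataclass(frozen=True)
class GelLane:
    """Band intensities of one gel lane (arbitrary fluorescence units)."""

    C: float
    P: float
    R: float
    lane_id: str = ""

    def __post_init__(self) -> None:
        if self.C < 0 or self.P < 0 or self.R < 0:
            raise ValueError(f"lane {self.lane_id!r}: band intensities must be >= 0")

    @property
    def total(self) -> float:
        return self.C + self.P + self.R


def conversion(lane: GelLane) -> float:
    """Percent of substrate consumed: (1 − R/(C+P+R))·100."""
    if lane.total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: all-zero lane, conversion undefined")
    return (1.0 - lane.R / lane.total) * 100.0


def selectivity(lane: GelLane) -> float:
    """Percent of ligated product that is monomeric ring: C/(C+P)·100."""
    ligated = lane.C + lane.P
    if ligated <= 0:
        raise SelectivityUndefinedError(
            f"lane {lane.lane_id!r}: no ligated product (C+P=0); selectivity undefined"
        )
    return lane.C / ligated * 100.0


def yield_pct(lane: GelLane) -> float:
    """Percent ring yield over all material: C/(C+P+R)·100."""
    if lane.total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: all-zero lane, yield undefined")
    return lane.C / lane.total * 100.0


def quantify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add conversion/selectivity/yield columns to a lane-intensity table.

    Expects columns ``lane_id, C, P, R``; returns a copy with
    ``conversion_pct``, ``selectivity_pct`` and ``yield_pct`` appended.
    Lanes with no ligated product get NaN selectivity.
    """
    required = {"lane_id", "C", "P", "R"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    out = table.copy()
    conv, sel, yld = [], [], []
    for row in out.itertuples(index=False):
        lane = GelLane(C=float(row.C), P=float(row.P), R=float(row.R),
                       lane_id=str(row.lane_id))
        conv.append(conversion(lane))
        yld.append(yield_pct(lane))
        try:
            sel.append(selectivity(lane))
        except SelectivityUndefinedError:
            sel.append(float("nan"))
    out["conversion_pct"] = conv
    out["selectivity_pct"] = sel
    out["yield_pct"] = yld
    return out
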