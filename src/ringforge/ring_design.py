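"""Circular-permutation design of l-DNA precursors for ssDNA rings.

A target ring of n nucleotides can be opened at any of its n phosphodiester
bonds; every resulting linear precursor (l-DNA) cyclizes back to the same
ring.  The terminal-hairpin strategy exploits that freedom: pick the
rotation whose linear form carries a hairpin starting 1-3 nt from one
terminus.  The hairpin sequesters the terminus, keeps the ligase-reactive
open form rare, and thereby suppresses intermolecular polymerization during
splint-mediated T4 ligation.

``design_ring`` scans all rotations, applies the positional rule
(terminus-to-stem distance 1-3 nt) and the stability window
(ΔG ≤ −3 kcal/mol, 50 °C ≤ Tm ≤ 80 °C), designs the 12-nt splint for each
qualifying precursor and ranks candidates by the predicted maximum
preparative concentration from the two-state equilibrium model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .equilibrium import EquilibriumResult, predict_equilibrium
from .hairpin_scan import Hairpin, find_hairpins
from .nn_thermo import CELSIUS_OFFSET, ThermoParams, revcomp, validate_sequence

__all__ = [
    "DesignRules",
    "LinearPrecursor",
    "DesignCandidate",
    "DesignResult",
    "rotations",
    "design_splint",
    "design_ring",
]

logger = logging.getLogger("ringforge.design")

#: Free-text caveats attached to every design report.  These conditions
#: influence real reactions but are outside the equilibrium model.
DESIGN_CAVEATS = (
    "Predictions assume splint-mediated T4 ligation at 25 C; DNA length, "
    "splint length and reaction temperature are not modeled.",
    "Diluted ligase buffer (0.05-0.1x) can further suppress polymerization; "
    "it is an experimental condition, not part of this model.",
)


@dataclass(frozen=True)
class DesignRules:
    """Thresholds of the terminal-hairpin design protocol.

    ``d_min``..``d_max`` — allowed number of unpaired nucleotides between
    the terminus and the first paired stem base (1-3 by default; distance 0
    only under ``allow_distance_zero``).  ``dG_ceiling`` / ``tm_floor`` —
    minimum hairpin stability (−ΔG > 3 kcal/mol, Tm > 50 °C).
    ``tm_ceiling`` — an over-stable hairpin (≥ ~85 °C) slows ligation and
    erodes selectivity, so 80 °C caps the window.  ``splint_arm`` — each
    splint half pairs this many terminal nucleotides.  Rings shorter than
    ``min_precursor_len`` get a warning (small rings cyclize poorly).
    """

    d_min: int = 1
    d_max: int = 3
    dG_ceiling: float = -3.0
    tm_floor: float = 50.0
    tm_ceiling: float = 80.0
    stem_len_preferred: frozenset[int] = frozenset({4, 5, 6})
    splint_arm: int = 6
    min_precursor_len: int = 44
    allow_distance_zero: bool = False
    require_splint_overlap: bool = False

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise ValueError("d_min must be <= d_max")
        if self.tm_floor >= self.tm_ceiling:
            raise ValueError("tm_floor must be < tm_ceiling")

    def to_dict(self) -> dict:
        return {
            "d_min": self.d_min,
            "d_max": self.d_max,
            "dG_ceiling": self.dG_ceiling,
            "tm_floor": self.tm_floor,
            "tm_ceiling": self.tm_ceiling,
            "stem_len_preferred": sorted(self.stem_len_preferred),
            "splint_arm": self.splint_arm,
            "min_precursor_len": self.min_precursor_len,
            "allow_distance_zero": self.allow_distance_zero,
            "require_splint_overlap": self.require_splint_overlap,
        }

    @staticmethod
    def from_dict(raw: dict) -> "DesignRules":
        kwargs = dict(raw)
        if "stem_len_preferred" in kwargs:
            kwargs["stem_len_preferred"] = frozenset(kwargs["stem_len_preferred"])
        return DesignRules(**kwargs)


@dataclass(frozen=True)
class LinearPrecursor:
    """One circular permutation of the ring: the ring opened after rotating
    by ``offset`` (0-based), read 5'→3'."""

    ring_id: str
    offset: int
    seq: str
    hairpins: tuple[Hairpin, ...]

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DesignCandidate:
    """A precursor/terminal-hairpin pairing with its splint, equilibrium
    prediction and per-rule pass flags."""

    precursor: LinearPrecursor
    terminal_hairpin: Hairpin
    terminal_side: str  # "5'" or "3'"
    distance: int
    splint: str
    equilibrium: EquilibriumResult
    passes: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.passes.values())

    @property
    def rank_score(self) -> tuple:
        return (
            -self.equilibrium.max_total_for_threshold,
            self.terminal_hairpin.dG,
            self.precursor.offset,
            self.terminal_side,
        )

    def to_row(self) -> dict:
        h = self.terminal_hairpin
        return {
            "offset": self.precursor.offset,
            "side": self.terminal_side,
            "distance": self.distance,
            "stem_len": h.stem_len,
            "loop_len": h.loop_len,
            "dG_kcal_mol": round(h.dG, 3),
            "tm_C": None if h.tm is None else round(h.tm, 2),
            "splint_seq": self.splint,
            "K": round(self.equilibrium.K, 4),
            "open_conc_uM": round(self.equilibrium.open_conc, 4),
            "max_conc_uM": round(self.equilibrium.max_total_for_threshold, 3),
            "pass_flags": ";".join(
                f"{k}={'ok' if v else 'FAIL'}" for k, v in sorted(self.passes.items())
            ),
        }


@dataclass(frozen=True)
class DesignResult:
    """Outcome of a ring scan: passing candidates (ranked), near-misses
    with the rule(s) they failed, and free-text caveats."""

    ring_id: str
    ring_length: int
    total_conc: float
    rules: DesignRules
    candidates: tuple[DesignCandidate, ...]
    near_misses: tuple[DesignCandidate, ...]
    warnings: tuple[str, ...] = ()
    caveats: tuple[str, ...] = DESIGN_CAVEATS

    @property
    def best(self) -> DesignCandidate | None:
        return self.candidates[0] if self.candidates else None


def rotations(
    ring_seq: str,
    ring_id: str = "ring",
    temperature_c: float = 25.0,
    params: ThermoParams | None = None,
) -> list[LinearPrecursor]:
    """All n circular permutations of an n-nt ring, each scanned for
    hairpins.  Offset k means the precursor starts at ring position k
    (0-based); cutting anywhere yields the same ring back."""
    s = validate_sequence(ring_seq, what="ring")
    n = len(s)
    out = []
    for k in range(n):
        lin = s[k:] + s[:k]
        hps = tuple(find_hairpins(lin, temperature_c=temperature_c, params=params))
        out.append(LinearPrecursor(ring_id=ring_id, offset=k, seq=lin, hairpins=hps))
    return out


def design_splint(linear_seq: str, arm: int = 6) -> str:
    """The splint for a linear precursor: reverse complement of
    (last ``arm`` nt ++ first ``arm`` nt), so its two halves pair the 3'-
    and 5'-termini and juxtapose them across the nick."""
    s = validate_sequence(linear_seq)
    if len(s) < 2 * arm:
        raise ValueError(f"precursor shorter than 2*arm = {2 * arm} nt")
    return revcomp(s[-arm:] + s[:arm])


def _evaluate(
    prec: LinearPrecursor,
    h: Hairpin,
    side: str,
    rules: DesignRules,
    total_conc: float,
    temperature_k: float,
    open_threshold: float,
) -> DesignCandidate:
    n = prec.length
    distance = h.start - 1 if side == "5'" else n - h.end
    dist_ok = rules.d_min <= distance <= rules.d_max or (
        distance == 0 and rules.allow_distance_zero
    )
    passes = {
        "distance": dist_ok,
        "stability": h.dG <= rules.dG_ceiling,
        "tm_window": h.tm is not None and rules.tm_floor <= h.tm <= rules.tm_ceiling,
    }
    if rules.require_splint_overlap:
        # stem must reach into the splint-binding terminal arm
        overlap = (
            h.start <= rules.splint_arm
            if side == "5'"
            else h.end > n - rules.splint_arm
        )
        passes["splint_overlap"] = overlap
    return DesignCandidate(
        precursor=prec,
        terminal_hairpin=h,
        terminal_side=side,
        distance=distance,
        splint=design_splint(prec.seq, rules.splint_arm),
        equilibrium=predict_equilibrium(
            h.dG, total_conc, temperature_k, open_threshold
        ),
        passes=passes,
    )


def design_ring(
    ring_seq: str,
    rules: DesignRules | None = None,
    total_conc: float = 5.0,
    ring_id: str = "ring",
    temperature_c: float = 25.0,
    open_threshold: float = 0.1,
    params: ThermoParams | None = None,
) -> DesignResult:
    """Scan every rotation of the ring and rank terminal-hairpin designs.

    For each rotation, every hairpin lying within ``d_max + 3`` nt of either
    terminus is evaluated against the positional and stability rules.
    Passing candidates carry the splint and equilibrium prediction at
    ``total_conc`` μM and are ranked by predicted maximum preparative
    concentration (descending), then by more negative ΔG, then offset.
    Failures inside the consideration window are returned as near-misses
    with per-rule flags; when nothing passes this is the structured
    near-miss report.
    """
    rules = rules or DesignRules()
    s = validate_sequence(ring_seq, what="ring")
    warnings: list[str] = []
    if len(s) < rules.min_precursor_len:
        warnings.append(
            f"ring length {len(s)} nt < {rules.min_precursor_len} nt: "
            "small rings cyclize with poor selectivity"
        )
    t_kelvin = temperature_c + CELSIUS_OFFSET
    window = rules.d_max + 3
    passing: list[DesignCandidate] = []
    near: list[DesignCandidate] = []
    for prec in rotations(s, ring_id, temperature_c, params):
        n = prec.length
        for h in prec.hairpins:
            for side, dist in (("5'", h.start - 1), ("3'", n - h.end)):
                if dist > window:
                    continue
                cand = _evaluate(
                    prec, h, side, rules, total_conc, t_kelvin, open_threshold
                )
                if cand.passed:
                    passing.append(cand)
                else:
                    failed = [k for k, v in cand.passes.items() if not v]
                    logger.info(
                        "offset %d %s-side hairpin at distance %d fails: %s",
                        prec.offset, side, cand.distance, ", ".join(failed),
                    )
                    near.append(cand)
    passing.sort(key=lambda c: c.rank_score)
    near.sort(key=lambda c: c.rank_score)
    return DesignResult(
        ring_id=ring_id,
        ring_length=len(s),
        total_conc=total_conc,
        rules=rules,
        candidates=tuple(passing),
        near_misses=tuple(near),
        warnings=tuple(warnings),
    )
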