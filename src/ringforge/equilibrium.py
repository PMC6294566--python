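"""Two-state folded/open equilibrium of a hairpin-bearing precursor.

Only the open (unfolded-terminus) form of an l-DNA is a substrate for
splint-mediated ligation.  With hairpin folding free energy ΔG < 0 the
equilibrium constant K = [folded]/[open] = exp(−ΔG/RT) is large, so the
open form — the ligase-reactive species — sits at total/(1+K).  Inverting
that partition gives the maximum total precursor concentration that keeps
the reactive species below a chosen ceiling (0.1 μM by default, the
empirical anchor for >85% ring selectivity).

K is always propagated unrounded; rounding happens only at display time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .nn_thermo import GAS_CONSTANT

__all__ = [
    "EquilibriumResult",
    "equilibrium_constant",
    "open_concentration",
    "max_total_concentration",
    "predict_selectivity_class",
    "predict_equilibrium",
]


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium summary for one precursor at one total concentration.

    Concentrations in μM; ``K`` is the dimensionless folded:open ratio;
    ``fraction_open`` = 1/(1+K) ∈ (0, 1].
    """

    K: float
    fraction_open: float
    open_conc: float
    total_conc: float
    temperature: float
    open_threshold: float
    max_total_for_threshold: float
    predicted_high_selectivity: bool

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "fraction_open": self.fraction_open,
            "open_conc_uM": self.open_conc,
            "total_conc_uM": self.total_conc,
            "temperature_K": self.temperature,
            "open_threshold_uM": self.open_threshold,
            "max_total_uM": self.max_total_for_threshold,
            "predicted_high_selectivity": self.predicted_high_selectivity,
        }


def equilibrium_constant(dG: float, temperature: float = 298.15) -> float:
    """K = [folded]/[open] = exp(−ΔG/(R·T)) for folding free energy ΔG
    (kcal/mol) at ``temperature`` kelvin.  K = 1 exactly when ΔG = 0."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return math.exp(-dG / (GAS_CONSTANT * temperature))


def open_concentration(total: float, K: float) -> float:
    """Open-form concentration total/(1+K) — the exact two-state partition."""
    if total < 0:
        raise ValueError("total concentration must be >= 0")
    if K < 0:
        raise ValueError("equilibrium constant must be >= 0")
    return total / (1.0 + K)


def max_total_concentration(K: float, open_threshold: float = 0.1) -> float:
    """Largest total concentration keeping the open form at or below
    ``open_threshold``: threshold · (1+K).  Inverse of
    :func:`open_concentration`."""
    if K < 0:
        raise ValueError("equilibrium constant must be >= 0")
    if open_threshold <= 0:
        raise ValueError("open-form threshold must be positive")
    return open_threshold * (1.0 + K)


def predict_selectivity_class(open_conc: float, open_threshold: float = 0.1) -> bool:
    """True iff the open-form concentration is at or below the threshold,
    predicting high (>85%) ring selectivity.  Boundary counts as high."""
    if open_conc < 0:
        raise ValueError("open concentration must be >= 0")
    return open_conc <= open_threshold


def predict_equilibrium(
    dG: float,
    total_conc: float,
    temperature: float = 298.15,
    open_threshold: float = 0.1,
) -> EquilibriumResult:
    """Full equilibrium prediction from a folding ΔG (kcal/mol)."""
    K = equilibrium_constant(dG, temperature)
    open_c = open_concentration(total_conc, K)
    return EquilibriumResult(
        K=K,
        fraction_open=1.0 / (1.0 + K),
        open_conc=open_c,
        total_conc=total_conc,
        temperature=temperature,
        open_threshold=open_threshold,
        max_total_for_threshold=max_total_concentration(K, open_threshold),
        predicted_high_selectivity=predict_selectivity_class(open_c, open_threshold),
    )
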