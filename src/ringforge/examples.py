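"""Synthetic demonstration sequences (all constructed, none genomic).

These rings are built so that their hairpin content is known by
construction: GC-only stems (which cannot pair with the pyrimidine-only
loops or the A/C-only filler), T/C loops and A/C filler.  A and C share no
Watson-Crick partner within {A, C}, so filler regions are self-inert.  The
demo rings emulate the geometry of a 64-nt precursor whose terminal
hairpin starts at the 3rd nucleotide (two unpaired nucleotides before the
stem, i.e. terminus distance 2) with a second hairpin mid-sequence.
"""

from __future__ import annotations

__all__ = [
    "demo_ring_64",
    "demo_ring_40",
    "hairpin_free_ring",
    "DEMO_DG_FOLDING",
]

#: Hairpin folding free energy (kcal/mol at 25 °C) used in the worked
#: equilibrium example.
DEMO_DG_FOLDING = -3.16


def demo_ring_64() -> str:
    """A synthetic 64-nt ring (given as its offset-0 linear form).

    Rotation 0 carries a terminal hairpin with a 6-bp GC stem starting at
    nt 3 (terminus distance 2, 11-nt loop) and a second, weaker 4-bp
    hairpin starting at nt 29 — the two-hairpin layout of a terminal-
    hairpin precursor.
    """
    return (
        "AA"                  # nt 1-2: unpaired spacer before the stem
        "GCCGCC"              # nt 3-8: 5' arm of the terminal hairpin
        "TTCTTCTTCTT"         # nt 9-19: 11-nt loop
        "GGCGGC"              # nt 20-25: 3' arm
        "ACA"                 # nt 26-28: spacer
        "CACC"                # nt 29-32: 5' arm of the internal hairpin
        "TTCTTCTTCTTCT"       # nt 33-45: 13-nt loop
        "GGTG"                # nt 46-49: 3' arm
        "AACAAACAAACAAAC"     # nt 50-64: inert A/C filler
    )


def demo_ring_40() -> str:
    """A synthetic 40-nt ring with one designed terminal hairpin
    (6-bp GC stem, 7-nt loop, stem starting at nt 3 of rotation 0)."""
    return (
        "AA"                  # nt 1-2
        "GCCGCC"              # nt 3-8: 5' arm
        "TTCTTCT"             # nt 9-15: 7-nt loop
        "GGCGGC"              # nt 16-21: 3' arm
        "AACAAACAAACAAACAAAC" # nt 22-40: inert filler
    )


def hairpin_free_ring(length: int = 48) -> str:
    """A ring over {A, C} only: no Watson-Crick pairing is possible in any
    rotation, so every permutation is hairpin-free."""
    if length < 1:
        raise ValueError("length must be positive")
    block = "AACAC"
    return (block * (length // len(block) + 1))[:length]
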