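# Methods

## Scope and model overview

`ringforge` predicts, for a target single-stranded DNA ring, which circular
permutation of its linear precursor (l-DNA) is best suited to
splint-mediated T4 ligation under the terminal-hairpin strategy. The
pipeline is: nearest-neighbor hairpin thermodynamics → exhaustive hairpin
enumeration → rotation scan with positional and stability rules → splint
design → two-state equilibrium prediction. Everything is thermodynamic and
sequence-level; ligase kinetics, buffer composition effects and gel
densitometry are outside the model (gel band intensities enter as numbers).

## Nearest-neighbor thermodynamics (`nn_thermo`)

Hairpin stems are scored with the SantaLucia unified DNA/DNA
nearest-neighbor parameters (ΔH per stack in kcal/mol, ΔS in cal/mol·K,
referenced to 1 M NaCl), shipped as a versioned JSON resource and
overridable by file path. For a perfect stem of *s* base pairs:

    ΔH = Σ stacks + terminal penalties (A·T: +2.3/+4.1; G·C: +0.1/−2.8)
    ΔS = Σ stacks + terminal penalties + 0.368·(s−1)·ln[Mon⁺]

The salt term is the standard entropic correction with the
monovalent-equivalent concentration [Mon⁺] = [Na⁺] + 120·√[Mg²⁺(mM)] mM;
at the default ligase-buffer condition (10 mM Mg²⁺, no added Na⁺) this is
0.38 M. Default evaluation temperature is 25 °C (298.15 K);
R = 1.987×10⁻³ kcal/(mol·K). Temperatures are kelvin internally, celsius
at user-facing interfaces.

Hairpin loops are charged a purely entropic penalty: the loop table stores
ΔG₃₇ increments for loops of 3–30 nt, converted as ΔS = −1000·ΔG₃₇/310.15.
Two deliberate choices:

- **Monotone smoothing.** Published DNA hairpin-loop increments dip at
  loop 5 (3.3 vs 3.5 kcal/mol at loop 4). The shipped table flattens
  loops 3–5 at 3.5 so the loop penalty is non-decreasing in loop length —
  a property the scanner and its tests rely on, costing at most
  0.2 kcal/mol for 5-nt loops.
- **Long loops** extrapolate logarithmically (Jacobson–Stockmayer form):
  ΔG(n) = ΔG(30) + 1.75·R·T·ln(n/30).

An A·T pair closing the loop carries an extra 0.5 kcal/mol (entropic, like
the loop). The unimolecular melting temperature is Tm = 1000·ΔH/ΔS K; it
is reported as undefined (a distinct error) when ΔS ≥ 0.

Only perfect Watson–Crick stems are modeled — no G·T wobbles, mismatches,
bulges or dangling ends. This keeps the model analyzable but makes it
conservative relative to full minimum-free-energy folders (Mfold-style),
which add dangling-end stacking worth roughly 0.5–1 kcal/mol per helix
end: for marginal geometries (e.g. a 4-bp stem with an 11-nt loop) this
engine can classify as borderline what an MFE folder calls comfortably
stable. No bit-compatibility with any MFE server is attempted; the
equilibrium module accepts ΔG as an explicit input precisely so that
predictions can be decoupled from the folding engine.

## Hairpin enumeration (`hairpin_scan`)

`find_hairpins` reports every **maximal** perfect-stem hairpin with
stem ≥ 3 bp and 3 ≤ loop ≤ 30 nt (defaults; loop ceiling of 30 covers
practical loops with headroom). Maximal means the stem can be extended
neither outward nor inward with a valid pair — nested sub-stems of one
helix are not double-reported. The implementation anchors on the outermost
pair and grows the stem inward greedily; it is tested for exact set
equality against an independent brute-force enumeration of all
(start, stem, loop) triples. Output is sorted by ascending ΔG with
deterministic tie-breaking by (start, stem length). Coordinates are
1-based and inclusive, `start` on the 5′-most paired base.

`assign_structure` selects a non-overlapping subset greedily in
ascending-ΔG order. This is a deterministic stand-in for an MFE fold: it
is exact when helices are disjoint (the designed use case) and may differ
from an MFE server on sequences with competing overlapping helices, which
is acceptable here — the design rules only need the terminal hairpin and
its energy.

## Design rules and rotation scan (`ring_design`)

An n-nt ring yields n precursors (offsets 0..n−1); all cyclize to the same
ring, so the scission point is free. For each rotation, each hairpin is
evaluated on both sides; the terminus distance is `start − 1` (5′ side) or
`n − end` (3′ side), counting the unpaired nucleotides between terminus
and stem. Thresholds (all configurable via `DesignRules`):

| rule | default | rationale |
|---|---|---|
| distance | 1–3 nt | selectivity stays ~90% at 1–3 nt and drops at 4–5 nt |
| ΔG ceiling | ≤ −3.0 kcal/mol | minimum stability for effective suppression |
| Tm floor | ≥ 50 °C | same screen threshold |
| Tm ceiling | ≤ 80 °C | over-stable hairpins (~85 °C) slow ligation and erode selectivity; the ceiling sits between the observed good (73 °C) and degraded (85 °C) cases |
| splint arm | 6 nt | 12-nt splint, 6 nt per terminus |
| length warning | < 44 nt | small rings cyclize with poor selectivity |

Distance 0 (stem starting directly at the terminus) is accepted only under
`allow_distance_zero`: such designs have worked in practice but were never
isolated experimentally from confounding refolding, so the strict window
starts at 1. An optional `require_splint_overlap` flag additionally demands
that the stem reach into the 6-nt splint-binding region; it is off by
default because terminus sequestration is a mechanistic conjecture, not an
established rule.

Passing candidates carry the splint — reverse complement of (last 6 nt ++
first 6 nt), juxtaposing the termini across the nick — and the equilibrium
prediction, and are ranked by predicted maximum preparative concentration
(descending), then more negative ΔG, then offset. Failures within
`d_max + 3` nt of a terminus are returned as near-misses with per-rule
flags and narrated at INFO logging, so an empty pass list still explains
itself. The scan is rotation-invariant by construction (each rotation is
scanned independently); this is verified exhaustively in the tests.

## Two-state equilibrium (`equilibrium`)

K = [folded]/[open] = exp(−ΔG/RT), with ΔG the *folding* free energy
(negative for stable hairpins). Open form = total/(1+K) exactly; maximum
preparative total = threshold·(1+K) is its inverse, so the round-trip is
an identity. The high-selectivity classifier is the single empirical
anchor: open form ≤ 0.1 μM predicts >85% ring selectivity (boundary
inclusive). No continuous selectivity-vs-concentration curve is invented.
K is always propagated unrounded — pre-rounding K to 210 before dividing
100 μM by (1+K) gives 0.474 μM instead of the correct 0.480 μM.
Caveats attached to every report: DNA length, splint length, reaction
temperature and diluted-buffer effects are real but unmodeled.

## Fragment screen (`screen`)

Classifies fragments by existence of ≥1 hairpin with Tm > 50 °C and
−ΔG > 3 kcal/mol (strict inequalities), position-independent — a ring can
always be rotated to put an existing hairpin at the terminus. The shipped
generator draws i.i.d. bases with a per-base GC probability (numpy PCG64,
seedable; identical FASTA bytes per seed).

What this does and does not emulate: uniform-random fragments lack genomic
composition (repeats, GC skew, CpG structure), and this engine lacks
dangling-end stabilization. Consequently the *absolute* positive fractions
on random fragments (~7% at 100 nt, ~2% at 50 nt with the defaults) are
far below what an MFE folder reports on genomic fragments (~70%/~40%);
only the qualitative ordering — longer fragments are positive at least as
often — is asserted, as a one-sided seeded trend. Passing that trend says
nothing quantitative about genomic DNA. Relaxed thresholds can be explored
through the CLI options; no default claim is made for them.

## Gel quantification (`gel_quant`)

From band intensities C (circular monomer), P (polymeric byproducts,
linear and multi-cyclic pooled) and R (remaining substrate):
conversion = (1 − R/(C+P+R))·100, selectivity = C/(C+P)·100,
yield = C/(C+P+R)·100, giving yield = selectivity·conversion/100 exactly
and scale invariance in all three. Whether remaining substrate belongs in
the selectivity denominator varies between conventions; the definition
used here (ligated products only) is the one consistent with the yield
identity above. A lane with no ligated product raises a distinct
"undefined selectivity" error rather than returning 0%.

## Synthetic demonstration sequences (`examples`)

The demo rings are constructed, not genomic, and are built from
non-interacting alphabets (GC-only stems, T/C loops, A/C filler) so their
hairpin content is known by construction. The 64-nt ring reproduces the
two-hairpin layout of a terminal-hairpin precursor — terminal hairpin
starting at nt 3 (distance 2) plus an internal hairpin at nt 29 — with a
6-bp stem for the terminal hairpin, chosen so that it clears the stability
window under this conservative engine (a 4-bp/11-nt-loop geometry is
borderline here for the reason given above; 4- and 6-bp stems are equally
canonical for the strategy).

## Problem sizes and numerics

Default test and acceptance runs use: 200 random sequences (≤ 30 nt) for
oracle parity, exhaustive 40-rotation invariance on a 40-nt ring, a
64-rotation design scan, 300 fragments per length for the screen trend and
1000 random lanes for the gel identity — sizes chosen so the whole suite
runs in seconds while every check is exercised at full fidelity.
Floating-point assertions use 1e-9 kcal/mol for energy identities; ties in
rankings are broken deterministically (offset, then side) so reports are
byte-stable.

## Known limitations

- No mismatched/bulged stems, wobble pairs, multiloops or pseudoknots;
  sequences whose real structure is dominated by such motifs will be
  under-folded by this model.
- Single two-state hairpin per terminus: cooperative or competing folds
  are not modeled (the greedy assignment approximates them).
- The 0.1 μM / >85% anchor is a threshold classifier taken from one
  experimental system; transferring it to very different lengths,
  splints or temperatures is an extrapolation.
- Bimolecular splint/precursor hybridization equilibria are not modeled.
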