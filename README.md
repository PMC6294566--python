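# ringforge

Design tool for preparative synthesis of single-stranded DNA rings by
splint-mediated T4 ligation, using the **terminal hairpin strategy**.

## The problem

Cyclizing a linear single-stranded DNA (l-DNA) into its monomeric ring
competes with intermolecular polymerization: at preparative substrate
concentrations the polymeric byproducts normally dominate. The classic fix
— keeping the substrate dilute throughout the reaction — is incompatible
with making useful amounts of material.

A hairpin whose stem begins 1–3 nt from one terminus of the l-DNA solves
this autonomously. The precursor then equilibrates between a **folded**
form (terminus sequestered in the stem, unreactive) and an **open** form
(ligase-reactive). For hairpin folding free energy ΔG < 0 the equilibrium
constant

&nbsp;&nbsp;&nbsp;&nbsp;*K* = [folded]/[open] = exp(−ΔG/RT)

is large, so the reactive species sits at [open] = total/(1 + *K*): "high
dilution conditions" are met even when all substrate is added in one
portion. Because every circular permutation of a ring cyclizes to the same
ring, the scission point is a free design parameter — `ringforge` scans all
of them and picks rotations whose terminal hairpin satisfies:

- **position**: 1–3 unpaired nt between terminus and first stem base;
- **stability**: ΔG ≤ −3 kcal/mol and 50 °C ≤ Tm ≤ 80 °C (stable enough
  to suppress polymerization, not so stable that ligation stalls).

Each passing rotation gets its 12-nt splint (reverse complement of the
joined 3′+5′ hexamers) and a predicted **maximum preparative
concentration** = 0.1 μM · (1 + *K*), the largest total concentration
keeping the open form at or below the 0.1 μM ceiling associated with high
(>85%) ring selectivity.

Hairpin energetics use the SantaLucia unified nearest-neighbor parameters
with hairpin-loop increments, an entropic salt correction for the ligase
buffer (10 mM Mg²⁺), and the unimolecular melting temperature
Tm = 1000·ΔH/ΔS − 273.15 (no concentration term). See `docs/methods.md`
for the model in full.

## Worked example

The two-state prediction for a hairpin with ΔG = −3.16 kcal/mol at 25 °C:

```sh
$ ringforge equilibrium --dg -3.16 --total 5
{
  "K": 207.2689194280584,
  "fraction_open": 0.0048014845553823815,
  "max_total_uM": 20.826891942805844,
  "open_conc_uM": 0.024007422776911907,
  "open_threshold_uM": 0.1,
  "predicted_high_selectivity": true,
  "temperature_K": 298.15,
  "total_conc_uM": 5.0
}
```

*K* ≈ 210: at 5 μM total only 0.024 μM of the precursor is ligase-reactive,
so intramolecular cyclization dominates, and the substrate can be taken up
to ~20 μM before the open form exceeds the 0.1 μM ceiling.

Designing precursors for a synthetic 64-nt demonstration ring (shipped as
`ringforge.examples.demo_ring_64()`, here written to `demo64.fa`):

```sh
$ ringforge design --ring demo64.fa --total-conc 5 --out cand.tsv
6 passing candidate(s), 354 near-miss(es) -> cand.tsv

$ head -6 cand.tsv   # comments trimmed
offset  side  distance  stem_len  loop_len  dG_kcal_mol  tm_C  splint_seq    K          open_conc_uM  max_conc_uM  pass_flags
0       5'    2         6         11        -4.659       58.6  CGGCTTGTTTGT  2601.5131  0.0019        260.251      distance=ok;stability=ok;tm_window=ok
1       5'    1         6         11        -4.659       58.6  GCGGCTTGTTTG  2601.5131  0.0019        260.251      distance=ok;stability=ok;tm_window=ok
26      3'    1         6         11        -4.659       58.6  GGTGTGTGCCGC  2601.5131  0.0019        260.251      distance=ok;stability=ok;tm_window=ok
```

The scan found the ring's one stable hairpin (6-bp stem, 11-nt loop,
ΔG = −4.66 kcal/mol, Tm = 58.6 °C) and kept exactly the six rotations that
place its stem 1–3 nt from a terminus — offset 0 is the precursor whose
stem starts at nt 3 (distance 2 on the 5′ side). Every candidate row
carries the splint to order and the equilibrium predictions at the chosen
total concentration. Rotations that place the stem 4 or more nt from the
terminus appear in the near-miss log with `distance=FAIL`.

Other subcommands: `ringforge scan` (hairpin table for any FASTA),
`ringforge screen` (fraction of fragments bearing a stable hairpin, with a
seedable random-fragment generator), `ringforge quant` (conversion /
selectivity / yield from gel band intensities).

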