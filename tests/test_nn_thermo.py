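"""Nearest-neighbor engine: stack sums, loop penalties, Tm."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from ringforge.nn_thermo import (
    EnergyTriple,
    SequenceError,
    StemError,
    ThermoParams,
    UndefinedTmError,
    hairpin_energy,
    hairpin_tm,
    revcomp,
    stem_energy,
)

PARAMS = ThermoParams.default()
T25 = 298.15


class TestEnergyTriple:
    def test_dG_consistent_with_dH_dS(self):
        e = EnergyTriple(-30.0, -80.0, T25)
        assert abs(e.dG_at_T - (-30.0 + T25 * 80.0 / 1000.0)) < 1e-9

    @given(
        dH=st.floats(-100, 0), dS=st.floats(-300, -1),
        t1=st.floats(250, 350), t2=st.floats(250, 350),
    )
    def test_dG_increases_with_T_when_dS_negative(self, dH, dS, t1, t2):
        lo, hi = sorted((t1, t2))
        assert EnergyTriple(dH, dS, lo).dG_at_T <= EnergyTriple(dH, dS, hi).dG_at_T + 1e-9


class TestStemEnergy:
    def test_gcgc_stem_is_hand_sum_of_table_entries(self):
        """GCGC/revcomp = three stacks GC, CG, GC + two G·C terminal
        penalties + salt entropy, summed by hand from the shipped table."""
        e = stem_energy("GCGC", revcomp("GCGC"), T25, PARAMS)
        dH = PARAMS.stack_dH["GC"] + PARAMS.stack_dH["CG"] + PARAMS.stack_dH["GC"]
        dH += 2 * PARAMS.terminal_dH["GC"]
        dS = PARAMS.stack_dS["GC"] + PARAMS.stack_dS["CG"] + PARAMS.stack_dS["GC"]
        dS += 2 * PARAMS.terminal_dS["GC"]
        mon = 120.0 * math.sqrt(10.0) / 1000.0  # 10 mM Mg2+ -> mol/L equivalent
        dS += 3 * 0.368 * math.log(mon)
        assert e.dH == pytest.approx(dH, abs=1e-12)
        assert e.dS == pytest.approx(dS, abs=1e-12)
        assert e.dG_at_T == pytest.approx(dH - T25 * dS / 1000.0, abs=1e-9)

    def test_matches_biopython_santalucia_stack_table(self):
        """The shipped stack parameters agree entry-for-entry with the
        independently curated SantaLucia table in Biopython."""
        from Bio.SeqUtils.MeltingTemp import DNA_NN3

        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for step in PARAMS.stack_dH:
            key = f"{step}/{comp[step[0]]}{comp[step[1]]}"
            alt = f"{revcomp(step)}/{comp[revcomp(step)[0]]}{comp[revcomp(step)[1]]}"
            ref = DNA_NN3.get(key) or DNA_NN3.get(alt)
            assert ref is not None, f"no Biopython entry for {step}"
            assert PARAMS.stack_dH[step] == pytest.approx(ref[0])
            assert PARAMS.stack_dS[step] == pytest.approx(ref[1])

    @pytest.mark.parametrize(
        "top,bottom,err",
        [
            ("G", "C", StemError),          # 1 bp: no stack exists
            ("GCGC", "GCGA", StemError),    # not reverse complements
            ("GCGC", "GCG", StemError),     # length mismatch
            ("GNGC", "GCNC", SequenceError),
        ],
    )
    def test_invalid_stems_rejected(self, top, bottom, err):
        with pytest.raises(err):
            stem_energy(top, bottom, T25, PARAMS)

    def test_strand_order_symmetry(self):
        rng = random.Random(7)
        for _ in range(20):
            top = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 10)))
            bottom = revcomp(top)
            a = stem_energy(top, bottom, T25, PARAMS)
            b = stem_energy(bottom, top, T25, PARAMS)
            assert a.dH == pytest.approx(b.dH, abs=1e-9)
            assert a.dS == pytest.approx(b.dS, abs=1e-9)


class TestHairpinEnergy:
    STEM = "GCCGCC"
    ARM3 = revcomp(STEM)

    def hairpin(self, loop_len: int) -> str:
        return self.STEM + "T" * loop_len + self.ARM3

    def test_mismatched_arms_rejected(self):
        with pytest.raises(StemError):
            hairpin_energy("GCCGCC" + "TTT" + "GGCGGA", 6, 3, T25, PARAMS)

    def test_loop_below_3_rejected(self):
        with pytest.raises(ValueError):
            hairpin_energy(self.STEM + "TT" + self.ARM3, 6, 2, T25, PARAMS)

    def test_4bp_stem_11nt_loop_structure(self):
        """4-bp stem + 11-nt loop: negative stacking enthalpy, positive
        (destabilizing) loop term, finite triple."""
        seq = "GCCG" + "T" * 11 + "CGGC"
        e = hairpin_energy(seq, 4, 11, T25, PARAMS)
        stem = stem_energy("GCCG", "CGGC", T25, PARAMS)
        assert e.dH < 0
        assert math.isfinite(e.dG_at_T)
        assert e.dG_at_T > stem.dG_at_T  # loop penalty destabilizes

    def test_dG_nondecreasing_in_loop_length(self):
        dgs = [
            hairpin_energy(self.hairpin(n), 6, n, T25, PARAMS).dG_at_T
            for n in range(3, 41)  # through the table and into extrapolation
        ]
        assert all(b >= a - 1e-9 for a, b in zip(dgs, dgs[1:]))

    def test_at_closing_pair_penalized(self):
        gc_close = hairpin_energy("GCCG" + "TTTT" + "CGGC", 4, 4, T25, PARAMS)
        at_close = hairpin_energy("GCCA" + "TTTT" + "TGGC", 4, 4, T25, PARAMS)
        # beyond the stack-composition difference, the A·T closing pair
        # carries an extra loop-closure penalty; check it is applied
        stem_delta = (
            stem_energy("GCCA", "TGGC", T25, PARAMS).dG_at_T
            - stem_energy("GCCG", "CGGC", T25, PARAMS).dG_at_T
        )
        hairpin_delta = at_close.dG_at_T - gc_close.dG_at_T
        assert hairpin_delta > stem_delta + 0.1


class TestHairpinTm:
    def test_tm_depends_only_on_dH_dS_ratio(self):
        for a in (0.5, 1.0, 2.0, 7.3):
            e = EnergyTriple(-59.248 * a, -198.7 * a, T25)
            assert hairpin_tm(e) == pytest.approx(
                1000.0 * 59.248 / 198.7 - 273.15, abs=1e-9
            )

    def test_nested_stems_rank_by_length(self):
        """Stems 4 ⊂ 6 ⊂ 7 bp sharing one loop melt in that order."""
        loop = "TTCTTCT"
        arms = {4: "CGCC", 6: "GCCGCC", 7: "AGCCGCC"}
        tms = {}
        for s, arm in arms.items():
            seq = arm + loop + revcomp(arm)
            tms[s] = hairpin_tm(hairpin_energy(seq, s, len(loop), T25, PARAMS))
        assert tms[4] < tms[6] < tms[7]

    def test_nonnegative_dS_is_an_error(self):
        with pytest.raises(UndefinedTmError):
            hairpin_tm(EnergyTriple(-10.0, 0.0, T25))
        with pytest.raises(UndefinedTmError):
            hairpin_tm(EnergyTriple(-10.0, 5.0, T25))


class TestLoopTable:
    def test_loop_table_monotone_and_positive(self):
        vals = [PARAMS.loop_penalty_dG(n) for n in range(3, 61)]
        assert all(v > 0 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_logarithmic_extrapolation_beyond_table(self):
        g30 = PARAMS.loop_penalty_dG(30)
        g60 = PARAMS.loop_penalty_dG(60)
        expected = g30 + 1.75 * PARAMS.gas_constant * PARAMS.loop_ref_temperature * math.log(2.0)
        assert g60 == pytest.approx(expected, abs=1e-9)

    def test_table_rejects_nonpositive_penalties(self):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(PARAMS, loop_dG37={3: -1.0})
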