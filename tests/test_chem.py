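"""Masses, net charge, isoelectric points and proteoform construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import electrochem as ec

from virtual2de import chem

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=40)


class TestMass:
    def test_glycine_values(self):
        # C2H5NO2 = 75.07 Da average; dipeptide loses one water
        assert chem.mass("G") == pytest.approx(75.07, abs=0.01)
        assert chem.mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_monoisotopic_below_average(self):
        assert chem.mass("PEPTIDE", kind="monoisotopic") < chem.mass("PEPTIDE")

    @given(s1=seqs, s2=seqs)
    @settings(max_examples=50, deadline=None)
    def test_concatenation_additivity_both_scales(self, s1, s2):
        for kind in ("average", "monoisotopic"):
            water = chem.WATER_AVG if kind == "average" else chem.WATER_MONO
            assert chem.mass(s1 + s2, kind=kind) == pytest.approx(
                chem.mass(s1, kind=kind) + chem.mass(s2, kind=kind) - water,
                abs=1e-9,
            )

    def test_modification_deltas(self):
        base = chem.mass("PEPTIDE")
        assert chem.mass("PEPTIDE", [chem.phospho(2)]) == pytest.approx(
            base + 2 * 79.98, abs=1e-9
        )
        g = chem.glyco({"NeuAc": 2, "Hex": 1})
        assert chem.mass("PEPTIDE", [g]) == pytest.approx(
            base + 2 * 291.26 + 162.14, abs=1e-9
        )

    def test_rejects_non_canonical_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            chem.mass("GGXGG")
        with pytest.raises(ValueError, match="empty"):
            chem.mass("")
        for aa in "UOBZX":
            with pytest.raises(ValueError):
                chem.mass(f"AA{aa}")


class TestNetCharge:
    def test_low_ph_limit_glycine(self, bjellqvist):
        assert chem.net_charge("G", pH=0.0, pka_set=bjellqvist) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_half_ionized_carboxyl(self, bjellqvist):
        # at pH = pKa(C-term) the carboxyl is half ionized, amine ~fully on
        q = chem.net_charge("G", pH=3.55, pka_set=bjellqvist)
        assert q == pytest.approx(0.5, abs=1e-3)

    def test_phospho_only_lowers_charge(self, bjellqvist):
        for ph in (2.0, 5.0, 7.0, 10.0):
            assert chem.net_charge("G", [chem.phospho()], ph, bjellqvist) < chem.net_charge(
                "G", [], ph, bjellqvist
            )

    @given(s=seqs)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_ph(self, s):
        grid = np.linspace(0.0, 14.0, 29)
        q = [chem.net_charge(s, pH=p) for p in grid]
        assert all(a > b for a, b in zip(q, q[1:]))

    def test_ph_out_of_range(self):
        with pytest.raises(ValueError):
            chem.net_charge("G", pH=14.5)


class TestIsoelectricPoint:
    def test_two_group_closed_form(self, bjellqvist):
        # one acid + one base: pI = mean of the two pKas
        expected = 0.5 * (3.55 + 7.5)
        assert chem.isoelectric_point("G") == pytest.approx(expected, abs=2e-4)

    def test_bisection_matches_grid_scan_oracle(self, bjellqvist):
        """Bisection equals the argmin of |Q| over a 1e-4 pH grid."""
        from conftest import random_peptides

        grid = np.arange(0.0, 14.0001, 1e-4)
        for seq in random_peptides(25, np.random.default_rng(7)):
            if not (set(seq) & set("DECY")) or not (set(seq) & set("HKR")):
                seq += "DK"  # ensure both group kinds
            groups = chem._ionizable_groups(seq, (), bjellqvist)
            q = np.zeros_like(grid)
            for kind, pka, n in groups:
                if kind == "basic":
                    q += n / (1.0 + 10.0 ** (grid - pka))
                else:
                    q -= n / (1.0 + 10.0 ** (pka - grid))
            oracle = grid[np.argmin(np.abs(q))]
            assert chem.isoelectric_point(seq) == pytest.approx(oracle, abs=2e-4)

    def test_agrees_with_independent_implementation(self):
        """Cross-check the whole charge model against pyteomics."""
        from conftest import random_peptides

        for seq in random_peptides(25, np.random.default_rng(11)):
            ours = chem.isoelectric_point(seq)
            ref = ec.pI(
                seq,
                pK=ec.pK_bjellqvist,
                pK_nterm=ec.pK_nterm_bjellqvist,
                pK_cterm=ec.pK_cterm_bjellqvist,
                precision_pI=1e-4,
            )
            assert ours == pytest.approx(ref, abs=5e-4)

    def test_monotone_in_phosphate_load(self):
        pis = [
            chem.isoelectric_point("ACDEFGHIKLMNPQRSTVWY", [chem.phospho(k)] if k else [])
            for k in range(4)
        ]
        assert all(a > b for a, b in zip(pis, pis[1:]))

    def test_no_sign_change_is_an_error(self):
        # blocking the only amine leaves acidic groups alone: the net
        # charge is negative over the whole pH range, so no pI exists
        with pytest.raises(chem.NoIsoelectricPointError):
            chem.isoelectric_point("G", [chem.acetyl()])


class TestPkaSets:
    def test_all_sets_cover_required_groups(self):
        for name in chem.available_pka_sets():
            s = chem.load_pka_set(name)
            assert set("DECYHKR") <= set(s.side_chain_pkas)
            assert "*" in s.nterm_pkas and "*" in s.cterm_pkas

    def test_unknown_set(self):
        with pytest.raises(KeyError):
            chem.load_pka_set("nosuch")


class TestProteoform:
    def test_mass_invariant_random_mod_lists(self, records):
        rng = np.random.default_rng(5)
        rec = records["P00738"]
        seq = rec.chain_sequence("beta")
        for _ in range(20):
            mods = []
            if rng.random() < 0.8:
                mods.append(chem.phospho(int(rng.integers(1, 5))))
            if rng.random() < 0.5:
                mods.append(chem.glyco({"Hex": 5, "HexNAc": 4, "NeuAc": int(rng.integers(0, 4))}))
            if rng.random() < 0.3:
                mods.append(chem.acetyl())
            pf = chem.make_proteoform(rec, "beta", mods)
            expected = chem.mass(seq) + sum(m.mass_delta("average") for m in mods)
            assert pf.Mw == pytest.approx(expected, abs=1e-6)

    def test_phospho_shifts(self, records):
        rec = records["P00738"]
        plain = chem.make_proteoform(rec, "beta", [])
        mod = chem.make_proteoform(rec, "beta", [chem.phospho()])
        assert mod.Mw - plain.Mw == pytest.approx(79.98, abs=1e-6)
        assert mod.pI < plain.pI

    def test_sialylated_glycan_shifts(self, records):
        rec = records["P00738"]
        plain = chem.make_proteoform(rec, "beta", [])
        g = chem.glyco({"NeuAc": 2, "Hex": 5, "HexNAc": 4})
        mod = chem.make_proteoform(rec, "beta", [g])
        expected_delta = 2 * 291.26 + 5 * 162.14 + 4 * 203.20
        assert mod.Mw - plain.Mw == pytest.approx(expected_delta, abs=1e-6)
        assert mod.pI < plain.pI

    def test_unknown_chain_and_overallocation(self, records):
        rec = records["P02768"]
        with pytest.raises(KeyError):
            chem.make_proteoform(rec, "nosuch")
        limited = chem.ProteinRecord(
            accession="X1", entry_name="X1_TEST", sequence="ACDEFGHIKLMNPQRSTVWY",
            chains=[chem.ChainRange("mature", 1, 20)], site_counts={"phospho": 1},
        )
        with pytest.raises(ValueError, match="exceed"):
            chem.make_proteoform(limited, "mature", [chem.phospho(2)])
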