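"""Axis calibration, section geometry, pattern construction and comparison."""

import numpy as np
import pytest

from virtual2de import mapping as mp
from virtual2de.quantify import ProteinQuant


def quant(acc="P1", section="0", empai=1.0):
    n_obsbl = 10
    return ProteinQuant(accession=acc, section_id=section, n_obs=5,
                        n_obsbl=n_obsbl, pai=0.5, empai=empai)


class TestPiAxis:
    def test_linear_midpoint(self):
        ax = mp.fit_pi_axis([(0.0, 3.0), (18.0, 11.0)])
        assert ax.ph_at(9.0) == pytest.approx(7.0)
        assert ax.ph_at(18.0) == pytest.approx(11.0)  # boundary included

    def test_round_trip_inverse(self):
        ax = mp.fit_pi_axis(mp.NL_3_11_ANCHORS_18CM)
        for pos in np.linspace(0.0, 18.0, 13):
            assert ax.position_at(ax.ph_at(pos)) == pytest.approx(pos, abs=1e-9)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            mp.fit_pi_axis([(0.0, 11.0), (18.0, 3.0)])
        with pytest.raises(ValueError):
            mp.fit_pi_axis([(0.0, 3.0), (0.0, 11.0)])

    def test_extrapolation_forbidden(self):
        ax = mp.fit_pi_axis([(0.0, 3.0), (18.0, 11.0)])
        with pytest.raises(mp.OffGelError):
            ax.ph_at(18.1)
        with pytest.raises(mp.OffGelError):
            ax.position_at(2.9)


class TestMwAxis:
    def test_geometric_mean_between_markers(self):
        ax = mp.fit_mw_axis([(0.2, 100_000.0), (0.8, 10_000.0)])
        assert ax.mw_at(0.5) == pytest.approx(31_623, rel=1e-4)

    def test_interpolates_through_two_markers(self):
        ax = mp.fit_mw_axis([(0.2, 100_000.0), (0.8, 10_000.0)])
        assert ax.mw_at(0.2) == pytest.approx(100_000.0, rel=1e-9)
        assert ax.migration_at(10_000.0) == pytest.approx(0.8, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            mp.fit_mw_axis([(0.5, 50_000.0)])
        with pytest.raises(ValueError):
            mp.fit_mw_axis([(0.5, 50_000.0), (0.5, 20_000.0)])
        with pytest.raises(ValueError):  # inverted ladder -> positive slope
            mp.fit_mw_axis([(0.2, 10_000.0), (0.8, 100_000.0)])


class TestSections:
    def test_strip36_assignment(self, strip_scheme):
        assert mp.locate_section(strip_scheme, 0.75) == (0, 1)
        assert mp.locate_section(strip_scheme, 0.5) == (0, 1)  # boundary -> higher
        assert mp.locate_section(strip_scheme, 18.0) == (0, 35)  # final closed

    def test_off_gel(self, strip_scheme):
        with pytest.raises(mp.OffGelError):
            mp.locate_section(strip_scheme, -0.01)
        with pytest.raises(mp.OffGelError):
            mp.locate_section(strip_scheme, 18.01)

    def test_grid_partitions_plane(self):
        scheme = mp.grid96_scheme((3.0, 11.0), (10_000.0, 250_000.0))
        assert scheme.n_rows * scheme.n_cols == 96
        rng = np.random.default_rng(1)
        # exhaustive-ish audit: every in-range point maps to exactly one section
        for x in np.r_[np.linspace(3.0, 11.0, 41), rng.uniform(3, 11, 50)]:
            for y in np.r_[10_000.0, 250_000.0, rng.uniform(10_000, 250_000, 3)]:
                row, col = mp.locate_section(scheme, float(x), float(y))
                lo, hi = scheme.col_window(col)
                assert lo <= x < hi or (x == scheme.col_edges[-1] and hi == x)
                rlo, rhi = scheme.row_window(row)
                assert rlo <= y < rhi or (y == scheme.row_edges[-1] and rhi == y)

    def test_section_id_round_trip(self, strip_scheme):
        scheme = mp.grid96_scheme((3.0, 11.0), (10_000.0, 250_000.0))
        for sch in (strip_scheme, scheme):
            for r in range(sch.n_rows):
                for c in range(sch.n_cols):
                    assert sch.parse_section_id(sch.section_id(r, c)) == (r, c)


class TestBuildPattern:
    def test_empty_quant_list(self, strip_scheme, strip_axis):
        pat = mp.build_pattern([], strip_scheme, pi_axis=strip_axis, theoretical_mw={})
        assert pat.spots == []

    def test_strip_mode_uses_theoretical_mw(self, strip_scheme, strip_axis):
        quants = [quant("HPT:alpha2", "5", 2.0), quant("HPT:beta", "5", 3.0)]
        mw = {"HPT:alpha2": 15_946.0, "HPT:beta": 27_265.0}
        pat = mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis, theoretical_mw=mw)
        got = {s.accession: s.mw_value for s in pat.spots}
        assert got == mw

    def test_missing_theoretical_mw_names_accession(self, strip_scheme, strip_axis):
        with pytest.raises(ValueError, match="P1"):
            mp.build_pattern([quant()], strip_scheme, pi_axis=strip_axis, theoretical_mw={})

    def test_conservation_of_total_empai(self, strip_scheme, strip_axis):
        rng = np.random.default_rng(9)
        quants = [
            quant("P1", str(int(s)), float(e))
            for s, e in zip(rng.integers(0, 36, 12), rng.exponential(2.0, 12))
        ]
        # collapse duplicate sections the way an upstream quantifier would
        seen = {}
        for q in quants:
            seen[q.section_id] = q
        quants = list(seen.values())
        pat = mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis,
                               theoretical_mw={"P1": 30_000.0})
        assert pat.total_empai() == pytest.approx(sum(q.empai for q in quants))

    def test_grid_mode_mw_is_row_midpoint(self):
        scheme = mp.grid96_scheme((3.0, 11.0), (10_000.0, 250_000.0))
        q = quant(section="2-7", empai=1.5)
        pat = mp.build_pattern([q], scheme)
        rlo, rhi = scheme.row_window(2)
        assert pat.spots[0].mw_value == pytest.approx(np.sqrt(rlo * rhi))
        assert pat.spots[0].pi_window == scheme.col_window(7)

    def test_duplicate_spot_rejected(self, strip_scheme, strip_axis):
        qs = [quant(section="4"), quant(section="4")]
        with pytest.raises(ValueError, match="more than one spot"):
            mp.build_pattern(qs, strip_scheme, pi_axis=strip_axis,
                             theoretical_mw={"P1": 1000.0})


class TestSpotExtent:
    def test_single_spot_zero_width(self, strip_scheme, strip_axis):
        pat = mp.build_pattern([quant(section="10")], strip_scheme, pi_axis=strip_axis,
                               theoretical_mw={"P1": 30_000.0})
        lo, hi, mlo, mhi = mp.spot_extent(pat, "P1")
        assert mlo == mhi == 30_000.0
        assert (lo, hi) == pat.spots[0].pi_window

    def test_strip_section_arithmetic(self, strip_scheme, strip_axis):
        # sections 0..11 of a linear pH 3-11 gradient over 18 cm:
        # 12 x 0.5 cm = 6 cm, i.e. one third of an 8-pH-unit span
        quants = [quant(section=str(c)) for c in range(12)]
        pat = mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis,
                               theoretical_mw={"P1": 30_000.0})
        lo, hi, *_ = mp.spot_extent(pat, "P1")
        assert lo == pytest.approx(3.0)
        assert hi == pytest.approx(3.0 + 8.0 * 6.0 / 18.0)

    def test_invariant_under_permutation(self, strip_scheme, strip_axis):
        quants = [quant(section=str(c)) for c in (3, 17, 9)]
        pat1 = mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis,
                                theoretical_mw={"P1": 30_000.0})
        pat2 = mp.build_pattern(quants[::-1], strip_scheme, pi_axis=strip_axis,
                                theoretical_mw={"P1": 30_000.0})
        assert mp.spot_extent(pat1, "P1") == mp.spot_extent(pat2, "P1")

    def test_absent_accession(self, strip_scheme, strip_axis):
        pat = mp.build_pattern([], strip_scheme, pi_axis=strip_axis, theoretical_mw={})
        with pytest.raises(KeyError):
            mp.spot_extent(pat, "P1")


class TestComparePatterns:
    def _pattern(self, empais, strip_scheme, strip_axis):
        quants = [quant("P1", str(c), e) for c, e in empais.items()]
        return mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis,
                                theoretical_mw={"P1": 30_000.0})

    def test_self_comparison_all_zero(self, strip_scheme, strip_axis):
        a = self._pattern({3: 1.0, 4: 2.0, 5: 0.5}, strip_scheme, strip_axis)
        cmp_ = mp.compare_patterns(a, a)
        assert len(cmp_.matched) == 3
        assert not cmp_.unmatched_a and not cmp_.unmatched_b
        assert all(r == 0.0 for _, _, r in cmp_.matched)

    def test_doubling_gives_log2_one(self, strip_scheme, strip_axis):
        a = self._pattern({3: 1.0, 4: 2.0}, strip_scheme, strip_axis)
        b = self._pattern({3: 2.0 + 0.01, 4: 4.0 + 0.03 - 0.02}, strip_scheme, strip_axis)
        # emPAI_b chosen so (a + c)/(b + c) is exactly 1/2 with c = 0.01
        cmp_ = mp.compare_patterns(a, b)
        assert [round(r, 10) for *_, r in cmp_.matched] == [-1.0, -1.0]

    def test_disjoint_accessions_unmatched(self, strip_scheme, strip_axis):
        a = self._pattern({3: 1.0}, strip_scheme, strip_axis)
        quants = [quant("P2", "3", 1.0)]
        b = mp.build_pattern(quants, strip_scheme, pi_axis=strip_axis,
                             theoretical_mw={"P2": 30_000.0})
        cmp_ = mp.compare_patterns(a, b)
        assert not cmp_.matched
        assert len(cmp_.unmatched_a) == 1 and len(cmp_.unmatched_b) == 1
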