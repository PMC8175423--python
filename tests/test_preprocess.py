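import numpy as np
import pytest

from voctrait.datamodel import CompoundRecord, EmissionMatrix, ValidationError
from voctrait.preprocess import (
    DEFAULT_GC_ACCUMULATION_MIN,
    DEFAULT_PTR_ACCUMULATION_MIN,
    SensitivityTable,
    area_time_normalize,
    flag_isotopologues,
    group_fragments,
    internal_standard_normalize,
    kovats_ri,
    ncps_to_pmol,
    normalize_reagent_ions,
    subtract_background,
)


class TestReagentNormalization:
    def test_direct_formula(self):
        assert normalize_reagent_ions(500.0, 2e6) == pytest.approx(250.0)

    def test_zero_maps_to_zero_and_elementwise(self):
        out = normalize_reagent_ions(np.array([0.0, 500.0, 1000.0]), 2e6)
        np.testing.assert_allclose(out, [0.0, 250.0, 500.0])

    def test_nonpositive_reagent_rejected(self):
        with pytest.raises(ValidationError):
            normalize_reagent_ions(1.0, 0.0)


class TestBackgroundSubtraction:
    def test_constant_background(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        out = subtract_background([1.5], [12.0], t, np.full(4, 5.0))
        assert out[0] == pytest.approx(7.0)

    def test_negative_clipped_to_zero(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        out = subtract_background([1.0], [2.0], t, np.full(4, 5.0))
        assert out[0] == 0.0

    def test_spline_through_collinear_points_is_the_line(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        out = subtract_background([1.5], [2.5], t, t.copy())
        assert out[0] == pytest.approx(1.0)  # 2.5 - b(1.5)=1.5

    def test_too_few_background_points(self):
        with pytest.raises(ValidationError, match="4"):
            subtract_background([0.5], [1.0], [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])


class TestAreaTimeNormalization:
    def test_direct_formula(self):
        assert area_time_normalize(140.0, 2.0, 70.0) == pytest.approx(1.0)

    def test_doubling_area_halves_result(self):
        one = area_time_normalize(10.0, 1.0, 5.0)
        assert area_time_normalize(10.0, 2.0, 5.0) == pytest.approx(one / 2)

    def test_platform_default_accumulation_times(self):
        assert DEFAULT_PTR_ACCUMULATION_MIN == 70.0
        assert DEFAULT_GC_ACCUMULATION_MIN == 960.0  # 16 h collection

    def test_nonpositive_divisors_rejected(self):
        with pytest.raises(ValidationError):
            area_time_normalize(1.0, 0.0, 70.0)


class TestNcpsToPmol:
    def test_known_sensitivity_converted(self):
        table = SensitivityTable({"c1": 10.0})
        out, flagged = ncps_to_pmol(np.array([[20.0]]), ["c1"], table)
        assert out[0, 0] == pytest.approx(2.0)
        assert flagged == []

    def test_missing_sensitivity_flagged_not_dropped(self):
        table = SensitivityTable({"c1": 10.0})
        out, flagged = ncps_to_pmol(np.array([[20.0, 7.0]]), ["c1", "c2"], table)
        assert out[0, 1] == pytest.approx(7.0)
        assert flagged == ["c2"]

    def test_monotone_in_ncps(self):
        table = SensitivityTable({"c1": 3.0})
        lo, _ = ncps_to_pmol(np.array([[1.0]]), ["c1"], table)
        hi, _ = ncps_to_pmol(np.array([[2.0]]), ["c1"], table)
        assert hi[0, 0] > lo[0, 0]

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(ValidationError):
            SensitivityTable({"c1": 0.0})


def _ptr_matrix(values, compound_ids):
    values = np.asarray(values, dtype=float)
    return EmissionMatrix(values, "PTR",
                          tuple((f"sp{i + 1:02d}", 1) for i in range(values.shape[0])),
                          tuple(compound_ids), "ncps_cm-2_s-1")


class TestIsotopologueFlagging:
    def _records(self, mzs, ids):
        return {i: CompoundRecord(compound_id=i, platform="PTR", mz=m)
                for i, m in zip(ids, mzs)}

    def test_carbon13_satellite_flagged(self):
        ids = ["parent", "satellite"]
        recs = self._records([59.049, 60.0524], ids)
        matrix = _ptr_matrix(np.array([[100.0, 3.3]] * 3), ids)
        out = flag_isotopologues(recs, matrix)
        assert out["satellite"].is_isotopologue
        assert not out["parent"].is_isotopologue

    def test_no_mass_pair_within_tolerance(self):
        ids = ["a", "b"]
        recs = self._records([59.049, 61.50], ids)
        matrix = _ptr_matrix(np.array([[100.0, 3.3]] * 3), ids)
        out = flag_isotopologues(recs, matrix)
        assert not any(r.is_isotopologue for r in out.values())

    def test_abundance_far_from_expectation_not_flagged(self):
        ids = ["parent", "big"]
        recs = self._records([59.049, 60.0524], ids)
        matrix = _ptr_matrix(np.array([[100.0, 90.0]] * 3), ids)  # ratio 0.9 >> 4.4%
        out = flag_isotopologues(recs, matrix)
        assert not out["big"].is_isotopologue

    def test_abundance_check_can_be_disabled(self):
        ids = ["parent", "big"]
        recs = self._records([59.049, 60.0524], ids)
        matrix = _ptr_matrix(np.array([[100.0, 90.0]] * 3), ids)
        out = flag_isotopologues(recs, matrix, check_abundance=False)
        assert out["big"].is_isotopologue


class TestFragmentGrouping:
    def test_proportional_columns_share_group(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=10)
        matrix = _ptr_matrix(np.column_stack([x, 3 * x, rng.lognormal(size=10)]),
                             ["a", "b", "c"])
        groups = group_fragments(matrix)
        assert groups.get("a") == groups.get("b")
        assert "c" not in groups

    def test_independent_noise_distinct(self):
        rng = np.random.default_rng(1)
        matrix = _ptr_matrix(rng.lognormal(size=(50, 5)), list("abcde"))
        assert group_fragments(matrix) == {}

    def test_transitive_components(self):
        # A and C each correlate with B but barely with each other
        n = 200
        rng = np.random.default_rng(2)
        b = rng.normal(size=n)
        a = b + rng.normal(scale=0.1, size=n)
        c = -b + rng.normal(scale=0.1, size=n)
        shift = 10.0  # keep nonnegative
        matrix = _ptr_matrix(np.column_stack([a, b, c]) + shift, ["A", "B", "C"])
        groups = group_fragments(matrix, r2_threshold=0.9)
        assert groups["A"] == groups["B"] == groups["C"]

    def test_constant_column_gets_no_edges(self):
        matrix = _ptr_matrix(np.column_stack([np.full(5, 2.0), np.arange(5.0)]),
                             ["const", "x"])
        assert group_fragments(matrix) == {}


class TestKovatsIndex:
    ALKANES = {n: float(n) for n in range(9, 26)}  # rt = carbon number, minutes

    def test_exact_at_alkane(self):
        assert kovats_ri(12.0, self.ALKANES) == pytest.approx(1200.0)

    def test_interpolated_case(self):
        assert kovats_ri(11.0, {10: 10.0, 11: 12.0}) == pytest.approx(1050.0)

    def test_strictly_increasing_in_rt(self):
        rts = np.linspace(9.0, 25.0, 40)
        ris = [kovats_ri(t, self.ALKANES) for t in rts]
        assert all(b > a for a, b in zip(ris, ris[1:]))

    def test_no_extrapolation(self):
        with pytest.raises(ValidationError, match="span"):
            kovats_ri(26.0, self.ALKANES)

    def test_inverse_interpolation_round_trip(self):
        alkanes = {n: 1.5 * n + 0.3 for n in range(9, 26)}
        for rt in [14.0, 20.05, 31.2]:
            ri = kovats_ri(rt, alkanes)
            # invert: find bracketing carbons and solve the linear form
            n0 = int(ri // 100)
            frac = ri / 100.0 - n0
            back = alkanes[n0] + frac * (alkanes[n0 + 1] - alkanes[n0])
            assert back == pytest.approx(rt, abs=1e-9)


class TestInternalStandard:
    def test_reference_match_unchanged(self):
        np.testing.assert_allclose(
            internal_standard_normalize(np.array([3.0, 4.0]), 10.0, 10.0),
            [3.0, 4.0])

    def test_half_standard_doubles_areas(self):
        np.testing.assert_allclose(
            internal_standard_normalize(np.array([3.0]), 5.0, 10.0), [6.0])

    def test_idempotent_once_normalized(self):
        once = internal_standard_normalize(np.array([3.0]), 5.0, 10.0)
        again = internal_standard_normalize(once, 10.0, 10.0)
        np.testing.assert_allclose(again, once)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValidationError):
            internal_standard_normalize(np.array([1.0]), 0.0, 10.0)


def test_full_ptr_chain_is_nonnegative():
    rng = np.random.default_rng(3)
    cps = rng.lognormal(size=20)
    ncps = normalize_reagent_ions(cps, 1.7e6)
    t = np.linspace(0, 10, 20)
    bg_t = np.linspace(0, 10, 8)
    corrected = subtract_background(t, ncps, bg_t, np.full(8, float(np.median(ncps))))
    final = area_time_normalize(corrected, 2.0, 70.0)
    assert (final >= 0).all()
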