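import math

import numpy as np
import pytest

from redlistrf import (
    AttributeSpec,
    NOT_APPLICABLE,
    ValidationError,
    bin_ordinal,
    commonness,
    dummy_expand,
    filter_attributes,
    phi_coefficient,
    specialization,
)


def brute_force_equalized_phi(presence, groups, target_group):
    """Independent oracle: classical 2×2 phi on the group-size-equalized
    contingency table (every site replicated so all groups reach the LCM
    of the group sizes)."""
    groups = np.asarray(groups, dtype=object)
    presence = np.asarray(presence)
    names = sorted(set(groups.tolist()))
    sizes = {g: int((groups == g).sum()) for g in names}
    lcm = 1
    for s in sizes.values():
        lcm = lcm * s // math.gcd(lcm, s)
    a = b = c = d = 0  # a: in-group & present, etc., with replication weights
    for g in names:
        w = lcm // sizes[g]
        pres = int(presence[groups == g].sum())
        abs_ = sizes[g] - pres
        if g == target_group:
            a += w * pres
            b += w * abs_
        else:
            c += w * pres
            d += w * abs_
    num = a * d - b * c
    den = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return num / den if den else 0.0


class TestPhi:
    def test_perfect_indicator(self):
        presence = np.array([1, 1, 1, 0, 0, 0])
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        prof = phi_coefficient(presence, groups)
        assert prof.phi == pytest.approx([1.0, -1.0])

    def test_ubiquitous_species_has_no_preference(self):
        prof = phi_coefficient(np.ones(8), np.array(["a"] * 4 + ["b"] * 4))
        assert prof.phi == pytest.approx([0.0, 0.0])
        prof = phi_coefficient(np.zeros(8), np.array(["a"] * 4 + ["b"] * 4))
        assert prof.phi == pytest.approx([0.0, 0.0])

    def test_unequal_groups_worked_example(self):
        # n = (4, 6), occupied = (3, 1): f = (0.75, 1/6), f̄ = 0.458333
        presence = np.array([1, 1, 1, 0] + [1, 0, 0, 0, 0, 0])
        groups = np.array(["g1"] * 4 + ["g2"] * 6)
        prof = phi_coefficient(presence, groups)
        assert prof.phi[0] == pytest.approx(0.585369, abs=1e-6)
        oracle = brute_force_equalized_phi(presence, groups, "g1")
        assert prof.phi[0] == pytest.approx(oracle, abs=1e-12)

    def test_matches_bruteforce_on_random_rows(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            K = int(rng.integers(2, 5))
            sizes = rng.integers(2, 9, size=K)
            groups = np.repeat([f"g{k}" for k in range(K)], sizes)
            presence = rng.integers(0, 2, size=sizes.sum())
            prof = phi_coefficient(presence, groups)
            for k, g in enumerate(prof.groups):
                oracle = brute_force_equalized_phi(presence, groups, g)
                assert prof.phi[k] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_within_group_duplication(self):
        rng = np.random.default_rng(7)
        groups = np.array(["a"] * 5 + ["b"] * 3 + ["c"] * 4)
        presence = rng.integers(0, 2, size=12)
        base = phi_coefficient(presence, groups)
        doubled = phi_coefficient(
            np.concatenate([presence, presence]), np.concatenate([groups, groups])
        )
        assert base.phi == pytest.approx(doubled.phi, abs=1e-12)

    def test_complement_antisymmetry_equal_groups(self):
        rng = np.random.default_rng(3)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        presence = rng.integers(0, 2, size=12)
        if presence.mean() in (0.0, 1.0):
            presence[0] = 1 - presence[0]
        base = phi_coefficient(presence, groups)
        comp = phi_coefficient(1 - presence, groups)
        assert comp.phi == pytest.approx(-base.phi, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            phi_coefficient(np.array([1, 0]), np.array(["a", "a"]))


class TestSpecialization:
    def test_zero_profile(self):
        prof = phi_coefficient(np.ones(4), np.array(["a", "a", "b", "b"]))
        assert specialization(prof) == 0.0

    def test_perfect_two_group_profile(self):
        prof = phi_coefficient(
            np.array([1, 1, 0, 0]), np.array(["a", "a", "b", "b"])
        )
        assert specialization(prof) == pytest.approx(math.sqrt(2.0))

    def test_worked_example(self):
        presence = np.array([1, 1, 1, 0] + [1, 0, 0, 0, 0, 0])
        groups = np.array(["g1"] * 4 + ["g2"] * 6)
        assert specialization(phi_coefficient(presence, groups)) == pytest.approx(
            0.827838, abs=1e-6
        )


class TestCommonness:
    def test_midpoint_is_zero(self):
        assert commonness(50, 100) == pytest.approx(0.0)

    def test_quarter_closed_form(self):
        assert commonness(25, 100) == pytest.approx(math.log(25.5 / 75.5), abs=1e-12)
        assert commonness(25, 100) == pytest.approx(-1.085454, abs=1e-6)

    def test_endpoints_finite(self):
        lo = commonness(0, 100)
        hi = commonness(100, 100)
        assert lo == pytest.approx(-5.303305, abs=1e-6)
        assert math.isfinite(lo) and math.isfinite(hi)
        assert hi == pytest.approx(-lo, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            commonness(1, 0)
        with pytest.raises(ValidationError):
            commonness(5, 4)


class TestBinOrdinal:
    def test_equal_width_bins(self):
        out = bin_ordinal(np.arange(10.0))
        assert out[0] == 0 and out[-1] == 4
        # width 1.8: values 0,1 -> bin 0; value 9 -> top bin
        assert out[1] == 0 and out[2] == 1

    def test_log_makes_decades_uniform(self):
        out = bin_ordinal(np.array([1.0, 10.0, 100.0, 1000.0, 10000.0]), use_log=True)
        assert list(out) == [0, 1, 2, 3, 4]

    def test_missing_preserved(self):
        out = bin_ordinal(np.array([0.0, np.nan, 5.0, 10.0]))
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2, 3]]).any()

    def test_monotone_in_input(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=200)
        out = bin_ordinal(v)
        order = np.argsort(v)
        assert (np.diff(out[order]) >= 0).all()

    def test_constant_vector_errors(self):
        with pytest.raises(ValidationError):
            bin_ordinal(np.full(5, 3.0))

    def test_interior_edge_goes_to_lower_bin(self):
        # edges at 0,1,2,3,4,5: the value 1.0 sits on an edge -> bin 0
        out = bin_ordinal(np.array([0.0, 1.0, 5.0]))
        assert out[1] == 0


class TestDummyExpand:
    @pytest.fixture
    def water_spec(self):
        return AttributeSpec(
            name="water", kind="binary", n_categories=2,
            labels=("stagnant", "running"), derivation="dummy",
        )

    def test_not_applicable_gets_all_zeros(self, water_spec):
        out = dummy_expand(["stagnant", NOT_APPLICABLE, "running"], water_spec)
        assert list(out.loc[1]) == [0.0, 0.0]

    def test_level_membership(self, water_spec):
        out = dummy_expand(["running"], water_spec)
        assert list(out.loc[0]) == [0.0, 1.0]

    def test_missing_stays_missing_in_every_dummy(self, water_spec):
        out = dummy_expand(["stagnant", float("nan")], water_spec)
        assert out.loc[1].isna().all()

    def test_unknown_level_errors(self, water_spec):
        with pytest.raises(ValidationError):
            dummy_expand(["swimming"], water_spec)


class TestFilterAttributes:
    def _table(self, values, kinds=None):
        import numpy as np
        from redlistrf import SpeciesTable

        n, p = values.shape
        specs = [
            AttributeSpec(name=f"a{j}", kind=(kinds[j] if kinds else "ordinal"),
                          n_categories=5)
            for j in range(p)
        ]
        return SpeciesTable(
            species_ids=[f"s{i}" for i in range(n)],
            kingdom=np.array(["animalia"] * n, dtype=object),
            group=np.array(["aves"] * n, dtype=object),
            values=values,
            specs=specs,
        )

    def test_dominant_category_dropped(self):
        values = np.zeros((200, 2), dtype=np.int16)
        values[0, 0] = 1          # a0: 199/200 = 0.995 in one category
        values[:100, 1] = 1       # a1: balanced
        table = self._table(values)
        kept, report = filter_attributes(table)
        assert kept.attribute_names == ["a1"]
        row = report[report.attribute == "a0"].iloc[0]
        assert row.rule == "dominant_category"
        assert row.fraction == pytest.approx(0.995)

    def test_missing_boundary_strict(self):
        values = np.ones((100, 2), dtype=np.int16)
        values[:50, 0] = 0
        values[:50, 1] = 0
        values[:25, 0] = -1       # exactly 25 % missing: retained
        values[:26, 1] = -1       # 26 % missing: dropped
        kept, report = filter_attributes(self._table(values))
        assert kept.attribute_names == ["a0"]
        assert report.iloc[0].rule == "missing"

    def test_idempotent(self, default_dataset):
        table, _, _ = default_dataset
        once, _ = filter_attributes(table)
        twice, report = filter_attributes(once)
        assert twice.attribute_names == once.attribute_names
        assert len(report) == 0

    def test_all_removed_errors(self):
        values = np.zeros((100, 1), dtype=np.int16)
        with pytest.raises(ValidationError):
            filter_attributes(self._table(values))
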