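"""Index kernels, graph/partition computation, closed forms and tables."""

import math

import pytest

from irrnet import (
    INDEX_IDS,
    IS_FAMILY,
    OT_FAMILY,
    IndexDomainError,
    chain,
    closed_form,
    compare_families,
    compute_from_graph,
    compute_from_partition,
    get_index,
    index_table,
    kernel_table,
)


class TestKernelTable:
    def test_twelve_definitions_in_order(self):
        assert tuple(d.id for d in kernel_table()) == INDEX_IDS

    def test_irf_kernel(self):
        assert get_index("IRF").kernel(4, 8) == 16

    def test_irdif_kernel(self):
        assert get_index("IRDIF").kernel(5, 10) == pytest.approx(1.5)

    @pytest.mark.parametrize("defn", kernel_table(), ids=lambda d: d.id)
    def test_zero_on_equal_degrees(self, defn):
        for d in (1, 2, 5, 8):
            assert defn.kernel(d, d) == 0
            assert defn.kernel_sym(d, d) == 0

    @pytest.mark.parametrize("defn", kernel_table(), ids=lambda d: d.id)
    def test_symmetric_and_float_matches_symbolic(self, defn):
        for a in range(1, 7):
            for b in range(a + 1, 8):
                k = defn.kernel(a, b)
                assert k == defn.kernel(b, a)
                assert k == pytest.approx(float(defn.kernel_sym(a, b)), rel=1e-12)
                assert k >= 0

    def test_known_kernel_values(self):
        # hand-computed spot checks
        assert get_index("IRLU").kernel(4, 8) == 1.0
        assert get_index("IRLA").kernel(4, 8) == pytest.approx(1 / 3)
        assert get_index("IRL").kernel(4, 8) == pytest.approx(math.log(2))
        assert get_index("IRD1").kernel(5, 10) == pytest.approx(math.log(6))
        assert get_index("IRB").kernel(4, 8) == pytest.approx(12 - 8 * math.sqrt(2))


class TestComputeFromGraph:
    def test_regular_graph_vanishes(self, icosahedron):
        assert compute_from_graph(icosahedron, "AL") == 0

    def test_cho2_albertson(self):
        # 8 edges of type (4,8), each contributing 4
        assert compute_from_graph(chain("CHO", 2), "AL") == pytest.approx(32)

    def test_chi2_total_irregularity(self):
        # half of 10 edges of type (5,10) x 5
        assert compute_from_graph(chain("CHI", 2), "IRRt") == pytest.approx(25)


class TestComputeFromPartition:
    def test_ot_n1_irf(self):
        assert compute_from_partition({(4, 4): 30, (4, 8): 36, (8, 8): 6}, "IRF") == 576

    def test_is_n2_irlu(self):
        part = {(5, 5): 468, (5, 10): 204, (10, 10): 48}
        assert compute_from_partition(part, "IRLU") == 204

    @pytest.mark.parametrize("index_id", INDEX_IDS)
    def test_single_degree_class_vanishes(self, index_id):
        assert compute_from_partition({(3, 3): 7}, index_id) == 0

    def test_integer_results_are_exact_ints(self):
        v = compute_from_partition(OT_FAMILY.evaluate(3), "IRLA")
        assert isinstance(v, int) and v == 216

    @pytest.mark.parametrize("index_id", sorted({"IRDIF", "IRL", "IRLU", "IRLF", "IRA", "IRGA"}))
    def test_degree_zero_raises_domain_error(self, index_id):
        with pytest.raises(IndexDomainError, match=index_id):
            compute_from_partition({(0, 2): 1}, index_id)

    def test_degree_zero_fine_for_difference_kernels(self):
        assert compute_from_partition({(0, 2): 1}, "AL") == 2


class TestClosedForm:
    def test_ot_irdif(self):
        cf = closed_form(OT_FAMILY, "IRDIF")
        assert cf.coefficients() == (54, 0, 0)

    def test_ot_albertson(self):
        assert closed_form(OT_FAMILY, "AL").coefficients() == (144, 0, 0)

    def test_is_total_irregularity(self):
        assert closed_form(IS_FAMILY, "IRRt").coefficients() == (135, -15, 0)

    def test_exact_symbolic_coefficients(self):
        import sympy as sp

        cf = closed_form(OT_FAMILY, "IRL")
        assert sp.simplify(cf.a2 - 36 * sp.log(2)) == 0

    @pytest.mark.parametrize("family", [OT_FAMILY, IS_FAMILY], ids=lambda f: f.name)
    @pytest.mark.parametrize("index_id", INDEX_IDS)
    def test_matches_partition_route_at_small_n(self, family, index_id):
        cf = closed_form(family, index_id)
        for n in range(1, 6):
            direct = compute_from_partition(family.evaluate(n), index_id)
            assert cf(n) == pytest.approx(direct, rel=1e-9)


class TestIndexTable:
    def test_ot_irrt_at_n3(self):
        df = index_table(OT_FAMILY, [3])
        assert df.loc["IRRt", 3] == 648

    def test_is_ird1_at_n1(self):
        df = index_table(IS_FAMILY, [1])
        assert df.loc["IRD1", 1] == pytest.approx(86.004432, rel=1e-4)

    def test_empty_n_values(self):
        df = index_table(OT_FAMILY, [])
        assert df.shape == (12, 0)

    def test_rejects_n_below_one(self):
        with pytest.raises(ValueError):
            index_table(OT_FAMILY, [0])


class TestCompareFamilies:
    def test_is_dominates_ot_on_irdif(self):
        result = compare_families(OT_FAMILY, IS_FAMILY, "IRDIF", 5)
        assert result.verdict == "family_2_dominates"
        # difference is 27n^2 - 9n
        assert result.differences == [27 * n * n - 9 * n for n in range(1, 6)]

    def test_identical_families_tie(self):
        result = compare_families(OT_FAMILY, OT_FAMILY, "AL", 3)
        assert result.verdict == "tie"
        assert result.differences == [0, 0, 0]

    def test_irf_differences(self):
        result = compare_families(OT_FAMILY, IS_FAMILY, "IRF", 2)
        assert result.differences == [624, 2796]

    def test_rejects_n_max_below_one(self):
        with pytest.raises(ValueError):
            compare_families(OT_FAMILY, IS_FAMILY, "AL", 0)
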