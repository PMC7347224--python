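import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import dense_box_oracle
from layervis.core import ExpressionMatrix, GeneList
from layervis.engine import hover
from layervis.errors import ValidationError
from layervis.pcp import (
    BoxQuery,
    ProfileSet,
    box_select,
    build_pcp,
    consecutive_select,
    five_number_summary,
    standardize,
)


def _profiles(values: np.ndarray, standardized=True) -> ProfileSet:
    values = np.asarray(values, dtype=float)
    n_genes, n_axes = values.shape
    return ProfileSet(
        tuple(f"s{i}" for i in range(n_axes)),
        tuple(f"g{i}" for i in range(n_genes)),
        values,
        standardized=standardized,
    )


def _random_profiles(n_genes=200, n_axes=5, seed=13) -> ProfileSet:
    rng = np.random.default_rng(seed)
    raw = rng.normal(0, 1, size=(n_genes, n_axes))
    z = (raw - raw.mean(1, keepdims=True)) / raw.std(1, ddof=1, keepdims=True)
    return _profiles(z)


class TestStandardize:
    def test_simple_row(self):
        m = ExpressionMatrix.from_arrays(["g"], [[1.0, 2.0, 3.0]], ["A.1", "A.2", "B.1"])
        profs = standardize(m)
        np.testing.assert_allclose(profs.values[0], [-1.0, 0.0, 1.0])

    def test_constant_row_flagged_and_zeroed(self):
        m = ExpressionMatrix.from_arrays(
            ["g", "h"], [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], ["A.1", "A.2", "B.1"]
        )
        profs = standardize(m)
        np.testing.assert_array_equal(profs.values[0], [0.0, 0.0, 0.0])
        assert profs.constant_genes == {"g"}

    def test_moments_recomputed_on_random_rows(self):
        rng = np.random.default_rng(17)
        counts = rng.uniform(0, 500, size=(100, 6))
        m = ExpressionMatrix.from_arrays(
            [f"g{i}" for i in range(100)],
            counts,
            ["A.1", "A.2", "A.3", "B.1", "B.2", "B.3"],
        )
        z = standardize(m).values
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-9


class TestFiveNumberSummary:
    def test_exact_order_statistics(self):
        profs = _profiles(np.array([[0.0], [1.0], [2.0], [3.0], [4.0]]))
        summary = five_number_summary(profs)
        assert summary.for_axis("s0") == (0.0, 1.0, 2.0, 3.0, 4.0)

    def test_constant_axis_collapses(self):
        profs = _profiles(np.full((4, 2), 7.0))
        summary = five_number_summary(profs)
        assert summary.for_axis("s1") == (7.0,) * 5

    def test_matches_sorted_array_quantile_oracle(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(size=(37, 3))
        summary = five_number_summary(_profiles(vals))
        for axis in range(3):
            col = np.sort(vals[:, axis])
            n = len(col)
            for p, got in zip([0, 0.25, 0.5, 0.75, 1.0], summary.values[axis]):
                # linear interpolation of order statistics at 1 + p(n-1)
                h = p * (n - 1)
                lo, frac = int(np.floor(h)), h - np.floor(h)
                expected = col[lo] if frac == 0 else col[lo] * (1 - frac) + col[lo + 1] * frac
                assert got == pytest.approx(expected, rel=1e-12)

    def test_ordering_invariant(self):
        summary = five_number_summary(_random_profiles(50, 4, seed=2))
        v = summary.values
        assert np.all(np.diff(v, axis=1) >= 0)


class TestBoxSelect:
    def test_full_extent_box_keeps_all(self):
        profs = _random_profiles(50, 4, seed=5)
        lo, hi = profs.values.min() - 1, profs.values.max() + 1
        assert len(box_select(profs, BoxQuery(0, lo, 10, hi))) == 50

    def test_partial_segment_discriminates(self):
        # axes at x=1,2; values (0, 10); box [1.2, 2] x [5, 10]:
        # f(1.2) = 2 < 5, so the gene is excluded even though f(2) = 10 passes
        profs = _profiles(np.array([[0.0, 10.0]]), standardized=False)
        query = BoxQuery(1.2, 5.0, 2.0, 10.0)
        assert len(box_select(profs, query)) == 0
        assert dense_box_oracle(profs.values, query).sum() == 0

    def test_whole_axis_box_equals_per_axis_threshold(self):
        profs = _random_profiles(120, 5, seed=31)
        query = BoxQuery(2.0, -1.0, 4.0, 1.0)  # spans whole axes 2,3,4
        got = set(box_select(profs, query))
        within = (np.abs(profs.values[:, 1:4]) <= 1.0).all(axis=1)
        expected = {g for g, ok in zip(profs.gene_ids, within) if ok}
        assert got == expected

    def test_matches_dense_sampling_oracle_on_random_queries(self):
        profs = _random_profiles(100, 5, seed=41)
        rng = np.random.default_rng(42)
        for _ in range(30):
            x1, x2 = np.sort(rng.uniform(0.5, 5.5, 2))
            y1, y2 = np.sort(rng.normal(0, 1.5, 2))
            query = BoxQuery(x1, y1, x2, y2)
            got = np.array([g in set(box_select(profs, query)) for g in profs.gene_ids])
            np.testing.assert_array_equal(got, dense_box_oracle(profs.values, query))

    def test_query_missing_all_axes_warns_and_keeps_all(self):
        profs = _random_profiles(10, 3, seed=1)
        with pytest.warns(UserWarning, match="misses all axes"):
            kept = box_select(profs, BoxQuery(10.0, -1.0, 12.0, 1.0))
        assert len(kept) == 10

    def test_malformed_query_rejected(self):
        with pytest.raises(ValidationError):
            BoxQuery(2.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            BoxQuery(1.0, 1.0, 2.0, 0.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(0.05, 2.0),
        st.floats(0.05, 2.0),
        st.integers(0, 10_000),
    )
    def test_shrinking_band_is_antimonotone(self, shrink_lo, shrink_hi, seed):
        profs = _random_profiles(40, 4, seed=seed % 100)
        outer = BoxQuery(1.5, -2.0, 3.5, 2.0)
        inner = BoxQuery(1.5, -2.0 + shrink_lo, 3.5, 2.0 - shrink_hi)
        if inner.y2 < inner.y1:
            return
        assert set(box_select(profs, inner)) <= set(box_select(profs, outer))


class TestConsecutiveSelect:
    def test_empty_query_list_is_identity(self):
        profs = _random_profiles(25, 4, seed=3)
        assert list(consecutive_select(profs, [])) == list(profs.gene_ids)

    def test_repeated_query_is_idempotent(self):
        profs = _random_profiles(60, 4, seed=7)
        q = BoxQuery(1.0, -1.0, 2.5, 1.0)
        assert list(consecutive_select(profs, [q, q])) == list(
            consecutive_select(profs, [q])
        )

    def test_equals_intersection_of_singles(self):
        profs = _random_profiles(200, 5, seed=19)
        rng = np.random.default_rng(20)
        for _ in range(10):
            queries = []
            for _ in range(2):
                x1, x2 = np.sort(rng.uniform(0.5, 5.5, 2))
                y1, y2 = np.sort(rng.normal(0, 1.5, 2))
                queries.append(BoxQuery(x1, y1, x2, y2))
            combined = set(consecutive_select(profs, queries))
            singles = [set(box_select(profs, q)) for q in queries]
            assert combined == singles[0] & singles[1]

    def test_result_preserves_profile_order(self):
        profs = _random_profiles(80, 4, seed=29)
        q = BoxQuery(1.0, -1.2, 4.0, 1.2)
        kept = list(consecutive_select(profs, [q]))
        assert kept == [g for g in profs.gene_ids if g in set(kept)]


class TestBuildPcp:
    def test_summary_only_figure(self):
        profs = _random_profiles(30, 4, seed=2)
        fig = build_pcp(profs, overlay=GeneList.of([]))
        assert fig.background.geom == "summary"
        assert len(fig.background.payload_doc["boxes"]) == 4
        assert fig.foreground.elements == ()

    def test_overlay_lines_and_hover(self):
        profs = _random_profiles(30, 4, seed=2)
        fig = build_pcp(profs, overlay=GeneList.of(["g3", "g7"]))
        assert len(fig.foreground.elements) == 2
        assert hover(fig, "foreground", "g7") == "g7"
        # polylines run through the profile values at integer positions
        element = next(e for e in fig.foreground.elements if e["id"] == "g3")
        np.testing.assert_allclose(
            [p[1] for p in element["path"]], profs.values[3]
        )

    def test_unresolvable_overlay_rejected(self):
        profs = _random_profiles(10, 3, seed=2)
        with pytest.raises(ValidationError):
            build_pcp(profs, overlay=GeneList.of(["nope"]))
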