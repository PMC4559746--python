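import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from targetability.expression_io import ExpressionMatrix, GroupLabels
from targetability.scoring import (
    ScoringError,
    pscore,
    score_all,
    score_pair,
    split_regions,
    two_sample_pvalue,
)
from targetability.synthetic_fixtures import SimulationConfig, generate
from targetability.pathway_map import build_pairs

from conftest import welch_pvalue_oracle


class TestSplitRegions:
    def test_boundary_value_goes_to_low_region(self):
        matrix = ExpressionMatrix(
            pd.DataFrame([[0.2, 0.5, 0.7]], index=["PG"], columns=["s1", "s2", "s3"])
        )
        split = split_regions(matrix, "PG")
        assert split.low_samples == frozenset({"s1", "s2"})
        assert split.high_samples == frozenset({"s3"})

    @pytest.mark.parametrize(
        "value,low_n,high_n", [(0.9, 0, 3), (0.5, 3, 0), (0.0, 3, 0)]
    )
    def test_degenerate_splits(self, value, low_n, high_n):
        matrix = ExpressionMatrix(
            pd.DataFrame([[value] * 3], index=["PG"], columns=["a", "b", "c"])
        )
        split = split_regions(matrix, "PG")
        assert (len(split.low_samples), len(split.high_samples)) == (low_n, high_n)

    def test_absent_gene_rejected(self, small_matrix):
        with pytest.raises(ScoringError, match="absent"):
            split_regions(small_matrix, "NOPE")


class TestTwoSamplePvalue:
    def test_identical_groups_give_p_one(self):
        x = [0.1, 0.2, 0.3]
        assert two_sample_pvalue(x, x, "welch") == 1.0

    def test_matches_independent_welch_oracle(self, rng):
        for _ in range(1000):
            nx, ny = rng.integers(2, 12, size=2)
            x = rng.uniform(0, 1, nx)
            y = rng.uniform(0, 1, ny)
            p = two_sample_pvalue(x, y, "welch")
            assert p == pytest.approx(welch_pvalue_oracle(x, y), abs=1e-10)

    def test_clearly_separated_groups(self):
        p = two_sample_pvalue([0.1, 0.2, 0.3], [0.7, 0.8, 0.9], "welch")
        assert p == pytest.approx(welch_pvalue_oracle([0.1, 0.2, 0.3], [0.7, 0.8, 0.9]), abs=1e-10)
        assert p < 0.01

    def test_zero_variance_equal_means_is_p_one(self):
        assert two_sample_pvalue([0.4, 0.4], [0.4, 0.4], "welch") == 1.0

    def test_zero_variance_unequal_means_floored(self):
        p = two_sample_pvalue([0.2, 0.2], [0.8, 0.8], "welch")
        assert 0 < p <= 1e-300

    def test_undersized_group_signals_undefined(self):
        assert two_sample_pvalue([0.5], [0.1, 0.2], "welch") is None

    @pytest.mark.parametrize("method", ["student", "mannwhitney"])
    def test_alternative_methods_available(self, method):
        p = two_sample_pvalue([0.1, 0.2, 0.3, 0.2], [0.7, 0.8, 0.9, 0.8], method)
        assert 0 < p < 0.05

    def test_unknown_method_rejected(self):
        with pytest.raises(ScoringError, match="unknown test method"):
            two_sample_pvalue([0.1, 0.2], [0.3, 0.4], "ttest")


class TestPscore:
    def test_anchor_half_at_p_001(self):
        assert pscore(0.01, +1) == pytest.approx(0.5, abs=1e-12)

    def test_zero_at_p_one(self):
        assert pscore(1.0, +1) == 0.0
        assert pscore(1.0, -1) == 0.0

    def test_closed_form_at_1e4(self):
        # x = 4 => g = 4/6
        assert pscore(1e-4, -1) == pytest.approx(-4.0 / 6.0, abs=1e-12)

    def test_sign_applied(self):
        assert pscore(0.001, -1) == -pscore(0.001, +1)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5, 2.0])
    def test_out_of_range_pvalue_rejected(self, bad):
        with pytest.raises(ScoringError):
            pscore(bad, +1)

    @given(
        p1=st.floats(1e-250, 1.0, exclude_max=True),
        ratio=st.floats(1e-3, 1.0, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_p(self, p1, ratio):
        p_small = p1 * ratio
        assert pscore(p_small, +1) > pscore(p1, +1)

    @given(p=st.floats(1e-250, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, p):
        assert 0.0 <= pscore(p, +1) < 1.0


def _matrix_from(values: dict, genes):
    """Build a matrix from a sample -> per-gene value-list mapping."""
    return ExpressionMatrix(pd.DataFrame(values, index=genes))


class TestScorePair:
    def _planted(self, n=25, shift=0.3, sd=0.05, seed=11):
        """Pathway gene splits samples half/half; case target shifted only
        in the high region."""
        rng = np.random.default_rng(seed)
        samples = [f"N{i}" for i in range(2 * n)] + [f"C{i}" for i in range(2 * n)]
        is_case = np.array([False] * 2 * n + [True] * 2 * n)
        pg = np.tile([0.25, 0.75], 2 * n)  # half low, half high in each group
        high = pg > 0.5
        target = 0.4 + shift * (is_case & high) + rng.normal(0, sd, 4 * n)
        matrix = ExpressionMatrix(
            pd.DataFrame([pg, np.clip(target, 0, 1)], index=["PG", "TG"], columns=samples)
        )
        labels = GroupLabels(
            {s: ("cancer" if c else "normal") for s, c in zip(samples, is_case)},
            "normal", "cancer",
        )
        return matrix, labels

    def test_high_region_shift_detected_only_in_high_region(self):
        matrix, labels = self._planted()
        ps = score_pair(matrix, labels, "PG", "TG")
        assert ps.hp.pscore > 0.5
        assert abs(ps.lp.pscore) < 0.2
        assert ps.defined

    def test_pscore_consistent_with_direct_welch_oracle(self):
        matrix, labels = self._planted()
        ps = score_pair(matrix, labels, "PG", "TG")
        split = split_regions(matrix, "PG")
        t = matrix.data.loc["TG"]
        for region, rs in [(split.low_samples, ps.lp), (split.high_samples, ps.hp)]:
            x = t[[s for s in labels.reference_samples if s in region]]
            y = t[[s for s in labels.case_samples if s in region]]
            assert rs.pvalue == pytest.approx(welch_pvalue_oracle(x, y), abs=1e-10)

    def test_null_target_scores_near_zero(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(80)]
        matrix = ExpressionMatrix(
            pd.DataFrame(
                [rng.uniform(0, 1, 80), rng.normal(0.5, 0.1, 80).clip(0, 1)],
                index=["PG", "TG"], columns=samples,
            )
        )
        labels = GroupLabels(
            {s: ("normal" if i < 40 else "cancer") for i, s in enumerate(samples)},
            "normal", "cancer",
        )
        ps = score_pair(matrix, labels, "PG", "TG")
        assert abs(ps.lp.pscore) < 0.5 and abs(ps.hp.pscore) < 0.5

    def test_empty_region_flags_pair_undefined(self):
        samples = [f"S{i}" for i in range(10)]
        matrix = _matrix_from(
            {s: [0.9, 0.5] for s in samples}, ["PG", "TG"]
        )
        labels = GroupLabels(
            {s: ("normal" if i < 5 else "cancer") for i, s in enumerate(samples)},
            "normal", "cancer",
        )
        ps = score_pair(matrix, labels, "PG", "TG")
        assert not ps.lp.defined
        assert ps.hp.defined
        assert not ps.defined


class TestScoreAll:
    def test_one_score_per_scoreable_pair(self, default_bundle, default_pairs):
        scores = score_all(default_bundle.matrix, default_bundle.labels, default_pairs)
        assert len(scores) == len(default_pairs)

    def test_label_swap_negates_every_defined_score(self, default_bundle, default_pairs):
        b = default_bundle
        fwd = score_all(b.matrix, b.labels, default_pairs)
        rev = score_all(b.matrix, b.labels.swapped(), default_pairs)
        assert len(fwd) == len(rev)
        for f, r in zip(fwd, rev):
            assert (f.pathway_gene, f.target_gene) == (r.pathway_gene, r.target_gene)
            for a, c in [(f.lp, r.lp), (f.hp, r.hp)]:
                assert a.defined == c.defined
                if a.defined:
                    assert c.pscore == pytest.approx(-a.pscore, abs=1e-12)
                    assert c.pvalue == pytest.approx(a.pvalue, abs=1e-12)

    def test_matches_scalar_score_pair(self, default_bundle, default_pairs):
        b = default_bundle
        scores = score_all(b.matrix, b.labels, default_pairs)
        for ps in scores[::37]:  # spot-check a spread of pairs
            single = score_pair(b.matrix, b.labels, ps.pathway_gene, ps.target_gene)
            for a, c in [(single.lp, ps.lp), (single.hp, ps.hp)]:
                assert (a.n_ref, a.n_case, a.defined) == (c.n_ref, c.n_case, c.defined)
                if a.defined:
                    assert a.pvalue == pytest.approx(c.pvalue, abs=1e-12)
                    assert a.pscore == pytest.approx(c.pscore, abs=1e-12)

    def test_pairs_with_missing_genes_dropped(self, default_bundle):
        from targetability.pathway_map import PathwayUnitMap, TFTargetMap

        b = default_bundle
        real_pg = b.truth["pathway_gene"].iloc[0]
        real_tg = b.truth.loc[b.truth["pathway_gene"] == real_pg, "target_gene"].iloc[0]
        units = PathwayUnitMap({real_pg: {"TFX"}, "GHOST": {"TFY"}})
        tft = TFTargetMap({"TFX": {real_tg, "GHOST_TG"}, "TFY": {real_tg}})
        pairs = build_pairs(units, tft)
        scores = score_all(b.matrix, b.labels, pairs)
        assert len(scores) == 1
        assert scores[0].pathway_gene == real_pg

    def test_all_pairs_missing_rejected(self, default_bundle):
        from targetability.pathway_map import PathwayUnitMap, TFTargetMap

        pairs = build_pairs(
            PathwayUnitMap({"GHOST": {"TF"}}), TFTargetMap({"TF": {"NOPE"}})
        )
        with pytest.raises(ScoringError, match="zero scoreable"):
            score_all(default_bundle.matrix, default_bundle.labels, pairs)

    def test_deterministic_and_order_independent(self, default_bundle, default_pairs):
        b = default_bundle
        s1 = score_all(b.matrix, b.labels, default_pairs)
        s2 = score_all(b.matrix, b.labels, default_pairs)
        assert s1 == s2
        keys = [(s.pathway_gene, s.target_gene) for s in s1]
        assert keys == sorted(keys)
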