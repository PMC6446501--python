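import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from richnet.enrichment import bh_adjust, camera_pr, classify_direction, run_enrichment
from richnet.geneset_io import GeneSetLibrary

from _oracles import naive_bh


def _series(values, prefix="g"):
    return pd.Series(np.asarray(values, float), index=[f"{prefix}{i}" for i in range(len(values))])


class TestCameraPr:
    def test_constant_stats_give_p_one(self):
        s = _series([2.0] * 8)
        direction, p = camera_pr(s, {"g0", "g3"}, inter_gene_cor=0.0)
        assert p == 1.0
        assert direction == "Up"

    def test_matches_pooled_two_sample_t(self):
        # ranks 1..10, set = top three: identical to the classical
        # equal-variance t-test of {8,9,10} against {1..7}
        s = _series(np.arange(1.0, 11.0))
        members = {"g7", "g8", "g9"}
        direction, p = camera_pr(s, members, inter_gene_cor=0.0)
        t_ref = sps.ttest_ind([8.0, 9.0, 10.0], np.arange(1.0, 8.0), equal_var=True)
        assert direction == "Up"
        assert p == pytest.approx(t_ref.pvalue, rel=1e-12)

    def test_variance_inflation_shrinks_significance(self):
        s = _series(np.arange(1.0, 11.0))
        members = {"g7", "g8", "g9"}
        _, p0 = camera_pr(s, members, inter_gene_cor=0.0)
        _, p1 = camera_pr(s, members, inter_gene_cor=0.01)
        assert p1 > p0

    def test_down_direction(self):
        s = _series([-5.0, -4.0, 0.1, 0.2, 0.3, 0.4])
        direction, p = camera_pr(s, {"g0", "g1"}, inter_gene_cor=0.0)
        assert direction == "Down"
        assert p < 0.05

    @pytest.mark.parametrize(
        "members,err",
        [(set(), "degenerate"), ({f"g{i}" for i in range(6)}, "degenerate"),
         ({"g0", "nope"}, "absent")],
    )
    def test_degenerate_inputs_rejected(self, members, err):
        s = _series(np.arange(6.0))
        with pytest.raises(ValueError, match=err):
            camera_pr(s, members)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, shift, scale, seed):
        """p-values are unchanged by shifting or positively scaling stats."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        s = _series(x)
        s2 = _series(x * scale + shift)
        members = {f"g{i}" for i in rng.choice(20, size=5, replace=False)}
        _, p = camera_pr(s, members)
        _, p2 = camera_pr(s2, members)
        assert p2 == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_rho_zero_balanced_split_is_textbook_t(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=12)
        s = _series(x)
        members = {f"g{i}" for i in range(6)}
        _, p = camera_pr(s, members, inter_gene_cor=0.0)
        ref = sps.ttest_ind(x[:6], x[6:], equal_var=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_worked_step_up(self):
        # step-up: (0.01*3/1, 0.02*3/2, 0.03*3/3) -> cummin from the top
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers())
    @settings(max_examples=60, deadline=None)
    def test_monotone_consistent_and_matches_naive(self, pvals, _seed):
        adj = bh_adjust(pvals)
        assert np.all((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1.0))
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj == pytest.approx(naive_bh(pvals), rel=1e-12, abs=1e-12)


class TestRunEnrichment:
    def test_row_count_and_order_match_library(self):
        rng = np.random.default_rng(0)
        s = _series(rng.normal(size=30))
        lib = GeneSetLibrary(
            {"B": {"g0", "g1", "g2"}, "A": {"g5", "g6"}, "C": {"g9", "g10", "g11"}}
        )
        raw = run_enrichment(s, lib)
        assert list(raw["name"]) == ["B", "A", "C"]
        assert list(raw["NGenes"]) == [3, 2, 3]

    def test_symmetric_stats_mixed_signal(self):
        # centered set holding the extreme |stats|: no net direction, but
        # strong dysregulation on the absolute scale
        s = _series([-3.0, -0.1, -0.05, 0.05, 0.1, 3.0])
        lib = GeneSetLibrary({"EXTREME": {"g0", "g5"}})
        raw = run_enrichment(s, lib, inter_gene_cor=0.0)
        p_dir = raw.loc[0, "PValue"]
        p_mixed = raw.loc[0, "PValue.Mixed"]
        ref_dir = sps.ttest_ind([-3.0, 3.0], [-0.1, -0.05, 0.05, 0.1], equal_var=True)
        ref_mix = sps.ttest_ind([3.0, 3.0], [0.1, 0.05, 0.05, 0.1], equal_var=True)
        assert p_dir == pytest.approx(ref_dir.pvalue, rel=1e-12)
        assert p_mixed == pytest.approx(ref_mix.pvalue, rel=1e-12)
        assert p_dir > 0.9
        assert p_mixed < p_dir

    def test_empty_library(self):
        s = _series(np.arange(5.0))
        raw = run_enrichment(s, GeneSetLibrary({}))
        assert raw.empty


class TestClassifyDirection:
    @staticmethod
    def _raw(rows):
        return pd.DataFrame(
            rows, columns=["name", "NGenes", "Direction", "PValue", "PValue.Mixed"]
        )

    def test_three_way_rule(self):
        # single-set tables: FDR == PValue, so the rule is directly visible
        kept_down = classify_direction(self._raw([("A", 5, "Down", 0.01, 0.50)]))
        assert kept_down.loc[0, "Direction"] == "Down"
        assert kept_down.loc[0, "FDR"] == pytest.approx(0.01)

        demoted = classify_direction(self._raw([("A", 5, "Up", 0.20, 0.01)]))
        assert demoted.loc[0, "Direction"] == "Mixed"
        assert demoted.loc[0, "FDR"] == pytest.approx(0.01)
        # the directional PValue is reported unreplaced
        assert demoted.loc[0, "PValue"] == pytest.approx(0.20)

        dropped = classify_direction(self._raw([("A", 5, "Up", 0.20, 0.20)]))
        assert dropped.empty

    def test_boundary_is_inclusive(self):
        kept = classify_direction(self._raw([("A", 5, "Up", 0.05, 0.9)]), alpha=0.05)
        assert kept.loc[0, "Direction"] == "Up"

    def test_adjustment_spans_all_sets_before_filtering(self):
        # with 2 sets, FDR of the better p doubles unless the worse follows
        raw = self._raw(
            [("A", 5, "Up", 0.03, 0.9), ("B", 5, "Up", 0.9, 0.9)]
        )
        out = classify_direction(raw, alpha=0.05)
        # BH: FDR_A = min(2*0.03, ...) = 0.06 > 0.05 -> demoted, then dropped
        assert out.empty

    def test_no_record_fails_both_cuts(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"S{i}", 5, "Up", float(rng.uniform()), float(rng.uniform()))
            for i in range(50)
        ]
        out = classify_direction(self._raw(rows), alpha=0.05)
        raw = self._raw(rows)
        fdr = bh_adjust(raw["PValue"])
        fdr_m = bh_adjust(raw["PValue.Mixed"])
        keep = {
            raw.loc[i, "name"]
            for i in range(len(raw))
            if fdr[i] <= 0.05 or fdr_m[i] <= 0.05
        }
        assert set(out["name"]) == keep
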