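import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.integrate import quad

from lncnet import (
    ExpressionMatrix,
    Group,
    Regulation,
    SyntheticDesign,
    TranscriptClass,
    ValidationError,
    generate_matrix,
    group_fold_change,
    hierarchical_cluster,
    two_sample_t,
    volcano_filter,
)


class TestGroupFoldChange:
    @pytest.mark.parametrize("tumor, normal, fc, log2fc", [
        ((16.0, 16.0), (2.0, 2.0), 8.0, 3.0),
        ((2.0, 2.0), (16.0, 16.0), 8.0, -3.0),
        ((5.0, 7.0), (5.0, 7.0), 1.0, 0.0),
    ])
    def test_mean_ratio_examples(self, tumor, normal, fc, log2fc):
        got_fc, got_log2 = group_fold_change(tumor, normal)
        assert got_fc == pytest.approx(fc)
        assert got_log2 == pytest.approx(log2fc)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            group_fold_change([], [1.0, 2.0])

    @given(
        xt=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
        xn=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_fc_at_least_one_and_consistent_with_log2(self, xt, xn):
        fc, log2fc = group_fold_change(xt, xn)
        assert fc >= 1.0
        assert fc == pytest.approx(2.0 ** abs(log2fc), abs=1e-12, rel=1e-12)


def t_density(u: float, df: int) -> float:
    """Student-t density written out, for an integration-based oracle."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + u * u / df) ** (-(df + 1) / 2)


class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        assert two_sample_t((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)) == 1.0

    def test_strong_separation_gives_tiny_p(self):
        a = (10.0, 11.0, 12.0, 13.0, 14.0)
        b = tuple(v + 100.0 for v in a)
        assert two_sample_t(a, b, on_log_scale=False) < 1e-6

    def test_matches_t_cdf_by_numerical_integration(self):
        """P agrees to 1e-9 with 2 * integral of the t density beyond the
        statistic, df = n1 + n2 - 2, computed independently of scipy.stats."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_obs = abs(a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        tail, err = quad(t_density, t_obs, np.inf, args=(df,))
        assert err < 1e-9  # quad's conservative estimate
        assert two_sample_t(a, b, on_log_scale=False) == pytest.approx(
            2 * tail, abs=1e-9)

    def test_zero_variance_unequal_means_gives_smallest_positive(self, caplog):
        with caplog.at_level("WARNING"):
            p = two_sample_t((2.0, 2.0), (4.0, 4.0))
        assert 0 < p < 1e-300
        assert any("zero variance" in r.message for r in caplog.records)

    def test_zero_variance_equal_means_gives_one(self):
        assert two_sample_t((2.0, 2.0), (2.0, 2.0)) == 1.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t((1.0,), (2.0, 3.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_permutation_null_on_5v5(self, seed):
        """The Student-t P agrees with the exact label-permutation null
        (all 252 5-of-10 splits) within the null's granularity (~1/252
        per split, 0.02 allowed)."""
        import itertools

        rng = np.random.default_rng(seed)
        a = rng.normal(5.0, 1.0, 5)
        b = rng.normal(5.6, 1.0, 5)
        pooled = np.concatenate([a, b])

        def tstat(u, v):
            sp2 = ((len(u) - 1) * u.var(ddof=1) +
                   (len(v) - 1) * v.var(ddof=1)) / (len(u) + len(v) - 2)
            return (u.mean() - v.mean()) / math.sqrt(sp2 * (2 / 5))

        obs = abs(tstat(a, b))
        hits = total = 0
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, bool)
            mask[list(idx)] = True
            hits += abs(tstat(pooled[mask], pooled[~mask])) >= obs - 1e-12
            total += 1
        p_perm = hits / total
        p_t = two_sample_t(a, b, on_log_scale=False)
        assert abs(p_t - p_perm) <= 0.02


def matrix_from_rows(rows: dict[str, list[float]], n_tumor: int,
                     classes: dict[str, TranscriptClass] | None = None
                     ) -> ExpressionMatrix:
    values = pd.DataFrame(rows).T
    n = values.shape[1]
    values.columns = [f"T{i}" for i in range(n_tumor)] + \
                     [f"N{i}" for i in range(n - n_tumor)]
    groups = {s: Group.TUMOR if s.startswith("T") else Group.NORMAL
              for s in values.columns}
    if classes is None:
        classes = {t: TranscriptClass.MRNA for t in values.index}
    return ExpressionMatrix(values, groups, classes)


class TestVolcanoFilter:
    def test_fold_change_boundary_is_inclusive(self):
        """FC exactly 2.0 with significant P is called; FC 1.99 is not,
        however small its P."""
        m = matrix_from_rows({
            "at_bound": [4.4, 4.0, 3.6, 2.2, 2.0, 1.8],      # means 4 vs 2
            "below":    [3.98, 3.98, 3.98, 2.0, 2.0, 2.0001],  # FC ~ 1.99, tiny P
        }, n_tumor=3)
        res = volcano_filter(m, fc_min=2.0, alpha=0.05)
        by_id = res.by_id()
        assert by_id["at_bound"].fold_change == pytest.approx(2.0)
        assert by_id["at_bound"].p_value < 0.05
        assert by_id["at_bound"].regulation is Regulation.UP
        assert by_id["below"].p_value < 1e-6
        assert by_id["below"].regulation is Regulation.UNCHANGED

    def test_p_boundary_is_strict(self):
        m = matrix_from_rows({
            "big_fc_flat_p": [9.0, 1.0, 5.0, 1.0, 2.0, 6.0],
        }, n_tumor=3)
        p = two_sample_t(m.values.iloc[0, :3], m.values.iloc[0, 3:])
        # alpha set exactly to the transcript's P: strict '<' leaves it unflagged
        res = volcano_filter(m, fc_min=1.0, alpha=p)
        assert res.by_id()["big_fc_flat_p"].regulation is Regulation.UNCHANGED

    def test_noise_free_synthetic_flags_exactly_the_planted_set(self):
        d = SyntheticDesign(seed=21, n_lncrna=20, n_mrna=80, de_fraction=0.2,
                            fc_range=(8.0, 8.0), noise_sd=1e-9, blocks=())
        m, truth = generate_matrix(d)
        res = volcano_filter(m)
        flagged = {r.transcript_id: r.regulation for r in res.records
                   if r.regulation is not Regulation.UNCHANGED}
        assert set(flagged) == set(truth.de_table)
        for t, (fc, direction) in truth.de_table.items():
            assert flagged[t].value == direction
        n_up, n_down = res.counts[TranscriptClass.LNCRNA]
        planted_lnc = [t for t in truth.de_table if t.startswith("lnc")]
        assert n_up + n_down == len(planted_lnc)

    def test_label_swap_flips_signs_and_counts(self, tiny_matrix):
        """Swapping tumor/normal labels negates every log2 fold change,
        swaps UP and DOWN counts, and leaves P values unchanged."""
        res = volcano_filter(tiny_matrix)
        swapped_groups = {
            s: Group.NORMAL if g is Group.TUMOR else Group.TUMOR
            for s, g in tiny_matrix.sample_group.items()}
        swapped = ExpressionMatrix(tiny_matrix.values.copy(), swapped_groups,
                                   dict(tiny_matrix.transcript_class))
        res_sw = volcano_filter(swapped)
        for r, rs in zip(res.records, res_sw.records):
            assert rs.log2_fold_change == pytest.approx(-r.log2_fold_change)
            assert rs.p_value == pytest.approx(r.p_value)
        for cls in TranscriptClass:
            assert res.counts[cls] == tuple(reversed(res_sw.counts[cls]))

    def test_bh_column_monotone_and_bounded(self, tiny_matrix):
        res = volcano_filter(tiny_matrix)
        ordered = sorted(res.records, key=lambda r: r.p_value)
        for r in res.records:
            assert r.p_adj_bh >= r.p_value - 1e-15
            assert r.p_adj_bh <= 1.0
        adj = [r.p_adj_bh for r in ordered]
        assert adj == sorted(adj)


class TestHierarchicalCluster:
    def test_separated_groups_split_at_top(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(4, 8, size=20)
        rows = {}
        for i in range(20):
            profile = np.concatenate([
                np.full(4, base[i] + (3.0 if i % 2 else 0.0)),
                np.full(4, base[i]),
            ]) + rng.normal(0, 0.05, 8)
            rows[f"tx{i:02d}"] = list(2.0 ** profile)
        m = matrix_from_rows(rows, n_tumor=4)
        order, _, linkage = hierarchical_cluster(m, list(rows))
        top2 = hierarchy.fcluster(linkage["samples"], t=2, criterion="maxclust")
        sample_sorted = sorted(m.sample_ids)
        clusters = {}
        for s, c in zip(sample_sorted, top2):
            clusters.setdefault(c, set()).add(s)
        assert set(map(frozenset, clusters.values())) == {
            frozenset({"T0", "T1", "T2", "T3"}),
            frozenset({"N0", "N1", "N2", "N3"})}
        assert set(order) == set(m.sample_ids)

    def test_single_transcript_subset_degenerates(self, tiny_matrix):
        order_s, order_t, linkage = hierarchical_cluster(tiny_matrix, ["t_up"])
        assert order_t == ["t_up"]
        assert linkage["transcripts"].shape == (0, 4)
        assert set(order_s) == set(tiny_matrix.sample_ids)

    def test_missing_subset_id_is_hard_error(self, tiny_matrix):
        with pytest.raises(ValidationError, match="ghost"):
            hierarchical_cluster(tiny_matrix, ["t_up", "ghost"])

    def test_leaf_order_independent_of_input_order(self, tiny_matrix):
        ids = tiny_matrix.transcript_ids
        o1 = hierarchical_cluster(tiny_matrix, ids)
        o2 = hierarchical_cluster(tiny_matrix, list(reversed(ids)))
        assert o1[0] == o2[0]
        assert o1[1] == o2[1]
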