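import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ricenet import (
    DataError,
    GeneSetCollection,
    TwoGroupDEModel,
    call_de,
    gene_set_overlap_graph,
    hypergeometric_enrichment,
    iqr_filter,
    moderated_t_test,
    p_to_q,
)


def frame(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{i}" for i in range(values.shape[1])],
    )


class TestIqrFilter:
    def test_gene_below_median_iqr_removed(self):
        # IQRs 1, 2, 3: median 2, so only the IQR-1 gene falls strictly below
        data = frame(
            [
                [0, 0.5, 0.5, 1.0],
                [0, 1.0, 1.0, 2.0],
                [0, 1.5, 1.5, 3.0],
            ]
        )
        kept = iqr_filter(data)
        assert kept == ["g1", "g2"]

    def test_identical_iqrs_keep_everything(self):
        data = frame([[0, 1, 2, 3], [10, 11, 12, 13]])
        assert iqr_filter(data) == ["g0", "g1"]

    def test_constant_gene_removed_when_others_vary(self):
        data = frame([[5, 5, 5, 5], [0, 1, 2, 3], [0, 2, 4, 6]])
        assert "g0" not in iqr_filter(data)


class TestModeratedT:
    def groups(self, n1, n2):
        labels = ["a"] * n1 + ["b"] * n2
        return pd.Series(labels, index=[f"s{i}" for i in range(n1 + n2)])

    def test_equal_means_give_zero_t(self):
        data = frame([[1.0, 2.0, 1.0, 2.0], [4.0, 6.0, 4.0, 6.0]])
        res = moderated_t_test(data, self.groups(2, 2))
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-12)

    def test_unmoderated_matches_pooled_t(self):
        rng = np.random.default_rng(0)
        data = frame(rng.normal(size=(30, 8)))
        res = moderated_t_test(data, self.groups(4, 4), moderated=False)
        for g in data.index:
            t_ref, p_ref = stats.ttest_ind(
                data.loc[g][4:], data.loc[g][:4], equal_var=True
            )
            assert res.loc[g, "t"] == pytest.approx(t_ref, abs=1e-10)
            assert res.loc[g, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_hand_computed_pooled_t_on_toy(self):
        # groups a=(1,2,3), b=(3,4,5): delta=2, s2 pooled = 1, t = 2/sqrt(2/3)
        data = frame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
        res = moderated_t_test(data, self.groups(3, 3), moderated=False)
        expected = 2.0 / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert res["t"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_moderation_shrinks_extreme_variances(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(200, 12))
        base[0] *= 0.01  # one gene with tiny variance
        data = frame(base)
        res = moderated_t_test(data, self.groups(6, 6))
        assert res["s2_post"].iloc[0] > res["s2"].iloc[0]

    def test_small_group_rejected(self):
        data = frame([[1.0, 2.0, 3.0]])
        with pytest.raises(DataError, match=">= 2 samples"):
            moderated_t_test(data, pd.Series(["a", "b", "b"], index=data.columns))

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: the moderated t of the limma workflow in R."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=(80, 10))
        values[:8, 5:] += 1.5
        data = frame(values)
        data.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
            design <- cbind(Intercept=1, Diff=c(rep(0,5), rep(1,5)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"Diff"], p=fit$p.value[,"Diff"])
            write.table(out, commandArgs(TRUE)[2], sep="\t", quote=FALSE)
            """
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "expr.tsv"), str(tmp_path / "out.tsv")],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = moderated_t_test(data, self.groups(5, 5))
        np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-5, atol=1e-10)


class TestBenjaminiHochberg:
    def test_hand_enumerated_step_up(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_i = min_j>=i (m p_j / j) = 0.04 each
        np.testing.assert_allclose(
            p_to_q([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_second_hand_enumeration(self):
        # p=(0.005, 0.04, 0.9): q = (0.015, 0.06, 0.9)
        np.testing.assert_allclose(
            p_to_q([0.005, 0.04, 0.9]), [0.015, 0.06, 0.9], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(p_to_q([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(p_to_q([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            p_to_q([0.5, 0.0])
        with pytest.raises(DataError):
            p_to_q([0.5, 1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_order_invariant_and_monotone(self, ps):
        q = p_to_q(ps)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = p_to_q(np.asarray(ps)[perm])
        np.testing.assert_allclose(np.asarray(q)[perm], q_perm, atol=1e-12)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestCallDe:
    def test_q_exactly_at_threshold_excluded(self):
        table = pd.DataFrame({"q": [0.01, 0.009]}, index=["ga", "gb"])
        assert call_de(table, 0.01) == ["gb"]

    def test_empty_when_nothing_significant(self):
        table = pd.DataFrame({"q": [0.5, 0.2]}, index=["ga", "gb"])
        assert call_de(table, 0.01) == []

    def test_deterministic_tie_break_by_id(self):
        table = pd.DataFrame({"q": [0.001, 0.001]}, index=["gb", "ga"])
        assert call_de(table, 0.01) == ["ga", "gb"]


def exhaustive_upper_tail(N, K, n, k):
    """Exact hypergeometric upper tail by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometric:
    def test_complete_overlap_closed_form(self):
        sets = GeneSetCollection({"S": frozenset(f"g{i}" for i in range(5))})
        universe = [f"g{i}" for i in range(20)]
        de = [f"g{i}" for i in range(5)]
        res = hypergeometric_enrichment(de, universe, sets)
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        sets = GeneSetCollection({"S": frozenset(["g0", "g1"])})
        universe = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(["g5", "g6"], universe, sets)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        """scipy upper tail == brute-force enumeration for all N <= 25."""
        rng = np.random.default_rng(0)
        for N in range(2, 26):
            for K, n in itertools.product(range(N + 1), range(N + 1)):
                for k in range(min(K, n) + 1):
                    expected = exhaustive_upper_tail(N, K, n, k)
                    got = stats.hypergeom.sf(k - 1, N, K, n)
                    assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_de_genes_outside_universe_rejected(self):
        sets = GeneSetCollection({"S": frozenset(["g0"])})
        with pytest.raises(DataError, match="subset"):
            hypergeometric_enrichment(["gX"], ["g0", "g1"], sets)

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError, match="empty"):
            hypergeometric_enrichment([], [], GeneSetCollection({"S": frozenset()}))


class TestOverlapGraph:
    def enrichment_for(self, sets, de, universe):
        return hypergeometric_enrichment(de, universe, sets, q_threshold=1.1)

    def test_identical_overlaps_connected(self):
        universe = [f"g{i}" for i in range(30)]
        de = universe[:5]
        sets = GeneSetCollection(
            {"A": frozenset(universe[:10]), "B": frozenset(universe[:5] + universe[20:25])}
        )
        enr = self.enrichment_for(sets, de, universe)
        enr["significant"] = True
        g = gene_set_overlap_graph(enr, de, sets)
        assert g.has_edge("A", "B")

    def test_disjoint_overlaps_not_connected(self):
        universe = [f"g{i}" for i in range(30)]
        de = universe[:10]
        sets = GeneSetCollection(
            {"A": frozenset(universe[:5]), "B": frozenset(universe[5:10])}
        )
        enr = self.enrichment_for(sets, de, universe)
        enr["significant"] = True
        g = gene_set_overlap_graph(enr, de, sets)
        assert not g.has_edge("A", "B")

    def test_no_self_loops(self):
        universe = [f"g{i}" for i in range(10)]
        de = universe[:4]
        sets = GeneSetCollection({"A": frozenset(universe[:4])})
        enr = self.enrichment_for(sets, de, universe)
        enr["significant"] = True
        g = gene_set_overlap_graph(enr, de, sets)
        assert list(g.nodes) == ["A"]
        assert g.number_of_edges() == 0


class TestTwoGroupDEModel:
    def test_recovers_planted_de_genes(self, study_bundle):
        res = TwoGroupDEModel(study_bundle.de_compendium, study_bundle.de_groups).fit()
        recovered = set(res.de_genes)
        planted = study_bundle.truth.de_genes
        recall = len(recovered & planted) / len(planted)
        assert recall >= 0.9

    def test_null_fraction_controlled(self):
        """Under the global null the q<0.01 call fraction stays near zero."""
        from ricenet import DESpec, SyntheticConfig, generate_two_group_experiment

        total, called = 0, 0
        for seed in range(50):
            cfg = SyntheticConfig(
                n_genes=200,
                n_tfs=3,
                n_samples_control=4,
                n_samples_stress=4,
                module_specs=(),
                de_spec=DESpec(n_de_genes=0, effect_size=0.0, n_per_group=10),
                seed=seed,
            )
            comp, groups, _ = generate_two_group_experiment(cfg)
            res = TwoGroupDEModel(comp, groups).fit()
            total += len(res.retained)
            called += len(res.de_genes)
        assert called / total <= 0.011

    def test_summary_reports_counts(self, study_bundle):
        res = TwoGroupDEModel(study_bundle.de_compendium, study_bundle.de_groups).fit()
        text = res.summary()
        assert "retained by IQR filter" in text
        assert "DE genes" in text
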