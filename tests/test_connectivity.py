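"""Connectivity scoring: pooling, reflection symmetry, Fisher aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from repositioning.connectivity import (
    ConnectivityResult,
    RankedProfile,
    aggregate_instances,
    connectivity_score,
    rank_matrix,
    rank_profile,
    score_panel,
)
from repositioning.errors import ValidationError
from repositioning.io_formats import ProfileMatrix
from repositioning.signatures import Signature, SignaturePanel
from tests.conftest import random_ranked_profile


class TestRankProfile:
    def test_rank_one_is_largest_score(self):
        prof = rank_profile({"a": 2.0, "b": -1.0, "c": 0.5})
        assert prof.rank_of == {"a": 1, "c": 2, "b": 3}

    def test_ties_break_by_gene_id(self):
        prof = rank_profile({"b": 1.0, "a": 1.0})
        assert prof.rank_of == {"a": 1, "b": 2}

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rank_profile({"a": float("nan"), "b": 1.0})

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            rank_profile({"a": 1.0})


class TestConnectivityScore:
    def test_up_genes_at_top(self, small_profile):
        sig = Signature(name="s", up_genes={"g1", "g2"}, down_genes=set())
        res = connectivity_score(sig, small_profile)
        # pooled ranks (1, 2): count_tuples_leq(2, 10, 2) = 3 of 100 tuples
        assert res.p_pos == pytest.approx(0.03, rel=1e-12)
        assert (res.k_up, res.k_down) == (2, 0)

    def test_reflection_gives_negative_match(self, small_profile):
        sig = Signature(name="s", up_genes={"g1", "g2"}, down_genes=set())
        p_pos = connectivity_score(sig, small_profile).p_pos
        p_neg_rev = connectivity_score(sig, small_profile.reversed()).p_neg
        assert p_pos == p_neg_rev  # bit-exact

    def test_worst_match_single_gene(self, small_profile):
        sig = Signature(name="s", up_genes={"g10"}, down_genes=set())
        assert connectivity_score(sig, small_profile).p_pos == 1.0

    def test_down_genes_use_reflected_ranks(self, small_profile):
        # g10 sits at rank 10; reflected rank 1 -> strong positive match
        sig = Signature(name="s", up_genes=set(), down_genes={"g10"})
        res = connectivity_score(sig, small_profile)
        assert res.p_pos == pytest.approx(0.1, rel=1e-12)

    def test_genes_outside_universe_reduce_k(self, small_profile):
        sig = Signature(name="s", up_genes={"g1", "nope"}, down_genes=set())
        res = connectivity_score(sig, small_profile)
        assert res.k_up == 1

    def test_signature_disjoint_from_universe_is_error(self, small_profile):
        sig = Signature(name="s", up_genes={"zz"}, down_genes=set())
        with pytest.raises(ValidationError):
            connectivity_score(sig, small_profile)

    def test_reflection_antisymmetry_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(15, 40))
            prof = random_ranked_profile(rng, n)
            genes = list(prof.rank_of)
            chosen = rng.choice(genes, size=6, replace=False)
            sig = Signature(
                name="s",
                up_genes=set(chosen[:3]),
                down_genes=set(chosen[3:]),
            )
            assert connectivity_score(sig, prof).p_pos == \
                connectivity_score(sig, prof.reversed()).p_neg

    def test_null_profile_pvalues_super_uniform(self):
        rng = np.random.default_rng(5)
        n, hits, reps = 500, 0, 400
        sig_genes = [f"g{i}" for i in range(20)]
        sig = Signature(name="s", up_genes=set(sig_genes[:10]),
                        down_genes=set(sig_genes[10:]))
        for _ in range(reps):
            prof = random_ranked_profile(rng, n)
            if connectivity_score(sig, prof).p_pos < 0.05 + 1e-12:
                hits += 1
        assert hits / reps <= 0.08  # 0.05 plus sampling slack at 400 draws


class TestAggregate:
    def _res(self, p_pos, p_neg=0.5):
        return ConnectivityResult(
            signature_name="s", instance_id="i", compound_id="c",
            k_up=1, k_down=1, p_pos=p_pos, p_neg=p_neg, method_used="exact",
        )

    def test_single_instance_passes_through(self):
        agg = aggregate_instances([self._res(0.123)])
        assert agg.p_pos == pytest.approx(0.123, rel=1e-12)
        assert agg.m_instances == 1

    def test_all_ones_combine_to_one(self):
        agg = aggregate_instances([self._res(1.0, 1.0), self._res(1.0, 1.0)])
        assert agg.p_pos == pytest.approx(1.0)

    def test_two_halves_closed_form(self):
        # X = -2(ln .5 + ln .5) = 2.7726; chi2_4 tail = e^{-X/2}(1 + X/2)
        agg = aggregate_instances([self._res(0.5), self._res(0.5)])
        x = -2 * (math.log(0.5) + math.log(0.5))
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert agg.p_pos == pytest.approx(expected, rel=1e-10)
        assert agg.p_pos == pytest.approx(0.5966, abs=5e-5)

    def test_mixed_compounds_rejected(self):
        a = self._res(0.5)
        b = ConnectivityResult(
            signature_name="s", instance_id="j", compound_id="other",
            k_up=1, k_down=1, p_pos=0.5, p_neg=0.5, method_used="exact",
        )
        with pytest.raises(ValidationError):
            aggregate_instances([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_instances([])

    def test_uniform_ps_combine_to_uniform(self):
        # Fisher combination of i.i.d. uniforms is uniform: check the mean
        rng = np.random.default_rng(9)
        combined = []
        for _ in range(2000):
            ps = rng.uniform(size=3)
            rs = [self._res(p) for p in ps]
            combined.append(aggregate_instances(rs).p_pos)
        assert abs(float(np.mean(combined)) - 0.5) < 0.02


class TestScorePanel:
    def _matrix(self):
        genes = [f"g{i}" for i in range(6)]
        values = np.array(
            [
                [1, 6],
                [2, 5],
                [3, 4],
                [4, 3],
                [5, 2],
                [6, 1],
            ],
            dtype=np.int64,
        )
        ann = pd.DataFrame(
            {
                "instance_id": ["i1", "i2"],
                "compound_id": ["cA", "cB"],
                "cell_line": ["MCF7", "PC3"],
            }
        )
        return ProfileMatrix(
            gene_universe=genes, instances=["i1", "i2"], values=values,
            annotations=ann, is_ranks=True,
        )

    def test_matches_single_profile_scoring(self):
        pm = self._matrix()
        sig = Signature(name="s", up_genes={"g0", "g1"}, down_genes={"g5"})
        panel = SignaturePanel((sig,))
        per_instance, aggregated = score_panel(panel, pm)
        prof = RankedProfile(
            instance_id="i1", compound_id="cA", cell_line="MCF7", n=6,
            rank_of={g: int(pm.values[i, 0]) for i, g in
                     enumerate(pm.gene_universe)},
        )
        direct = connectivity_score(sig, prof)
        by_inst = {r.instance_id: r for r in per_instance}
        assert by_inst["i1"].p_pos == direct.p_pos
        assert by_inst["i1"].p_neg == direct.p_neg
        # i2 is i1 reversed: reflection antisymmetry across the matrix
        assert by_inst["i2"].p_neg == by_inst["i1"].p_pos
        assert len(aggregated) == 2

    def test_rank_matrix_from_scores_matches_rank_profile(self):
        genes = ["a", "b", "c"]
        scores = np.array([[2.0], [-1.0], [0.5]])
        ann = pd.DataFrame(
            {"instance_id": ["i1"], "compound_id": ["c"], "cell_line": ["x"]}
        )
        pm = ProfileMatrix(gene_universe=genes, instances=["i1"],
                           values=scores, annotations=ann)
        ranks = rank_matrix(pm)
        prof = rank_profile(dict(zip(genes, scores[:, 0])))
        assert [int(v) for v in ranks[:, 0]] == \
            [prof.rank_of[g] for g in genes]


class TestNonDefaultOptions:
    def test_split_fisher_mode_single_side_matches_pooled(self, small_profile):
        # with only an up set the split mode has one tail = the pooled score
        sig = Signature(name="s", up_genes={"g1", "g3"}, down_genes=set())
        pooled = connectivity_score(sig, small_profile)
        split = connectivity_score(sig, small_profile, mode="split_fisher")
        assert split.p_pos == pooled.p_pos
        assert split.p_neg == pooled.p_neg

    def test_split_fisher_mode_combines_two_tails(self, small_profile):
        import math
        from scipy.stats import chi2

        sig = Signature(name="s", up_genes={"g1"}, down_genes={"g10"})
        split = connectivity_score(sig, small_profile, mode="split_fisher")
        p_up = connectivity_score(
            Signature(name="u", up_genes={"g1"}, down_genes=set()),
            small_profile,
        ).p_pos
        p_down = connectivity_score(
            Signature(name="d", up_genes=set(), down_genes={"g10"}),
            small_profile,
        ).p_pos
        x = -2 * (math.log(p_up) + math.log(p_down))
        assert split.p_pos == pytest.approx(float(chi2.sf(x, 4)), rel=1e-12)
        assert split.p_pos != connectivity_score(sig, small_profile).p_pos

    def test_unknown_mode_rejected(self, small_profile):
        sig = Signature(name="s", up_genes={"g1"}, down_genes=set())
        with pytest.raises(ValueError):
            connectivity_score(sig, small_profile, mode="bogus")

    def test_stratified_aggregation_groups_by_cell_line(self):
        import math
        from scipy.stats import chi2

        def res(inst, p):
            return ConnectivityResult(
                signature_name="s", instance_id=inst, compound_id="c",
                k_up=1, k_down=0, p_pos=p, p_neg=p, method_used="exact",
            )

        results = [res("i1", 0.1), res("i2", 0.2), res("i3", 0.3)]
        flat = aggregate_instances(results)
        strat = aggregate_instances(results, cell_lines=["A", "A", "B"])

        def fisher(ps):
            x = -2 * sum(math.log(p) for p in ps)
            return float(chi2.sf(x, 2 * len(ps)))

        expected = fisher([fisher([0.1, 0.2]), fisher([0.3])])
        assert strat.p_pos == pytest.approx(expected, rel=1e-10)
        assert strat.p_pos != flat.p_pos

    def test_stratified_label_count_must_match(self):
        r = ConnectivityResult(
            signature_name="s", instance_id="i", compound_id="c",
            k_up=1, k_down=0, p_pos=0.5, p_neg=0.5, method_used="exact",
        )
        with pytest.raises(ValidationError):
            aggregate_instances([r], cell_lines=["A", "B"])
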