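"""The synthetic study generator: determinism, permutation invariants, planting."""

import numpy as np
import pytest

from repositioning.connectivity import RankedProfile, connectivity_score
from repositioning.errors import SignatureError, ValidationError
from repositioning.signatures import extract_signature, translate_signature
from repositioning.synthetic import (
    PlantedCompound,
    SimConfig,
    child_seed,
    random_panel,
    simulate_ortholog_map,
    simulate_profile_matrix,
    simulate_timecourse_de,
)


class TestSeedFanout:
    def test_stable_and_bounded(self):
        a = child_seed(1, "x")
        assert a == child_seed(1, "x")
        assert 0 <= a < 2**31 - 1
        assert child_seed(1, "y") != a
        assert child_seed(2, "x") != a


class TestTimecourse:
    def test_deterministic_given_seed(self):
        t1 = simulate_timecourse_de(200, 2, 30, seed=5)
        t2 = simulate_timecourse_de(200, 2, 30, seed=5)
        for a, b in zip(t1, t2):
            assert a.table.equals(b.table)

    def test_extractor_recovers_planted_genes(self):
        tables = simulate_timecourse_de(500, 3, 40, lfc_effect=2.0, seed=1)
        for t in tables:
            sig = extract_signature(t, lfc_min=1.0, q_max=0.05, min_size=5)
            planted = set(
                t.table.loc[
                    (t.table["log2fc"].abs() >= 2.0)
                    & (t.table["p_adj"] < 0.05),
                    "gene_id",
                ]
            )
            recovered = sig.genes() & planted
            assert len(recovered) >= 0.9 * len(planted)

    def test_zero_signature_genes_makes_extraction_fail(self):
        tables = simulate_timecourse_de(100, 1, 0, seed=1)
        with pytest.raises(SignatureError, match="too small"):
            extract_signature(tables[0], min_size=10)

    def test_impossible_sizes_rejected(self):
        with pytest.raises(ValidationError):
            simulate_timecourse_de(10, 1, 50, seed=1)


class TestOrthologMap:
    def test_zero_fractions_give_bijection(self):
        genes = [f"zf:g{i:03d}" for i in range(50)]
        m = simulate_ortholog_map(genes, seed=1)
        assert len(m) == 50
        assert m.pairs["source_gene"].is_unique
        assert m.pairs["target_gene"].is_unique

    def test_fraction_counts_respected(self):
        genes = [f"zf:g{i:03d}" for i in range(100)]
        m = simulate_ortholog_map(
            genes, frac_one_to_many=0.2, frac_unmapped=0.1, seed=3
        )
        per_source = m.pairs.groupby("source_gene").size()
        assert (per_source == 2).sum() == 20
        assert len(per_source) == 90  # 10 sources unmapped

    def test_fully_unmapped_breaks_translation(self):
        genes = [f"zf:g{i:03d}" for i in range(20)]
        m = simulate_ortholog_map(genes, frac_unmapped=1.0, seed=1)
        panel = random_panel(genes, 1, genes_per_side=3, seed=1)
        with pytest.raises(SignatureError, match="untranslatable"):
            translate_signature(panel.signatures[0], m)

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ortholog_map(["a"], frac_one_to_many=0.7, frac_unmapped=0.6)

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(30)]
        m1 = simulate_ortholog_map(genes, frac_unmapped=0.2, seed=9)
        m2 = simulate_ortholog_map(genes, frac_unmapped=0.2, seed=9)
        assert m1.pairs.equals(m2.pairs)


class TestProfileMatrix:
    def _cfg(self, **kw):
        base = dict(n_genes=300, n_compounds=6, instances_per_compound=2,
                    panel_size=2, seed=11)
        base.update(kw)
        return SimConfig(**base)

    def test_every_column_is_a_permutation(self):
        cfg = self._cfg(planted=(
            PlantedCompound("drug0000", "positive", 0.9, 0.8),
            PlantedCompound("drug0001", "negative", 0.5, 0.5),
        ))
        universe = [f"hs:g{i:04d}" for i in range(cfg.n_genes)]
        panel = random_panel(universe, 2, genes_per_side=10, seed=2)
        pm = simulate_profile_matrix(cfg, panel, universe=universe)
        n = pm.n_genes
        for j in range(pm.values.shape[1]):
            assert np.array_equal(
                np.sort(pm.values[:, j]), np.arange(1, n + 1)
            )

    def test_full_strength_plant_is_detected(self):
        # delta=1, phi=1: the planted instance's up genes occupy the very
        # top ranks; its positive match p-value collapses
        universe = [f"hs:g{i:04d}" for i in range(2000)]
        panel = random_panel(universe, 1, genes_per_side=20, seed=7)
        cfg = SimConfig(
            n_genes=2000, n_compounds=3, instances_per_compound=1,
            panel_size=1, seed=7,
            planted=(PlantedCompound("drug0000", "positive", 1.0, 1.0),),
        )
        pm = simulate_profile_matrix(cfg, panel, universe=universe)
        sig = panel.signatures[0]
        j = pm.instances.index("drug0000.1")
        prof = RankedProfile(
            instance_id="drug0000.1", compound_id="drug0000", cell_line="x",
            n=pm.n_genes,
            rank_of={g: int(pm.values[i, j])
                     for i, g in enumerate(pm.gene_universe)},
        )
        up_ranks = sorted(prof.rank_of[g] for g in sig.up_genes)
        assert up_ranks == list(range(1, 21))
        assert connectivity_score(sig, prof).p_pos < 1e-6

    def test_zero_effect_matches_null_distribution(self):
        universe = [f"hs:g{i:04d}" for i in range(300)]
        panel = random_panel(universe, 1, genes_per_side=10, seed=3)
        cfg_null = self._cfg(planted=())
        cfg_zero = self._cfg(
            planted=(PlantedCompound("drug0000", "positive", 0.0, 1.0),)
        )
        pm_null = simulate_profile_matrix(cfg_null, panel, universe=universe)
        pm_zero = simulate_profile_matrix(cfg_zero, panel, universe=universe)
        np.testing.assert_array_equal(pm_null.values, pm_zero.values)

    def test_tiny_phi_warns_and_moves_nothing(self):
        universe = [f"hs:g{i:04d}" for i in range(300)]
        panel = random_panel(universe, 1, genes_per_side=1, seed=3)
        cfg = self._cfg(
            planted=(PlantedCompound("drug0000", "positive", 0.9, 0.01),)
        )
        with pytest.warns(UserWarning, match="no genes moved"):
            simulate_profile_matrix(cfg, panel, universe=universe)

    def test_unknown_planted_compound_rejected(self):
        with pytest.raises(ValidationError, match="does not exist"):
            self._cfg(planted=(
                PlantedCompound("nope", "positive", 0.5, 0.5),
            ))

    def test_panel_gene_outside_universe_rejected(self):
        from repositioning.signatures import Signature, SignaturePanel

        cfg = self._cfg()
        universe = [f"hs:g{i:04d}" for i in range(cfg.n_genes)]
        panel = SignaturePanel((
            Signature(name="s", up_genes={"EXTRA", universe[0]},
                      down_genes={universe[1]}),
        ))
        with pytest.raises(ValidationError, match="missing from universe"):
            simulate_profile_matrix(cfg, panel, universe=universe)

    def test_deterministic_given_seed(self):
        cfg = self._cfg()
        universe = [f"hs:g{i:04d}" for i in range(cfg.n_genes)]
        panel = random_panel(universe, 2, genes_per_side=10, seed=2)
        pm1 = simulate_profile_matrix(cfg, panel, universe=universe)
        pm2 = simulate_profile_matrix(cfg, panel, universe=universe)
        np.testing.assert_array_equal(pm1.values, pm2.values)
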