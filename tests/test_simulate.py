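import numpy as np
import pytest

from tagdge.simulate import (
    ADAPTER_SENTINEL,
    ENRICHED_TERM,
    SimulationConfig,
    generate_annotations,
    generate_family_fixtures,
    generate_unigenes,
    simulate_tag_library,
    spike_truth,
)


class TestGenerateUnigenes:
    def test_exact_gene_count_and_catg_free_fraction(self):
        cfg = SimulationConfig(n_genes=100, catg_free_fraction=0.1, seed=7)
        unigenes, truth = generate_unigenes(cfg)
        assert len(unigenes) == 100
        free = [g for g, s in unigenes.items() if "CATG" not in s]
        assert len(free) == 10
        assert set(free) == set(truth.index[truth["catg_free"]])

    def test_tagged_genes_have_extractable_site(self):
        cfg = SimulationConfig(n_genes=50, catg_free_fraction=0.2, seed=3)
        unigenes, truth = generate_unigenes(cfg)
        for gene, row in truth.iterrows():
            seq = unigenes[gene]
            if row["catg_free"]:
                assert row["true_tag"] == ""
            else:
                tag = row["true_tag"]
                assert len(tag) == 21 and tag.startswith("CATG")
                assert tag in seq
                # 3'-most extractable site: no later CATG has 17 downstream bases
                pos = seq.rfind(tag)
                later = seq.find("CATG", pos + 1)
                while later != -1:
                    assert later + 21 > len(seq)
                    later = seq.find("CATG", later + 1)

    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(n_genes=40, seed=7)
        a = generate_unigenes(cfg)
        b = generate_unigenes(cfg)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_fixed_length_range(self):
        cfg = SimulationConfig(n_genes=20, length_range=(25, 25), seed=1)
        unigenes, _ = generate_unigenes(cfg)
        assert all(len(s) == 25 for s in unigenes.values())

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"length_range": (10, 25)},
            {"length_range": (100, 50)},
            {"catg_free_fraction": 1.5},
            {"error_rate": 1.0},
            {"n_contaminant_reads": -1},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            generate_unigenes(SimulationConfig(seed=0, **kwargs))


class TestSpikeTruth:
    def test_labels_and_folds_consistent(self, small_unigenes):
        _, truth = small_unigenes
        spiked = spike_truth(truth, n_up=10, n_down=5, fold=8.0, seed=11)
        assert (spiked["de_label"] == "up").sum() == 10
        assert (spiked["de_label"] == "down").sum() == 5
        # fold_change == 1 exactly when de_label == null
        null = spiked["de_label"] == "null"
        assert (spiked.loc[null, "fold_change"] == 1.0).all()
        assert (spiked.loc[~null, "fold_change"] != 1.0).all()
        # CATG-free genes are never spiked
        assert not spiked.loc[spiked["catg_free"], "de_label"].ne("null").any()


class TestSimulateTagLibrary:
    def test_conservation_and_error_free_limit(self, small_unigenes, small_config):
        unigenes, truth = small_unigenes
        lib = simulate_tag_library(unigenes, truth, treated=False, config=small_config)
        assert sum(lib.tags.values()) == small_config.library_size
        assert int(lib.true_counts.sum()) == small_config.library_size
        # error_rate=0: every read matches a reference tag exactly
        true_tags = set(truth.loc[~truth["catg_free"], "true_tag"])
        assert set(lib.tags) <= true_tags

    def test_contaminants_appended(self, small_unigenes):
        unigenes, truth = small_unigenes
        cfg = SimulationConfig(n_genes=100, library_size=5000, n_contaminant_reads=100, seed=5)
        lib = simulate_tag_library(unigenes, truth, treated=False, config=cfg)
        n_adapter = lib.tags.get(ADAPTER_SENTINEL, 0)
        n_n = sum(c for t, c in lib.tags.items() if "N" in t)
        assert n_adapter + n_n == 100
        assert sum(lib.tags.values()) == 5100

    def test_binomial_sampling_bound(self):
        # gene at relative weight 0.01, library 10^6: count within 3 sd of 10^4
        cfg = SimulationConfig(n_genes=100, length_range=(100, 200), library_size=10**6, seed=9)
        unigenes, truth = generate_unigenes(cfg)
        truth = truth.copy()
        truth["baseline_abundance"] = 1.0
        target = truth.index[~truth["catg_free"]][0]
        n_obs = int((~truth["catg_free"]).sum())
        # weight target so its relative share is exactly 0.01
        truth.loc[target, "baseline_abundance"] = (n_obs - 1) / 99.0
        lib = simulate_tag_library(unigenes, truth, treated=False, config=cfg)
        count = int(lib.true_counts[target])
        sd = np.sqrt(10**6 * 0.01 * 0.99)
        assert abs(count - 10**4) <= 3 * sd

    def test_all_zero_weights_raise(self, small_unigenes, small_config):
        unigenes, truth = small_unigenes
        truth = truth.copy()
        truth["baseline_abundance"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            simulate_tag_library(unigenes, truth, treated=False, config=small_config)

    def test_determinism(self, small_unigenes, small_config):
        unigenes, truth = small_unigenes
        a = simulate_tag_library(unigenes, truth, treated=True, config=small_config)
        b = simulate_tag_library(unigenes, truth, treated=True, config=small_config)
        assert a.tags == b.tags


class TestGenerateAnnotations:
    def test_extreme_rates_annotate_exactly_de_genes(self, small_unigenes):
        _, truth = small_unigenes
        spiked = spike_truth(truth, n_up=8, n_down=4, fold=8.0, seed=2)
        ann = generate_annotations(spiked, n_terms=5, enriched_rate=1.0, background_rate=0.0, seed=1)
        de_genes = set(spiked.index[spiked["de_label"] != "null"])
        assert {g for g, ts in ann.items() if ENRICHED_TERM in ts} == de_genes

    def test_fixed_seed_identical(self, small_unigenes):
        _, truth = small_unigenes
        a = generate_annotations(truth, 10, 0.5, 0.05, seed=4)
        b = generate_annotations(truth, 10, 0.5, 0.05, seed=4)
        assert a == b

    def test_enriched_count_within_binomial_bound(self):
        cfg = SimulationConfig(n_genes=2000, length_range=(100, 200), seed=21)
        _, truth = generate_unigenes(cfg)
        spiked = spike_truth(truth, n_up=100, n_down=0, fold=8.0, seed=22)
        ann = generate_annotations(spiked, n_terms=10, enriched_rate=0.6, background_rate=0.05, seed=23)
        de_genes = set(spiked.index[spiked["de_label"] != "null"])
        m = sum(1 for g in de_genes if ENRICHED_TERM in ann.get(g, set()))
        sd = np.sqrt(100 * 0.6 * 0.4)
        assert abs(m - 60) <= 3 * sd

    def test_invalid_rates(self, small_unigenes):
        _, truth = small_unigenes
        with pytest.raises(ValueError):
            generate_annotations(truth, 5, 1.2, 0.05, seed=0)


class TestFamilyFixtures:
    def test_constructed_properties(self):
        fixtures, expected = generate_family_fixtures(seed=0)
        assert len(fixtures["fix_too_short"]) == 350
        assert set(expected.values()) == {
            "removed_short",
            "removed_short_orf",
            "kept",
            "removed_variant",
        }
        # variant pair differs at <5% of aligned positions (same suffix, few subs)
        long, short = fixtures["fix_variant_long"], fixtures["fix_variant_short"]
        suffix = long[len(long) - len(short) :]
        diffs = sum(a != b for a, b in zip(suffix, short))
        assert diffs / len(short) < 0.05

    def test_deterministic(self):
        assert generate_family_fixtures(3) == generate_family_fixtures(3)
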