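import math

import numpy as np
import pandas as pd
import pytest

from unilib.regulatory_models import (
    CNNConfig,
    MAMParams,
    TrainingSet,
    count_motifs,
    encode_design_sequence,
    evaluate,
    fit_mam_calibration,
    mam_from_enrichment,
    mam_predict,
    one_hot_encode,
    predict,
    select_training_set,
    train_cnn,
)


class TestMAM:
    PARAMS = MAMParams(
        boost_weights={"a1": 4.0, "a2": 6.0},
        repressors=frozenset({"r1", "r2"}),
        calibration=(0.25, 1.0),
    )

    def test_motif_free_cassette_fold_one(self):
        expr, fold = mam_predict((), self.PARAMS, "weak")
        assert fold == 1.0
        assert expr == self.PARAMS.core_levels["weak"]

    def test_single_repressor_halves(self):
        _, fold = mam_predict(("r1",), self.PARAMS)
        assert fold == pytest.approx(0.5)

    def test_attenuation_independent_of_repressor_count(self):
        _, f1 = mam_predict(("r1",), self.PARAMS)
        _, f2 = mam_predict(("r1", "r2", "r1"), self.PARAMS)
        assert f1 == pytest.approx(f2)

    def test_linear_in_summed_weights(self):
        _, f1 = mam_predict(("a1",), self.PARAMS)
        _, f2 = mam_predict(("a1", "a1"), self.PARAMS)
        # doubling the summed weight doubles the boost over baseline
        assert (f2 - 1.0) == pytest.approx(2 * (f1 - 1.0))

    def test_multiplicative_in_core_level(self):
        e_weak, _ = mam_predict(("a1", "r1"), self.PARAMS, "weak")
        e_strong, _ = mam_predict(("a1", "r1"), self.PARAMS, "strong")
        ratio = self.PARAMS.core_levels["strong"] / self.PARAMS.core_levels["weak"]
        assert e_strong == pytest.approx(e_weak * ratio)

    def test_adding_activator_never_decreases_fold(self):
        _, f1 = mam_predict(("a1",), self.PARAMS)
        _, f2 = mam_predict(("a1", "a2"), self.PARAMS)
        assert f2 >= f1

    def test_unknown_promoter_rejected(self):
        with pytest.raises(KeyError):
            mam_predict((), self.PARAMS, "mythical")

    def test_params_from_classification(self):
        cls = pd.DataFrame(
            {"p_up": [1e-6, 0.9, 0.5], "p_down": [0.9, 1e-5, 0.6],
             "classification": ["activating", "repressing", "undetermined"]},
            index=["a", "r", "u"],
        )
        params = mam_from_enrichment(cls)
        assert params.boost_weights == {"a": pytest.approx(6.0)}
        assert params.repressors == frozenset({"r"})


class TestCalibrationFit:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_mam_calibration(2.0 * x + 1.0, x)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(1.0)
        assert fit["r"] == pytest.approx(1.0)

    def test_noisy_line_slope_recovered(self, rng):
        x = rng.uniform(1, 10, size=200)
        y = 0.8 * x + 1.0 + rng.normal(0, 0.2, size=200)
        fit = fit_mam_calibration(y, x)
        assert fit["slope"] == pytest.approx(0.8, abs=0.05)

    def test_constant_folds_give_zero_slope(self):
        fit = fit_mam_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert fit["slope"] == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mam_calibration([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestEncoding:
    def test_identity_pattern(self):
        m = one_hot_encode("ACGT", 4)
        assert np.array_equal(m, np.eye(4))

    def test_uniform_padding(self):
        m = one_hot_encode("A" * 101, 186)
        assert m.shape == (4, 186)
        assert np.allclose(m[:, 101:], 0.25)
        assert np.allclose(m.sum(axis=0), 1.0)  # every column sums to 1

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            one_hot_encode("ACGX", 4)
        with pytest.raises(ValueError):
            one_hot_encode("ACKG", 4)  # strict encoder refuses design symbols

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            one_hot_encode("ACGTA", 4)

    def test_design_encoder_splits_mixed_channels(self):
        m = encode_design_sequence("KM", 2)
        assert np.allclose(m[:, 0], [0, 0, 0.5, 0.5])  # K = G/T
        assert np.allclose(m[:, 1], [0.5, 0.5, 0, 0])  # M = A/C


def _additive_dataset(small_catalog, chassis, rng, n_test=59):
    from unilib.library_designer import enumerate_variants
    variants = enumerate_variants(small_catalog, 3, chassis=chassis)
    ids = small_catalog.motif_ids
    beta = {"m0": 600.0, "m1": -400.0, "m2": 250.0}
    seqs, counts, y = [], [], []
    for v in variants:
        c = count_motifs(v.motif_ids, ids)
        seqs.append(v.variable_region)
        counts.append(c)
        y.append(1500.0 + float(np.dot([beta.get(m, 0.0) for m in ids], c)))
    counts = np.array(counts)
    y = np.array(y)
    order = rng.permutation(len(seqs))
    tr, te = order[n_test:], order[:n_test]
    train = TrainingSet([seqs[i] for i in tr], y[tr], motif_counts=counts[tr])
    test = TrainingSet([seqs[i] for i in te], y[te], motif_counts=counts[te])
    return train, test


class TestCNN:
    def test_mlam_learns_additive_truth(self, small_catalog, chassis, rng):
        """Reduced-scale hybrid model reaches high held-out correlation on
        exactly additive data."""
        train, test = _additive_dataset(small_catalog, chassis, rng)
        cfg = CNNConfig(include_motif_counts=True, ensemble_size=3,
                        epochs=8, rng_seed=2)
        ens = train_cnn(train, cfg)
        preds = predict(ens, test.sequences, test.motif_counts)
        r = np.corrcoef(preds, test.targets)[0, 1]
        assert r >= 0.9

    def test_seeded_determinism(self, small_catalog, chassis, rng):
        train, test = _additive_dataset(small_catalog, chassis, rng)
        cfg = CNNConfig(ensemble_size=2, epochs=2, rng_seed=7)
        p1 = predict(train_cnn(train, cfg), test.sequences)
        p2 = predict(train_cnn(train, cfg), test.sequences)
        assert np.array_equal(p1, p2)

    def test_bins_output_mode_probabilities(self, small_catalog, chassis, rng):
        train, test = _additive_dataset(small_catalog, chassis, rng)
        span = train.targets.max() - train.targets.min()
        frac = (train.targets - train.targets.min()) / span
        targets = np.stack([(1 - frac) / 2, (1 - frac) / 2,
                            frac / 2, frac / 2], axis=1)
        ts = TrainingSet(train.sequences, targets)
        cfg = CNNConfig(output_mode="bins", ensemble_size=1, epochs=2, rng_seed=3)
        ens = train_cnn(ts, cfg)
        probs = predict(ens, test.sequences)
        assert probs.shape == (len(test.sequences), 4)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_mlam_mode_requires_counts(self, small_catalog, chassis, rng):
        train, test = _additive_dataset(small_catalog, chassis, rng)
        cfg = CNNConfig(include_motif_counts=True, ensemble_size=1, epochs=1)
        ens = train_cnn(train, cfg)
        with pytest.raises(ValueError, match="motif_counts"):
            predict(ens, test.sequences)
        with pytest.raises(ValueError, match="shape"):
            predict(ens, test.sequences, test.motif_counts[:, :3])

    def test_mlam_accepts_longer_padded_input(self, small_catalog, chassis, rng):
        """Training at length 186 accepts both 101 nt and 186 nt inputs."""
        train, test = _additive_dataset(small_catalog, chassis, rng)
        cfg = CNNConfig(include_motif_counts=True, ensemble_size=1, epochs=1,
                        max_input_length=186)
        ens = train_cnn(train, cfg)
        long_seq = test.sequences[0] + chassis.sequence[:85]
        out = predict(ens, [test.sequences[0], long_seq],
                      test.motif_counts[[0, 0]])
        assert out.shape == (2,)
        assert np.isfinite(out).all()


class TestEvaluate:
    def test_perfect_prediction(self):
        x = np.arange(11, dtype=float)
        res = evaluate(x, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.bootstrap_sd == pytest.approx(0.0)
        assert res.n_subsets == math.comb(11, 9)  # all 55 subsets of size n-2

    def test_anticorrelated(self):
        x = np.arange(10, dtype=float)
        res = evaluate(x, -x)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_random_subsets_scheme(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(0, 0.5, size=100)
        res = evaluate(x, y, scheme="random_subsets", subset_size=30,
                       n_subsets=100, seed=1)
        assert res.n_subsets == 100
        assert abs(res.bootstrap_mean - res.pearson_r) < 0.1

    def test_zero_variance_flagged(self):
        res = evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.pearson_r)


class TestTrainingSelection:
    @staticmethod
    def _records(manifest, rng):
        vids = sorted(manifest.variant_motifs())
        return pd.DataFrame(
            {
                "expression": rng.uniform(1000, 6000, size=len(vids)),
                "total_reads": rng.integers(10, 1000, size=len(vids)),
                "x": 0.25, "y": 0.25, "z": 0.25, "w": 0.25,
            },
            index=vids,
        )

    def test_amm_selects_deep_variants(self, mixed_catalog):
        from unilib.library_designer import (
            allocate_barcodes, design_desert, enumerate_variants,
            generate_barcodes,
        )
        chassis = design_desert(101, [], seed=41)
        variants = enumerate_variants(mixed_catalog, 2, chassis=chassis)
        bs = generate_barcodes(2 * len(variants) + 20 * 4, seed=43)
        man = allocate_barcodes(variants, bs, deep_count=4, seed=47)
        rng = np.random.default_rng(3)
        records = self._records(man, rng)
        train, held = select_training_set(records, man, mixed_catalog,
                                          mode="AMM", holdout_fraction=0.25,
                                          seed=5)
        assert len(train) + len(held) == 4
        deep = set(man.deep_variants())
        assert set(train.ids) | set(held.ids) == deep

    def test_mbo_subset_of_amm(self, mixed_catalog):
        from unilib.library_designer import (
            allocate_barcodes, design_desert, enumerate_variants,
            generate_barcodes,
        )
        chassis = design_desert(101, [], seed=53)
        variants = enumerate_variants(mixed_catalog, 2, chassis=chassis)
        bs = generate_barcodes(2 * len(variants) + 20 * 8, seed=59)
        man = allocate_barcodes(variants, bs, deep_count=8, seed=61)
        rng = np.random.default_rng(4)
        records = self._records(man, rng)
        amm_tr, amm_h = select_training_set(records, man, mixed_catalog,
                                            mode="AMM", seed=1)
        mbo_tr, mbo_h = select_training_set(records, man, mixed_catalog,
                                            mode="MBO", seed=1)
        amm_ids = set(amm_tr.ids) | set(amm_h.ids)
        mbo_ids = set(mbo_tr.ids) | set(mbo_h.ids)
        assert mbo_ids <= amm_ids
        mixed_ids = {m.motif_id for m in mixed_catalog.mixed_motifs}
        vm = man.variant_motifs()
        assert all(any(m in mixed_ids for m in vm[v]) for v in mbo_ids)

    def test_adm_cutoff_and_empty_selection(self, small_manifest, rng):
        records = self._records(small_manifest, rng)
        train, held = select_training_set(records, small_manifest,
                                          None or _catalog_of(small_manifest),
                                          mode="ADM", read_cutoff=500, seed=2)
        sel = records[records["total_reads"] > 500]
        assert len(train) + len(held) == len(sel)
        with pytest.raises(ValueError, match="empty"):
            select_training_set(records, small_manifest,
                                _catalog_of(small_manifest),
                                mode="ADM", read_cutoff=10**9)


def _catalog_of(manifest):
    from unilib.motif_catalog import MixedBaseMotif, MotifCatalog
    ids = sorted({m for ms in manifest.variant_motifs().values() for m in ms})
    # sequences are irrelevant for selection; rebuild minimal catalog
    return MotifCatalog([MixedBaseMotif(i, "ACGTACGTAC") for i in ids])
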