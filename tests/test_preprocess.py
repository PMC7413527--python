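import numpy as np
import pandas as pd
import pytest

from fertresponse import preprocess as prep
from fertresponse.synth import GeneratorConfig, generate_trials


@pytest.fixture(scope="module")
def features_and_trials(truth_params):
    cfg = GeneratorConfig(n_trials=8, trial_type="mixed", noise_sd=1.0,
                          block_sd=0.5, seed=21)
    trials, weather, _ = generate_trials(cfg, truth_params)
    fm = prep.build_features(trials, weather)
    return fm, trials


class TestBuildFeatures:
    def test_rows_align_with_plots(self, features_and_trials):
        fm, trials = features_and_trials
        assert len(fm) == len(trials)
        assert list(fm.meta["trial_id"]) == list(trials["trial_id"])

    def test_expected_feature_groups_present(self, features_and_trials):
        fm, _ = features_and_trials
        for col in ("dose_N", "dose_P", "dose_K", "bal_texture_c", "bal_al_p",
                    "bal_mg_ca", "ppt", "sdi", "gdd", "t_mean",
                    "soiltype_gleyed_podzolized", "maturity_mid"):
            assert col in fm.X.columns
        assert fm.X.notna().all().all()

    def test_balance_columns_documented_in_provenance(self, features_and_trials):
        fm, _ = features_and_trials
        assert fm.provenance["bal_silt_sand"].startswith("ilr")

    def test_sdi_within_unit_interval(self, features_and_trials):
        fm, _ = features_and_trials
        assert fm.X["sdi"].between(0, 1).all()

    def test_unseen_maturity_class_warns_and_zero_encodes(self, features_and_trials):
        _, trials = features_and_trials
        odd = trials.head(3).copy()
        odd["maturity_class"] = "brand_new"
        with pytest.warns(UserWarning, match="unseen"):
            fm = prep.build_features(odd, None)
        assert (fm.X.filter(like="maturity_").to_numpy() == 0).all()


class TestStandardizer:
    def test_training_columns_zero_mean_unit_variance(self, features_and_trials):
        fm, _ = features_and_trials
        std = prep.Standardizer().fit(fm.X)
        Z = std.transform(fm.X)
        numeric = [c for c in Z.columns if c not in std.binary_]
        assert np.abs(Z[numeric].mean()).max() < 1e-9
        assert np.abs(Z[numeric].var(ddof=0) - 1.0).max() < 1e-6

    def test_binary_columns_untouched(self, features_and_trials):
        fm, _ = features_and_trials
        std = prep.Standardizer().fit(fm.X)
        Z = std.transform(fm.X)
        for col in std.binary_:
            np.testing.assert_array_equal(Z[col].to_numpy(), fm.X[col].to_numpy())

    def test_training_statistics_reused_on_test(self, features_and_trials):
        fm, trials = features_and_trials
        half = len(fm.X) // 2
        std = prep.Standardizer().fit(fm.X.iloc[:half])
        Ztest = std.transform(fm.X.iloc[half:])
        manual = (fm.X.iloc[half:] - std.mean_) / std.scale_
        np.testing.assert_allclose(Ztest.to_numpy(), manual[std.columns_].to_numpy())

    def test_unfitted_raises(self, features_and_trials):
        fm, _ = features_and_trials
        with pytest.raises(RuntimeError):
            prep.Standardizer().transform(fm.X)


class TestOutlierRemoval:
    def test_identical_values_drop_nothing(self):
        df = pd.DataFrame({"a": np.ones(50)})
        with pytest.warns(UserWarning, match="zero variance"):
            kept, dropped = prep.remove_outliers_zscore(df)
        assert dropped == 0 and len(kept) == 50

    def test_constructed_outlier_dropped(self, rng):
        vals = rng.normal(0, 1, 1000)
        vals[123] = vals.mean() + 4 * vals.std()
        kept, dropped = prep.remove_outliers_zscore(pd.DataFrame({"a": vals}))
        assert 123 not in kept.index
        assert dropped >= 1

    def test_infinite_threshold_keeps_everything(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 200)})
        kept, dropped = prep.remove_outliers_zscore(df, threshold=np.inf)
        assert dropped == 0
        pd.testing.assert_frame_equal(kept, df)


class TestBlockSplit:
    @staticmethod
    def _table(n_blocks=10, rows_per_block=6):
        rows = []
        for b in range(n_blocks):
            for r in range(rows_per_block):
                rows.append({"block_id": f"B{b}", "trial_type": "N", "y": r})
        return pd.DataFrame(rows)

    def test_equal_blocks_split_seven_three(self):
        train, test = prep.split_blocks(self._table(), 0.7, seed=0)
        assert train["block_id"].nunique() == 7
        assert test["block_id"].nunique() == 3

    def test_no_block_in_both_sets(self, truth_params):
        cfg = GeneratorConfig(n_trials=12, trial_type="mixed", seed=5)
        trials, _, _ = generate_trials(cfg, truth_params)
        train, test = prep.split_blocks(trials, 0.7, seed=3)
        assert not (set(train["block_id"]) & set(test["block_id"]))
        assert len(train) + len(test) == len(trials)

    def test_achieved_share_within_five_points(self, truth_params):
        cfg = GeneratorConfig(n_trials=16, trial_type="mixed", seed=6)
        trials, _, _ = generate_trials(cfg, truth_params)
        train, _ = prep.split_blocks(trials, 0.7, seed=1)
        assert abs(len(train) / len(trials) - 0.7) <= 0.05

    def test_same_seed_same_split(self):
        tbl = self._table()
        t1, _ = prep.split_blocks(tbl, 0.7, seed=9)
        t2, _ = prep.split_blocks(tbl, 0.7, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_tiny_stratum_goes_to_training_with_warning(self):
        tbl = self._table(n_blocks=1)
        with pytest.warns(UserWarning, match="too small"):
            train, test = prep.split_blocks(tbl, 0.7, seed=0)
        assert len(test) == 0 and len(train) == len(tbl)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            prep.split_blocks(self._table(), 1.2)


class TestFeatureRanking:
    def test_scores_sum_to_one_descending(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (200, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = X["f0"] * 2 + rng.normal(0, 0.1, 200)
        scores = prep.rank_features(X, y, seed=0)
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert (scores.diff().dropna() <= 1e-12).all()

    def test_noise_feature_ranks_below_dose(self, truth_params, rng):
        cfg = GeneratorConfig(n_trials=6, trial_type="N", noise_sd=0.0,
                              block_sd=0.0, seed=13)
        trials, _, _ = generate_trials(cfg, truth_params)
        X = trials[["dose_N", "dose_P", "dose_K"]].copy()
        X["pure_noise"] = rng.normal(0, 1, len(X))
        scores = prep.rank_features(X, trials["marketable_yield"], seed=0)
        assert scores["pure_noise"] < scores["dose_N"]

    def test_dose_n_ranks_first_on_noiseless_n_trials(self, truth_params, rng):
        cfg = GeneratorConfig(n_trials=10, trial_type="N", noise_sd=0.0,
                              block_sd=0.0, seed=14)
        trials, _, _ = generate_trials(cfg, truth_params)
        X = trials[["dose_N", "ph_water", "planting_density", "season_length"]].copy()
        scores = prep.rank_features(X, trials["marketable_yield"], seed=0)
        assert scores.index[0] == "dose_N"

    def test_constant_target_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        with pytest.raises(ValueError, match="constant"):
            prep.rank_features(X, np.ones(50))
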