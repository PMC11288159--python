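import numpy as np
import pytest

from nanoml5mou import (
    ModEffect,
    benchmark_algorithms,
    benchmark_to_frame,
    load_models,
    predict_proba,
    save_models,
    simulate_kmer_dataset,
    train_kmer_model,
)
from nanoml5mou.errors import InsufficientDataError, LabellingError, SchemaError, UsageError
from nanoml5mou.features import KmerDataset
from nanoml5mou.models import train_kmer_models

FAST_GRID = {
    "svm": [{"C": 1.0}],
    "random_forest": [{"n_estimators": 100, "max_depth": 8}],
    "gbt": [{"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}],
}


class TestTrainKmerModel:
    def test_near_separable_classes_reach_high_auroc(self, small_strong_dataset):
        model = train_kmer_model(
            small_strong_dataset, "gbt", "all", seed=3, grid=FAST_GRID["gbt"]
        )
        assert model.cv_report.auroc[0] >= 0.95
        assert model.feature_schema == list(small_strong_dataset.X.columns)

    def test_zero_effect_gives_chance_level_auroc(self, null_dataset):
        model = train_kmer_model(null_dataset, "gbt", "all", seed=3, grid=FAST_GRID["gbt"])
        assert 0.40 <= model.cv_report.auroc[0] <= 0.60

    def test_insufficient_positives_named_in_error(self, small_strong_dataset):
        mask = np.concatenate([np.flatnonzero(small_strong_dataset.y == 1)[:5],
                               np.flatnonzero(small_strong_dataset.y == 0)])
        tiny = KmerDataset(
            kmer=small_strong_dataset.kmer,
            X=small_strong_dataset.X.iloc[mask].reset_index(drop=True),
            y=small_strong_dataset.y[mask],
            meta=small_strong_dataset.meta.iloc[mask].reset_index(drop=True),
        )
        with pytest.raises(InsufficientDataError, match="AGTCC"):
            train_kmer_model(tiny, "gbt")

    def test_single_class_rejected(self, small_strong_dataset):
        mask = small_strong_dataset.y == 1
        single = KmerDataset(
            kmer=small_strong_dataset.kmer,
            X=small_strong_dataset.X[mask].reset_index(drop=True),
            y=small_strong_dataset.y[mask],
            meta=small_strong_dataset.meta[mask].reset_index(drop=True),
        )
        with pytest.raises(LabellingError):
            train_kmer_model(single, "gbt")

    def test_unknown_algorithm(self, small_strong_dataset):
        with pytest.raises(UsageError):
            train_kmer_model(small_strong_dataset, "deep_net")

    def test_deterministic_given_seed(self, small_strong_dataset):
        a = train_kmer_model(small_strong_dataset, "gbt", "mid", seed=9, grid=FAST_GRID["gbt"])
        b = train_kmer_model(small_strong_dataset, "gbt", "mid", seed=9, grid=FAST_GRID["gbt"])
        assert a.cv_report == b.cv_report
        assert a.best_params == b.best_params


@pytest.fixture(scope="module")
def model(small_strong_dataset):
    return train_kmer_model(
        small_strong_dataset, "random_forest", "all", seed=3,
        grid=FAST_GRID["random_forest"],
    )


class TestPredictProba:
    def test_probabilities_in_unit_interval(self, model, small_strong_dataset):
        proba = predict_proba(model, small_strong_dataset)
        assert proba.shape == (len(small_strong_dataset),)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_positives_score_above_half(self, model, small_strong_dataset):
        proba = predict_proba(model, small_strong_dataset)
        pos = proba[small_strong_dataset.y == 1]
        assert np.mean(pos > 0.5) > 0.5

    def test_empty_input_gives_empty_output(self, model):
        assert predict_proba(model, []).shape == (0,)

    def test_missing_columns_raise_schema_error(self, model, small_strong_dataset):
        with pytest.raises(SchemaError):
            predict_proba(model, small_strong_dataset.X.iloc[:, :19])

    def test_wrong_kmer_raises_schema_error(self, model):
        other = simulate_kmer_dataset("CCTCC", 25, ModEffect.null(), seed=5)
        with pytest.raises(SchemaError):
            predict_proba(model, other)

    def test_persistence_round_trip(self, model, small_strong_dataset, tmp_path):
        save_models({model.kmer: model}, tmp_path)
        loaded = load_models(tmp_path)[model.kmer]
        assert loaded.feature_schema == model.feature_schema
        np.testing.assert_allclose(
            predict_proba(loaded, small_strong_dataset),
            predict_proba(model, small_strong_dataset),
        )


class TestBenchmark:
    def test_nine_scheme_algorithm_groups(self, small_strong_dataset):
        rows = benchmark_algorithms(small_strong_dataset, seed=3, grid=FAST_GRID)
        assert len(rows) == 9
        frame = benchmark_to_frame(rows)
        assert sorted(frame["group"]) == sorted(
            f"{s}_{a}" for s in ("all", "mid", "midn") for a in ("svm", "random_forest", "gbt")
        )

    def test_full_features_at_least_as_good_as_centre_only(self, small_strong_dataset):
        """With effects on all five positions, the 20-column scheme cannot be
        materially worse than the centre-only scheme (information nesting)."""
        rows = benchmark_algorithms(
            small_strong_dataset, algorithms=("gbt",), seed=3, grid=FAST_GRID
        )
        by_scheme = {r.scheme: r.report.auroc[0] for r in rows}
        assert by_scheme["all"] >= by_scheme["mid"] - 0.02

    def test_empty_algorithm_list_gives_empty_table(self, small_strong_dataset):
        assert benchmark_algorithms(small_strong_dataset, algorithms=(), seed=3) == []


def test_train_many_kmers_skips_low_coverage(template_reads):
    from nanoml5mou import build_kmer_datasets, extract_windows

    template, mod, unmod = template_reads
    windows = [w for r in mod + unmod for w in extract_windows(r, template)]
    datasets = build_kmer_datasets(windows)
    # 40 reads/class -> every expressed kmer has 40/class; raise the bar for some
    models = train_kmer_models(datasets, "gbt", "all", seed=1, min_per_class=20,
                               grid=FAST_GRID["gbt"])
    assert set(models) == set(datasets)
    huge_bar = train_kmer_models(datasets, "gbt", "all", seed=1, min_per_class=1000)
    assert huge_bar == {}
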