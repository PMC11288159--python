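import numpy as np
import pytest

from nanoml5mou import (
    FEATURE_NAMES,
    SCHEME_COLUMNS,
    EventRecord,
    ReadEvents,
    build_kmer_datasets,
    extract_windows,
    feature_subset,
    read_feature_table,
    write_feature_table,
)
from nanoml5mou.errors import CoordinateError, LabellingError, UsageError
from nanoml5mou.features import frame_to_windows, windows_to_frame


def _full_read(reference, read_id="r1", label=None, skip=()):
    events = [
        EventRecord(read_id, "tpl", p, reference[p], 0.1 * p, 0.1 * p, 0.05, p + 1)
        for p in range(len(reference))
        if p not in skip
    ]
    return ReadEvents(read_id, "tpl", events, sample_label=label)


def brute_force_window_count(reference, event_positions):
    """Independent oracle: interior T positions with all five events present."""
    have = set(event_positions)
    return sum(
        1
        for p in range(2, len(reference) - 2)
        if reference[p] == "T" and all(q in have for q in range(p - 2, p + 3))
    )


class TestExtractWindows:
    def test_single_agttc_window(self):
        windows = extract_windows(_full_read("AGTTC"), "AGTTC")
        assert len(windows) == 1
        w = windows[0]
        assert w.kmer == "AGTTC"
        assert w.center_pos == 2
        assert w.features.shape == (20,)
        # feature order: means, medians, sds, dwells by position
        assert np.allclose(w.features[15:20], [1, 2, 3, 4, 5])

    def test_no_central_t_means_no_windows(self):
        assert extract_windows(_full_read("AAACGGG"), "AAACGGG") == []

    def test_poly_t_has_three_interior_centers(self):
        windows = extract_windows(_full_read("TTTTTTT"), "TTTTTTT")
        assert [w.center_pos for w in windows] == [2, 3, 4]
        assert {w.kmer for w in windows} == {"TTTTT"}

    def test_gapped_context_window_dropped(self):
        # missing event at position 0 kills the window centred at 2 but not 3
        ref = "AGTTCAA"
        windows = extract_windows(_full_read(ref, skip=(0,)), ref)
        assert [w.center_pos for w in windows] == [3]

    def test_count_matches_brute_force_on_random_fixtures(self, rng):
        from nanoml5mou import make_template

        for trial in range(20):
            ref = make_template(50, seed=trial, u_density=0.3)
            positions = sorted(
                rng.choice(50, size=int(rng.integers(10, 50)), replace=False).tolist()
            )
            read = ReadEvents(
                "r",
                "tpl",
                [EventRecord("r", "tpl", p, ref[p], 0.0, 0.0, 0.1, 1) for p in positions],
            )
            assert len(extract_windows(read, ref)) == brute_force_window_count(ref, positions)

    def test_reference_too_short_raises(self):
        with pytest.raises(CoordinateError):
            extract_windows(_full_read("AGTTC"), "AGT")

    def test_kmer_comes_from_reference(self):
        # events claim base A everywhere; the reference decides the k-mer
        read = ReadEvents(
            "r", "tpl", [EventRecord("r", "tpl", p, "A", 0.0, 0.0, 0.1, 1) for p in range(5)]
        )
        windows = extract_windows(read, "CCTGG")
        assert windows[0].kmer == "CCTGG"


class TestKmerDatasets:
    def test_single_kmer_partition(self):
        windows = extract_windows(_full_read("AGTTC", label=1), "AGTTC")
        windows += extract_windows(_full_read("AGTTC", "r2", label=0), "AGTTC")
        datasets = build_kmer_datasets(windows)
        assert set(datasets) == {"AGTTC"}
        assert datasets["AGTTC"].n_pos == 1
        assert datasets["AGTTC"].n_neg == 1

    def test_partition_conserves_window_count(self):
        from nanoml5mou import ModEffect, PoreModel, simulate_reads

        template = "ACGTA" * 12
        pore = PoreModel(seed=1)
        reads = simulate_reads(pore, template, 25, modified=1, effect=ModEffect.null(), seed=2)
        reads += simulate_reads(pore, template, 25, modified=0, effect=ModEffect.null(), seed=3)
        windows = [w for r in reads for w in extract_windows(r, template)]
        datasets = build_kmer_datasets(windows)
        assert sum(len(d) for d in datasets.values()) == len(windows)
        for kmer, ds in datasets.items():
            assert (ds.meta["kmer"] == kmer).all()

    def test_unlabelled_windows_rejected(self):
        windows = extract_windows(_full_read("AGTTC"), "AGTTC")
        with pytest.raises(LabellingError):
            build_kmer_datasets(windows)


class TestFeatureSubset:
    @pytest.fixture()
    def dataset(self):
        windows = extract_windows(_full_read("AGTTC", label=1), "AGTTC")
        windows += extract_windows(_full_read("AGTTC", "r2", label=0), "AGTTC")
        return build_kmer_datasets(windows)["AGTTC"]

    @pytest.mark.parametrize("scheme, n_cols", [("all", 20), ("mid", 4), ("midn", 12)])
    def test_scheme_column_counts(self, dataset, scheme, n_cols):
        assert len(feature_subset(dataset, scheme).X.columns) == n_cols

    def test_mid_keeps_central_position_statistics(self, dataset):
        assert list(feature_subset(dataset, "mid").X.columns) == [
            "mean_3", "mdintense_3", "sd_3", "L_3",
        ]

    def test_schemes_nest(self, dataset):
        cols = {s: set(feature_subset(dataset, s).X.columns) for s in ("mid", "midn", "all")}
        assert cols["mid"] < cols["midn"] < cols["all"]
        assert cols["all"] == set(FEATURE_NAMES)

    def test_all_is_identity_on_columns(self, dataset):
        assert list(feature_subset(dataset, "all").X.columns) == list(dataset.X.columns)

    def test_unknown_scheme(self, dataset):
        with pytest.raises(UsageError):
            feature_subset(dataset, "everything")

    def test_scheme_registry_shapes(self):
        assert {s: len(c) for s, c in SCHEME_COLUMNS.items()} == {
            "all": 20, "mid": 4, "midn": 12,
        }


def test_feature_table_round_trip(tmp_path):
    windows = extract_windows(_full_read("TTTTTTT", label=1), "TTTTTTT")
    path = tmp_path / "features.tsv"
    write_feature_table(windows, path)
    back = read_feature_table(path)
    assert [w.center_pos for w in back] == [w.center_pos for w in windows]
    assert all(np.allclose(a.features, b.features) for a, b in zip(back, windows))
    assert [w.label for w in back] == [1, 1, 1]


def test_frame_round_trip_preserves_unknown_label():
    windows = extract_windows(_full_read("AGTTC"), "AGTTC")
    back = frame_to_windows(windows_to_frame(windows))
    assert back[0].label is None
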