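import numpy as np
import pytest

from acp_ada.augment import AugmentationConfig
from acp_ada.cv import CVConfig, run_ablation, run_cv, run_grid
from acp_ada.encoders import EncoderConfig
from acp_ada.model import ModelConfig
from acp_ada.preprocess import LengthConfig
from acp_ada.synthetic import SyntheticConfig, generate_dataset

# cheap but non-trivial settings shared across the harness tests
FAST_MODEL = ModelConfig(n_estimators_boost=3, rf_n_estimators=20)
ENC = EncoderConfig(Lx=30, n_selected=20)
LEN = LengthConfig(Lx=30)


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(SyntheticConfig(n_pos=50, n_neg=50, seed=12))


def test_folds_partition_the_dataset(dataset, property_table):
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=1), AugmentationConfig(seed=1))
    seen = []
    for fold in report.provenance["folds"]:
        seen.extend(fold["test_indices"])
    assert sorted(seen) == list(range(len(dataset)))


def test_augmentation_doubles_each_training_fold(dataset, property_table):
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=1),
                    AugmentationConfig(n_percent=100, seed=1))
    for fold in report.provenance["folds"]:
        assert fold["n_train_after_augment"] == \
            2 * fold["n_train_before_augment"]


def test_no_augmentation_leaves_training_folds_alone(dataset, property_table):
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=1, augment=False))
    for fold in report.provenance["folds"]:
        assert fold["n_train_after_augment"] == fold["n_train_before_augment"]


def test_report_is_bit_reproducible(dataset, property_table):
    kwargs = dict(length_cfg=LEN, enc_cfg=ENC, model_cfg=FAST_MODEL,
                  cv_cfg=CVConfig(fold_seed=7),
                  aug_cfg=AugmentationConfig(seed=7))
    a = run_cv(dataset, property_table, **kwargs).to_json()
    b = run_cv(dataset, property_table, **kwargs).to_json()
    assert a == b


def test_fold_assignment_ignores_features(dataset, property_table):
    """Folds depend only on labels and seed, not on encodings."""
    r1 = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                CVConfig(fold_seed=3, augment=False))
    enc_small = EncoderConfig(Lx=20, n_selected=10)
    r2 = run_cv(dataset, property_table, LengthConfig(20), enc_small,
                FAST_MODEL, CVConfig(fold_seed=3, augment=False))
    folds1 = [f["test_indices"] for f in r1.provenance["folds"]]
    folds2 = [f["test_indices"] for f in r2.provenance["folds"]]
    assert folds1 == folds2


def test_per_fold_selection_sees_training_rows_only(dataset, property_table):
    """Selections fitted per fold differ across folds (trained on
    different row subsets) and are recorded in the provenance."""
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=5, augment=False))
    selections = [tuple(f["selection_indices"])
                  for f in report.provenance["folds"]]
    assert all(len(s) == ENC.n_selected for s in selections)
    assert len(set(selections)) > 1


def test_global_selection_policy_shares_one_selection(dataset, property_table):
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=5, augment=False,
                             selection_policy="global"))
    selections = {tuple(f["selection_indices"])
                  for f in report.provenance["folds"]}
    assert len(selections) == 1


def test_mean_matches_fold_average(dataset, property_table):
    report = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                    CVConfig(fold_seed=1, augment=False))
    accs = [r.acc for r in report.fold_reports]
    assert report.mean["acc"] == pytest.approx(np.mean(accs))


def test_too_few_class_members_rejected(property_table):
    records = generate_dataset(SyntheticConfig(n_pos=3, n_neg=40, seed=0))
    with pytest.raises(ValueError, match="class"):
        run_cv(records, property_table, LEN, ENC, FAST_MODEL, CVConfig())


def test_unlabeled_records_rejected(dataset, property_table):
    from dataclasses import replace
    records = [replace(dataset[0], label=None)] + list(dataset[1:])
    with pytest.raises(ValueError, match="label"):
        run_cv(records, property_table, LEN, ENC, FAST_MODEL, CVConfig())


class TestGrid:
    def test_singleton_grid_matches_run_cv(self, dataset, property_table):
        result = run_grid(dataset, property_table, [30], [100],
                          enc_cfg=ENC, model_cfg=FAST_MODEL,
                          cv_cfg=CVConfig(fold_seed=2),
                          aug_cfg=AugmentationConfig(seed=2))
        direct = run_cv(dataset, property_table, LEN, ENC, FAST_MODEL,
                        CVConfig(fold_seed=2),
                        AugmentationConfig(n_percent=100, seed=2))
        assert result.reports[(30, 100.0)].mean == direct.mean
        assert result.best == (30, 100.0)

    def test_full_grid_has_one_report_per_cell(self, dataset, property_table):
        result = run_grid(dataset, property_table, [20, 30], [0, 100],
                          enc_cfg=EncoderConfig(Lx=20, n_selected=10),
                          model_cfg=FAST_MODEL,
                          cv_cfg=CVConfig(fold_seed=2),
                          aug_cfg=AugmentationConfig(seed=2))
        assert len(result.reports) == 4
        table = result.to_table()
        assert list(table.columns) == ["Lx", "N%", "ACC%", "PRE%", "SEN%",
                                       "SPE%", "MCC%"]
        # best cell is the argmax of mean MCC over the table
        best_mcc = result.reports[result.best].mean["mcc"]
        assert best_mcc == pytest.approx(
            max(r.mean["mcc"] for r in result.reports.values()))

    def test_empty_grid_rejected(self, dataset, property_table):
        with pytest.raises(ValueError, match="grid"):
            run_grid(dataset, property_table, [], [100])


class TestAblation:
    def test_cartesian_row_count(self, dataset, property_table):
        frame = run_ablation(
            dataset, property_table,
            combos=[("aac",), ("bpf", "aac")],
            classifiers=["RF", "KN"],
            length_cfg=LEN, enc_cfg=ENC, model_cfg=FAST_MODEL,
            cv_cfg=CVConfig(fold_seed=4),
            aug_cfg=AugmentationConfig(seed=4))
        assert len(frame) == 2 * 2 * 2
        assert set(frame["features"]) == {"AAC", "BPF+AAC"}

    def test_empty_combo_rejected(self, dataset, property_table):
        with pytest.raises(ValueError, match="combo"):
            run_ablation(dataset, property_table, combos=[()])
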