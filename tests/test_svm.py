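import numpy as np
import pandas as pd
import pytest

from rps19struct.svm import (TrainedModel, TrainingConfig, cross_validate,
                             saturation_scan, select_features_and_hyperparams,
                             train_final)
from rps19struct.synthetic import FeatureTableSpec, make_feature_table

INFORMATIVE = ("ddg", "rsasa", "conservation", "bsa", "hb_num")


def separable_table(n=30):
    rng = np.random.default_rng(0)
    rows = []
    for label, shift in (("dba", 3.0), ("neutral", -3.0)):
        for _ in range(n):
            rows.append({"label": label,
                         "f1": rng.normal(shift, 0.3),
                         "f2": rng.normal(-shift, 0.3),
                         "f3": rng.normal(0, 1.0)})
    return pd.DataFrame(rows)


def test_separable_table_reaches_perfect_cv_mcc():
    out = cross_validate(separable_table(), ("f1", "f2"), c=1.0, gamma=0.1)
    assert out.mcc_pooled == 1.0
    assert out.n_correct_positive == out.n_positive == 30


def test_permuted_labels_give_near_zero_cv_mcc():
    rng = np.random.default_rng(1)
    mccs = []
    for rep in range(20):
        table = separable_table()
        table["label"] = rng.permutation(table["label"].to_numpy())
        out = cross_validate(table, ("f1", "f2", "f3"), c=1.0, gamma=0.1,
                             seed=rep)
        mccs.append(out.mcc_pooled)
    assert np.mean(np.abs(mccs)) < 0.35


def test_cv_is_deterministic_for_fixed_seed(feature_table):
    a = cross_validate(feature_table, INFORMATIVE, 100, 0.01, seed=7)
    b = cross_validate(feature_table, INFORMATIVE, 100, 0.01, seed=7)
    assert a.mcc_pooled == b.mcc_pooled
    assert a.confusion == b.confusion
    c = cross_validate(feature_table, INFORMATIVE, 100, 0.01, seed=8)
    assert c.confusion != a.confusion or c.mcc_pooled != a.mcc_pooled


def test_cv_requires_both_classes_and_enough_samples():
    table = separable_table(6)
    single = table[table.label == "dba"]
    with pytest.raises(ValueError):
        cross_validate(single, ("f1",), 1, 0.1)
    tiny = pd.concat([table[table.label == "dba"].head(3),
                      table[table.label == "neutral"].head(3)])
    with pytest.raises(ValueError):
        cross_validate(tiny, ("f1",), 1, 0.1, folds=5)


def test_selection_recovers_informative_features():
    """5 informative + 2 noise candidates: the winner keeps >= 4 informative."""
    table = make_feature_table(FeatureTableSpec(n_positive=29, n_negative=30,
                                                seed=7))
    cfg = TrainingConfig(candidate_features=INFORMATIVE + ("noise1", "noise2"),
                         min_features=5, c_grid=(1.0, 100.0),
                         gamma_grid=(0.01, 0.1), seed=0)
    feats, c, gamma, mcc = select_features_and_hyperparams(table, cfg)
    assert len(set(feats) & set(INFORMATIVE)) >= 4
    assert mcc >= 0.5
    assert c in cfg.c_grid and gamma in cfg.gamma_grid


def test_single_combination_when_min_equals_pool(feature_table):
    cfg = TrainingConfig(candidate_features=("ddg", "rsasa", "conservation",
                                             "bsa", "hb_num"),
                         min_features=5, c_grid=(1.0,), gamma_grid=(0.1,))
    feats, c, gamma, mcc = select_features_and_hyperparams(feature_table, cfg)
    assert feats == ("ddg", "rsasa", "conservation", "bsa", "hb_num")
    direct = cross_validate(feature_table, feats, 1.0, 0.1)
    assert mcc == direct.mcc_pooled


def test_tie_breaks_prefer_fewer_features():
    # two redundant copies of one perfectly separating feature: every combo
    # reaches MCC 1, so the 2-feature minimum must win over the 3-feature set
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(4, 0.2, 20), rng.normal(-4, 0.2, 20)])
    table = pd.DataFrame({
        "label": ["dba"] * 20 + ["neutral"] * 20,
        "a": x, "b": x.copy(), "c": x.copy(),
    })
    cfg = TrainingConfig(candidate_features=("a", "b", "c"), min_features=2,
                         c_grid=(0.1, 1.0), gamma_grid=(0.1, 1.0))
    feats, c, gamma, mcc = select_features_and_hyperparams(table, cfg)
    assert mcc == 1.0
    assert feats == ("a", "b")      # fewest features, lexicographic
    assert (c, gamma) == (0.1, 0.1)  # smallest C, then smallest gamma


def test_budget_guard():
    cfg = TrainingConfig(candidate_features=tuple("abcdefghijkl"),
                         min_features=5, fit_budget=10)
    with pytest.raises(RuntimeError, match="budget"):
        select_features_and_hyperparams(pd.DataFrame(), cfg)


def test_resubstitution_inflates_mcc_relative_to_cv():
    """Leak check: evaluating on the training data wildly overstates a noise
    model, while the cross-validated protocol stays near zero."""
    table = make_feature_table(FeatureTableSpec(separation=0.0, seed=13))
    feats = INFORMATIVE
    honest = cross_validate(table, feats, c=100.0, gamma=1.0, seed=0)
    leaky_model = train_final(table, feats, c=100.0, gamma=1.0)
    from sklearn.metrics import matthews_corrcoef
    y = (table.label == "dba").astype(int)
    leaky_mcc = matthews_corrcoef(y, leaky_model.predict(table))
    assert abs(honest.mcc_pooled) < 0.35
    assert leaky_mcc > honest.mcc_pooled + 0.4


def test_final_model_separable_training_predictions(feature_table):
    table = separable_table()
    model = train_final(table, ("f1", "f2"), c=1.0, gamma=0.1)
    pred = model.predict(table)
    y = (table.label == "dba").astype(int).to_numpy()
    assert (pred == y).all()
    scores = model.scores(table)
    assert scores.min() >= 0.0 and scores.max() <= 1.0
    # deep-margin points sit near the extremes
    f = model.decision_values(table)
    assert scores[np.argmax(f)] > 0.9
    assert scores[np.argmin(f)] < 0.1


def test_model_save_load_round_trip(tmp_path, feature_table):
    model = train_final(feature_table, INFORMATIVE, c=100.0, gamma=0.01,
                        cv_mcc=0.8)
    path = tmp_path / "model.json"
    model.save(path)
    back = TrainedModel.load(path, table=feature_table)
    np.testing.assert_allclose(back.scores(feature_table),
                               model.scores(feature_table), atol=1e-9)
    assert back.cv_mcc == 0.8
    with pytest.raises(ValueError):
        TrainedModel.load(path)


def test_saturation_scan_covers_all_cells(feature_table):
    model = train_final(feature_table, ("ddg", "rsasa", "conservation",
                                        "bsa", "hb_num"), c=100.0, gamma=0.01)
    rng = np.random.default_rng(5)

    def featureizer(pos, wt, mut):
        return {"ddg": float(rng.lognormal(0, 1)),
                "rsasa": float(rng.beta(2, 5)),
                "conservation": float(rng.normal(0, 1)),
                "bsa": float(rng.lognormal(2, 1)),
                "hb_num": int(rng.poisson(1))}

    scan = saturation_scan(model, featureizer, "MKWNPGAFTS")
    assert scan.scores.shape == (10, 20)
    assert int(scan.scores.notna().sum().sum()) == 190   # 10 x 19 cells
    for pos, wt in enumerate("MKWNPGAFTS", start=1):
        assert np.isnan(scan.scores.loc[pos, wt])
    values = scan.scores.to_numpy()
    finite = values[np.isfinite(values)]
    assert finite.min() >= 0.0 and finite.max() <= 1.0


def test_scan_proline_intolerance_with_planted_model():
    """A model trained to flag proline substitutions scores the Pro column
    highest in helix positions."""
    rng = np.random.default_rng(8)
    rows = []
    for _ in range(40):
        is_pro = rng.random() < 0.5
        rows.append({"label": "dba" if is_pro else "neutral",
                     "is_proline_sub": float(is_pro),
                     "jitter": rng.normal()})
    table = pd.DataFrame(rows)
    model = train_final(table, ("is_proline_sub", "jitter"), c=10.0, gamma=0.1)

    def featureizer(pos, wt, mut):
        return {"is_proline_sub": float(mut == "P"), "jitter": 0.0}

    scan = saturation_scan(model, featureizer, "AAALLL")
    pro = scan.scores["P"].to_numpy()
    others = scan.scores.drop(columns=["P"]).to_numpy()
    assert np.nanmin(pro) > np.nanmax(others)
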