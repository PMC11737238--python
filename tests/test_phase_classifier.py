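"""Forest machinery: mtry rule, OOB mechanics, combination, minimal depth,
partial dependence — each against brute-force re-computation."""

import numpy as np
import pandas as pd
import pytest

from foxphase import phase_classifier as pc


def synthetic_rows(n_per_class=120, seed=0, noise_col=False):
    """Separable 3-class table where every standard predictor carries some
    phase signal (class-shifted distributions)."""
    rng = np.random.default_rng(seed)
    frames = []
    spec = {
        "exploratory": dict(pv=0.05, sl=180.0, ta_sd=1.8, dist=1800.0,
                            seasons=["winter", "spring"], p_day=0.9),
        "transient": dict(pv=0.30, sl=200.0, ta_sd=0.3, dist=600.0,
                          seasons=["autumn"], p_day=0.05),
        "stationary": dict(pv=0.00, sl=80.0, ta_sd=1.8, dist=1200.0,
                           seasons=["summer", "autumn"], p_day=0.5),
    }
    landclass_w = {
        "exploratory": [0.05, 0.8, 0.05, 0.02, 0.02, 0.03, 0.03],
        "transient": [0.8, 0.05, 0.05, 0.02, 0.02, 0.03, 0.03],
        "stationary": [0.05, 0.05, 0.1, 0.7, 0.05, 0.02, 0.03],
    }
    for phase, p in spec.items():
        n = n_per_class
        frames.append(pd.DataFrame({
            "individual_id": "a",
            "phase": phase,
            "sl": rng.normal(p["sl"], 25.0, n),
            "ta": rng.normal(0.0, p["ta_sd"], n).clip(-np.pi, np.pi),
            "pv": rng.normal(p["pv"], 0.04, n),
            "landclass": rng.choice(np.arange(1, 8), n, p=landclass_w[phase]),
            "dist_flowing_waters": rng.gamma(3.0, p["dist"] / 3.0, n),
            "dist_protected_areas": rng.gamma(2.0, p["dist"] / 2.0, n),
            "dist_district_road": rng.gamma(4.0, p["dist"] / 4.0, n),
            "dist_agricultural_road": rng.gamma(3.0, p["dist"] / 3.0, n),
            "dist_linear_anthropogenic": rng.gamma(2.0, p["dist"] / 2.0, n),
            "season": rng.choice(p["seasons"], n),
            "time_of_day": rng.choice(
                ["day", "night"], n, p=[p["p_day"], 1 - p["p_day"]]
            ),
        }))
    rows = pd.concat(frames, ignore_index=True)
    if noise_col:
        rows["noise"] = rng.normal(size=len(rows))
    return rows


def test_auto_mtry_is_floor_sqrt_p():
    assert pc.auto_mtry(11) == 3
    assert pc.auto_mtry(9) == 3
    assert pc.auto_mtry(8) == 2
    model = pc.fit_forest(synthetic_rows(), n_trees=20, seed=0)
    assert model.mtry == 3


def test_single_class_input_rejected():
    rows = synthetic_rows()
    with pytest.raises(ValueError, match="single phase"):
        pc.fit_forest(rows[rows["phase"] == "transient"], n_trees=5, seed=0)


def test_unbalanced_input_warns():
    rows = pd.concat([synthetic_rows(), synthetic_rows().iloc[:10]])
    with pytest.warns(UserWarning, match="balanced"):
        pc.fit_forest(rows, n_trees=5, seed=0)


def test_per_tree_oob_fraction_near_e_inverse():
    model = pc.fit_forest(synthetic_rows(n_per_class=200), n_trees=150, seed=1)
    frac = model.oob_fractions()
    assert frac.mean() == pytest.approx(np.exp(-1), abs=0.02)


def test_same_seed_same_oob_predictions():
    rows = synthetic_rows()
    a = pc.fit_forest(rows, n_trees=40, seed=3)
    b = pc.fit_forest(rows, n_trees=40, seed=3)
    assert np.array_equal(pc.oob_votes(a), pc.oob_votes(b))


def test_combine_forests_counts_and_identity():
    rows = synthetic_rows()
    models = [pc.fit_forest(rows, n_trees=30, seed=s) for s in range(5)]
    combined = pc.combine_forests(models)
    assert combined.n_trees == 150
    empty = pc.ForestModel(
        trees=[], inbag=[], schema=models[0].schema, mtry=models[0].mtry,
        X=models[0].X, y=models[0].y,
    )
    again = pc.combine_forests([models[0], empty])
    assert again.n_trees == models[0].n_trees
    assert np.array_equal(pc.oob_votes(again), pc.oob_votes(models[0]))


def test_combine_rejects_mismatched_training_data():
    a = pc.fit_forest(synthetic_rows(seed=0), n_trees=5, seed=0)
    b = pc.fit_forest(synthetic_rows(seed=99), n_trees=5, seed=0)
    with pytest.raises(ValueError, match="identical"):
        pc.combine_forests([a, b])


def test_combined_oob_vote_equals_brute_force_tally():
    rows = synthetic_rows(n_per_class=60)
    models = [pc.fit_forest(rows, n_trees=25, seed=s) for s in (0, 1)]
    combined = pc.combine_forests(models)
    votes = pc.oob_votes(combined)
    # brute force: walk every tree of every constituent
    n = combined.n_rows
    want = np.zeros_like(votes)
    for m in models:
        for k, tree in enumerate(m.trees):
            inbag = set(m.inbag[k].tolist())
            oob = [i for i in range(n) if i not in inbag]
            pred = tree.predict(m.X[oob]).astype(int)
            for i, p in zip(oob, pred):
                want[i, p] += 1
    assert np.array_equal(votes, want)


def test_oob_confusion_perfect_and_conservation():
    rows = synthetic_rows(n_per_class=150)
    model = pc.combine_forests(
        [pc.fit_forest(rows, n_trees=100, seed=s) for s in (0, 1, 2)]
    )
    rep = pc.oob_confusion(model)
    # row sums = per-class OOB-covered counts
    counts = rows["phase"].value_counts()
    for cls in rep.confusion.index:
        assert rep.confusion.loc[cls].sum() <= counts[cls]
    total = rep.confusion.to_numpy().sum() + rep.n_excluded
    assert total == model.n_rows
    # strongly separable -> near-perfect OOB accuracy
    assert rep.accuracy >= 95.0
    assert rep.accuracy == pytest.approx(100.0 - rep.overall_error)


def test_minimal_depth_hand_built_tree():
    """A depth-2 stump-like tree: root splits on pv, depth-1 node on sl."""
    rows = pd.DataFrame({
        "individual_id": "a",
        "phase": ["transient"] * 4 + ["stationary"] * 2 + ["exploratory"] * 2,
        "sl": [200, 210, 190, 205, 80, 82, 200, 195],
        "ta": 0.0,
        "pv": [0.3, 0.31, 0.29, 0.3, 0.0, 0.01, 0.05, 0.04],
        "landclass": 1,
        "dist_flowing_waters": 1.0, "dist_protected_areas": 1.0,
        "dist_district_road": 1.0, "dist_agricultural_road": 1.0,
        "dist_linear_anthropogenic": 1.0,
        "season": "autumn", "time_of_day": "night",
    })
    from sklearn.tree import DecisionTreeClassifier

    schema = pc.ForestSchema()
    X = schema.encode(rows)
    y = schema.encode_classes(rows["phase"])
    tree = DecisionTreeClassifier(random_state=0).fit(X, y)
    model = pc.ForestModel(
        trees=[tree], inbag=[np.arange(len(y))], schema=schema, mtry=3,
        X=X, y=y,
    )
    rep = pc.minimal_depth(model).set_index("variable")
    assert rep.loc["pv", "mean_minimal_depth"] == 0.0  # root split
    used = rep[rep["trees_used"] == 1].index
    depths = rep.loc[used, "mean_minimal_depth"]
    assert set(depths) <= {0.0, 1.0}
    # unused variables carry max depth + 1
    fill = rep["mean_minimal_depth"].max()
    assert fill == tree.get_depth() + 1
    assert (rep.loc[rep["trees_used"] == 0, "mean_minimal_depth"] == fill).all()


def test_minimal_depth_invariant_to_tree_order():
    rows = synthetic_rows()
    model = pc.fit_forest(rows, n_trees=30, seed=5)
    rep1 = pc.minimal_depth(model)
    shuffled = pc.ForestModel(
        trees=list(reversed(model.trees)),
        inbag=list(reversed(model.inbag)),
        schema=model.schema, mtry=model.mtry, X=model.X, y=model.y,
    )
    rep2 = pc.minimal_depth(shuffled)
    pd.testing.assert_frame_equal(rep1, rep2)


def test_pure_noise_predictor_ranks_last_in_most_runs():
    schema = pc.ForestSchema(
        predictors=pc.PREDICTORS + ("noise",),
    )
    wins = 0
    for seed in range(10):
        rows = synthetic_rows(seed=seed, noise_col=True)
        model = pc.fit_forest(rows, n_trees=60, seed=seed, schema=schema)
        rep = pc.minimal_depth(model)
        wins += rep["variable"].iloc[-1] == "noise"
    assert wins >= 9


def test_class_probability_normalized_and_matches_brute_force():
    rows = synthetic_rows()
    model = pc.fit_forest(rows, n_trees=40, seed=7)
    X = model.X[:50]
    probs = pc.class_probability(model, X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    want = np.zeros_like(probs)
    for tree in model.trees:
        p = tree.predict_proba(X)
        want[:, tree.classes_.astype(int)] += p
    want /= model.n_trees
    assert np.allclose(probs, want)
    with pytest.raises(ValueError, match="schema"):
        pc.class_probability(model, X[:, :5])


def test_pdp_probabilities_sum_to_one_and_modes():
    rows = synthetic_rows()
    model = pc.fit_forest(rows, n_trees=40, seed=8)
    for var, mode in (("pv", "average"), ("season", "average"),
                      ("sl", "at_means"), ("landclass", "at_means")):
        grid = pc.partial_dependence(model, var, grid_size=9, mode=mode,
                                     sample=100, seed=0)
        assert np.allclose(grid.probabilities.sum(axis=1), 1.0, atol=1e-9)
        if var in model.schema.categorical:
            assert len(grid.grid) == len(model.schema.categorical[var])
    with pytest.raises(ValueError, match="unknown variable"):
        pc.partial_dependence(model, "altitude")


def test_constant_features_give_flat_pdp():
    """If no split is possible every tree is a single leaf: flat profiles."""
    rng = np.random.default_rng(1)
    rows = synthetic_rows(n_per_class=40)
    for col in rows.columns:
        if col not in ("individual_id", "phase"):
            rows[col] = rows[col].iloc[0]
    model = pc.fit_forest(rows, n_trees=10, seed=0)
    grid = pc.partial_dependence(model, "pv", grid_size=5, sample=None)
    assert np.allclose(grid.probabilities, grid.probabilities[0])


def test_transient_probability_increases_with_pv(pipeline_result):
    """On the separable cohort the transient-class partial dependence rises
    from the bottom to the top of the pv grid."""
    model = pipeline_result.model
    grid = pc.partial_dependence(model, "pv", grid_size=15, sample=300, seed=0)
    j = list(grid.class_order).index("transient")
    assert grid.probabilities[-1, j] > grid.probabilities[0, j]
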