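"""Random-forest characterization of movement phases.

The classifier is an ensemble of CART trees (Gini splits, unlimited depth,
per-tree bootstrap) over the 11 predictors, with the three movement phases
as target.  Categorical predictors (landclass, season, time of day) enter as
single integer-coded columns, one per variable, so that every predictor gets
exactly one candidate slot in each mtry draw and minimal depth is comparable
across variables — the factor semantics of classical random-forest
implementations.  The module adds, on top of the fitted trees:

* combination of several independently seeded forests into one model whose
  out-of-bag (OOB) prediction for a row pools the votes of every tree for
  which that row was OOB;
* the OOB confusion matrix with overall and class-conditional error rates;
* minimal-depth variable importance (depth of the shallowest node splitting
  on a variable, per tree, root = 0; trees not using the variable contribute
  their maximum depth + 1);
* partial dependence profiles of the three class probabilities.

Tree growth itself is delegated to scikit-learn's RandomForestClassifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .covariates import CATEGORICAL_LEVELS, PREDICTORS

CLASS_ORDER = ("exploratory", "transient", "stationary")


@dataclass(frozen=True)
class ForestSchema:
    """Predictor names, categorical levels and encoded-column layout."""

    predictors: tuple[str, ...] = PREDICTORS
    categorical: dict = field(default_factory=lambda: dict(CATEGORICAL_LEVELS))
    class_order: tuple[str, ...] = CLASS_ORDER

    @property
    def feature_names(self) -> list[str]:
        return list(self.predictors)

    @property
    def feature_vars(self) -> list[str]:
        """Original variable behind each encoded column (identity here)."""
        return list(self.predictors)

    def level_code(self, variable: str, level) -> float:
        return float(self.categorical[variable].index(level) + 1)

    def encode(self, rows: pd.DataFrame) -> np.ndarray:
        """One column per predictor; categorical levels as integer codes."""
        cols = []
        for p in self.predictors:
            if p in self.categorical:
                lut = {lvl: i + 1.0 for i, lvl in enumerate(self.categorical[p])}
                bad = set(rows[p].unique()) - set(lut)
                if bad:
                    raise ValueError(f"{p}: unknown levels {sorted(map(str, bad))}")
                cols.append(rows[p].map(lut).to_numpy(float))
            else:
                cols.append(rows[p].to_numpy(float))
        return np.column_stack(cols)

    def encode_classes(self, phases: pd.Series) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_order)}
        bad = set(phases.unique()) - set(lut)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        return phases.map(lut).to_numpy()


def auto_mtry(n_predictors: int) -> int:
    """Candidate predictors per split: floor of the square root of p."""
    return int(np.floor(np.sqrt(n_predictors)))


@dataclass
class ForestModel:
    """A fitted (possibly combined) ensemble with its training data."""

    trees: list                      # sklearn DecisionTreeClassifier objects
    inbag: list[np.ndarray]          # per-tree in-bag row-index multisets
    schema: ForestSchema
    mtry: int
    X: np.ndarray                    # encoded training matrix
    y: np.ndarray                    # class indices into schema.class_order

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def oob_mask(self, k: int) -> np.ndarray:
        """Boolean mask of rows out of bag for tree ``k``."""
        counts = np.bincount(self.inbag[k], minlength=self.n_rows)
        return counts == 0

    def oob_fractions(self) -> np.ndarray:
        """Per-tree fraction of rows left out of the bootstrap sample."""
        return np.array([self.oob_mask(k).mean() for k in range(self.n_trees)])


def fit_forest(
    rows: pd.DataFrame,
    n_trees: int = 300,
    mtry: int | str = "auto",
    seed: int = 0,
    schema: ForestSchema | None = None,
) -> ForestModel:
    """Fit one constituent forest on a (balanced) feature table.

    ``mtry="auto"`` resolves to floor(sqrt(p)) for p original predictors
    (3 for the 11-variable table).  A warning is appropriate for unbalanced
    input, an error for single-class input.
    """
    schema = schema or ForestSchema()
    if rows["phase"].nunique() < 2:
        raise ValueError("training data holds a single phase class")
    counts = rows["phase"].value_counts()
    if counts.max() != counts.min():
        import warnings

        warnings.warn("training data is not class-balanced", stacklevel=2)
    X = schema.encode(rows)
    y = schema.encode_classes(rows["phase"])
    m = auto_mtry(len(schema.predictors)) if mtry == "auto" else int(mtry)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m,
        criterion="gini",
        min_samples_leaf=1,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    inbag = [np.asarray(s, dtype=np.int64) for s in rf.estimators_samples_]
    return ForestModel(list(rf.estimators_), inbag, schema, m, X, y)


def combine_forests(models: list[ForestModel]) -> ForestModel:
    """Concatenate constituent forests trained on identical data.

    The combined model's OOB machinery pools, for each training row, the
    votes of every tree (across constituents) for which the row was OOB.
    """
    if not models:
        raise ValueError("no models to combine")
    head = models[0]
    for m in models[1:]:
        if m.schema != head.schema or m.X.shape != head.X.shape or not np.array_equal(m.y, head.y) or not np.array_equal(m.X, head.X):
            raise ValueError("forests were not trained on identical data/schema")
        if m.mtry != head.mtry:
            raise ValueError("forests differ in mtry")
    return ForestModel(
        trees=[t for m in models for t in m.trees],
        inbag=[b for m in models for b in m.inbag],
        schema=head.schema,
        mtry=head.mtry,
        X=head.X,
        y=head.y,
    )


# ---------------------------------------------------------------------------
# OOB validation
# ---------------------------------------------------------------------------

def oob_votes(model: ForestModel) -> np.ndarray:
    """(n_rows, n_classes) counts of OOB hard votes."""
    n_cls = len(model.schema.class_order)
    votes = np.zeros((model.n_rows, n_cls), dtype=np.int64)
    for k, tree in enumerate(model.trees):
        oob = np.flatnonzero(model.oob_mask(k))
        if oob.size == 0:
            continue
        pred = tree.predict(model.X[oob]).astype(int)
        np.add.at(votes, (oob, pred), 1)
    return votes


@dataclass
class OobReport:
    confusion: pd.DataFrame          # rows = true class, cols = predicted
    overall_error: float             # percent
    accuracy: float                  # percent
    per_class_error: dict[str, float]
    n_excluded: int                  # rows OOB in zero trees

    def to_frame(self) -> pd.DataFrame:
        out = self.confusion.copy()
        out["class_error_pct"] = [
            self.per_class_error[c] for c in out.index
        ]
        return out


def oob_confusion(model: ForestModel) -> OobReport:
    """OOB confusion matrix plus overall and class-conditional errors (%).

    A row's OOB prediction is the majority class over the votes of all trees
    for which the row was out of bag (ties broken toward the first class in
    ``schema.class_order``); rows that were OOB in no tree are excluded and
    counted.
    """
    votes = oob_votes(model)
    covered = votes.sum(axis=1) > 0
    n_excluded = int((~covered).sum())
    if covered.sum() < 0.99 * model.n_rows:
        raise ValueError(
            f"OOB votes available for only {covered.sum()} of {model.n_rows} "
            "rows; grow more trees"
        )
    pred = votes[covered].argmax(axis=1)
    true = model.y[covered]
    classes = model.schema.class_order
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    np.add.at(mat, (true, pred), 1)
    confusion = pd.DataFrame(mat, index=list(classes), columns=list(classes))
    overall = 100.0 * (pred != true).mean()
    per_class = {
        c: (100.0 * (pred[true == i] != i).mean()) if (true == i).any() else np.nan
        for i, c in enumerate(classes)
    }
    return OobReport(confusion, overall, 100.0 - overall, per_class, n_excluded)


# ---------------------------------------------------------------------------
# minimal depth
# ---------------------------------------------------------------------------

def _node_depths(tree) -> np.ndarray:
    t = tree.tree_
    depths = np.zeros(t.node_count, dtype=int)
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depths[node] = d
        if t.children_left[node] != -1:
            stack.append((t.children_left[node], d + 1))
            stack.append((t.children_right[node], d + 1))
    return depths


def minimal_depth(model: ForestModel) -> pd.DataFrame:
    """Mean minimal depth per original variable, ascending (most important first).

    Within a tree, a variable's minimal depth is the depth of the shallowest
    node that splits on any of its encoded columns (root = 0).  A tree that
    never uses the variable contributes that tree's maximum depth + 1, a
    documented fill-in convention isolated here.  Also reports in how many
    trees each variable is used at least once.
    """
    varnames = list(model.schema.predictors)
    var_of_col = model.schema.feature_vars
    sums = {v: 0.0 for v in varnames}
    used = {v: 0 for v in varnames}
    for tree in model.trees:
        t = tree.tree_
        depths = _node_depths(tree)
        split = t.children_left != -1
        fill = depths.max() + 1
        best = {v: fill for v in varnames}
        for node in np.flatnonzero(split):
            v = var_of_col[t.feature[node]]
            if depths[node] < best[v]:
                best[v] = depths[node]
        for v in varnames:
            sums[v] += best[v]
            if best[v] < fill:
                used[v] += 1
    out = pd.DataFrame({
        "variable": varnames,
        "mean_minimal_depth": [sums[v] / model.n_trees for v in varnames],
        "trees_used": [used[v] for v in varnames],
    })
    return out.sort_values("mean_minimal_depth", ignore_index=True)


# ---------------------------------------------------------------------------
# prediction and partial dependence
# ---------------------------------------------------------------------------

def class_probability(model: ForestModel, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Mean over trees of per-tree leaf class proportions; rows sum to 1."""
    if isinstance(X, pd.DataFrame):
        X = model.schema.encode(X)
    if X.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"schema mismatch: expected {model.X.shape[1]} encoded columns, "
            f"got {X.shape[1]}"
        )
    n_cls = len(model.schema.class_order)
    acc = np.zeros((X.shape[0], n_cls))
    for tree in model.trees:
        proba = tree.predict_proba(X)
        cols = tree.classes_.astype(int)
        acc[:, cols] += proba
    return acc / model.n_trees


@dataclass
class PdpGrid:
    variable: str
    grid: np.ndarray
    probabilities: np.ndarray        # (len(grid), 3), class_order columns
    class_order: tuple[str, ...]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"grid": self.grid})
        for j, c in enumerate(self.class_order):
            out[f"p_{c}"] = self.probabilities[:, j]
        return out


def _set_variable(schema: ForestSchema, X: np.ndarray, variable: str, value):
    col = schema.feature_names.index(variable)
    X = X.copy()
    if variable in schema.categorical:
        X[:, col] = schema.level_code(variable, value)
    else:
        X[:, col] = value
    return X


def partial_dependence(
    model: ForestModel,
    variable: str,
    grid_size: int = 50,
    mode: str = "average",
    sample: int | None = 500,
    seed: int = 0,
) -> PdpGrid:
    """Partial dependence of the three class probabilities on one predictor.

    ``mode="average"`` (Friedman's definition, the default): for each grid
    value the variable is overwritten in every training row (or in a seeded
    subsample of ``sample`` rows, for tractability) and the predicted
    class-probability vectors are averaged.  ``mode="at_means"`` predicts a
    single profile with the other numeric variables held at their training
    means and categoricals at their modes.  Numeric grids are equally spaced
    quantiles of the training values; categorical grids are all levels.
    """
    if variable not in model.schema.predictors:
        raise ValueError(f"unknown variable {variable!r}")
    if mode not in ("average", "at_means"):
        raise ValueError(f"unknown mode {mode!r}")
    schema = model.schema
    if variable in schema.categorical:
        grid = np.asarray(schema.categorical[variable], dtype=object)
    else:
        col = schema.feature_names.index(variable)
        vals = model.X[:, col]
        grid = np.unique(np.quantile(vals, np.linspace(0.0, 1.0, grid_size)))

    if mode == "average":
        base = model.X
        if sample is not None and sample < base.shape[0]:
            rng = np.random.default_rng(seed)
            base = base[rng.choice(base.shape[0], sample, replace=False)]
    else:
        base = model.X.mean(axis=0, keepdims=True).copy()
        for cat in schema.categorical:  # categoricals at their mode
            col = schema.feature_names.index(cat)
            vals, counts = np.unique(model.X[:, col], return_counts=True)
            base[0, col] = vals[np.argmax(counts)]

    probs = np.empty((len(grid), len(schema.class_order)))
    for gi, v in enumerate(grid):
        Xm = _set_variable(schema, base, variable, v)
        probs[gi] = class_probability(model, Xm).mean(axis=0)
    return PdpGrid(variable, grid, probs, schema.class_order, mode)
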