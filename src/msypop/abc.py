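"""ABC random-forest model choice and parameter estimation.

Scenario choice follows the ABC-RF procedure of Pudlo et al. (2016): a
classification forest is trained on a reference table of per-scenario
simulations summarized by the unfolded SFS; the selected scenario is the
majority vote of the trees at the observed summary, and the posterior
probability of that selection is estimated by a regression forest trained on
the out-of-bag success indicator of the classifier.  Parameter estimation
for the selected scenario uses quantile regression forests (Meinshausen
2006): the point estimate is the forest mean at the observed point and the
posterior quantiles come from the leaf-co-occupancy-weighted distribution of
training responses.

The two estimators (:class:`ABCModelChoice`, :class:`ABCParameterEstimator`)
are scikit-learn compatible (``fit``/``predict``, ``get_params``) so they
compose with sklearn model-selection tooling; the module-level functions
mirror the pipeline's operation names and stay thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .coalescent import DemographicModel, simulate_sfs_batch

#: fixed tie-break order for argmax over vote fractions
MODEL_ORDER = ("demic", "cultural", "continuous_migration")


@dataclass
class ReferenceTable:
    """(model label, parameter draw, summary vector) rows for ABC.

    Summary dimension must be identical across models; parameter columns may
    be NaN for models lacking a parameter (e.g. m outside the
    continuous-migration scenario).
    """

    model_labels: np.ndarray
    params: pd.DataFrame
    summaries: np.ndarray
    summary_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model_labels = np.asarray(self.model_labels)
        self.summaries = np.asarray(self.summaries, dtype=float)
        if np.isnan(self.summaries).any():
            raise ValueError("reference table has missing summaries")
        if len(self.model_labels) != self.summaries.shape[0]:
            raise ValueError("label / summary row mismatch")
        if self.summaries.shape[1] != len(self.summary_names):
            raise ValueError("summary dimension does not match names")

    @property
    def n_models(self) -> int:
        return len(np.unique(self.model_labels))

    def restrict_to(self, model: str) -> "ReferenceTable":
        mask = self.model_labels == model
        if not mask.any():
            raise ValueError(f"no rows for model {model!r}")
        params = self.params.loc[mask].dropna(axis=1, how="all").reset_index(
            drop=True
        )
        return ReferenceTable(
            model_labels=self.model_labels[mask],
            params=params,
            summaries=self.summaries[mask],
            summary_names=list(self.summary_names),
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.summaries, columns=self.summary_names
        )
        out = pd.concat(
            [pd.Series(self.model_labels, name="model"), self.params, df], axis=1
        )
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        sum_cols = [c for c in df.columns if c.startswith("sfs_") or c == "total_S"]
        par_cols = [c for c in df.columns if c not in sum_cols and c != "model"]
        return cls(
            model_labels=df["model"].to_numpy(),
            params=df[par_cols].reset_index(drop=True),
            summaries=df[sum_cols].to_numpy(dtype=float),
            summary_names=sum_cols,
        )


@dataclass
class ModelChoiceResult:
    selected_model: str
    vote_fractions: dict[str, float]
    posterior_probability: float
    oob_prior_error: float
    n_trees: int
    seed: int | None


@dataclass
class ParameterEstimate:
    name: str
    point: float
    q05: float
    q50: float
    q95: float
    flatness: float


# ---------------------------------------------------------------------------
# Reference-table construction


def build_reference_table(
    models: dict[str, DemographicModel],
    n_sims_per_model: int,
    base_seed: int,
) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` prior-predictive rows for each model.

    Models must share deme structure and sample sizes so their summary
    vectors are directly comparable.  Row i of model j is seeded
    ``base_seed + j * n_sims_per_model + i`` and therefore reproducible in
    isolation.
    """
    sizes = {name: tuple(sorted(m.sample_sizes.items())) for name, m in models.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models have mismatched sample sizes: {sizes}")
    labels: list[str] = []
    param_rows: list[dict] = []
    summaries: list[np.ndarray] = []
    names: list[str] | None = None
    for j, (name, model) in enumerate(models.items()):
        rows = simulate_sfs_batch(
            model, n_sims_per_model, base_seed + j * n_sims_per_model
        )
        for draw, sfs in rows:
            labels.append(name)
            param_rows.append(draw.as_row())
            vec = sfs.flatten()
            if names is None:
                names = sfs.column_names()
            elif len(vec) != len(names):
                raise ValueError("summary dimension mismatch across models")
            summaries.append(vec)
    return ReferenceTable(
        model_labels=np.asarray(labels),
        params=pd.DataFrame(param_rows),
        summaries=np.vstack(summaries),
        summary_names=list(names or []),
        provenance={
            "base_seed": base_seed,
            "n_sims_per_model": n_sims_per_model,
            "models": list(models),
        },
    )


# ---------------------------------------------------------------------------
# Estimators


def _tie_break_order(classes: np.ndarray) -> list[str]:
    """Classes in the fixed documented order, unknown names appended sorted."""
    known = [m for m in MODEL_ORDER if m in classes]
    extra = sorted(c for c in classes if c not in MODEL_ORDER)
    return known + extra


class ABCModelChoice(BaseEstimator, ClassifierMixin):
    """Random-forest scenario classifier with ABC-RF posterior probability.

    Parameters
    ----------
    n_trees : int, default 500
        Forest size; fewer than 50 trees triggers a warning.
    random_state : int, optional
        Seeds both forests; results are deterministic given
        (training table, random_state, n_trees).

    Attributes
    ----------
    classes_ : ndarray of model labels.
    oob_prior_error_ : float
        Out-of-bag misclassification rate — the ABC-RF "prior error rate".
    confusion_ : DataFrame
        Out-of-bag confusion matrix (rows: true model, columns: predicted).
    """

    def __init__(self, n_trees: int = 500, random_state: int | None = None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y) -> "ABCModelChoice":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("model choice needs >= 2 distinct model labels")
        if counts.min() < 2:
            raise ValueError("each model needs >= 2 reference rows")
        if self.n_trees < 50:
            warnings.warn("n_trees < 50: vote fractions will be noisy", stacklevel=2)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        oob = self.forest_.oob_decision_function_
        # rows never out-of-bag (tiny tables) count as misclassified
        valid = ~np.isnan(oob).any(axis=1)
        oob_pred = np.full(len(y), -1, dtype=int)
        oob_pred[valid] = np.argmax(oob[valid], axis=1)
        true_idx = np.searchsorted(self.classes_, y)
        success = (oob_pred == true_idx) & valid
        self.oob_success_ = success.astype(float)
        self.oob_prior_error_ = float(1.0 - success.mean())
        conf = np.zeros((len(self.classes_), len(self.classes_)), dtype=int)
        for t, p in zip(true_idx[valid], oob_pred[valid]):
            conf[t, p] += 1
        self.confusion_ = pd.DataFrame(
            conf, index=self.classes_, columns=self.classes_
        )
        self.posterior_forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.posterior_forest_.fit(X, self.oob_success_)
        return self

    def vote_fractions(self, X) -> np.ndarray:
        """(n_points, n_classes) fraction of trees voting for each class."""
        check_is_fitted(self, "forest_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.forest_.estimators_:
            pred = tree.predict(X).astype(int)
            for c in range(len(self.classes_)):
                votes[:, c] += pred == c
        return votes / len(self.forest_.estimators_)

    def predict(self, X) -> np.ndarray:
        """Majority-vote model per point, ties broken in fixed model order."""
        votes = self.vote_fractions(X)
        order = _tie_break_order(self.classes_)
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        out = []
        for row in votes:
            best = max(order, key=lambda c: (row[class_pos[c]], -order.index(c)))
            out.append(best)
        return np.asarray(out)

    def posterior_probability(self, X) -> np.ndarray:
        """ABC-RF posterior probability that the selected model is correct."""
        check_is_fitted(self, "posterior_forest_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.clip(self.posterior_forest_.predict(X), 0.0, 1.0)

    def choose(self, observed_summary) -> ModelChoiceResult:
        """Full model-choice result for a single observed summary vector."""
        obs = np.atleast_2d(np.asarray(observed_summary, dtype=float))
        if obs.shape[1] != self.forest_.n_features_in_:
            raise ValueError(
                f"observed summary has dimension {obs.shape[1]}, "
                f"table has {self.forest_.n_features_in_}"
            )
        votes = self.vote_fractions(obs)[0]
        fractions = {c: float(v) for c, v in zip(self.classes_, votes)}
        selected = self.predict(obs)[0]
        post = float(self.posterior_probability(obs)[0])
        return ModelChoiceResult(
            selected_model=str(selected),
            vote_fractions=fractions,
            posterior_probability=post,
            oob_prior_error=self.oob_prior_error_,
            n_trees=self.n_trees,
            seed=self.random_state,
        )


class ABCParameterEstimator(BaseEstimator, RegressorMixin):
    """Quantile regression forest for one model parameter.

    ``predict`` returns the forest-mean point estimate; ``quantiles`` returns
    weighted quantiles of the training responses, with weights given by
    leaf co-occupancy with the query point averaged over trees.
    """

    def __init__(self, n_trees: int = 500, random_state: int | None = None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y) -> "ABCParameterEstimator":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < 500:
            warnings.warn(
                f"only {len(y)} reference rows; >= 500 recommended", stacklevel=2
            )
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.y_train_ = y
        self.train_leaves_ = self.forest_.apply(X)  # (n_rows, n_trees)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def _weights(self, x: np.ndarray) -> np.ndarray:
        leaves = self.forest_.apply(x.reshape(1, -1))[0]  # (n_trees,)
        w = np.zeros(len(self.y_train_))
        for t in range(self.train_leaves_.shape[1]):
            mask = self.train_leaves_[:, t] == leaves[t]
            k = mask.sum()
            if k:
                w[mask] += 1.0 / k
        return w / self.train_leaves_.shape[1]

    def quantiles(self, X, q=(0.05, 0.5, 0.95)) -> np.ndarray:
        """Weighted quantiles of the training responses at each query point."""
        check_is_fitted(self, "forest_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(q)))
        order = np.argsort(self.y_train_)
        y_sorted = self.y_train_[order]
        for i, x in enumerate(X):
            w = self._weights(x)[order]
            cw = np.cumsum(w)
            if cw[-1] == 0:
                out[i] = np.quantile(y_sorted, q)
                continue
            cw = cw / cw[-1]
            out[i] = [float(y_sorted[np.searchsorted(cw, qq, side="left")]) for qq in q]
        return out


# ---------------------------------------------------------------------------
# Operation wrappers


def rf_model_choice(
    table: ReferenceTable,
    observed_summary,
    n_trees: int = 500,
    seed: int | None = None,
) -> ModelChoiceResult:
    """Train the ABC-RF classifier on a reference table and classify one point."""
    clf = ABCModelChoice(n_trees=n_trees, random_state=seed)
    clf.fit(table.summaries, table.model_labels)
    return clf.choose(observed_summary)


def prior_error_rate(
    table: ReferenceTable, n_trees: int = 500, seed: int | None = None
) -> tuple[float, pd.DataFrame]:
    """Out-of-bag prior error rate and per-model confusion matrix."""
    labels, counts = np.unique(table.model_labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each model needs >= 2 rows for OOB error")
    clf = ABCModelChoice(n_trees=n_trees, random_state=seed)
    clf.fit(table.summaries, table.model_labels)
    return clf.oob_prior_error_, clf.confusion_


def estimate_parameters(
    table: ReferenceTable,
    observed_summary,
    n_trees: int = 500,
    seed: int | None = None,
    prior_bounds: dict[str, tuple[float, float]] | None = None,
) -> list[ParameterEstimate]:
    """Quantile-regression-forest estimates for every parameter column.

    ``table`` should already be restricted to the selected model.  The
    flatness diagnostic is the ratio of the posterior 5-95% interquantile
    width to the prior's (0.9 x prior range for a uniform prior); values
    near 1 mean the summaries carry little information about the parameter.
    """
    obs = np.asarray(observed_summary, dtype=float).reshape(1, -1)
    out = []
    for col in table.params.columns:
        y = table.params[col].to_numpy(dtype=float)
        if np.isnan(y).any():
            continue
        if np.ptp(y) == 0:
            warnings.warn(f"parameter {col} is constant in table", stacklevel=2)
            v = float(y[0])
            out.append(ParameterEstimate(col, v, v, v, v, 0.0))
            continue
        est = ABCParameterEstimator(n_trees=n_trees, random_state=seed)
        est.fit(table.summaries, y)
        point = float(est.predict(obs)[0])
        q05, q50, q95 = est.quantiles(obs)[0]
        if prior_bounds and col in prior_bounds:
            lo, hi = prior_bounds[col]
            prior_width = 0.9 * (hi - lo)
        else:
            prior_width = float(np.quantile(y, 0.95) - np.quantile(y, 0.05))
        flat = (q95 - q05) / prior_width if prior_width > 0 else float("nan")
        out.append(ParameterEstimate(col, point, q05, q50, q95, flat))
    return out


def run_model_comparison(
    models: dict[str, DemographicModel],
    observed_summary,
    n_sims_per_model: int = 2_000,
    n_trees: int = 500,
    seed: int = 0,
    table: ReferenceTable | None = None,
) -> dict:
    """End-to-end scenario comparison for one observed summary vector.

    Builds (or reuses) the reference table, runs model choice, then estimates
    the selected model's parameters.  Returns a machine-readable report with
    all seeds recorded.
    """
    if table is None:
        table = build_reference_table(models, n_sims_per_model, base_seed=seed)
    choice = rf_model_choice(table, observed_summary, n_trees=n_trees, seed=seed)
    sub = table.restrict_to(choice.selected_model)
    sel_model = models[choice.selected_model]
    bounds = {f"ne_{d}": b for d, b in sel_model.size_priors.items()}
    if sel_model.migration_prior is not None:
        bounds["m"] = sel_model.migration_prior
    estimates = estimate_parameters(
        sub, observed_summary, n_trees=n_trees, seed=seed, prior_bounds=bounds
    )
    return {
        "selected_model": choice.selected_model,
        "vote_fractions": choice.vote_fractions,
        "posterior_probability": choice.posterior_probability,
        "oob_prior_error": choice.oob_prior_error,
        "n_trees": n_trees,
        "n_sims_per_model": int(table.provenance.get("n_sims_per_model", -1)),
        "seed": seed,
        "parameter_estimates": [vars(e) for e in estimates],
    }
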