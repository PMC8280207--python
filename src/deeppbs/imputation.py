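"""Missing-value imputation for per-second vital-sign tables.

Six techniques are supported: three summary-statistic fills (mean, median,
mode of the observed values of each signal within one infant's recording),
two model-based single imputations in which each signal is regressed on the
other concurrently measured signals with chained equations (decision tree,
Bayesian ridge), and multiple imputation, which draws five completed
datasets from the Bayesian-ridge posterior.  Observed entries are never
modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImputationMethod", "impute", "make_imputer", "evaluate_imputers",
           "METHOD_NAMES"]

METHOD_NAMES = ("mean", "median", "mode", "decision_tree", "bayesian_ridge",
                "multiple")
MULTIPLE_N_DRAWS = 5
CHAINED_MAX_ITER = 10
CHAINED_TOL = 1e-3


@dataclass
class ImputationMethod:
    name: str
    n_draws: int = MULTIPLE_N_DRAWS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(
                f"unknown imputation method {self.name!r}; "
                f"choose from {METHOD_NAMES}")
        if self.name == "multiple" and self.n_draws != MULTIPLE_N_DRAWS:
            raise ValueError(
                f"multiple imputation uses exactly {MULTIPLE_N_DRAWS} draws")


def _check_observed(X: np.ndarray, feature_names) -> None:
    fully_missing = np.flatnonzero(~np.isfinite(X).any(axis=0))
    if fully_missing.size:
        names = [feature_names[i] if feature_names is not None else str(i)
                 for i in fully_missing]
        raise ValueError(f"feature(s) fully missing, cannot impute: {names}")


def _column_fill(X: np.ndarray, stat: str) -> np.ndarray:
    out = X.copy()
    for j in range(X.shape[1]):
        col = out[:, j]
        obs = col[np.isfinite(col)]
        if stat == "mean":
            fill = obs.mean()
        elif stat == "median":
            fill = np.median(obs)
        else:  # mode of values rounded to integers (mode is ill-defined on
            # continuous data); smallest mode wins ties
            vals, counts = np.unique(np.round(obs), return_counts=True)
            fill = vals[np.argmax(counts)]
        col[~np.isfinite(col)] = fill
    return out


def _chained(X: np.ndarray, estimator, seed: int, sample_posterior: bool = False
             ) -> np.ndarray:
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    imp = IterativeImputer(estimator=estimator, max_iter=CHAINED_MAX_ITER,
                           tol=CHAINED_TOL, sample_posterior=sample_posterior,
                           random_state=seed, keep_empty_features=False)
    return imp.fit_transform(X)


def impute(X: np.ndarray, method: ImputationMethod | str, feature_names=None
           ) -> np.ndarray | list[np.ndarray]:
    """Fill NaN entries of a (n_samples, n_features) matrix.

    Returns one completed matrix, or a list of five for multiple imputation
    (identical at observed positions, differing at imputed ones).
    """
    if isinstance(method, str):
        method = ImputationMethod(method)
    X = np.asarray(X, dtype=float)
    _check_observed(X, feature_names)
    if not np.isnan(X).any():
        return [X.copy() for _ in range(method.n_draws)] \
            if method.name == "multiple" else X.copy()

    if method.name in ("mean", "median", "mode"):
        return _column_fill(X, method.name)
    if method.name == "decision_tree":
        from sklearn.tree import DecisionTreeRegressor
        return _chained(X, DecisionTreeRegressor(random_state=method.seed),
                        method.seed)
    if method.name == "bayesian_ridge":
        from sklearn.linear_model import BayesianRidge
        return _chained(X, BayesianRidge(), method.seed)
    # multiple: five Bayesian-ridge draws from different posteriors
    from sklearn.linear_model import BayesianRidge
    return [
        _chained(X, BayesianRidge(), method.seed + i, sample_posterior=True)
        for i in range(method.n_draws)
    ]


def make_imputer(method: ImputationMethod | str, draw: int | None = None):
    """A (matrix, feature_names=...) -> matrix callable for the preprocessing
    pipeline.  For multiple imputation, `draw` picks which of the five
    completed datasets this imputer produces."""
    if isinstance(method, str):
        method = ImputationMethod(method)

    def _impute(X: np.ndarray, feature_names=None) -> np.ndarray:
        if method.name == "multiple":
            # draws are independently seeded, so one draw needs one fit
            X = np.asarray(X, dtype=float)
            _check_observed(X, feature_names)
            if not np.isnan(X).any():
                return X.copy()
            from sklearn.linear_model import BayesianRidge
            return _chained(X, BayesianRidge(), method.seed + (draw or 0),
                            sample_posterior=True)
        return impute(X, method, feature_names)

    return _impute


def evaluate_imputers(recordings, clinical, model_config, train_config,
                      methods=METHOD_NAMES, trainer=None, target_hours: float = 80.0):
    """Cross-validated downstream metrics per imputation technique.

    For each method the cohort is completed, preprocessed, and run through
    fourfold cross-validated training; reported metrics are fold averages,
    additionally averaged over the five completed datasets for multiple
    imputation.  ``trainer(samples, train_config, model_config)`` must return
    fold results with a ``best_metrics`` mapping; defaults to
    :func:`deeppbs.training.train_model`.
    """
    import pandas as pd

    from .preprocessing import preprocess_cohort

    if trainer is None:
        from .training import train_model as trainer
    if len(recordings) < train_config.folds:
        raise ValueError(
            f"{len(recordings)} infants < {train_config.folds} folds")

    rows = {}
    for name in methods:
        method = ImputationMethod(name, seed=train_config.seed)
        n_sets = MULTIPLE_N_DRAWS if name == "multiple" else 1
        per_set = []
        for draw in range(n_sets):
            samples = preprocess_cohort(
                recordings, clinical, imputer=make_imputer(method, draw),
                target_hours=target_hours)
            folds = trainer(samples, train_config, model_config)
            metrics = pd.DataFrame([f.best_metrics for f in folds]).mean()
            per_set.append(metrics)
        rows[name] = pd.concat(per_set, axis=1).mean(axis=1)
    table = pd.DataFrame(rows).T
    table.index.name = "method"
    return table
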