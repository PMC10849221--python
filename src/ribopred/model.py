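"""Learned translation rates ("New_TR") and their evaluation.

The central object is :class:`TranslationRateModel`, a statsmodels-style
model built from a feature table and a response (protein abundance, PA, or
abundance per transcript, PA/mRNA).  ``fit()`` returns a
:class:`TranslationRateResults` carrying the per-gene predictions, the
train/test split, Spearman scores on the test split and on the whole
dataset, and a ``summary()`` table.

Six regressor families are supported: ordinary least squares, Ridge, Lasso,
Elastic Net, Random Forest, and RBF-kernel support-vector regression.  The
New_TR predictor of the wider pipeline is simply this model fitted on the
two mechanistic rates (log10 initiation rate, elongation rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.svm import SVR

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "TranslationRateModel",
    "TranslationRateResults",
    "train_test_split",
    "fit_new_tr",
    "spearman",
    "ttest_two_tailed",
    "model_report",
]

#: The six supported regressor families.
ALGORITHMS = ("LINEAR", "RIDGE", "LASSO", "ELASTIC_NET", "RANDOM_FOREST", "SVR_RBF")


def _make_regressor(algorithm: str, hyperparams: Mapping[str, object], seed: int):
    hp = dict(hyperparams)
    if algorithm == "LINEAR":
        return LinearRegression(**hp)
    if algorithm == "RIDGE":
        return Ridge(**hp)
    if algorithm == "LASSO":
        hp.setdefault("alpha", 0.01)
        return Lasso(**hp)
    if algorithm == "ELASTIC_NET":
        hp.setdefault("alpha", 0.01)
        return ElasticNet(**hp)
    if algorithm == "RANDOM_FOREST":
        hp.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, **hp)
    if algorithm == "SVR_RBF":
        hp.setdefault("kernel", "rbf")
        return SVR(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one New_TR fit."""

    algorithm: str = "SVR_RBF"
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    target: str = "pa"              # "pa" or "pa_per_mrna"
    log_transform_target: bool = True
    train_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )


def train_test_split(
    gene_ids: Sequence[str], ratio: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic disjoint-and-exhaustive 80:20-style split.

    Train size is round(ratio * n); the permutation is drawn from
    ``numpy.random.default_rng(seed)`` so the same seed always yields the
    same partition.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = list(gene_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 genes to split")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of average-tie ranks).

    Returns NaN with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("spearman needs two equal-length vectors of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        import warnings

        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def ttest_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student's t-test, two-tailed.

    Pooled-variance by default (the classical Student variant); Welch's
    unequal-variance form with ``welch=True``.  Zero pooled variance is an
    error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


class TranslationRateModel:
    """Regression model mapping feature columns to an expression response.

    Parameters
    ----------
    features : DataFrame
        Gene-indexed numeric design columns (already encoded).
    response : Series
        Positive expression response (PA or PA/mRNA), same index.
    spec : ModelSpec
        Algorithm, seed, target transform and split configuration.
    log_columns : sequence of column names
        Columns log10-transformed before standardization (used for the
        initiation rate, which spans many decades).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        response: pd.Series,
        spec: ModelSpec | None = None,
        log_columns: Sequence[str] = (),
    ) -> None:
        if not features.index.equals(response.index):
            response = response.reindex(features.index)
        if response.isna().any():
            raise ValueError("response missing for some genes")
        self.spec = spec or ModelSpec()
        X = features.astype(float).copy()
        for col in log_columns:
            if col in X:
                if (X[col] <= 0).any():
                    raise ValueError(f"column {col} must be positive to log")
                X[col] = np.log10(X[col])
        if (X.std(ddof=0) == 0).any():
            bad = list(X.columns[X.std(ddof=0) == 0])
            raise ValueError(f"degenerate constant input column(s): {bad}")
        self.exog = X
        self.endog = response.astype(float)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        feature_columns: Sequence[str],
        target: str = "pa",
        spec: ModelSpec | None = None,
        log_columns: Sequence[str] = (),
    ) -> "TranslationRateModel":
        spec = spec or ModelSpec(target=target)
        return cls(
            table[list(feature_columns)], table[target], spec=spec,
            log_columns=log_columns,
        )

    def fit(self) -> "TranslationRateResults":
        spec = self.spec
        n = len(self.exog)
        # Same deterministic permutation as train_test_split, positional.
        n_train = min(max(int(round(spec.train_ratio * n)), 1), n - 1)
        perm = np.random.default_rng(spec.seed).permutation(n)
        train_pos = np.sort(perm[:n_train])
        test_pos = np.sort(perm[n_train:])
        train_ids = list(self.exog.index[train_pos])
        test_ids = list(self.exog.index[test_pos])

        X = self.exog.to_numpy(dtype=float)
        # Standardize on training statistics only.
        mu = X[train_pos].mean(axis=0)
        sd = X[train_pos].std(axis=0)
        sd[sd == 0.0] = 1.0
        Zv = (X - mu) / sd
        y = self.endog
        yv = y.to_numpy(dtype=float)
        y_fit = np.log10(yv) if spec.log_transform_target else yv
        # Standardize the target on training statistics too (essential for
        # the epsilon-insensitive SVR loss, harmless for the others); the
        # prediction is mapped back to the response's (log) scale.
        y_mu = float(y_fit[train_pos].mean())
        y_sd = float(y_fit[train_pos].std()) or 1.0
        y_z = (y_fit - y_mu) / y_sd

        Z = pd.DataFrame(Zv, index=self.exog.index, columns=self.exog.columns)
        reg = _make_regressor(spec.algorithm, spec.hyperparams, spec.seed)
        reg.fit(Zv[train_pos], y_z[train_pos])
        test_pred = reg.predict(Zv[test_pos]) * y_sd + y_mu
        sp_test = spearman(test_pred, yv[test_pos])
        return TranslationRateResults(
            model=self,
            spec=spec,
            regressor=reg,
            train_ids=train_ids,
            test_ids=test_ids,
            spearman_test=sp_test,
            _design=Z,
            _y_scale=(y_mu, y_sd),
        )


@dataclass
class TranslationRateResults:
    """Fitted New_TR predictor with its evaluation scores.

    Full-dataset predictions (``new_tr``) and the full-dataset Spearman
    (``spearman_total``) are computed on first access — the exhaustive
    subset search scores thousands of candidate fits on the test split only
    and re-evaluates just the winners on all genes.
    """

    model: TranslationRateModel
    spec: ModelSpec
    regressor: object
    train_ids: list[str]
    test_ids: list[str]
    spearman_test: float
    _design: pd.DataFrame
    _y_scale: tuple[float, float]
    _new_tr: pd.Series | None = None
    _spearman_total: float | None = None

    @property
    def new_tr(self) -> pd.Series:
        if self._new_tr is None:
            y_mu, y_sd = self._y_scale
            self._new_tr = pd.Series(
                self.regressor.predict(self._design.to_numpy()) * y_sd + y_mu,
                index=self._design.index,
                name="new_tr",
            )
        return self._new_tr

    @property
    def spearman_total(self) -> float:
        if self._spearman_total is None:
            self._spearman_total = spearman(self.new_tr, self.model.endog)
        return self._spearman_total

    @property
    def split_sizes(self) -> tuple[int, int]:
        return len(self.train_ids), len(self.test_ids)

    def summary(self) -> str:
        n_train, n_test = self.split_sizes
        lines = [
            "Translation-rate regression results",
            "=" * 48,
            f"algorithm:        {self.spec.algorithm}",
            f"target:           {self.spec.target}",
            f"features:         {', '.join(self.model.exog.columns)}",
            f"n (train/test):   {n_train}/{n_test}",
            f"Spearman (test):  {self.spearman_test:.4f}",
            f"Spearman (total): {self.spearman_total:.4f}",
        ]
        return "\n".join(lines)


def fit_new_tr(
    rates: pd.DataFrame,
    response: pd.Series,
    spec: ModelSpec | None = None,
) -> TranslationRateResults:
    """Fit the New_TR predictor from the two mechanistic rates.

    ``rates`` must carry ``initiation_rate`` (log10-transformed internally;
    it spans ~8 decades) and ``elongation_rate``; both are z-scored on
    training statistics before the regressor sees them.  The prediction is
    produced for every gene; Spearman is evaluated against the raw
    (untransformed) response on the test split and on the full set.
    """
    spec = spec or ModelSpec()
    model = TranslationRateModel(
        rates[["initiation_rate", "elongation_rate"]],
        response,
        spec=spec,
        log_columns=("initiation_rate",),
    )
    return model.fit()


def model_report(
    rates: pd.DataFrame,
    responses: pd.DataFrame,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    hyperparams: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Score every algorithm against PA and PA/mRNA (test and total).

    Returns the algorithm x {pa, pa_per_mrna} x {test, total} Spearman
    matrix, one row per algorithm — the package's analogue of a model
    comparison table.
    """
    hyperparams = hyperparams or {}
    common = rates.index.intersection(responses.index)
    rows = {}
    for algo in algorithms:
        row = {}
        for target in ("pa", "pa_per_mrna"):
            spec = ModelSpec(
                algorithm=algo, seed=seed, target=target,
                hyperparams=hyperparams.get(algo, {}),
            )
            res = fit_new_tr(
                rates.loc[common], responses.loc[common, target], spec
            )
            row[f"{target}_test"] = res.spearman_test
            row[f"{target}_total"] = res.spearman_total
        rows[algo] = row
    return pd.DataFrame.from_dict(rows, orient="index")
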