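"""L1-penalised logistic regression with forced-in covariates.

The fitting problem is

    min_{b0, b}  (1/n) * sum_i log(1 + exp(-(2 y_i - 1) (b0 + x_i' b)))
                 + lam * sum_j w_j |b_j|,

where the penalty weights ``w_j`` are 1 on the (high-dimensional, mutually
correlated) texture descriptors and 0 on the intercept and the forced
adjustment covariates. The LASSO penalty handles the strong correlation
between baseline and follow-up descriptors that destabilises an unpenalised
logistic fit; the regularisation strength ``lam`` is chosen over a grid by
the Akaike Information Criterion, AIC = 2k - 2 loglik, with k the number of
nonzero coefficients plus one for the intercept.

The solver is FISTA (accelerated proximal gradient with adaptive restart)
on the standardised design; it is deterministic, supports warm starts along
the lambda path, and never thresholds unpenalised coordinates, so forced
covariates cannot be zeroed by the penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, FitError, ParameterError

__all__ = [
    "aic",
    "PenalizedLogit",
    "PenalizedLogitResults",
    "fit_penalized_logistic",
    "predict_probability",
]


def aic(loglik: float, k: int) -> float:
    """Akaike Information Criterion, ``2k - 2 loglik``."""
    if k < 0:
        raise ParameterError("k must be non-negative")
    return 2.0 * k - 2.0 * loglik


def _log_likelihood(z: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor *z* (natural log)."""
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def _fista(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    lam: float,
    beta0: np.ndarray,
    b0: float,
    lipschitz: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float]:
    """FISTA on the penalised logistic objective; returns (beta, intercept).

    Uses the gradient-based adaptive restart of the momentum sequence and a
    step-change stopping rule, both of which avoid extra passes over the
    data; one iteration costs two matrix-vector products.
    """
    n = len(y)
    step = 1.0 / lipschitz
    thresh = lam * weights * step

    beta, b = beta0.copy(), b0
    vbeta, vb = beta.copy(), b
    t = 1.0
    for _ in range(max_iter):
        z = X @ vbeta + vb
        p = 1.0 / (1.0 + np.exp(-z))
        resid = (p - y) / n
        new_beta = vbeta - step * (X.T @ resid)
        new_beta = np.sign(new_beta) * np.maximum(np.abs(new_beta) - thresh, 0.0)
        new_b = vb - step * float(resid.sum())

        dbeta = new_beta - beta
        db = new_b - b
        # restart when the momentum direction opposes the descent direction
        if (vbeta - new_beta) @ dbeta + (vb - new_b) * db > 0:
            t = 1.0
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        momentum = (t - 1.0) / t_next
        vbeta = new_beta + momentum * dbeta
        vb = new_b + momentum * db
        beta, b, t = new_beta, new_b, t_next

        # stop when the generalised gradient (step change / step size) is tiny
        if max(float(np.max(np.abs(dbeta))), abs(db)) <= tol * step:
            break
    return beta, b


@dataclass
class PenalizedLogitResults:
    """Fit results: coefficients, selection path, likelihood and diagnostics.

    Coefficients are reported on the original (unstandardised) feature scale;
    ``params`` includes the intercept under ``"const"``. ``standardization``
    stores the per-feature training mean and SD actually used, which a caller
    needs to score new data identically.
    """

    model: "PenalizedLogit"
    params: pd.Series
    lambda_: float
    llf: float
    aic: float
    df_model: int
    lambda_path: np.ndarray
    aic_path: np.ndarray
    standardization: tuple[np.ndarray, np.ndarray]

    @property
    def nonzero(self) -> pd.Index:
        coefs = self.params.drop("const")
        return coefs.index[coefs != 0.0]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted progression probabilities for new records."""
        X = self.model._validate_new(X)
        z = X @ self.params.drop("const").to_numpy() + self.params["const"]
        return 1.0 / (1.0 + np.exp(-z))

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            "Penalized Logit Results",
            "=" * 46,
            f"{'No. observations:':<26}{self.model.nobs}",
            f"{'No. features:':<26}{len(self.params) - 1}",
            f"{'Nonzero coefficients:':<26}{self.df_model}",
            f"{'Selected lambda:':<26}{self.lambda_:.6g}",
            f"{'Log-likelihood:':<26}{self.llf:.3f}",
            f"{'AIC:':<26}{self.aic:.3f}",
            "-" * 46,
            f"{'term':<24}{'coef':>12}  {'penalized':>8}",
            "-" * 46,
        ]
        pen = dict(zip(self.model.column_names, self.model.penalized))
        lines.append(f"{'const':<24}{self.params['const']:>12.5f}  {'':>8}")
        for name, value in self.params.drop("const").items():
            if value != 0.0:
                lines.append(f"{name:<24}{value:>12.5f}  {str(pen[name]):>8}")
        lines.append("=" * 46)
        return "\n".join(lines)


class PenalizedLogit:
    """Logistic model with LASSO-penalised and forced-in feature groups.

    Parameters
    ----------
    endog : array of 0/1
        Binary response; both classes must be present.
    exog : DataFrame or 2D array
        Feature matrix; standardised internally per fit.
    penalized : boolean array, optional
        Marks the features subject to the L1 penalty; unmarked features
        (and the intercept) are forced in. Default: penalise everything.
    column_names : sequence of str, optional
        Feature names when *exog* is a bare array.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: pd.DataFrame | np.ndarray,
        penalized: np.ndarray | None = None,
        column_names: list[str] | None = None,
    ) -> None:
        if isinstance(exog, pd.DataFrame):
            column_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.asarray(exog, dtype=float)
            if column_names is None:
                column_names = [f"x{j}" for j in range(exog.shape[1])]
        y = np.asarray(endog).astype(float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise FitError("endog must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise FitError("endog contains a single class; cannot fit")
        if not np.all(np.isfinite(exog)):
            raise DataError("exog contains non-finite values")
        if exog.shape[0] != len(y):
            raise DataError("endog and exog lengths differ")
        self.endog = y
        self.exog = exog
        self.column_names = column_names
        self.nobs = len(y)
        if penalized is None:
            penalized = np.ones(exog.shape[1], dtype=bool)
        penalized = np.asarray(penalized, dtype=bool)
        if penalized.shape != (exog.shape[1],):
            raise DataError("penalized mask length must match the feature count")
        self.penalized = penalized

    def _validate_new(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.column_names:
                raise DataError("column map of new data does not match training")
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[np.newaxis, :]
        if X.shape[1] != len(self.column_names):
            raise DataError("feature count of new data does not match training")
        return X

    def default_lambda_grid(self, n_points: int = 8, decades: float = 2.0) -> np.ndarray:
        """Descending grid from the smallest lambda zeroing every penalised term."""
        Xs, _, _ = self._standardized()
        y = self.endog
        if not self.penalized.any():
            return np.array([0.0])
        score = np.abs(Xs.T @ (y - y.mean())) / self.nobs
        lam_max = float(score[self.penalized].max())
        if lam_max <= 0:
            lam_max = 1e-3
        return lam_max * np.logspace(0.0, -decades, n_points)

    def _standardized(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (self.exog - mean) / sd, mean, sd

    def fit(
        self,
        lambda_grid: np.ndarray | None = None,
        tol: float = 1e-6,
        max_iter: int = 2000,
    ) -> PenalizedLogitResults:
        """Fit the lambda path and return the AIC-selected model.

        The grid is traversed from strongest to weakest penalty with warm
        starts; for each lambda the training log-likelihood and AIC
        (k = nonzero coefficients + 1) are recorded and the minimiser is
        returned. Deterministic given the inputs.
        """
        Xs, mean, sd = self._standardized()
        y = self.endog
        weights = self.penalized.astype(float)
        if lambda_grid is None:
            lambda_grid = self.default_lambda_grid()
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

        # Lipschitz constant of the logistic gradient: sigma_max^2 / (4n)
        # over the design including the intercept column.
        Xi = np.hstack([np.ones((self.nobs, 1)), Xs])
        smax = _spectral_norm(Xi)
        lipschitz = smax * smax / (4.0 * self.nobs)

        beta = np.zeros(Xs.shape[1])
        b = float(np.log(y.mean() / (1.0 - y.mean())))
        best = None
        aics = np.empty(len(lambda_grid))
        for i, lam in enumerate(lambda_grid):
            beta, b = _fista(Xs, y, weights, lam, beta, b, lipschitz, tol, max_iter)
            llf = _log_likelihood(Xs @ beta + b, y)
            k = int(np.count_nonzero(beta)) + 1
            aics[i] = aic(llf, k)
            if best is None or aics[i] < best[0]:
                best = (aics[i], lam, beta.copy(), b, llf, k)

        best_aic, lam, beta, b, llf, k = best
        # report on the original feature scale
        coef = beta / sd
        intercept = b - float(mean @ coef)
        params = pd.Series(
            np.concatenate([[intercept], coef]),
            index=["const"] + list(self.column_names),
        )
        return PenalizedLogitResults(
            model=self,
            params=params,
            lambda_=float(lam),
            llf=llf,
            aic=float(best_aic),
            df_model=k - 1,
            lambda_path=lambda_grid,
            aic_path=aics,
            standardization=(mean, sd),
        )


def _spectral_norm(X: np.ndarray, n_iter: int = 12, seed: int = 0) -> float:
    """Largest singular value by power iteration (deterministic start)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(X.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        u = X @ v
        v = X.T @ u
        norm = np.linalg.norm(v)
        if norm == 0:
            return 0.0
        v /= norm
    return float(np.linalg.norm(X @ v))


def fit_penalized_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    penalized_mask: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> PenalizedLogitResults:
    """Functional wrapper: build a :class:`PenalizedLogit` and fit it.

    *seed* is accepted for interface symmetry with the stochastic stages;
    the fit itself is deterministic and ignores it.
    """
    return PenalizedLogit(y, X, penalized=penalized_mask).fit(lambda_grid=lambda_grid)


def predict_probability(
    results: PenalizedLogitResults, X: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Progression probabilities of new records under a fitted model."""
    return results.predict(X)
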