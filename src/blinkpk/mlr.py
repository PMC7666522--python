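"""Multinomial logistic modelling of sedation depth on EMG features.

The sedation score (six ordered aRASS levels, 0 to −5) is modelled as a
nominal multinomial logit on the selected predictors: for each non-reference
class c,

    log( P(class = c) / P(class = ref) ) = b0_c + sum_k b_kc * x_k .

The reference class is the most-awake level present (aRASS 0 by default),
so the deepest level keeps its own logit.  The fit maximizes the multinomial
log-likelihood by Newton-Raphson with step-halving; standard errors come
from the inverse observed information.

Diagnostics follow the conventions of likelihood-based model reporting:
overall chi-square against the intercept-only model, Nagelkerke pseudo-R²,
in-sample classification accuracy, and per-predictor likelihood-ratio tests
(df = number of classes − 1 for a single-column predictor).

A separately published *binary* logit for the probability of
unresponsiveness (aRASS = −5), with its eight fixed coefficients, ships as
a versioned data file and is evaluated — never refitted — by ``eval_published_logit``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "MlrModel",
    "FitDiagnostics",
    "SeparationError",
    "prune_collinear",
    "PublishedLogit",
    "PUBLISHED_LOGIT_PREDICTORS",
    "select_features",
    "fit_multinomial",
    "likelihood_ratio_test",
    "nagelkerke_r2",
    "classify_and_accuracy",
    "fit_diagnostics",
    "load_published_logit",
    "eval_published_logit",
]

#: Predictors of the published final model (window-suffixed feature names).
PUBLISHED_LOGIT_PREDICTORS = (
    "ce_ug_ml",
    "v_mean_T1",
    "f_mean_T1",
    "f_median_T1",
    "p_bandwidth_T1",
    "spectral_entropy_T1",
    "f_mean_T2",
    "spectral_entropy_T2",
)

#: Divergence cap on *standardized* coefficients (slope × predictor SD).
#: The scale-free view matters: legitimately fitted slopes on small-range
#: predictors (a spectral entropy in [0, 1], say) run into the thousands in
#: raw units while staying modest per predictor SD.
MAX_STD_COEF = 500.0


class SeparationError(ValueError):
    """(Quasi-)complete separation: the multinomial MLE does not exist."""

    def __init__(self, predictor: str, class_label: float, detail: str = ""):
        self.predictor = predictor
        self.class_label = class_label
        super().__init__(
            f"separation detected: coefficient of {predictor!r} for class "
            f"{class_label} diverges (no finite MLE){detail}"
        )


@dataclass(frozen=True)
class MlrModel:
    """Fitted multinomial logit.

    ``coefficients`` has shape (n_classes − 1, n_predictors + 1); row k holds
    the intercept and slopes of the logit of ``classes[k + 1]`` against the
    reference ``classes[0]``.
    """

    classes: tuple[float, ...]  # reference first, then the rest (descending awake->deep)
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    log_likelihood: float
    n_obs: int
    cov: np.ndarray | None = None  # covariance of vec(coefficients)

    @property
    def reference_class(self) -> float:
        return self.classes[0]

    @property
    def n_free_parameters(self) -> int:
        return self.coefficients.size

    def design(self, table: pd.DataFrame) -> np.ndarray:
        x = table[list(self.predictor_names)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(x)), x])

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class probabilities, columns ordered as ``self.classes``."""
        return _proba(self.design(table), self.coefficients)

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("model was fitted without covariance")
        return np.sqrt(np.diag(self.cov)).reshape(self.coefficients.shape)


@dataclass(frozen=True)
class FitDiagnostics:
    overall_chi2: float
    overall_df: int
    overall_p: float
    nagelkerke_r2: float
    accuracy: float
    lr_tests: dict[str, tuple[float, int, float]]  # name -> (chi2, df, p)


def _proba(x: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Softmax probabilities with an implicit zero logit for the reference."""
    eta = x @ coef.T  # (n, K-1)
    logits = np.column_stack([np.zeros(len(x)), eta])
    logits -= logits.max(axis=1, keepdims=True)  # log-sum-exp stabilization
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def _order_classes(values: np.ndarray, reference: float | None) -> tuple[float, ...]:
    present = sorted(set(float(v) for v in values), reverse=True)  # awake (0) first
    if reference is None:
        reference = present[0]
    if reference not in present:
        raise ValueError(f"reference class {reference} not present in the data")
    rest = [c for c in present if c != reference]
    return tuple([reference] + rest)


def fit_multinomial(table: pd.DataFrame, predictors: Sequence[str],
                    class_col: str = "arass", reference: float | None = None,
                    max_iter: int = 200, score_tol: float = 1e-6,
                    ll_tol: float = 1e-10) -> MlrModel:
    """Maximum-likelihood multinomial logit by Newton-Raphson.

    Step-halving enforces likelihood ascent; convergence is declared when
    the largest score component falls below ``score_tol`` or the relative
    log-likelihood change falls below ``ll_tol``.

    Raises
    ------
    ValueError
        On a singular design, or on (quasi-)complete separation, reported
        with the offending predictor's name.
    """
    y_raw = table[class_col].to_numpy(dtype=float)
    classes = _order_classes(y_raw, reference)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")
    for col in predictors:
        if table[col].isna().any():
            raise ValueError(f"predictor {col!r} contains missing values")
    x = np.column_stack([np.ones(len(table))] +
                        [table[c].to_numpy(dtype=float) for c in predictors])
    n, p1 = x.shape
    k = len(classes)
    if n <= (k - 1) * p1:
        raise ValueError("not enough observations for the number of free parameters")
    rank = np.linalg.matrix_rank(x)
    if rank < p1:
        raise ValueError(
            "singular design matrix: predictors are collinear "
            f"(rank {rank} < {p1} columns)"
        )
    # one-hot responses for the non-reference classes
    y = np.zeros((n, k - 1))
    for j, c in enumerate(classes[1:]):
        y[:, j] = y_raw == c

    # column scales for the standardized divergence check (1 for intercept)
    col_scale = np.ones(p1)
    if p1 > 1:
        col_scale[1:] = np.maximum(x[:, 1:].std(axis=0), 1e-300)

    coef = np.zeros((k - 1, p1))
    pr = _proba(x, coef)
    ll = float(np.sum(np.log(np.clip(pr[np.arange(n), _class_index(y_raw, classes)],
                                     1e-300, None))))
    names = ("intercept",) + tuple(predictors)
    info = None
    for _ in range(max_iter):
        pr_nr = pr[:, 1:]  # non-reference columns
        score = ((y - pr_nr).T @ x).ravel()  # (K-1)*p1
        # observed information: block (a,b) = X' diag(p_a (delta_ab - p_b)) X
        info = np.empty(((k - 1) * p1, (k - 1) * p1))
        for a in range(k - 1):
            for b in range(k - 1):
                w = pr_nr[:, a] * ((a == b) - pr_nr[:, b])
                info[a * p1:(a + 1) * p1, b * p1:(b + 1) * p1] = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(info, score).reshape(k - 1, p1)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix during fit: {exc}") from exc

        # step-halving: never decrease the log-likelihood
        scale = 1.0
        for _ in range(40):
            trial = coef + scale * step
            pr_t = _proba(x, trial)
            ll_t = float(np.sum(np.log(np.clip(
                pr_t[np.arange(n), _class_index(y_raw, classes)], 1e-300, None))))
            if ll_t >= ll - 1e-12:
                break
            scale *= 0.5
        coef, pr = trial, pr_t
        std_coef = np.abs(coef) * col_scale
        if std_coef.max() > MAX_STD_COEF:
            row, col = _worst_coefficient(std_coef)
            raise SeparationError(names[col], classes[row + 1])
        converged = (np.abs(score).max() < score_tol
                     or abs(ll_t - ll) < ll_tol * (abs(ll) + 1.0))
        ll = ll_t
        if converged:
            break
    else:
        raise ValueError("Newton-Raphson did not converge")

    # a (quasi-)separated fit can stall before the cap: a vanishing deviance
    # with every row classified at near-certainty means the MLE is at
    # infinity, not at this iterate
    p_obs = pr[np.arange(n), _class_index(y_raw, classes)]
    if p_obs.min() > 1.0 - 1e-8:
        row, col = _worst_coefficient(np.abs(coef) * col_scale)
        raise SeparationError(names[col], classes[row + 1],
                              detail="; fit classifies perfectly")

    cov = np.linalg.inv(info) if info is not None else None
    return MlrModel(classes=classes, predictor_names=tuple(predictors),
                    coefficients=coef, log_likelihood=ll, n_obs=n, cov=cov)


def _worst_coefficient(std_coef: np.ndarray) -> tuple[int, int]:
    """Locate the diverging coefficient, preferring a slope over the intercept
    (the intercept compensates a runaway slope and often tops the raw list)."""
    if std_coef.shape[1] > 1 and std_coef[:, 1:].max() > 1.0:
        row, col = np.unravel_index(std_coef[:, 1:].argmax(),
                                    std_coef[:, 1:].shape)
        return row, col + 1
    return np.unravel_index(std_coef.argmax(), std_coef.shape)


def _class_index(y_raw: np.ndarray, classes: tuple[float, ...]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[float(v)] for v in y_raw])


def likelihood_ratio_test(full: MlrModel, reduced: MlrModel) -> tuple[float, int, float]:
    """LR test of a nested (reduced) model against the full model.

    chi2 = 2 (LL_full − LL_reduced), df = difference in free parameters.
    """
    if not set(reduced.predictor_names) <= set(full.predictor_names):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.n_obs != full.n_obs or reduced.classes != full.classes:
        raise ValueError("models were fitted on different data")
    df = full.n_free_parameters - reduced.n_free_parameters
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = 1.0 if df == 0 else float(_stats.chi2.sf(chi2, df))
    return chi2, df, p


def nagelkerke_r2(model: MlrModel, null_model: MlrModel, n: int | None = None) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell rescaled to a [0, 1] maximum."""
    if null_model.predictor_names:
        raise ValueError("null_model must be intercept-only")
    n = n if n is not None else model.n_obs
    ll1, ll0 = model.log_likelihood, null_model.log_likelihood
    if ll1 < ll0 - 1e-8:
        raise ValueError("fitted model has lower likelihood than the null: fit bug")
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    return min(1.0, r2_cs / denom) if denom > 0 else 0.0


def classify_and_accuracy(model: MlrModel, table: pd.DataFrame,
                          class_col: str = "arass") -> float:
    """Fraction of rows whose argmax-probability class matches the label.

    Probability ties break toward the deeper-sedation class.
    """
    pr = model.predict_proba(table)
    cls = np.asarray(model.classes)
    # deeper class = smaller aRASS value; prefer it on ties
    order = np.argsort(cls)  # ascending: deepest first
    pick = order[np.argmax(pr[:, order], axis=1)]
    predicted = cls[pick]
    return float(np.mean(predicted == table[class_col].to_numpy(dtype=float)))


def fit_diagnostics(model: MlrModel, table: pd.DataFrame,
                    class_col: str = "arass") -> FitDiagnostics:
    """Overall chi-square, Nagelkerke R², accuracy, and per-predictor LR tests."""
    null = fit_multinomial(table, predictors=(), class_col=class_col,
                           reference=model.reference_class)
    chi2, df, p = likelihood_ratio_test(model, null)
    r2 = nagelkerke_r2(model, null)
    acc = classify_and_accuracy(model, table, class_col=class_col)
    lr = {}
    for name in model.predictor_names:
        rest = tuple(c for c in model.predictor_names if c != name)
        reduced = fit_multinomial(table, predictors=rest, class_col=class_col,
                                  reference=model.reference_class)
        lr[name] = likelihood_ratio_test(model, reduced)
    return FitDiagnostics(overall_chi2=chi2, overall_df=df, overall_p=p,
                          nagelkerke_r2=r2, accuracy=acc, lr_tests=lr)


# ---------------------------------------------------------------------------
# Feature selection and the published fitted logit
# ---------------------------------------------------------------------------

def select_features(pk_frame: pd.DataFrame, pk_threshold: float = 0.700,
                    r_threshold: float = 0.500,
                    drop_collinear_complement: bool = True) -> pd.DataFrame:
    """Features whose direction-folded Pk strictly exceeds the threshold.

    Returns the selected rows of the Pk table with an added boolean
    ``r_selected`` flag marking features that additionally have
    |R with Ce| > ``r_threshold``.  ``v_diff`` is dropped whenever ``v_mean``
    is selected for the same window (they are exact complements, so keeping
    both would make any regression design singular).

    Raises
    ------
    ValueError
        If no feature passes.
    """
    sel = pk_frame[pk_frame["pk"] > pk_threshold].copy()
    if drop_collinear_complement:
        keep = []
        for _, row in sel.iterrows():
            if row["feature"] == "v_diff" and (
                (sel["feature"] == "v_mean") & (sel["window"] == row["window"])
            ).any():
                continue
            keep.append(row.name)
        sel = sel.loc[keep]
    if sel.empty:
        raise ValueError(f"no feature has Pk > {pk_threshold}")
    sel["r_selected"] = sel["r_ce"].abs() > r_threshold
    return sel


def prune_collinear(table: pd.DataFrame, predictors: Sequence[str],
                    tol: float = 1e-8) -> list[str]:
    """Greedily drop predictors that add no rank to the design.

    Predictors are scanned in the given order (rank them by relevance
    first); a column is kept only if it is not (numerically) a linear
    combination of the intercept and the columns already kept.  Catches
    exact redundancies such as a feature and its complement or a total and
    its mean over a fixed bin count.
    """
    kept: list[str] = []
    n = len(table)
    basis = np.ones((n, 1))
    for name in predictors:
        col = table[name].to_numpy(dtype=float)[:, None]
        scale = np.abs(col).max()
        if scale == 0:
            continue
        trial = np.column_stack([basis, col / scale])
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] > tol * s[0]:
            kept.append(name)
            basis = trial
    return kept


@dataclass(frozen=True)
class PublishedLogit:
    """The published unresponsiveness logit: an intercept and 8 slopes."""

    intercept: float
    coefficients: dict[str, float]
    version: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != 8:
            raise ValueError("the published logit has exactly 8 slope coefficients")


def load_published_logit() -> PublishedLogit:
    """Load the shipped, versioned coefficient file."""
    text = resources.files("blinkpk").joinpath("data/published_logit.json").read_text()
    raw = json.loads(text)
    return PublishedLogit(intercept=raw["intercept"], coefficients=raw["coefficients"],
                     version=raw["version"])


def eval_published_logit(features: Mapping[str, float],
             coeffs: PublishedLogit | None = None) -> tuple[float, float]:
    """Evaluate the published logit on one predictor vector.

    Returns (logit, probability of unresponsiveness).  Predictors must be in
    the published units (passed through as-is).

    Raises
    ------
    KeyError
        If any of the 8 predictors is missing.
    """
    logit_model = coeffs if coeffs is not None else load_published_logit()
    missing = [k for k in logit_model.coefficients if k not in features]
    if missing:
        raise KeyError(f"missing predictor(s) for the published logit: {missing}")
    logit = logit_model.intercept + sum(b * float(features[k])
                                for k, b in logit_model.coefficients.items())
    # numerically safe logistic
    if logit >= 0:
        prob = 1.0 / (1.0 + math.exp(-logit))
    else:
        e = math.exp(logit)
        prob = e / (1.0 + e)
    return logit, prob
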