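"""OPLS fitting, effect projections (EP), cross-validation and CV-ANOVA.

Orthogonal projections to latent structures (OPLS) splits the variation
in a predictor matrix ``X`` into one component correlated with a
response ``y`` (the predictive component, with weight vector ``w`` and
loading ``p``) and components orthogonal to it.  Two flavours are used
here:

* **OPLS-DA** for independent two-group discrimination: ``X`` is
  centered and scaled by the pooled within-class standard deviation and
  ``y`` encodes class membership.
* **OPLS-EP** (effect projections) for dependent, paired data: ``X`` is
  a matrix of within-pair differences, scaled by the per-variable
  standard deviation but *not* centered, and the response is a constant
  vector of ones — the model asks how consistently the differences
  point in a common direction.  For a single variable this reduces
  exactly to the paired two-tailed t-test.

Model significance is assessed by CV-ANOVA on the cross-validated
predicted responses, and the cross-validation itself mirrors the
chemometrics convention of re-selecting significant variables inside
every fold before predicting the held-out pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from smartscan.errors import DegenerateVariableError, RankError, SampleSizeError, SchemaError

_TINY = 1e-12

ModelKind = Literal["EP", "DA"]


@dataclass
class ScalingRecord:
    """Per-variable divisors and optional centers used to scale a matrix."""

    divisors: np.ndarray
    centers: np.ndarray | None = None

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.centers is not None:
            X = X - self.centers
        return X / self.divisors


@dataclass
class OPLSModel:
    """A fitted single-response OPLS model.

    Attributes
    ----------
    w : ndarray
        Unit-norm predictive weight vector.
    p : ndarray
        Predictive loading vector.
    t : ndarray
        Predictive score per training observation.
    b : float
        Score-to-response regression coefficient; the fitted response is
        ``b * t``.
    W_ortho, P_ortho, T_ortho : ndarray
        Orthogonal weights / loadings / scores, one column per removed
        component (empty for a pure one-component model).
    scaling : ScalingRecord
        Scaling applied to the raw data before fitting; re-applied to
        new data at prediction time.
    """

    w: np.ndarray
    p: np.ndarray
    t: np.ndarray
    b: float
    W_ortho: np.ndarray
    P_ortho: np.ndarray
    T_ortho: np.ndarray
    scaling: ScalingRecord
    kind: str = "EP"
    variable_ids: list[str] | None = None

    @property
    def n_ortho(self) -> int:
        return self.W_ortho.shape[1]

    @property
    def n_components(self) -> int:
        """Total component count (predictive + orthogonal)."""
        return 1 + self.n_ortho

    @property
    def y_hat(self) -> np.ndarray:
        """Fitted (in-sample) response."""
        return self.b * self.t

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "t": self.t.tolist(),
            "b": self.b,
            "n_ortho": self.n_ortho,
            "scaling_divisors": self.scaling.divisors.tolist(),
            "scaling_centers": None if self.scaling.centers is None else self.scaling.centers.tolist(),
            "variable_ids": self.variable_ids,
        }


@dataclass
class CVResult:
    """Cross-validation outcome for one model.

    ``computable`` is False when some cross-validation round selected no
    significant variables, in which case no model is reported (Q² and
    the CV-ANOVA p-value are NaN sentinels rather than exceptions).
    """

    y: np.ndarray
    y_pred: np.ndarray
    Q2: float
    p_cvanova: float
    selected_vars_per_fold: list[np.ndarray]
    n_components: int
    kind: str = "EP"
    computable: bool = True
    perfect_fit: bool = False
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "Q2": self.Q2,
            "p_cvanova": self.p_cvanova,
            "computable": self.computable,
            "n_components": self.n_components,
            "kind": self.kind,
            "selected_vars_per_fold": [s.tolist() for s in self.selected_vars_per_fold],
            "settings": self.settings,
        }


def _sd(X: np.ndarray, axis: int = 0) -> np.ndarray:
    # sample sd (n-1 denominator); required for the paired-t equivalence
    return np.std(X, axis=axis, ddof=1)


def scale_ep(D: np.ndarray) -> tuple[np.ndarray, ScalingRecord]:
    """EP scaling: divide each column by its standard deviation, no centering."""
    D = np.asarray(D, dtype=float)
    sd = _sd(D)
    bad = np.flatnonzero(sd <= _TINY)
    if bad.size:
        raise DegenerateVariableError(f"zero-variance column(s) at index {bad.tolist()}")
    return D / sd, ScalingRecord(divisors=sd, centers=None)


def scale_uv(X: np.ndarray, y: np.ndarray | None = None) -> tuple[np.ndarray, ScalingRecord]:
    """Unit-variance scaling: center, divide by the (class-pooled) sd.

    When ``y`` encodes two classes the pooled within-class standard
    deviation is used, as is conventional for OPLS-DA.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    if y is None:
        sd = _sd(X)
    else:
        y = np.asarray(y)
        classes = np.unique(y)
        ss = np.zeros(X.shape[1])
        dof = 0
        for c in classes:
            Xi = X[y == c]
            if len(Xi) > 1:
                ss += (len(Xi) - 1) * _sd(Xi) ** 2
                dof += len(Xi) - 1
        if dof == 0:
            raise DegenerateVariableError("pooled sd undefined: all classes are singletons")
        sd = np.sqrt(ss / dof)
    bad = np.flatnonzero(sd <= _TINY)
    if bad.size:
        raise DegenerateVariableError(f"zero-variance column(s) at index {bad.tolist()}")
    return (X - mean) / sd, ScalingRecord(divisors=sd, centers=mean)


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    scaling: ScalingRecord | None = None,
    kind: str = "EP",
    variable_ids: list[str] | None = None,
) -> OPLSModel:
    """Fit an OPLS model on an already-scaled matrix.

    The predictive weight is ``w ∝ Xᵀy``; each orthogonal component is
    extracted from the loading part orthogonal to ``w`` and deflated
    from ``X`` before the final predictive component is computed.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    n, p_vars = X.shape
    if len(y) != n:
        raise SchemaError(f"response length {len(y)} != number of rows {n}")
    if n < 3:
        raise SampleSizeError(f"need at least 3 observations, got {n}")
    if scaling is None:
        scaling = ScalingRecord(divisors=np.ones(p_vars), centers=None)

    w = X.T @ y
    w_norm = np.linalg.norm(w)
    if w_norm <= _TINY:
        # response orthogonal to every column: null model
        zeros = np.zeros(p_vars)
        return OPLSModel(
            w=zeros, p=zeros, t=np.zeros(n), b=0.0,
            W_ortho=np.zeros((p_vars, 0)), P_ortho=np.zeros((p_vars, 0)),
            T_ortho=np.zeros((n, 0)), scaling=scaling, kind=kind, variable_ids=variable_ids,
        )
    w = w / w_norm
    # sign convention: largest-magnitude weight positive, so that
    # negating the data negates scores (and the single-variable EP score
    # t-statistic matches the signed paired t-test)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w

    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o <= 1e-10:
            raise RankError(f"no orthogonal variation left for component {len(W_o) + 1}")
        w_o = w_o / norm_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = X @ w
    tt = t @ t
    if tt <= _TINY:
        p_load = np.zeros(p_vars)
        b = 0.0
    else:
        p_load = X.T @ t / tt
        b = (y @ t) / tt
    stack = lambda cols, m: np.column_stack(cols) if cols else np.zeros((m, 0))
    return OPLSModel(
        w=w, p=p_load, t=t, b=b,
        W_ortho=stack(W_o, p_vars), P_ortho=stack(P_o, p_vars), T_ortho=stack(T_o, n),
        scaling=scaling, kind=kind, variable_ids=variable_ids,
    )


def fit_opls_ep(D, n_ortho: int = 0, variable_ids: list[str] | None = None) -> OPLSModel:
    """Fit an OPLS-EP model on a paired-difference matrix.

    ``D`` may be a PairedCohort or a pairs-by-variables array.  The data
    are sd-scaled (uncentered) and the response is a constant vector of
    ones; the model estimates the common effect direction across pairs.
    """
    if hasattr(D, "d_matrix"):
        if variable_ids is None:
            variable_ids = list(D.variable_ids)
        D = D.d_matrix
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if D.shape[0] < 3:
        raise SampleSizeError(f"OPLS-EP needs at least 3 pairs, got {D.shape[0]}")
    Z, scaling = scale_ep(D)
    return fit_opls(Z, np.ones(D.shape[0]), n_ortho=n_ortho, scaling=scaling,
                    kind="EP", variable_ids=variable_ids)


def predict(model: OPLSModel, D_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict new observations: returns (y_hat, predictive scores).

    The training scaling record is applied, orthogonal components are
    removed sequentially, and the predictive score/response computed.
    """
    D_new = np.asarray(D_new, dtype=float)
    if D_new.ndim == 1:
        D_new = D_new[:, None]
    if D_new.shape[1] != model.w.shape[0]:
        raise SchemaError(
            f"variable mismatch: model has {model.w.shape[0]} variables, data has {D_new.shape[1]}"
        )
    Z = model.scaling.apply(D_new)
    for j in range(model.n_ortho):
        t_o = Z @ model.W_ortho[:, j]
        Z = Z - np.outer(t_o, model.P_ortho[:, j])
    t = Z @ model.w
    return model.b * t, t


def score_t_test(model: OPLSModel) -> tuple[float, float]:
    """One-sample t-test of the predictive scores against zero.

    For a single-variable EP model this equals the paired two-tailed
    t-test on the raw differences (the sd-scaling cancels).
    """
    t_scores = model.t
    n = len(t_scores)
    sd = np.std(t_scores, ddof=1)
    if sd <= _TINY:
        return (np.nan, np.nan)
    t_stat = t_scores.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t_stat), df=n - 1)
    return float(t_stat), float(p)


def _make_folds(n: int, k_folds: int, fold_seed: int) -> list[np.ndarray]:
    """Balanced folds from a seeded permutation of the observations."""
    if k_folds > n:
        raise SampleSizeError(f"k_folds={k_folds} exceeds n={n}")
    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k_folds)]


def cross_validate(
    D: np.ndarray,
    model_kind: ModelKind = "EP",
    y: np.ndarray | None = None,
    n_ortho: int = 0,
    k_folds: int = 7,
    select_vars: bool = True,
    alpha: float = 0.05,
    fold_seed: int = 0,
) -> CVResult:
    """k-fold cross-validation with per-fold variable selection.

    In every round an OPLS model is fitted on the training pairs; when
    ``select_vars`` is on, only the variables reaching two-sided
    significance (p < ``alpha``) on *both* per-variable criteria — the
    paired-t on the difference column (loading w) and the cosine
    similarity between the scaled column and the model-estimated
    response (loading p) — are kept, the model is refitted on those, and
    the held-out responses are predicted.  If some round selects no
    variable at all, the model is declared non-computable and a sentinel
    result (NaN Q², NaN p) is returned.

    Q² = 1 − PRESS/SS(y) from the pooled held-out predictions, with
    SS(y) = Σy² for the uncentered EP response and Σ(y − ȳ)² for DA.
    """
    # local import: the per-variable statistics live in their own module
    # but have no back-dependency on the CV machinery
    from smartscan.significance import cosine_similarities, cosine_t_matrix, w_statistics_matrix

    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    n, p_vars = D.shape
    if model_kind == "EP":
        y_full = np.ones(n)
    else:
        if y is None:
            raise SchemaError("model_kind='DA' requires an explicit response vector y")
        y_full = np.asarray(y, dtype=float)

    folds = _make_folds(n, k_folds, fold_seed)
    y_pred = np.full(n, np.nan)
    selected: list[np.ndarray] = []
    computable = True

    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        D_tr, D_te = D[train_mask], D[test_idx]
        y_tr = y_full[train_mask]

        # drop variables that are constant in this training fold; they
        # cannot be scaled and carry no information for the round
        sds = _sd(D_tr)
        usable = np.flatnonzero(sds > _TINY)
        if usable.size == 0:
            computable = False
            selected.append(np.array([], dtype=int))
            continue

        if select_vars:
            if model_kind == "EP":
                model = fit_opls_ep(D_tr[:, usable], n_ortho=n_ortho)
                _, p_w = w_statistics_matrix(D_tr[:, usable])
            else:
                Z_da, rec = scale_uv(D_tr[:, usable], y_tr)
                model = fit_opls(Z_da, y_tr - y_tr.mean(), n_ortho=n_ortho, scaling=rec, kind="DA")
                classes = np.unique(y_tr)
                _, p_w = stats.ttest_ind(
                    D_tr[np.ix_(y_tr == classes[0], usable)],
                    D_tr[np.ix_(y_tr == classes[-1], usable)],
                    axis=0,
                )
            Z_tr = model.scaling.apply(D_tr[:, usable])
            cs = cosine_similarities(Z_tr, model.y_hat)
            _, p_p = cosine_t_matrix(cs, len(y_tr))
            pass_both = (np.nan_to_num(p_w, nan=1.0) < alpha) & (np.nan_to_num(p_p, nan=1.0) < alpha)
            keep = usable[pass_both]
        else:
            keep = usable
        selected.append(keep)
        if keep.size == 0:
            computable = False
            continue

        if model_kind == "EP":
            sub_model = fit_opls_ep(D_tr[:, keep], n_ortho=n_ortho)
            y_hat_te, _ = predict(sub_model, D_te[:, keep])
        else:
            Z, rec = scale_uv(D_tr[:, keep], y_tr)
            sub_model = fit_opls(Z, y_tr - y_tr.mean(), n_ortho=n_ortho, scaling=rec, kind="DA")
            y_hat_te, _ = predict(sub_model, D_te[:, keep])
            y_hat_te = y_hat_te + y_tr.mean()
        y_pred[test_idx] = y_hat_te

    settings = {
        "k_folds": k_folds, "n_ortho": n_ortho, "select_vars": select_vars,
        "alpha": alpha, "fold_seed": fold_seed,
    }
    n_components = 1 + n_ortho
    if not computable:
        return CVResult(
            y=y_full, y_pred=y_pred, Q2=np.nan, p_cvanova=np.nan,
            selected_vars_per_fold=selected, n_components=n_components,
            kind=model_kind, computable=False, settings=settings,
        )

    press = float(np.sum((y_full - y_pred) ** 2))
    if model_kind == "EP":
        ss = float(np.sum(y_full**2))
    else:
        ss = float(np.sum((y_full - y_full.mean()) ** 2))
    q2 = 1.0 - press / ss
    result = CVResult(
        y=y_full, y_pred=y_pred, Q2=q2, p_cvanova=np.nan,
        selected_vars_per_fold=selected, n_components=n_components,
        kind=model_kind, settings=settings,
    )
    result.p_cvanova, result.perfect_fit = cv_anova(result, n_components)
    return result


def cv_anova(cv: CVResult, n_components: int | None = None) -> tuple[float, bool]:
    """CV-ANOVA: F-test of cross-validated residuals against total variation.

    Decomposition (analysis of variance of the cross-validated
    residuals): SS_total = SS_regression + PRESS, where PRESS is the sum
    of squared cross-validated prediction errors.  Degrees of freedom
    follow the CV-ANOVA convention that each model component consumes
    *two* degrees of freedom (one for the score direction, one for the
    score-response regression):

        DF_total = n       (uncentered EP response)
                 = n - 1   (centered DA response)
        DF_reg   = 2 * n_components
        DF_res   = DF_total - DF_reg
        F        = (SS_reg / DF_reg) / (PRESS / DF_res)

    The p-value is the upper tail of F(DF_reg, DF_res); a negative
    SS_reg (PRESS exceeding total variation) gives p = 1.

    Returns (p_value, perfect_fit_flag).
    """
    if n_components is None:
        n_components = cv.n_components
    y, y_pred = cv.y, cv.y_pred
    if np.isnan(y_pred).any():
        return np.nan, False
    press = float(np.sum((y - y_pred) ** 2))
    n = len(y)
    if cv.kind == "EP":
        ss_tot, df_tot = float(np.sum(y**2)), n
    else:
        ss_tot, df_tot = float(np.sum((y - y.mean()) ** 2)), n - 1
    if press <= _TINY * max(ss_tot, 1.0):
        return 0.0, True
    df_reg = 2 * n_components
    df_res = df_tot - df_reg
    if df_res <= 0:
        raise SampleSizeError(f"too few observations ({n}) for {n_components} component(s)")
    ss_reg = ss_tot - press
    if ss_reg <= 0:
        return 1.0, False
    F = (ss_reg / df_reg) / (press / df_res)
    return float(stats.f.sf(F, df_reg, df_res)), False
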