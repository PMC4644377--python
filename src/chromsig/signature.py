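"""Penalized Cox signature training with nested cross-validation.

The gene signature is trained with elastic-net-regularized Cox
regression inside a double cross-validation loop: an outer
leave-one-out loop produces an unbiased cross-validated prognostic
index per patient, while an inner 10-fold loop on each outer training
set picks the penalty strength lambda by cross-validated
partial-likelihood deviance. Per outer fold the active gene set at the
chosen lambda is refit by unpenalized Cox and the held-out patient's
prognostic index is the linear predictor under that fit. The final
model takes the active set at the average of the per-fold lambdas on
the full data, refit unpenalized — yielding a small gene panel with
per-gene Cox coefficients, the published-style signature.

The elastic-net Cox solver is an IRLS scheme on the Efron partial
likelihood: each step builds the diagonal-Hessian working response and
solves the penalized weighted least-squares subproblem by coordinate
descent (sklearn's ElasticNet engine); KKT conditions of the penalized
partial-likelihood problem can be verified at every grid point via
``kkt_violation``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import (
    CohortData,
    CoxFit,
    auc_at_horizon,
    cox_fit,
    cox_partial_loglik,
    logrank_test,
    prognostic_index,
)

__all__ = [
    "TrainParams",
    "CoxnetPath",
    "elastic_net_cox_path",
    "kkt_violation",
    "SignatureModel",
    "CoxSignatureModel",
    "SignatureResults",
]


@dataclass
class TrainParams:
    """Knobs of the nested-CV elastic-net Cox training."""

    alpha: float = 0.5  # elastic-net mixing (1 = lasso)
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    inner_folds: int = 10
    risk_threshold: float = 0.0
    horizon: float = 60.0  # months, for the ROC AUC

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.inner_folds < 2:
            raise ValueError("need at least 2 inner folds")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Partial-likelihood derivatives with respect to the linear predictor


def _eta_grad_weights(eta, time, event, order=None, no_event_ties=None):
    """Gradient and diagonal curvature of the Efron log partial
    likelihood with respect to the linear predictor.

    Returns (g, w) with g_i = dl/deta_i and w_i = -d2l/deta_i^2
    (floored at 1e-10). Vectorized cumulative-sum path throughout;
    tied event times get the Efron within-tie coefficients. ``order``
    and ``no_event_ties`` may be precomputed (they depend only on
    time/event) to save repeated sorting inside iterative solvers.
    """
    n = eta.shape[0]
    if order is None:
        order = np.lexsort((1 - event, time))
    e = eta[order] - eta.max()
    t, d = time[order], event[order]
    ew = np.exp(e)
    S0 = np.cumsum(ew[::-1])[::-1]  # risk-set sum at each sorted index

    ev = d == 1
    if no_event_ties is None:
        no_event_ties = np.unique(t[ev]).size == int(ev.sum())
    if no_event_ties:
        # no tied event times: fully vectorized (censoring ties are fine,
        # censored subjects sort after the event at an equal time)
        r1 = np.where(ev, 1.0 / S0, 0.0)
        b1 = np.cumsum(r1)
        b2 = np.cumsum(np.where(ev, 1.0 / S0**2, 0.0))
        g = d - ew * b1
        w = ew * b1 - ew**2 * b2
        gg = np.empty(n)
        ww = np.empty(n)
        gg[order] = g
        ww[order] = w
        return gg, np.maximum(ww, 1e-10)

    # per-subject cumulative sums over event-time groups with t_k <= t_i
    b1 = np.zeros(n)  # sum_l 1/phi
    b2 = np.zeros(n)  # sum_l 1/phi^2
    adj1 = np.zeros(n)  # own-group Efron correction, sum_l (l/d)/phi
    adj2 = np.zeros(n)  # own-group, sum_l (1 - (1-l/d)^2)/phi^2
    run1 = run2 = 0.0
    i = 0
    while i < n:
        tt = t[i]
        j = i
        while j < n and t[j] == tt:
            j += 1
        ev_hi = i
        while ev_hi < j and d[ev_hi] == 1:
            ev_hi += 1  # events sorted before censored within a time
        dd = ev_hi - i
        if dd:
            d0 = ew[i:ev_hi].sum()
            o1 = o2 = 0.0
            for l in range(dd):
                f = l / dd
                phi = S0[i] - f * d0
                run1 += 1.0 / phi
                run2 += 1.0 / phi**2
                o1 += f / phi
                o2 += (1.0 - (1.0 - f) ** 2) / phi**2
            adj1[i:ev_hi] = o1
            adj2[i:ev_hi] = o2
        b1[i:j] = run1
        b2[i:j] = run2
        i = j
    c1 = b1 - adj1
    c2 = b2 - adj2
    g = d - ew * c1
    w = ew * c1 - ew**2 * c2
    gg = np.empty(n)
    ww = np.empty(n)
    gg[order] = g
    ww[order] = w
    return gg, np.maximum(ww, 1e-10)


# ---------------------------------------------------------------------------
# Elastic-net path


@dataclass
class CoxnetPath:
    """Coefficient path of the elastic-net Cox problem.

    The objective at each grid point is
    -(1/n) l(beta) + lambda * (alpha*||beta||_1 + (1-alpha)*||beta||_2^2/2)
    on internally standardized covariates; ``coefs`` are reported on
    the original covariate scale, ``coefs_std`` on the standardized
    scale the KKT conditions refer to.
    """

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambdas, p), original scale
    coefs_std: np.ndarray  # (n_lambdas, p), standardized scale
    alpha: float
    names: list[str]
    center: np.ndarray
    scale: np.ndarray

    def active_set(self, lam: float, tol: float = 0.0) -> list[int]:
        k = int(np.argmin(np.abs(self.lambdas - lam)))
        return list(np.flatnonzero(np.abs(self.coefs[k]) > tol))

    def coef_at(self, lam: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[k]


def _standardize(X):
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population (1/n) standard deviation
    if np.any(scale == 0):
        raise ValueError("constant covariates cannot be standardized")
    return (X - center) / scale, center, scale


try:  # fast path: sklearn's Cython coordinate-descent kernel
    from sklearn.linear_model._cd_fast import enet_coordinate_descent as _cd_kernel
except ImportError:  # pragma: no cover - fallback for changed internals
    _cd_kernel = None
_cd_rng = np.random.RandomState(0)  # unused (cyclic order), required by API


def _solve_wls_enet(Xs, z, w, lam, alpha, beta0, enet=None, cd_tol=1e-12):
    """Penalized weighted least squares by coordinate descent.

    Minimizes (1/2n) sum w_i (z_i - x_i beta)^2
    + lam*(alpha*|beta|_1 + (1-alpha)*|beta|^2/2) via sklearn's
    ElasticNet coordinate-descent engine (warm-started); lam = 0 falls
    back to a dense least-squares solve (the Newton step).
    """
    sw = np.sqrt(w)
    Xw = Xs * sw[:, None]
    zw = z * sw
    if lam <= 0.0:
        beta, *_ = np.linalg.lstsq(Xw, zw, rcond=None)
        return beta, enet
    n = Xw.shape[0]
    if _cd_kernel is not None:
        coef = np.ascontiguousarray(beta0, dtype=np.float64).copy()
        out = _cd_kernel(
            coef,
            lam * alpha * n,
            lam * (1.0 - alpha) * n,
            np.asfortranarray(Xw, dtype=np.float64),
            np.ascontiguousarray(zw, dtype=np.float64),
            100_000,
            cd_tol,
            _cd_rng,
            0,
            0,
        )
        return out[0], enet
    from sklearn.linear_model import ElasticNet

    if enet is None:
        enet = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            warm_start=True, max_iter=100_000, tol=cd_tol,
        )
    enet.alpha = lam
    enet.coef_ = beta0.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Xw, zw)
    return enet.coef_.copy(), enet


def _fit_one_lambda(Xs, time, event, lam, alpha, beta, enet,
                    max_irls=200, tol=1e-9, order=None, no_ties=None):
    eta = Xs @ beta
    cd_tol = max(1e-12, tol * 1e-4)
    for _ in range(max_irls):
        g, w = _eta_grad_weights(eta, time, event, order, no_ties)
        z = eta + g / w
        new_beta, enet = _solve_wls_enet(Xs, z, w, lam, alpha, beta, enet,
                                         cd_tol=cd_tol)
        delta = np.max(np.abs(new_beta - beta)) if beta.size else 0.0
        beta = new_beta
        eta = Xs @ beta
        if delta < tol:
            break
    else:
        raise ValueError(f"IRLS did not converge at lambda={lam:.4g}")
    return beta, enet


def _polish_active_set(Xs, time, event, lam, alpha, beta, order, no_ties,
                       grad_tol=1e-11, max_rounds=30):
    """Active-set Newton refinement of one elastic-net Cox solution.

    Drives the penalized stationarity conditions to near machine
    precision: the active coefficients are refined by (approximate)
    Newton steps on the smooth restriction with the l1 term linearized
    at fixed signs, coordinates whose sign collapses are dropped, and
    inactive coordinates violating |score| <= lambda*alpha are added.
    """
    n, p = Xs.shape
    beta = beta.copy()
    for _ in range(max_rounds):
        active = np.flatnonzero(beta)
        if active.size == 0:
            g, _ = _eta_grad_weights(np.zeros(n), time, event, order, no_ties)
            score = Xs.T @ g / n
            worst = int(np.argmax(np.abs(score)))
            if abs(score[worst]) <= lam * alpha + grad_tol:
                return beta
            beta[worst] = 1e-8 * np.sign(score[worst])
            continue
        Xa = Xs[:, active]
        for _ in range(200):
            sgn = np.sign(beta[active])
            eta = Xa @ beta[active]
            g, w = _eta_grad_weights(eta, time, event, order, no_ties)
            grad = -Xa.T @ g / n + lam * (alpha * sgn
                                          + (1 - alpha) * beta[active])
            if np.max(np.abs(grad)) < grad_tol:
                break
            H = (Xa * w[:, None]).T @ Xa / n + lam * (1 - alpha) * np.eye(
                active.size
            )
            step = np.linalg.solve(H, grad)
            new = beta[active] - step
            flipped = np.sign(new) * sgn < 0
            new[flipped] = 0.0
            beta[active] = new
            if flipped.any():
                break  # re-derive the active set
        eta = Xs @ beta
        g, _ = _eta_grad_weights(eta, time, event, order, no_ties)
        score = Xs.T @ g / n
        inactive = beta == 0.0
        viol = np.abs(score) - lam * alpha
        viol[~inactive] = -np.inf
        worst = int(np.argmax(viol))
        if viol[worst] > grad_tol:
            beta[worst] = 1e-8 * np.sign(score[worst])
            continue
        nz = beta != 0
        if not nz.any():
            return beta
        active_resid = np.max(np.abs(
            -score[nz] + lam * (alpha * np.sign(beta[nz])
                                + (1 - alpha) * beta[nz])
        ))
        if active_resid < 10 * grad_tol:
            return beta
    return beta


def elastic_net_cox_path(
    covariates,
    time,
    event,
    alpha: float = 0.5,
    lambdas: Sequence[float] | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    names: Sequence[str] | None = None,
    tol: float = 1e-9,
    polish: bool | None = None,
) -> CoxnetPath:
    """Elastic-net-penalized Cox coefficient path.

    Covariates are standardized internally; the lambda grid defaults to
    ``n_lambdas`` log-spaced values from lambda_max (the smallest
    penalty with an empty active set) down to
    lambda_max * lambda_min_ratio, solved with warm starts. An explicit
    grid may include 0, solved as an unpenalized Newton fit. ``tol``
    is the IRLS coefficient-change tolerance; ``polish`` (default: on
    whenever tol <= 1e-9) runs an active-set Newton refinement that
    drives the KKT residual of the penalized partial-likelihood
    problem to near machine precision at every grid point.
    """
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    Xs, center, scale = _standardize(X)

    g0, _ = _eta_grad_weights(np.zeros(n), time, event)
    score0 = np.abs(Xs.T @ g0) / n
    lam_max = float(score0.max()) / alpha
    if lambdas is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    else:
        lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)

    beta = np.zeros(p)
    enet = None
    do_polish = polish if polish is not None else (tol <= 1e-9)
    order = np.lexsort((1 - event, time))
    ev = event == 1
    no_ties = bool(np.unique(time[ev]).size == int(ev.sum()))
    coefs_std = np.empty((len(lambdas), p))
    for k, lam in enumerate(lambdas):
        if lam >= lam_max and np.all(beta == 0):
            coefs_std[k] = 0.0
            continue
        beta, enet = _fit_one_lambda(Xs, time, event, lam, alpha, beta, enet,
                                     tol=tol, order=order, no_ties=no_ties)
        if do_polish and lam > 0.0:
            beta = _polish_active_set(Xs, time, event, lam, alpha, beta,
                                      order, no_ties)
        coefs_std[k] = beta
    coefs = coefs_std / scale[None, :]
    return CoxnetPath(
        np.asarray(lambdas, float), coefs, coefs_std, alpha, list(names),
        center, scale,
    )


def kkt_violation(path: CoxnetPath, X, time, event, k: int) -> float:
    """Max KKT violation of grid point ``k`` of a fitted path.

    At a solution, for every active covariate
    -(1/n) x_j' g + lambda*(alpha*sign(beta_j) + (1-alpha)*beta_j) = 0
    and for every inactive one |(1/n) x_j' g| <= lambda*alpha, on the
    standardized scale. Returns the largest absolute violation.
    """
    X = np.asarray(X, dtype=float)
    Xs = (X - path.center) / path.scale
    beta = path.coefs_std[k]
    lam = path.lambdas[k]
    g, _ = _eta_grad_weights(Xs @ beta, np.asarray(time, float),
                             np.asarray(event, int))
    score = Xs.T @ g / X.shape[0]
    viol = 0.0
    for j in range(Xs.shape[1]):
        if beta[j] != 0.0:
            resid = -score[j] + lam * (
                path.alpha * np.sign(beta[j]) + (1 - path.alpha) * beta[j]
            )
            viol = max(viol, abs(resid))
        else:
            viol = max(viol, max(0.0, abs(score[j]) - lam * path.alpha))
    return viol


# ---------------------------------------------------------------------------
# Cross-validated deviance and lambda selection


def _cap_active(active, beta_std, n_events):
    """Unpenalized refits need fewer covariates than events; keep the
    largest penalized coefficients when the active set is too big."""
    if len(active) >= n_events:
        order = np.argsort(-np.abs(beta_std[active]))
        active = sorted(np.asarray(active)[order[: max(n_events - 1, 1)]])
    return list(active)


def _polish_args(X, time, event, lam, alpha, path):
    """Assemble arguments to refine a path endpoint at ``lam`` exactly."""
    Xs = (X - path.center) / path.scale
    order = np.lexsort((1 - event, time))
    ev = event == 1
    no_ties = bool(np.unique(time[ev]).size == int(ev.sum()))
    beta = path.coefs_std[int(np.argmin(np.abs(path.lambdas - lam)))].copy()
    return Xs, time, event, lam, alpha, beta, order, no_ties


def _cv_fold_labels(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.resize(np.arange(n_folds), n)
    rng.shuffle(labels)
    return labels


def _select_lambda_cv(
    X, time, event, alpha, lambdas, n_folds, rng, tol: float = 1e-3,
    early_stop: int = 8,
) -> tuple[float, np.ndarray]:
    """Pick lambda minimizing cross-validated partial-likelihood deviance.

    Deviance per fold follows Verweij & van Houwelingen: with beta_k
    fit on the training portion, the fold contributes
    -2 * (l_full(beta_k) - l_train(beta_k)), which stays well defined
    for left-out portions too small to carry a partial likelihood of
    their own. Fold paths are advanced lambda by lambda with warm
    starts; the descent stops once the summed deviance has risen for
    ``early_stop`` consecutive grid points past the current minimum
    (the curve is evaluated only on this fold set, so the selection
    never sees data outside it).
    """
    n, p = X.shape
    folds = _cv_fold_labels(n, n_folds, rng)
    states = []
    for f in range(n_folds):
        train = folds != f
        Xt = X[train]
        Xs, center, scale = _standardize(Xt)
        tt, et = time[train], event[train]
        order = np.lexsort((1 - et, tt))
        ev = et == 1
        no_ties = bool(np.unique(tt[ev]).size == int(ev.sum()))
        states.append({
            "Xs": Xs, "scale": scale, "t": tt, "e": et,
            "order": order, "no_ties": no_ties,
            "beta": np.zeros(p), "enet": None, "train": train,
        })
    dev = np.full(len(lambdas), np.nan)
    best = 0
    for k, lam in enumerate(lambdas):
        d = 0.0
        for st in states:
            st["beta"], st["enet"] = _fit_one_lambda(
                st["Xs"], st["t"], st["e"], lam, alpha, st["beta"],
                st["enet"], tol=tol, order=st["order"],
                no_ties=st["no_ties"],
            )
            beta_orig = st["beta"] / st["scale"]
            ll_full = cox_partial_loglik(X, time, event, beta_orig)
            ll_train = cox_partial_loglik(
                X[st["train"]], time[st["train"]], event[st["train"]],
                beta_orig,
            )
            d += -2.0 * (ll_full - ll_train)
        dev[k] = d
        if d < dev[best]:
            best = k
        elif k - best >= early_stop:
            break
    return float(lambdas[best]), dev


# ---------------------------------------------------------------------------
# Signature model objects


@dataclass
class SignatureModel:
    """Selected genes, their Cox coefficients and training metadata."""

    genes: list[str]
    coefficients: list[float]
    alpha: float
    lambda_bar: float
    seed: int | None = None

    def __post_init__(self):
        if len(self.genes) != len(self.coefficients):
            raise ValueError("one coefficient per gene required")
        if any(c == 0 for c in self.coefficients):
            raise ValueError("zero coefficients must not be stored")

    @property
    def coef_map(self) -> dict[str, float]:
        return dict(zip(self.genes, self.coefficients))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "genes": self.genes,
                "coefficients": self.coefficients,
                "alpha": self.alpha,
                "lambda_bar": self.lambda_bar,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["genes"], d["coefficients"], d["alpha"], d["lambda_bar"],
                   d.get("seed"))


@dataclass
class SignatureResults:
    """Nested-CV training output: per-patient cross-validated prognostic
    indices, the averaged-lambda final model and its unpenalized Cox
    refit."""

    cv_index: pd.Series  # cross-validated PI per patient
    empty_folds: list  # patients whose outer fold had no active gene
    lambda_per_fold: np.ndarray
    lambda_bar: float
    model: SignatureModel
    final_fit: CoxFit
    time: np.ndarray
    event: np.ndarray
    params: TrainParams

    def risk_groups(self) -> pd.Series:
        thr = self.params.risk_threshold
        return pd.Series(
            np.where(self.cv_index.to_numpy() <= thr, "low", "high"),
            index=self.cv_index.index,
            name="risk_group",
        )

    def logrank(self):
        groups = self.risk_groups().to_numpy()
        if np.unique(groups).size < 2:
            from .survival import LogrankResult

            return LogrankResult(0.0, 1.0)
        return logrank_test(self.time, self.event, groups)

    def auc(self, horizon: float | None = None) -> float:
        return auc_at_horizon(
            self.cv_index.to_numpy(), self.time, self.event,
            horizon or self.params.horizon,
        )

    def plot_risk_groups(self, ax=None):
        """Kaplan-Meier curves of the cross-validated risk groups."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        if ax is None:
            _, ax = plt.subplots()
        groups = self.risk_groups().to_numpy()
        for name, color in (("low", "tab:blue"), ("high", "tab:red")):
            mask = groups == name
            if mask.any():
                KaplanMeierFitter(label=f"{name} risk (n={mask.sum()})").fit(
                    self.time[mask], self.event[mask]
                ).plot_survival_function(ax=ax, color=color)
        lr = self.logrank()
        ax.set_xlabel("months")
        ax.set_ylabel("recurrence-free fraction")
        ax.set_title(f"log-rank p = {lr.p:.2g}")
        return ax

    def summary(self) -> str:
        lr = self.logrank()
        genes = ", ".join(
            f"{g} ({c:+.3f})"
            for g, c in zip(self.model.genes, self.model.coefficients)
        )
        lines = [
            "Nested-CV elastic-net Cox signature",
            f"  patients              {len(self.cv_index)}"
            f" ({int(self.event.sum())} events)",
            f"  alpha                 {self.params.alpha}",
            f"  average lambda        {self.lambda_bar:.4g}",
            f"  signature genes       {len(self.model.genes)}",
            f"    {genes}",
            f"  CV risk-split logrank chi2 = {lr.statistic:.3f}, p = {lr.p:.3g}",
        ]
        if self.empty_folds:
            lines.append(
                f"  outer folds with empty active set: {len(self.empty_folds)} "
                "(PI set to 0)"
            )
        return "\n".join(lines)


class CoxSignatureModel:
    """Elastic-net Cox signature trainer over a patient cohort.

    Built from a :class:`~chromsig.survival.CohortData` (or directly
    from a patients x genes DataFrame with time/event vectors);
    ``fit(seed)`` runs the double cross-validation and returns
    :class:`SignatureResults`.
    """

    def __init__(
        self,
        cohort: CohortData,
        gene_set: Sequence[str] | None = None,
        params: TrainParams | None = None,
    ):
        self.params = params or TrainParams()
        expr = cohort.expression
        if gene_set is not None:
            present = [g for g in gene_set if g in expr.columns]
            missing = sorted(set(gene_set) - set(present))
            if missing:
                warnings.warn(f"genes absent from cohort: {missing}")
            if not present:
                raise ValueError("no gene of the requested set is present")
            expr = expr.loc[:, present]
        self.expression = expr
        self.time = cohort.time
        self.event = cohort.event
        if cohort.n_patients < 30:
            raise ValueError("nested cross-validation needs >= 30 patients")

    @classmethod
    def from_dataframes(
        cls, expression: pd.DataFrame, time, event,
        gene_set: Sequence[str] | None = None,
        params: TrainParams | None = None,
    ) -> "CoxSignatureModel":
        cohort = CohortData(expression, np.asarray(time), np.asarray(event))
        return cls(cohort, gene_set, params)

    def _lambda_grid(self, X, time, event) -> np.ndarray:
        p = self.params
        g0, _ = _eta_grad_weights(np.zeros(X.shape[0]), time, event)
        Xs, _, _ = _standardize(X)
        lam_max = float(np.abs(Xs.T @ g0).max()) / X.shape[0] / p.alpha
        return np.geomspace(lam_max, lam_max * p.lambda_min_ratio, p.n_lambdas)

    def fit(self, seed: int | None = 0) -> SignatureResults:
        p = self.params
        X = self.expression.to_numpy(float)
        genes = list(self.expression.columns)
        time, event = self.time, self.event
        n = X.shape[0]

        cv_pi = np.zeros(n)
        lam_per_fold = np.zeros(n)
        empty: list = []
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            Xt, tt, et = X[train], time[train], event[train]
            grid = self._lambda_grid(Xt, tt, et)
            # each outer fold draws its inner-fold assignment from an rng
            # keyed by (seed, fold) so the held-out patient's outcome can
            # never influence its own fold's tuning
            fold_rng = np.random.default_rng([0 if seed is None else seed, i])
            lam_i, _ = _select_lambda_cv(
                Xt, tt, et, p.alpha, grid, p.inner_folds, fold_rng
            )
            lam_per_fold[i] = lam_i
            # warm-started truncated path down to the chosen lambda, with
            # the endpoint polished to exact KKT for a stable active set
            grid_sub = grid[grid >= lam_i * (1 - 1e-12)]
            path = elastic_net_cox_path(Xt, tt, et, alpha=p.alpha,
                                        lambdas=grid_sub, tol=1e-5,
                                        polish=False)
            beta_std = _polish_active_set(
                *_polish_args(Xt, tt, et, lam_i, p.alpha, path)
            )
            active = list(np.flatnonzero(beta_std))
            if not active:
                empty.append(self.expression.index[i])
                cv_pi[i] = 0.0
                continue
            beta_orig = beta_std / path.scale
            active = _cap_active(active, beta_std, int(et.sum()))
            try:
                refit = cox_fit(Xt[:, active], tt, et,
                                names=[genes[j] for j in active])
                cv_pi[i] = float(X[i, active] @ refit.coef)
            except ValueError:
                # degenerate refit (separation): score the held-out
                # patient with the penalized coefficients instead
                cv_pi[i] = float(X[i] @ beta_orig)

        lam_bar = float(lam_per_fold.mean())
        full_grid = self._lambda_grid(X, time, event)
        grid_with_bar = np.unique(np.append(full_grid, lam_bar))[::-1]
        full_path = elastic_net_cox_path(
            X, time, event, alpha=p.alpha, lambdas=grid_with_bar
        )
        k_bar = int(np.argmin(np.abs(full_path.lambdas - lam_bar)))
        active = list(np.flatnonzero(full_path.coefs[k_bar] != 0.0))
        if not active:
            raise ValueError(
                "empty active set at the average lambda; no signature"
            )
        active = _cap_active(active, full_path.coefs_std[k_bar],
                             int(event.sum()))
        final = cox_fit(X[:, active], time, event,
                        names=[genes[j] for j in active])
        model = SignatureModel(
            [genes[j] for j in active], [float(b) for b in final.coef],
            p.alpha, lam_bar, seed,
        )
        return SignatureResults(
            pd.Series(cv_pi, index=self.expression.index,
                      name="prognostic_index"),
            empty, lam_per_fold, lam_bar, model, final, time, event, p,
        )


# ---------------------------------------------------------------------------
# Validation of a trained signature on an external cohort


def validate_signature(
    model: SignatureModel,
    cohort: CohortData,
    horizon: float = 60.0,
    threshold: float = 0.0,
) -> dict:
    """Apply trained coefficients to an external cohort.

    Returns prognostic indices, risk groups, the log-rank split, the
    horizon AUC and (when clinical data is present) the D'Amico
    cross-tabulation. Missing signature genes raise KeyError listing
    them.
    """
    from .survival import damico_classify

    pi_table = prognostic_index(cohort.expression, model.coef_map, threshold)
    groups = pi_table["risk_group"].to_numpy()
    out: dict = {"pi_table": pi_table}
    if np.unique(groups).size == 2:
        lr = logrank_test(cohort.time, cohort.event, groups)
        out["logrank_statistic"], out["logrank_p"] = lr.statistic, lr.p
    else:
        out["logrank_statistic"], out["logrank_p"] = 0.0, 1.0
    try:
        out["auc"] = auc_at_horizon(
            pi_table["prognostic_index"].to_numpy(), cohort.time,
            cohort.event, horizon,
        )
    except ValueError:
        out["auc"] = float("nan")
    if cohort.clinical is not None and {"cT", "gleason", "psa"}.issubset(
        cohort.clinical.columns
    ):
        damico = [
            damico_classify(r["cT"], r["gleason"], r["psa"])
            for _, r in cohort.clinical.iterrows()
        ]
        out["damico_crosstab"] = pd.crosstab(
            pd.Series(damico, index=pi_table.index, name="damico"),
            pi_table["risk_group"],
        )
    return out
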