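"""Survival analytics for expression cohorts.

Kaplan-Meier estimation, the two-group log-rank test, Cox proportional
hazards by Newton-Raphson with Efron tie handling, patient clustering
on a gene set, time-horizon ROC AUC for a risk score, the D'Amico
clinical risk classification, PCA projection of a signature, and the
prognostic-index risk rule (PI = sum beta_i * x_i; PI <= 0 -> low
risk).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

__all__ = [
    "CohortData",
    "CoxFit",
    "center_expression",
    "cluster_patients",
    "km_curve",
    "logrank_test",
    "LogrankResult",
    "cox_fit",
    "cox_partial_loglik",
    "auc_at_horizon",
    "damico_classify",
    "pca_projection",
    "multivariate_adjustment",
    "encode_clinical",
    "prognostic_index",
]


@dataclass
class CohortData:
    """Patient expression matrix plus survival and clinical record.

    ``expression`` is patients x genes; ``time`` is follow-up in
    months; ``event`` is 1 for biochemical recurrence (or metastasis)
    and 0 for censoring. ``clinical`` may carry gleason, pT, pN, psa
    and cT columns for adjustment and D'Amico classification.
    """

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    clinical: pd.DataFrame | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.expression)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time and event must have one entry per patient")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if not np.all(np.isfinite(self.expression.to_numpy())):
            raise ValueError("expression must be finite")
        self.event = self.event.astype(int)
        if self.clinical is not None and len(self.clinical) != n:
            raise ValueError("clinical table must match the expression rows")

    @property
    def n_patients(self) -> int:
        return len(self.expression)

    @classmethod
    def from_files(cls, expression_tsv, clinical_tsv) -> "CohortData":
        """Load genes x patients expression TSV and a clinical TSV.

        The clinical TSV needs columns patient, time_months, event and
        optionally gleason, pT, pN, psa, cT.
        """
        expr = pd.read_csv(expression_tsv, sep="\t", index_col=0).T
        clin = pd.read_csv(clinical_tsv, sep="\t").set_index("patient")
        clin = clin.loc[expr.index]
        extra = [c for c in ("gleason", "pT", "pN", "psa", "cT") if c in clin]
        return cls(
            expr,
            clin["time_months"].to_numpy(float),
            clin["event"].to_numpy(int),
            clin[extra] if extra else None,
        )


def center_expression(
    expression: pd.DataFrame, probe_to_gene: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Average probes per gene, then mean-center every gene column.

    ``probe_to_gene`` maps column names (probes) to gene symbols; when
    given, probe columns of the same gene are averaged first.
    """
    if probe_to_gene is not None:
        expression = expression.T.groupby(
            lambda c: probe_to_gene.get(c, c)
        ).mean().T
    return expression - expression.mean(axis=0)


def cluster_patients(
    expression: pd.DataFrame, gene_set: Sequence[str]
) -> np.ndarray:
    """2-group hierarchical clustering of patients on a gene set.

    Distance 1 - Pearson correlation over the gene set, average
    linkage, deterministic. Genes absent from the matrix are dropped
    with a warning; fewer than two present genes is an error.
    """
    import warnings

    present = [g for g in gene_set if g in expression.columns]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"genes absent from expression matrix: {missing}")
    if len(present) < 2:
        raise ValueError("need at least two genes present to cluster on")
    x = expression.loc[:, present].to_numpy(float)
    sds = x.std(axis=1)
    for i, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"patient {expression.index[i]} has zero variance over the "
                "gene set; correlation distance undefined"
            )
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - (corr + corr.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(dist[np.triu_indices_from(dist, k=1)], method="average")
    return hierarchy.fcluster(z, t=2, criterion="maxclust")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) table.

    Right-continuous non-increasing step function with S(0) = 1,
    computed by lifelines. With every subject censored the estimate is
    identically 1 and the ``all_censored`` attribute flags it.
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    df = kmf.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    df.attrs["all_censored"] = bool(event.sum() == 0)
    return df


class LogrankResult:
    def __init__(self, statistic: float, p: float):
        self.statistic = statistic
        self.p = p

    def __iter__(self):
        return iter((self.statistic, self.p))

    def __repr__(self):
        return f"LogrankResult(statistic={self.statistic:.4g}, p={self.p:.4g})"


def logrank_test(time, event, groups) -> LogrankResult:
    """Standard two-group log-rank test.

    statistic = (sum over event times of (O1 - E1))^2 / sum V, with the
    hypergeometric mean and variance at each event time; p from
    chi-square with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two nonempty groups, got {labels.size}")
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(0.0, 1.0)
    stat = o_minus_e**2 / var
    return LogrankResult(float(stat), float(sps.chi2.sf(stat, 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Efron ties)


@dataclass
class CoxFit:
    """Cox regression estimates with Wald uncertainty."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.96 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.96 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * sps.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "HR 95% lower": self.ci_lower,
                "HR 95% upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.names,
        )


def _efron_groups(time: np.ndarray, event: np.ndarray):
    """Sorted order plus event-group bookkeeping for Efron's method."""
    order = np.lexsort((1 - event, time))  # time asc, events before censored
    return order


def _cox_stats(X, time, event, beta):
    """Efron log partial likelihood, gradient and (optional) Hessian.

    Returns (loglik, grad, hess). X is n x p; subjects sorted by time
    ascending internally.
    """
    n, p = X.shape
    order = _efron_groups(time, event)
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # stabilize exponentials (shifts cancel)
    w = np.exp(eta)
    xw = Xs * w[:, None]
    # suffix sums over the risk set: subjects with time >= t
    # handled per distinct event time below
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # risk-set suffix cumulative sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(xw[::-1], axis=0)[::-1]
    S2 = np.einsum("ij,ik->ijk", Xs, xw)
    S2 = np.cumsum(S2[::-1], axis=0)[::-1]
    i = 0
    while i < n:
        if ds[i] == 1:
            t = ts[i]
            j = i
            while j < n and ts[j] == t and ds[j] == 1:
                j += 1
            d = j - i
            # risk set = indices >= first index with time >= t; since sorted
            # ascending and events sorted first within a time, suffix at i
            # includes censored subjects at the same time
            r0, r1, r2 = S0[i], S1[i], S2[i]
            d0 = w[i:j].sum()
            d1 = xw[i:j].sum(axis=0)
            d2 = np.einsum("ij,ik->jk", Xs[i:j], xw[i:j])
            for l in range(d):
                f = l / d
                phi0 = r0 - f * d0
                phi1 = r1 - f * d1
                phi2 = r2 - f * d2
                loglik -= math.log(phi0)
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
            loglik += eta[i:j].sum()
            grad += Xs[i:j].sum(axis=0)
            i = j
        else:
            i += 1
    return loglik, grad, hess


def _loglik_eta(eta, time, event) -> float:
    """Efron log partial likelihood as a function of the linear predictor.

    O(n log n); vectorized when all event times are distinct, grouped
    Efron summation under ties.
    """
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = eta.shape[0]
    order = np.lexsort((1 - event, time))
    e = eta[order] - eta.max()
    t, d = time[order], event[order]
    ew = np.exp(e)
    S0 = np.cumsum(ew[::-1])[::-1]
    ev = d == 1
    t_ev = t[ev]
    if np.unique(t_ev).size == t_ev.size:
        return float(e[ev].sum() - np.log(S0[ev]).sum())
    ll = 0.0
    i = 0
    while i < n:
        tt = t[i]
        j = i
        while j < n and t[j] == tt:
            j += 1
        ev_hi = i
        while ev_hi < j and d[ev_hi] == 1:
            ev_hi += 1
        dd = ev_hi - i
        if dd:
            d0 = ew[i:ev_hi].sum()
            ll += e[i:ev_hi].sum()
            for l in range(dd):
                ll -= math.log(S0[i] - (l / dd) * d0)
        i = j
    return float(ll)


def cox_partial_loglik(X, time, event, beta) -> float:
    """Efron log partial likelihood at ``beta``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _loglik_eta(X @ np.asarray(beta, float), time, event)


def cox_fit(
    covariates,
    time,
    event,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox regression by Newton-Raphson with Efron tie handling.

    Standard errors come from the inverse observed information; HR
    confidence bounds are exp(beta +/- 1.96 se). Raises on a constant
    covariate, on non-convergence within ``max_iter`` iterations and on
    monotone likelihood (coefficients diverging, as under perfect
    separation).
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
    if event.sum() < p:
        raise ValueError("need at least as many events as covariates")
    sds = X.std(axis=0)
    const = [names[j] for j in range(p) if sds[j] == 0]
    if const:
        raise ValueError(f"constant covariates: {const}")

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_stats(X, time, event, beta)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-8 and ll >= ll_old - 1e-12:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = cox_partial_loglik(X, time, event, cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 50:
            raise ValueError(
                "coefficients diverging (monotone likelihood / separation)"
            )
        if np.max(np.abs(scale * step)) < tol:
            ll_old = ll
            break
        ll_old = ll
    else:
        raise ValueError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(last gradient norm {gnorm:.3g})"
        )
    ll, grad, hess = _cox_stats(X, time, event, beta)
    cov = np.linalg.inv(-hess)
    return CoxFit(
        list(names), beta, np.sqrt(np.diag(cov)), float(ll), n,
        int(event.sum()), it,
    )


# ---------------------------------------------------------------------------
# Risk scores and downstream summaries


def prognostic_index(
    expression_row, coefficients: Mapping[str, float], threshold: float = 0.0
):
    """PI = sum beta_i * x_i and the low/high risk call (PI <= 0 -> low).

    ``expression_row`` may be a Series (one patient) or DataFrame
    (patients x genes); every signature gene must be present.
    """
    genes = list(coefficients.keys())
    if isinstance(expression_row, pd.DataFrame):
        missing = sorted(set(genes) - set(expression_row.columns))
        if missing:
            raise KeyError(f"missing signature genes: {missing}")
        pi = expression_row.loc[:, genes].to_numpy(float) @ np.array(
            [coefficients[g] for g in genes]
        )
        risk = np.where(pi <= threshold, "low", "high")
        return pd.DataFrame(
            {"prognostic_index": pi, "risk_group": risk},
            index=expression_row.index,
        )
    row = expression_row
    missing = sorted(set(genes) - set(row.index))
    if missing:
        raise KeyError(f"missing signature genes: {missing}")
    pi = float(sum(coefficients[g] * row[g] for g in genes))
    return pi, ("low" if pi <= threshold else "high")


def auc_at_horizon(pi, time, event, horizon: float = 60.0) -> float:
    """ROC AUC of a risk score for events within a time horizon.

    Cases are subjects with an event by ``horizon`` (months); controls
    are subjects followed event-free beyond it; subjects censored
    before the horizon are excluded. AUC is the Mann-Whitney
    concordance probability with ties counted 1/2.
    """
    from sklearn.metrics import roc_auc_score

    pi = np.asarray(pi, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    case = (event == 1) & (time <= horizon)
    control = time > horizon
    keep = case | control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"need at least one case and one control at horizon {horizon}"
        )
    return float(roc_auc_score(case[keep].astype(int), pi[keep]))


_T_RE = re.compile(r"^[cp]?T?(\d)([abc]?)$", re.IGNORECASE)


def _parse_t_stage(t) -> tuple[int, int]:
    m = _T_RE.match(str(t).strip())
    if not m:
        raise ValueError(f"unparseable T stage: {t!r}")
    sub = {"": 0, "a": 0, "b": 1, "c": 2}[m.group(2).lower()]
    return int(m.group(1)), sub


def damico_classify(clinical_t, gleason, psa) -> str:
    """D'Amico clinical risk group from clinical T, biopsy Gleason, PSA.

    high: cT >= T2c or Gleason >= 8 or PSA > 20 ng/ml;
    intermediate: cT = T2b or Gleason = 7 or 10 <= PSA <= 20;
    low otherwise (standard published thresholds).
    """
    stage, sub = _parse_t_stage(clinical_t)
    gleason = int(gleason)
    psa = float(psa)
    if (stage, sub) >= (2, 2) or gleason >= 8 or psa > 20:
        return "high"
    if (stage, sub) == (2, 1) or gleason == 7 or 10 <= psa <= 20:
        return "intermediate"
    return "low"


def pca_projection(
    expression: pd.DataFrame, gene_set: Sequence[str], n_components: int = 2
) -> pd.DataFrame:
    """Per-sample scores on the top PCs of a gene-set submatrix.

    Columns are centered; the sign of each component is fixed by
    making its largest-magnitude loading positive, so scores are
    reproducible across runs and platforms.
    """
    from sklearn.decomposition import PCA

    present = [g for g in gene_set if g in expression.columns]
    if len(present) < 2 or len(expression) < 3:
        raise ValueError("need >= 2 genes and >= 3 samples for PCA")
    x = expression.loc[:, present].to_numpy(float)
    x = x - x.mean(axis=0)
    pca = PCA(n_components=min(n_components, len(present)))
    scores = pca.fit_transform(x)
    for k in range(scores.shape[1]):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, lead] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(
        scores,
        index=expression.index,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Encode clinical covariates for multivariate Cox adjustment.

    Gleason ordinal (numeric as-is), pathologic T stage ordinal
    (stage*3 + substage rank), node status binary (pN > 0), PSA
    log2-transformed.
    """
    out = pd.DataFrame(index=clinical.index)
    out["gleason"] = clinical["gleason"].astype(float)
    ts = clinical["pT"].map(_parse_t_stage)
    out["t_stage"] = [3 * s + sub for s, sub in ts]
    pn = clinical["pN"]
    if pn.dtype == object:
        out["node_positive"] = (
            pn.astype(str).str.extract(r"(\d)")[0].astype(int) > 0
        ).astype(float)
    else:
        out["node_positive"] = (pn.astype(float) > 0).astype(float)
    out["log2_psa"] = np.log2(clinical["psa"].astype(float))
    return out


def multivariate_adjustment(
    pi, clinical: pd.DataFrame, time, event
) -> CoxFit:
    """Joint Cox fit of the prognostic index and clinical covariates.

    Reports the PI hazard ratio adjusted for Gleason, T stage, node
    status and (log) PSA.
    """
    covs = encode_clinical(clinical)
    covs.insert(0, "prognostic_index", np.asarray(pi, dtype=float))
    return cox_fit(covs, time, event)
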