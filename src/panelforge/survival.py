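"""Cox proportional-hazards modeling and staged variable selection.

The selection scheme is the classic multi-step screen used for small
cohorts: univariable screening at p <= 0.5, backward elimination by AIC
from the joint model, a p <= 0.1 cut, AIC forward selection over the
screened pool, another p <= 0.1 cut, AIC bidirectional refinement, and
a final significance call at p <= 0.05. Patients are then stratified by
the median of the fitted linear predictor (risk score).

The partial-likelihood maximizer is a small Newton solver (Efron tie
handling) tuned for the many small fits the stepwise search performs;
it is validated against lifelines in the test suite, and lifelines also
provides the Kaplan-Meier machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


# ---------------------------------------------------------------------------
# partial likelihood (Efron ties)


def cox_loglik(beta: np.ndarray, X: np.ndarray, T: np.ndarray, E: np.ndarray) -> float:
    ll, _, _ = _cox_derivatives(beta, X, T, E, want=0)
    return ll


def _cox_derivatives(beta, X, T, E, want=2):
    """Efron log partial likelihood with gradient and information matrix.

    Vectorized over events: each event contributes one Efron term with
    tie fraction f = l/d within its tie group; group aggregates are
    segment sums, risk-set aggregates are suffix cumulative sums.
    """
    n, p = X.shape
    order = np.argsort(T, kind="stable")
    X = X[order]
    T = T[order]
    E = E[order].astype(bool)
    eta = X @ beta if p else np.zeros(n)
    eta = eta - eta.max()  # rescale for stability; ll is shift-invariant
    w = np.exp(eta)
    # tie groups of equal time (sorted, so group ids are nondecreasing)
    _, g = np.unique(T, return_inverse=True)
    first = np.full(g.max() + 1 if n else 1, n, dtype=int)
    np.minimum.at(first, g, np.arange(n))

    ev = np.flatnonzero(E)
    if ev.size == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))
    gev = g[ev]
    d_per_group = np.bincount(gev, minlength=first.size)
    # rank of each event within its tie group -> Efron fraction l/d
    rank = np.arange(ev.size) - np.concatenate(([0], np.cumsum(d_per_group)))[gev]
    f = rank / d_per_group[gev]

    S0 = np.cumsum(w[::-1])[::-1]
    wD = np.bincount(gev, w[ev], minlength=first.size)
    s0 = S0[first[gev]] - f * wD[gev]
    ll = float(eta[ev].sum() - np.log(s0).sum())
    if not (p and want):
        return ll, np.zeros(p), np.zeros((p, p))

    wx = w[:, None] * X
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    wxD = np.zeros((first.size, p))
    np.add.at(wxD, gev, wx[ev])
    s1 = S1[first[gev]] - f[:, None] * wxD[gev]
    mu = s1 / s0[:, None]
    grad = X[ev].sum(axis=0) - mu.sum(axis=0)
    if want < 2:
        return ll, grad, np.zeros((p, p))

    wxx = wx[:, :, None] * X[:, None, :]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    S2D = np.zeros((first.size, p, p))
    np.add.at(S2D, gev, wxx[ev])
    s2 = S2[first[gev]] - f[:, None, None] * S2D[gev]
    info = np.einsum("l,lpq->pq", 1.0 / s0, s2) - np.einsum("lp,lq->pq", mu, mu)
    return ll, grad, info


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    flagged: bool = False

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, np.inf)

    @property
    def p_values(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.covariates)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.beta,
                "hazard_ratio": self.hazard_ratios,
                "se": self.se,
                "z": self.z,
                "p": self.p_values,
            }
        )


class FitError(RuntimeError):
    pass


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    max_iter: int = 50,
    tol: float = 1e-9,
    max_abs_beta: float = 15.0,
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) by Newton's method.

    Raises :class:`FitError` for unusable inputs (no events, constant
    covariate); a diverging fit (monotone likelihood) is returned with
    ``flagged=True`` so callers can exclude it from model selection.
    """
    T = df[time_col].to_numpy(dtype=float)
    E = df[event_col].to_numpy(dtype=int)
    if np.any(T <= 0):
        raise FitError("survival times must be positive")
    if E.sum() < 1:
        raise FitError("need at least one event")
    X = df[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(T), 0))
    for name in covariates:
        if df[name].nunique() < 2:
            raise FitError(f"covariate {name!r} is constant across subjects")
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_derivatives(beta, X, T, E)
    converged = p == 0
    for _ in range(max_iter if p else 0):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return CoxFit(covariates, beta, np.full(p, np.inf), ll,
                          len(T), int(E.sum()), False, flagged=True)
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_derivatives(new_beta, X, T, E)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 10:
            step = step / 2
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_derivatives(new_beta, X, T, E)
            halvings += 1
        beta, grad, info = new_beta, new_grad, new_info
        if abs(new_ll - ll) < tol and np.max(np.abs(step)) < 1e-6:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    flagged = (not converged) or bool(np.any(np.abs(beta) > max_abs_beta))
    if p:
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.inf)
            flagged = True
    else:
        se = np.zeros(0)
    return CoxFit(list(covariates), beta, se, ll, len(T), int(E.sum()),
                  converged, flagged)


# ---------------------------------------------------------------------------
# staged selection


@dataclass
class SelectionThresholds:
    univ_p: float = 0.5
    stage_p: float = 0.1
    final_p: float = 0.05


@dataclass
class CollettResult:
    final_fit: CoxFit
    significant: list[str]
    trace: list[dict] = field(default_factory=list)

    @property
    def final_model(self) -> list[str]:
        return list(self.final_fit.covariates)


def _try_fit(df, covs, time_col, event_col) -> CoxFit | None:
    if not covs:
        return cox_fit(df, [], time_col, event_col)
    try:
        fit = cox_fit(df, covs, time_col, event_col)
    except FitError as e:
        warnings.warn(f"fit on {covs} failed: {e}")
        return None
    if fit.flagged:
        warnings.warn(f"fit on {covs} flagged (non-convergence/monotone likelihood)")
        return None
    return fit


def _aic_of(df, covs, time_col, event_col) -> tuple[float, CoxFit | None]:
    fit = _try_fit(df, covs, time_col, event_col)
    return (np.inf if fit is None else fit.aic), fit


def collett_select(
    df: pd.DataFrame,
    candidates: list[str],
    thresholds: SelectionThresholds = SelectionThresholds(),
    time_col: str = "time",
    event_col: str = "event",
) -> CollettResult:
    """Multi-step Cox variable selection with a full trace.

    Stages: (1) univariable screen at p <= univ_p; (2) backward AIC
    elimination from the joint model of the screened pool; (3) keep
    p <= stage_p; (4) forward AIC selection over the screened pool;
    (5) keep p <= stage_p; (6) bidirectional AIC refinement; (7) report
    variables at p <= final_p as significant. Candidate order never
    affects the result (ties resolve by the sorted candidate order);
    an empty pool at any stage yields an empty-model result.
    """
    candidates = sorted(candidates)
    trace: list[dict] = []

    def record(stage, action, model, aic, extra=None):
        trace.append(
            {"stage": stage, "action": action, "model": list(model), "aic": aic,
             **(extra or {})}
        )

    def empty_result() -> CollettResult:
        fit = cox_fit(df, [], time_col, event_col)
        record("final", "empty-model", [], fit.aic)
        return CollettResult(fit, [], trace)

    # stage 1: univariable screen
    pool = []
    for c in candidates:
        fit = _try_fit(df, [c], time_col, event_col)
        if fit is None:
            record("univariable", "flagged", [c], np.inf)
            continue
        p = float(fit.p_values[0])
        record("univariable", "fit", [c], fit.aic, {"p": p})
        if p <= thresholds.univ_p:
            pool.append(c)
    if not pool:
        return empty_result()

    # stage 2: backward elimination by AIC from the joint model
    current = list(pool)
    aic, fit = _aic_of(df, current, time_col, event_col)
    while fit is None and current:
        current = current[:-1]
        aic, fit = _aic_of(df, current, time_col, event_col)
    record("backward", "start", current, aic)
    while current:
        options = []
        for c in current:
            reduced = [x for x in current if x != c]
            a, f = _aic_of(df, reduced, time_col, event_col)
            options.append((a, c, reduced, f))
        options.sort(key=lambda t: (t[0], t[1]))
        best_aic, dropped, reduced, best_fit = options[0]
        if best_aic < aic:
            current, aic, fit = reduced, best_aic, best_fit
            record("backward", f"drop {dropped}", current, aic)
        else:
            break
    if not current:
        return empty_result()

    # stage 3: p <= stage_p cut
    current = [
        c for c, p in zip(fit.covariates, fit.p_values) if p <= thresholds.stage_p
    ]
    record("cut1", "keep p<=stage_p", current, np.nan)
    aic, fit = _aic_of(df, current, time_col, event_col)

    # stage 4: forward selection over the univariable pool
    record("forward", "start", current, aic)
    while True:
        options = []
        for c in pool:
            if c in current:
                continue
            extended = sorted(current + [c])
            a, f = _aic_of(df, extended, time_col, event_col)
            options.append((a, c, extended, f))
        if not options:
            break
        options.sort(key=lambda t: (t[0], t[1]))
        best_aic, added, extended, best_fit = options[0]
        if best_aic < aic:
            current, aic, fit = extended, best_aic, best_fit
            record("forward", f"add {added}", current, aic)
        else:
            break
    if not current or fit is None:
        return empty_result()

    # stage 5: p <= stage_p cut
    current = [
        c for c, p in zip(fit.covariates, fit.p_values) if p <= thresholds.stage_p
    ]
    record("cut2", "keep p<=stage_p", current, np.nan)
    aic, fit = _aic_of(df, current, time_col, event_col)

    # stage 6: bidirectional refinement
    record("bidirectional", "start", current, aic)
    while True:
        options = []
        for c in pool:
            if c in current:
                continue
            extended = sorted(current + [c])
            a, f = _aic_of(df, extended, time_col, event_col)
            options.append((a, f"add {c}", extended, f))
        for c in current:
            reduced = [x for x in current if x != c]
            a, f = _aic_of(df, reduced, time_col, event_col)
            options.append((a, f"drop {c}", reduced, f))
        if not options:
            break
        options.sort(key=lambda t: (t[0], t[1]))
        best_aic, move, model, best_fit = options[0]
        if best_aic < aic:
            current, aic, fit = model, best_aic, best_fit
            record("bidirectional", move, current, aic)
        else:
            break
    if not current or fit is None:
        return empty_result()

    significant = [
        c for c, p in zip(fit.covariates, fit.p_values) if p <= thresholds.final_p
    ]
    record("final", "significant p<=final_p", significant, fit.aic)
    return CollettResult(fit, significant, trace)


# ---------------------------------------------------------------------------
# stratification and screening


def km_median(times: np.ndarray, events: np.ndarray) -> float | None:
    """Kaplan-Meier median: first time survival drops to <= 0.5."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


@dataclass
class RiskStratification:
    scores: pd.Series
    groups: pd.Series  # "low" / "high"
    km_median_low: float | None
    km_median_high: float | None
    degenerate: bool = False


def stratify(
    fit: CoxFit,
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
) -> RiskStratification:
    """Median split of the linear predictor (ties go to the low group)."""
    if not fit.covariates:
        raise ValueError("cannot stratify on an empty model")
    lp = pd.Series(
        df[fit.covariates].to_numpy(dtype=float) @ fit.beta, index=df.index
    )
    if lp.nunique() == 1:
        warnings.warn("all risk scores identical: single-group stratification")
        groups = pd.Series("low", index=df.index)
        return RiskStratification(
            lp, groups,
            km_median(df[time_col].to_numpy(), df[event_col].to_numpy()),
            None, degenerate=True,
        )
    med = lp.median()
    groups = pd.Series(np.where(lp <= med, "low", "high"), index=df.index)
    med_of = {}
    for label in ("low", "high"):
        mask = groups == label
        med_of[label] = km_median(
            df.loc[mask, time_col].to_numpy(), df.loc[mask, event_col].to_numpy()
        )
    return RiskStratification(lp, groups, med_of["low"], med_of["high"])


def encode_age(years: float) -> int:
    """1 for adult (2-7 years), 0 for senior."""
    return 1 if 2 <= years <= 7 else 0


def covariate_screen(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """One univariable Cox fit per clinical covariate.

    Categorical covariates are dummy-encoded (first level as reference)
    within their single fit; single-level covariates are skipped with a
    warning.
    """
    rows = []
    for cov in covariates:
        if df[cov].nunique() < 2:
            warnings.warn(f"covariate {cov!r} has a single level: skipped")
            continue
        if df[cov].dtype == object or str(df[cov].dtype) == "category":
            enc = pd.get_dummies(df[cov], prefix=cov, drop_first=True).astype(float)
        else:
            enc = df[[cov]].astype(float)
        work = pd.concat([df[[time_col, event_col]], enc], axis=1)
        try:
            fit = cox_fit(work, list(enc.columns), time_col, event_col)
        except FitError as e:
            warnings.warn(f"covariate {cov!r}: {e}")
            continue
        for name, b, hr, p in zip(
            fit.covariates, fit.beta, fit.hazard_ratios, fit.p_values
        ):
            rows.append(
                {"covariate": cov, "term": name, "coef": float(b),
                 "hazard_ratio": float(hr), "p": float(p)}
            )
    return pd.DataFrame(rows, columns=["covariate", "term", "coef", "hazard_ratio", "p"])
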