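"""Cox proportional-hazards engine and the per-trait association scan.

The engine maximizes the Cox partial likelihood with Efron tie correction by
Newton–Raphson with step halving, and stores a Breslow baseline cumulative
hazard.  On top of it sit the study's model specifications:

* Model I    — trait only (crude),
* Model II   — trait + age, sex, AJCC stage,
* Model III  — Model II + BMI, time from operation to blood draw,
               operation type, CRP > 10 mg/l,

each fit for all-cause or CRC-specific mortality (non-CRC deaths are right
censored in the CRC-specific view), on the whole sample, excluding stage 4,
or within one stage.  Scan p-values are Wald; multiplicity is controlled by
Benjamini–Hochberg across the traits of one scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glycomics import TraitMatrix, rank_normal_transform

logger = logging.getLogger(__name__)

#: adjustment covariates per model specification (trait added on top)
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "I": (),
    "II": ("age", "sex", "stage"),
    "III": ("age", "sex", "stage", "bmi", "op_to_sample", "op_type", "crp_gt10"),
}


class CoxError(ValueError):
    """Raised for degenerate Cox fits (no events, separation, constant covariate)."""


# ---------------------------------------------------------------------------
# Partial likelihood with Efron ties
# ---------------------------------------------------------------------------


def _prepare(X, time, event):
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _event_groups(time, event):
    """Tie groups of event times on an ascending-sorted dataset.

    Returns ``(singles_idx, singles_risk, tied_groups)``: vectorizable
    arrays for untied events (event index, first index of its risk set) and
    a list of (risk_start, tied_index_array) for tied event times.
    """
    ev_idx = np.flatnonzero(event)
    if ev_idx.size == 0:
        return np.empty(0, int), np.empty(0, int), []
    ev_t = time[ev_idx]
    boundaries = np.flatnonzero(np.diff(ev_t) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [ev_idx.size]])
    risk_starts = np.searchsorted(time, ev_t[starts], side="left")
    single = (ends - starts) == 1
    singles_idx = ev_idx[starts[single]]
    singles_risk = risk_starts[single]
    tied_groups = [
        (risk_starts[k], ev_idx[starts[k]:ends[k]])
        for k in np.flatnonzero(~single)
    ]
    return singles_idx, singles_risk, tied_groups


def _loglik_grad_hess(beta, X, time, event, groups, want_derivs=True):
    """Efron partial log-likelihood and derivatives on sorted data."""
    n, p = X.shape
    singles_idx, singles_risk, tied_groups = groups
    eta = X @ beta
    eta = eta - eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    # suffix sums over the risk sets
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    if want_derivs:
        xxw = w[:, None, None] * (X[:, :, None] * X[:, None, :])
        s2 = np.cumsum(xxw[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    if singles_idx.size:  # vectorized path for untied event times
        s0r = s0[singles_risk]
        xbar = s1[singles_risk] / s0r[:, None]
        ll += eta[singles_idx].sum() - np.log(s0r).sum()
        if want_derivs:
            grad += X[singles_idx].sum(axis=0) - xbar.sum(axis=0)
            hess += (s2[singles_risk] / s0r[:, None, None]).sum(axis=0)
            hess -= xbar.T @ xbar
    for risk_start, tied in tied_groups:
        d = tied.size
        wt = w[tied]
        Xt = X[tied]
        S0r, S1r = s0[risk_start], s1[risk_start]
        S0d = wt.sum()
        S1d = (wt[:, None] * Xt).sum(axis=0)
        if want_derivs:
            S2r = s2[risk_start]
            S2d = (wt[:, None, None] * (Xt[:, :, None] * Xt[:, None, :])).sum(axis=0)
        ll += eta[tied].sum()
        if want_derivs:
            grad += Xt.sum(axis=0)
        for l in range(d):
            f = l / d
            den = S0r - f * S0d
            ll -= np.log(den)
            if want_derivs:
                xbar_t = (S1r - f * S1d) / den
                grad -= xbar_t
                hess += (S2r - f * S2d) / den - np.outer(xbar_t, xbar_t)
    if want_derivs:
        return ll, grad, hess
    return ll


def cox_partial_loglik(beta, X, time, event) -> float:
    """Efron partial log-likelihood at a fixed coefficient vector."""
    Xs, ts, es = _prepare(X, time, event)
    groups = _event_groups(ts, es)
    return float(_loglik_grad_hess(np.asarray(beta, float), Xs, ts, es, groups,
                                   want_derivs=False))


# ---------------------------------------------------------------------------
# The fit object
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_dropped: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        """exp(coef +/- 1.96 SE), rows (low, high) per covariate."""
        half = 1.959963984540054 * self.se
        return np.column_stack([np.exp(self.coef - half), np.exp(self.coef + half)])

    @property
    def zscores(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zscores))

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.coef

    def baseline_cumhaz_at(self, t: float) -> float:
        """Breslow cumulative baseline hazard H0(t), last step carried forward."""
        if self.baseline_times.size == 0:
            return 0.0
        if t > self.baseline_times[-1]:
            logger.info("horizon %.3g beyond last event time; using last H0 step", t)
        i = np.searchsorted(self.baseline_times, t, side="right")
        return float(self.baseline_cumhaz[i - 1]) if i > 0 else 0.0

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coef, "hr": self.hr, "se": self.se,
                "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": self.p,
            },
            index=self.covariates,
        )


def fit_cox(
    X,
    time,
    event,
    covariate_names: list[str] | None = None,
    *,
    max_iter: int = 100,
    tol_score: float = 1e-9,
    tol_loglik: float = 1e-12,
    max_coef: float = 20.0,
) -> CoxFit:
    """Fit a Cox model by Newton–Raphson on the Efron partial likelihood.

    Convergence when the largest score component is below ``tol_score`` or
    the relative log-likelihood change is below ``tol_loglik``.  A
    coefficient diverging past ``max_coef`` signals monotone likelihood
    (perfect separation) and raises :class:`CoxError` naming the covariate.
    """
    Xs, ts, es = _prepare(X, time, event)
    n, p = Xs.shape
    names = list(covariate_names) if covariate_names else [f"x{i}" for i in range(p)]
    if (ts < 0).any():
        raise CoxError("negative follow-up time")
    n_events = int(es.sum())
    if n_events == 0:
        raise CoxError("no events in dataset")
    sds = Xs.std(axis=0)
    if (sds == 0).any():
        bad = names[int(np.argmax(sds == 0))]
        raise CoxError(f"constant covariate: {bad}")

    groups = _event_groups(ts, es)
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, Xs, ts, es, groups)
    ll_null = ll
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        new_beta = beta + step
        new = _loglik_grad_hess(new_beta, Xs, ts, es, groups)
        halvings = 0
        while new[0] < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new = _loglik_grad_hess(new_beta, Xs, ts, es, groups)
            halvings += 1
        beta, (new_ll, grad, hess) = new_beta, new
        if np.abs(beta).max() > max_coef:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise CoxError(f"monotone likelihood (separation) for covariate: {bad}")
        converged = np.abs(grad).max() < tol_score or (
            abs(new_ll - ll) <= tol_loglik * max(1.0, abs(ll))
        )
        ll = new_ll
        if converged:
            break
    else:
        logger.warning("Cox Newton iteration limit reached (max|score|=%.2e)",
                       np.abs(grad).max())

    cov = np.linalg.inv(hess)
    # Breslow baseline cumulative hazard at distinct event times
    w = np.exp(Xs @ beta)
    s0 = np.cumsum(w[::-1])[::-1]
    singles_idx, singles_risk, tied_groups = groups
    entries = [(ts[i], 1, r) for i, r in zip(singles_idx, singles_risk)]
    entries += [(ts[tied[0]], tied.size, r) for r, tied in tied_groups]
    entries.sort()
    times = [e[0] for e in entries]
    increments = [d / s0[r] for _, d, r in entries]
    return CoxFit(
        covariates=names, coef=beta, cov=cov, loglik=float(ll),
        loglik_null=float(ll_null), n=n, n_events=n_events,
        baseline_times=np.array(times), baseline_cumhaz=np.cumsum(increments),
    )


# ---------------------------------------------------------------------------
# Design matrices from cohort records
# ---------------------------------------------------------------------------


def build_design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix with dummy coding for categorical covariates.

    ``stage`` becomes stage_2/3/4 indicators (stage 1 reference), ``sex``
    an is-female indicator, ``op_type`` dummies against its first level.
    """
    cols = {}
    for c in covariates:
        if c == "stage":
            s = records["stage"].astype(int)
            for k in (2, 3, 4):
                cols[f"stage_{k}"] = (s == k).astype(float)
        elif c == "sex":
            v = records["sex"]
            cols["sex"] = (
                (v == "F").astype(float) if v.dtype == object else v.astype(float)
            )
        elif c == "op_type":
            v = records["op_type"].astype(str)
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols[f"op_type_{lev}"] = (v == lev).astype(float)
        else:
            cols[c] = pd.to_numeric(records[c], errors="coerce").astype(float)
    return pd.DataFrame(cols, index=records.index)


def crc_outcome_view(records: pd.DataFrame) -> pd.DataFrame:
    """CRC-specific outcome: non-CRC deaths become censored at death time."""
    out = records.copy()
    out["event"] = out["event_crc"].astype(bool)
    return out


def _outcome(records: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "all":
        return records["event_all"].to_numpy(bool)
    if outcome == "crc":
        return records["event_crc"].to_numpy(bool)
    raise ValueError(f"unknown outcome {outcome!r}")


def _subset(records: pd.DataFrame, stratum) -> pd.DataFrame:
    if stratum in (None, "whole"):
        return records
    if stratum == "exclude_stage4":
        return records[records["stage"] != 4]
    if isinstance(stratum, str) and stratum.startswith("stage"):
        return records[records["stage"] == int(stratum.removeprefix("stage"))]
    raise ValueError(f"unknown stratum {stratum!r}")


def fit_cox_records(
    records: pd.DataFrame,
    covariates,
    outcome: str = "all",
    stratum=None,
    extra: pd.DataFrame | None = None,
) -> CoxFit:
    """Complete-case Cox fit on cohort records (+ optional extra columns)."""
    rec = _subset(records, stratum)
    design = build_design(rec, covariates)
    if extra is not None:
        design = pd.concat([extra.loc[rec.index], design], axis=1)
    ok = design.notna().all(axis=1) & rec["time"].notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("complete-case analysis dropped %d of %d rows", dropped, len(rec))
    rec, design = rec[ok], design[ok]
    # covariates constant after subsetting (e.g. stage dummies within a stratum)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    fit = fit_cox(
        design[keep].to_numpy(), rec["time"].to_numpy(),
        _outcome(rec, outcome), keep,
    )
    fit.n_dropped = dropped
    return fit


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """One scan configuration: model family, outcome and cohort subset."""

    name: str = "I"
    outcome: str = "all"
    stratum: str = "whole"
    transform: str = "rank"  # "rank" or "none"

    @property
    def covariates(self) -> tuple[str, ...]:
        covs = MODEL_COVARIATES[self.name]
        if self.stratum not in (None, "whole", "exclude_stage4"):
            covs = tuple(c for c in covs if c != "stage")
        return covs


def association_scan(
    traits: TraitMatrix | pd.DataFrame,
    records: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """One Cox fit per retained trait; BH q-values across the scanned family.

    Traits whose fit fails (separation, degeneracy) are reported with the
    failure reason and excluded from the BH family.
    """
    if isinstance(traits, TraitMatrix):
        trait_df = (
            traits.values.set_index("sample_id")[traits.retained_names]
            .reindex(records["sample_id"])
            .set_axis(records.index)
        )
    else:
        # a plain DataFrame is taken as already aligned with ``records``
        trait_df = traits.loc[records.index]

    rows = []
    for name in trait_df.columns:
        x = trait_df[name]
        if spec.transform == "rank":
            try:
                x = pd.Series(rank_normal_transform(x), index=x.index)
            except Exception as exc:  # degenerate trait
                rows.append({"trait": name, "status": f"transform failed: {exc}"})
                continue
        try:
            fit = fit_cox_records(
                records, spec.covariates, spec.outcome, spec.stratum,
                extra=x.to_frame(name),
            )
        except CoxError as exc:
            rows.append({"trait": name, "status": f"fit failed: {exc}"})
            continue
        ci = fit.ci95[0]
        rows.append(
            {
                "trait": name, "n": fit.n, "n_events": fit.n_events,
                "coef": fit.coef[0], "hr": fit.hr[0],
                "ci_low": ci[0], "ci_high": ci[1], "p": fit.p[0], "status": "ok",
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["trait", "n", "n_events", "coef", "hr", "ci_low", "ci_high",
                     "p", "q", "status", "outcome", "model", "stratum"]
        )
    ok = out["status"] == "ok"
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["outcome"], out["model"], out["stratum"] = (
        spec.outcome, spec.name, spec.stratum,
    )
    return out


# ---------------------------------------------------------------------------
# Diagnostics and risk prediction
# ---------------------------------------------------------------------------


def ph_diagnostics(fit: CoxFit, X, time, event) -> pd.Series:
    """Proportional-hazards p-value per covariate.

    Correlates the scaled Schoenfeld residuals with the rank of event time
    (a Grambsch–Therneau-style screen); small p flags a time-varying effect.
    """
    Xs, ts, es = _prepare(X, time, event)
    if int(es.sum()) < 2:
        raise CoxError("PH diagnostics need at least 2 events")
    singles_idx, singles_risk, tied_groups = _event_groups(ts, es)
    w = np.exp(Xs @ fit.coef)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    resid, times = [], []
    for i, r in zip(singles_idx, singles_risk):
        resid.append(Xs[i] - s1[r] / s0[r])
        times.append(ts[i])
    for risk_start, tied in tied_groups:
        xbar = s1[risk_start] / s0[risk_start]
        for i in tied:
            resid.append(Xs[i] - xbar)
            times.append(ts[i])
    resid = np.asarray(resid)
    scaled = fit.n_events * (resid @ fit.cov)  # Grambsch–Therneau scaling
    ranks = stats.rankdata(times)
    pvals = {}
    for j, name in enumerate(fit.covariates):
        if np.allclose(scaled[:, j], scaled[0, j]):
            pvals[name] = 1.0
        else:
            pvals[name] = stats.pearsonr(scaled[:, j], ranks).pvalue
    return pd.Series(pvals, name="ph_p")


def linearity_check(
    records: pd.DataFrame,
    covariate: str,
    base_covariates=(),
    outcome: str = "all",
) -> float:
    """Likelihood-ratio p of quartile-categorical vs linear covariate coding.

    Small p flags deviation from linearity on the log-hazard scale.
    """
    rec = records.dropna(subset=[covariate])
    x = pd.to_numeric(rec[covariate])
    quart = pd.qcut(x, 4, labels=False, duplicates="drop")
    dummies = pd.get_dummies(quart, prefix=f"{covariate}_q", drop_first=True)
    fit_lin = fit_cox_records(rec, base_covariates, outcome,
                              extra=x.to_frame(covariate))
    fit_cat = fit_cox_records(rec, base_covariates, outcome,
                              extra=dummies.astype(float))
    df = len(fit_cat.covariates) - len(fit_lin.covariates)
    lr = 2.0 * (fit_cat.loglik - fit_lin.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))


def predict_risk(fit: CoxFit, X, horizon: float) -> np.ndarray:
    """Per-patient probability of an event by ``horizon``.

    1 - exp(-H0(horizon) * exp(linear predictor)), Breslow baseline.
    """
    h0 = fit.baseline_cumhaz_at(horizon)
    return 1.0 - np.exp(-h0 * np.exp(fit.linear_predictor(X)))
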