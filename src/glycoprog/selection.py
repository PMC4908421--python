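"""Glycan variable selection for augmenting clinical Cox models.

Three procedures:

* :func:`bootstrap_importance` — gradient-boosted Cox stumps refit on
  bootstrap resamples; per-trait relative influence (normalized to sum to
  100) averaged across bootstraps gives the ranking, with the stopping
  iteration chosen on inner folds once.
* :func:`forward_llr_select` — a single ranked forward pass adding a trait
  when the likelihood-ratio statistic against the current model clears the
  chi-square(1) critical value.
* :func:`l1_cox_deviance_compare` — clinical-only vs glyco-clinical Cox
  with an L1 penalty on the glycan terms only (clinical unpenalised),
  penalty chosen by inner cross-validated partial-likelihood deviance,
  compared on outer-fold validation deviance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.ensemble import GradientBoostingSurvivalAnalysis
from sksurv.util import Surv

from .survival import CoxError, CoxFit, cox_partial_loglik, fit_cox

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bootstrap boosted-stump importance
# ---------------------------------------------------------------------------


@dataclass
class ImportanceRanking:
    importance: pd.Series  # mean relative influence per trait, sums to ~100
    selection_frequency: pd.Series  # fraction of bootstraps with influence > 0
    order: list[str] = field(default_factory=list)  # descending importance

    def __post_init__(self) -> None:
        if not self.order:
            # descending importance, ties broken lexicographically
            self.order = list(
                self.importance.sort_index()
                .sort_values(ascending=False, kind="stable").index
            )


def _choose_n_estimators(X, y, learning_rate, max_estimators, inner_folds, rng):
    """Stopping iteration by inner-fold validation of the Cox ensemble."""
    n = len(X)
    inner_folds = min(inner_folds, max(2, n // 25))
    kf = KFold(n_splits=inner_folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    stages = None
    losses = []
    for tr, va in kf.split(X):
        model = GradientBoostingSurvivalAnalysis(
            learning_rate=learning_rate, n_estimators=max_estimators,
            max_depth=1, random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(X[tr], y[tr])
        fold_scores = []
        time_va = y[va]["time"]
        event_va = y[va]["event"]
        for pred in model.staged_predict(X[va]):
            # validation partial-likelihood deviance of the staged predictor
            ll = cox_partial_loglik(
                np.array([1.0]), pred.reshape(-1, 1), time_va, event_va
            )
            fold_scores.append(-2.0 * ll)
        losses.append(fold_scores)
        stages = len(fold_scores)
    mean_loss = np.mean([l[:stages] for l in losses], axis=0)
    return int(np.argmin(mean_loss)) + 1


def bootstrap_importance(
    traits: pd.DataFrame,
    time,
    event,
    n_boot: int = 100,
    seed: int = 0,
    learning_rate: float = 0.05,
    max_estimators: int = 400,
    inner_folds: int = 10,
) -> ImportanceRanking:
    """Average boosted-Cox-stump relative influence over bootstrap resamples."""
    if n_boot < 1:
        raise SelectionError("n_boot must be >= 1")
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if not event.any():
        raise SelectionError("no events")
    names = sorted(traits.columns)  # column-order invariance
    X = traits[names].to_numpy(float)
    y = Surv.from_arrays(event=event, time=time)
    rng = np.random.default_rng(seed)
    n_estimators = _choose_n_estimators(
        X, y, learning_rate, max_estimators, inner_folds, rng
    )
    logger.info("boosting stopping iteration chosen on inner folds: %d",
                n_estimators)
    n = len(X)
    imps = np.zeros((n_boot, len(names)))
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        if not event[idx].any():  # resample without events cannot be fit
            continue
        model = GradientBoostingSurvivalAnalysis(
            learning_rate=learning_rate, n_estimators=n_estimators,
            max_depth=1, random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(X[idx], y[idx])
        raw = model.feature_importances_
        tot = raw.sum()
        imps[b] = 100.0 * raw / tot if tot > 0 else 0.0
    mean_imp = pd.Series(imps.mean(axis=0), index=names)
    freq = pd.Series((imps > 0).mean(axis=0), index=names)
    if mean_imp.sum() == 0:
        logger.warning("no splits in any bootstrap; uniform importance order")
    return ImportanceRanking(mean_imp, freq)


# ---------------------------------------------------------------------------
# Forward selection by likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    selected: list[str]
    steps: pd.DataFrame  # per candidate: llr, p, accepted
    final_fit: CoxFit


def forward_llr_select(
    ranking: ImportanceRanking | list[str],
    traits: pd.DataFrame,
    base_design: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    max_failures: int = 1,
) -> SelectionResult:
    """Single ranked forward pass with a chi-square(1) LLR acceptance rule.

    Stops after ``max_failures`` consecutive rejected candidates.  The base
    model (clinical covariates only; empty design = null model) must fit.
    """
    order = ranking.order if isinstance(ranking, ImportanceRanking) else list(ranking)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)

    def _fit(cols: list[str]) -> CoxFit:
        design = pd.concat([base_design, traits[cols]], axis=1)
        if design.shape[1] == 0:
            # null model: no covariates — represent with loglik only
            ll = cox_partial_loglik(np.zeros(1), np.zeros((len(time), 1)),
                                    time, event)
            return CoxFit([], np.zeros(0), np.zeros((0, 0)), ll, ll,
                          len(time), int(event.sum()),
                          np.zeros(0), np.zeros(0))
        return fit_cox(design.to_numpy(float), time, event,
                       list(design.columns))

    current = _fit([])
    selected: list[str] = []
    rows = []
    failures = 0
    for name in order:
        if name not in traits.columns:
            continue
        try:
            candidate = _fit(selected + [name])
        except CoxError as exc:
            rows.append({"trait": name, "llr": np.nan, "p": np.nan,
                         "accepted": False, "note": str(exc)})
            continue
        llr = 2.0 * (candidate.loglik - current.loglik)
        p = float(stats.chi2.sf(max(llr, 0.0), 1))
        accepted = p < alpha
        rows.append({"trait": name, "llr": llr, "p": p, "accepted": accepted,
                     "note": ""})
        if accepted:
            selected.append(name)
            current = candidate
            failures = 0
        else:
            failures += 1
            if failures >= max_failures:
                break
    return SelectionResult(selected, pd.DataFrame(rows), current)


# ---------------------------------------------------------------------------
# L1-penalised Cox deviance comparison
# ---------------------------------------------------------------------------


def _fit_l1_cox(design: pd.DataFrame, time, event, penalties: np.ndarray):
    """lifelines Cox fit with a per-covariate L1 penalty vector."""
    from lifelines import CoxPHFitter

    df = design.copy()
    df["_time"], df["_event"] = np.asarray(time, float), np.asarray(event, bool)
    cph = CoxPHFitter(penalizer=penalties, l1_ratio=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event")
    return cph.params_.to_numpy()


def _validation_deviance(beta, design, time, event) -> float:
    ll = cox_partial_loglik(beta, design.to_numpy(float), time, event)
    ll0 = cox_partial_loglik(np.zeros(design.shape[1]),
                             design.to_numpy(float), time, event)
    return -2.0 * (ll - ll0)


def l1_cox_deviance_compare(
    clinical_design: pd.DataFrame,
    traits: pd.DataFrame,
    time,
    event,
    folds: int = 5,
    inner_folds: int = 3,
    seed: int = 0,
    penalty_grid=(0.01, 0.03, 0.1, 0.3, 1.0),
) -> dict:
    """Outer-fold validation deviances, clinical-only vs glyco-clinical.

    The glyco-clinical model penalises glycan coefficients only (L1),
    choosing the penalty on inner folds by validation partial-likelihood
    deviance.  Returns the per-fold paired deviances and a t-interval for
    the mean difference (glyco-clinical minus clinical; negative favours
    glycans).
    """
    if folds < 2:
        raise SelectionError("folds must be >= 2")
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    # rank-transforming monotone-related traits leaves exactly collinear
    # columns, which break the penalised Newton solver; keep one per group
    corr = traits.corr().abs()
    drop: list[str] = []
    cols = list(traits.columns)
    for i, a in enumerate(cols):
        if a in drop:
            continue
        drop += [b for b in cols[i + 1:]
                 if b not in drop and corr.loc[a, b] > 0.999]
    if drop:
        logger.info("dropping %d near-duplicate trait column(s): %s",
                    len(drop), drop)
        traits = traits.drop(columns=drop)
    full = pd.concat([clinical_design, traits], axis=1)
    pen_mask = np.array(
        [1.0 if c in traits.columns else 0.0 for c in full.columns]
    )
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    rows = []
    for k, (tr, va) in enumerate(kf.split(full)):
        if not event[va].any() or not event[tr].any():
            logger.warning("fold %d has no events; skipped", k)
            continue
        # inner CV over the penalty grid
        inner = KFold(n_splits=inner_folds, shuffle=True,
                      random_state=int(rng.integers(2**31 - 1)))
        inner_dev = np.zeros(len(penalty_grid))
        for itr, iva in inner.split(tr):
            a, b = tr[itr], tr[iva]
            if not event[a].any() or not event[b].any():
                continue
            for gi, lam in enumerate(penalty_grid):
                try:
                    beta = _fit_l1_cox(full.iloc[a], time[a], event[a],
                                       lam * pen_mask)
                except Exception:  # non-convergence at this penalty
                    inner_dev[gi] += 1e9
                    continue
                inner_dev[gi] += _validation_deviance(
                    beta, full.iloc[b], time[b], event[b]
                )
        lam = penalty_grid[int(np.argmin(inner_dev))]
        beta_g = _fit_l1_cox(full.iloc[tr], time[tr], event[tr], lam * pen_mask)
        fit_c = fit_cox(clinical_design.iloc[tr].to_numpy(float),
                        time[tr], event[tr], list(clinical_design.columns))
        dev_g = _validation_deviance(beta_g, full.iloc[va], time[va], event[va])
        dev_c = _validation_deviance(fit_c.coef, clinical_design.iloc[va],
                                     time[va], event[va])
        rows.append({"fold": k, "penalty": lam,
                     "deviance_clinical": dev_c, "deviance_glycoclinical": dev_g})
    table = pd.DataFrame(rows)
    diff = table["deviance_glycoclinical"] - table["deviance_clinical"]
    m, s, nf = diff.mean(), diff.std(ddof=1), len(diff)
    half = stats.t.ppf(0.975, nf - 1) * s / np.sqrt(nf) if nf > 1 else np.inf
    return {
        "folds": table,
        "deviance_clinical": float(table["deviance_clinical"].mean()),
        "deviance_glycoclinical": float(table["deviance_glycoclinical"].mean()),
        "difference_mean": float(m),
        "difference_ci95": (float(m - half), float(m + half)),
    }
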