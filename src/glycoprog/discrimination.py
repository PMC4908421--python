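"""Prognostic discrimination metrics: Harrell's C, cumulative/dynamic AUC,
discrimination slopes and the integrated discrimination improvement (IDI).

Conventions: higher risk score = worse prognosis; risk ties contribute 1/2
to concordance-type statistics, which makes C(risk) + C(-risk) = 1 exact in
the absence of ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines.utils import concordance_index

logger = logging.getLogger(__name__)


class DiscriminationError(ValueError):
    pass


def harrells_c(risk, time, event) -> float:
    """Harrell's concordance for right-censored data.

    Over all usable pairs (the shorter follow-up ends in an event), the
    fraction in which the riskier-scored patient fails first; risk ties
    count 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if not event.any() or len(time) < 2:
        raise DiscriminationError("no usable pairs for concordance")
    try:
        # lifelines scores "higher = longer survival", hence the sign flip
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as exc:
        raise DiscriminationError("no usable pairs for concordance") from exc


def _censoring_survival(time, event):
    """Kaplan-Meier of the censoring distribution G(t) = P(C > t)."""
    time = np.asarray(time, float)
    cens = ~np.asarray(event, bool)
    order = np.argsort(time, kind="stable")
    t, c = time[order], cens[order]
    n = len(t)
    at_risk = n - np.arange(n)
    # group ties: censorings at t count only against risk sets at earlier times
    uniq, start = np.unique(t, return_index=True)
    surv = []
    g = 1.0
    for u, s in zip(uniq, start):
        end = start[np.searchsorted(uniq, u) + 1] if u != uniq[-1] else n
        d_c = int(c[s:end].sum())
        g *= 1.0 - d_c / at_risk[s]
        surv.append(g)
    return uniq, np.asarray(surv)


def _G(uniq, surv, t, left=False):
    """Evaluate the censoring KM at t (or just before t when left=True)."""
    side = "left" if left else "right"
    i = np.searchsorted(uniq, t, side=side)
    return np.where(i > 0, surv[np.clip(i - 1, 0, len(surv) - 1)], 1.0)


def cumulative_dynamic_auc(risk, time, event, horizon: float) -> float:
    """Cumulative/dynamic time-dependent AUC at ``horizon``.

    Estimates P(risk_i > risk_j | T_i <= t < T_j) — a subject with an event
    by the horizon ranks above one event-free past it.  Censoring is handled
    by inverse-probability-of-censoring weights from the Kaplan–Meier
    estimate of the censoring distribution; with no censoring the estimator
    reduces exactly to the Mann–Whitney AUC of the dichotomized outcome.
    Risk ties count 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    cases = (time <= horizon) & event
    controls = time > horizon
    if not cases.any() or not controls.any():
        raise DiscriminationError("need at least one case and one control")
    uniq, surv = _censoring_survival(time, event)
    w_case = 1.0 / _G(uniq, surv, time[cases], left=True)
    g_t = float(_G(uniq, surv, np.array([horizon]))[0])
    if not np.isfinite(w_case).all() or g_t <= 0:
        raise DiscriminationError("censoring weights undefined at the horizon")
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_t)
    zc = risk[cases][:, None]
    zk = risk[controls][None, :]
    wins = (zc > zk) + 0.5 * (zc == zk)
    ww = w_case[:, None] * w_ctrl[None, :]
    return float((wins * ww).sum() / ww.sum())


def discrimination_slope(probabilities, labels) -> float:
    """Mean predicted probability in events minus non-events."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise DiscriminationError("both outcome classes required for the slope")
    return float(p[y].mean() - p[~y].mean())


def idi(p_new, p_old, labels) -> float:
    """Integrated discrimination improvement: difference of slopes."""
    return discrimination_slope(p_new, labels) - discrimination_slope(p_old, labels)


@dataclass
class DiscriminationReport:
    """Table-3-style metric block for one model-vs-comparator pair."""

    harrells_c: float
    auc_t: float
    horizon: float
    slope_model: float
    slope_comparator: float
    n_excluded: int = 0

    @property
    def idi(self) -> float:
        return self.slope_model - self.slope_comparator

    def to_dict(self) -> dict:
        return {
            "harrells_c": self.harrells_c, "auc": self.auc_t,
            "horizon_years": self.horizon, "idi": self.idi,
            "slope_model": self.slope_model,
            "slope_comparator": self.slope_comparator,
            "n_excluded_before_horizon": self.n_excluded,
        }


def evaluate_pair(
    risk_model,
    prob_model,
    prob_comparator,
    time,
    event,
    horizon: float = 5.0,
) -> DiscriminationReport:
    """Discrimination of a model against a comparator at one horizon.

    Slopes (and hence the IDI) use observed status at the horizon; patients
    censored event-free before the horizon are excluded from the slope
    computation and counted.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    known = (time >= horizon) | event
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("%d patients censored before the %g-year horizon excluded "
                    "from discrimination slopes", n_excluded, horizon)
    y = (time <= horizon) & event
    return DiscriminationReport(
        harrells_c=harrells_c(risk_model, time, event),
        auc_t=cumulative_dynamic_auc(risk_model, time, event, horizon),
        horizon=horizon,
        slope_model=discrimination_slope(
            np.asarray(prob_model, float)[known], y[known]
        ),
        slope_comparator=discrimination_slope(
            np.asarray(prob_comparator, float)[known], y[known]
        ),
        n_excluded=n_excluded,
    )
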