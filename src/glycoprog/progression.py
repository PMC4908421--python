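"""Stage-stratified rapid-progressor classification and the
with/without-glycans model comparison.

A *rapid progressor* in a stage is a patient who died of CRC with follow-up
in the lower tertile of the CRC-death times of that stage (type-7
percentile).  A zoo of classifier configurations is evaluated by repeated
stratified cross-validation — validation folds untouched by any filtering
or fitting — once on clinical features only and once on clinical + glycan
features.  The paired per-configuration differences in merged validation
AUC feed a Wilcoxon signed-rank test: W over all configurations, Wd over
the disparate subset (one configuration per model class).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


class ProgressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass
class ProgressorLabels:
    stage: int
    cutoff_years: float
    labels: pd.Series  # 1 = rapid progressor
    n_crc_deaths: int


def label_rapid_progressors(records: pd.DataFrame, stage: int) -> ProgressorLabels:
    """Rapid = died of CRC with time <= the stage's lower-tertile cutoff.

    The cutoff is the 33.33rd percentile (linear/type-7 interpolation) of
    CRC-death times within the stage.  All other patients of the stage —
    slower CRC deaths, other-cause deaths, censored — are labelled not
    rapid.  Raises when the stage has fewer than 3 CRC deaths (the stage-1
    situation, where the classification is skipped).
    """
    rec = records[records["stage"] == stage]
    crc_times = rec.loc[rec["event_crc"].astype(bool), "time"]
    if len(crc_times) < 3:
        raise ProgressionError(
            f"stage {stage}: only {len(crc_times)} CRC deaths; "
            "rapid-progressor classification skipped"
        )
    cutoff = float(np.percentile(crc_times, 100.0 / 3.0, method="linear"))
    labels = (rec["event_crc"].astype(bool) & (rec["time"] <= cutoff)).astype(int)
    return ProgressorLabels(stage, cutoff, labels, len(crc_times))


def label_five_year_crc_death(records: pd.DataFrame, horizon: float = 5.0):
    """5-year CRC-death labels and an eligibility mask.

    Label 1: CRC death by the horizon.  Label 0: followed event-free past
    the horizon, or died (any cause) after it, or died of another cause —
    the outcome is CRC-specific.  Patients censored event-free before the
    horizon are masked out (count logged).
    """
    time = records["time"]
    crc = records["event_crc"].astype(bool)
    dead = records["event_all"].astype(bool)
    labels = (crc & (time <= horizon)).astype(int)
    eligible = (time >= horizon) | dead
    n_masked = int((~eligible).sum())
    if n_masked:
        logger.info("%d patients censored before %g years excluded from the "
                    "5-year classification", n_masked, horizon)
    return labels, eligible


# ---------------------------------------------------------------------------
# Classifier zoo
# ---------------------------------------------------------------------------


class KDENaiveBayes:
    """Naive Bayes with Gaussian-kernel-density marginal distributions.

    Class-conditional densities are products of per-feature KDEs
    (Scott's-rule bandwidth); degenerate (near-constant) features fall back
    to a narrow Gaussian.  Scores are log-posterior differences.
    """

    def __init__(self, min_bandwidth: float = 1e-3):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.classes_ = np.unique(y)
        self.priors_ = {c: float((y == c).mean()) for c in self.classes_}
        self.kdes_ = {}
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(X.shape[1]):
                v = Xc[:, j]
                if len(v) < 2 or np.std(v) < self.min_bandwidth:
                    feats.append(("gauss", float(np.mean(v)),
                                  max(float(np.std(v)), self.min_bandwidth)))
                else:
                    feats.append(("kde", stats.gaussian_kde(v), None))
            self.kdes_[c] = feats
        return self

    def _class_loglik(self, X, c):
        ll = np.full(len(X), np.log(self.priors_[c]))
        for j, spec in enumerate(self.kdes_[c]):
            kind = spec[0]
            if kind == "kde":
                dens = spec[1](X[:, j])
            else:
                _, m, s = spec
                dens = stats.norm.pdf(X[:, j], m, s)
            ll += np.log(np.maximum(dens, 1e-300))
        return ll

    def decision_scores(self, X):
        X = np.asarray(X, float)
        if len(self.classes_) == 1:
            return np.zeros(len(X))
        return self._class_loglik(X, self.classes_[-1]) - self._class_loglik(
            X, self.classes_[0]
        )


class _ProbaWrapper:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.est.fit(X, y)
        return self

    def decision_scores(self, X):
        proba = self.est.predict_proba(X)
        return proba[:, -1] if proba.shape[1] > 1 else np.zeros(len(X))


class _DecisionWrapper(_ProbaWrapper):
    def decision_scores(self, X):
        return np.asarray(self.est.decision_function(X), float)


class _CentroidWrapper:
    """Nearest shrunken centroids scored by signed centroid-distance margin."""

    def __init__(self, shrink_threshold: float = 0.2):
        self.est = NearestCentroid(shrink_threshold=shrink_threshold)

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.est.fit(X, y)
        return self

    def decision_scores(self, X):
        X = np.asarray(X, float)
        cents = self.est.centroids_
        if len(cents) == 1:
            return np.zeros(len(X))
        d0 = np.linalg.norm(X - cents[0], axis=1)
        d1 = np.linalg.norm(X - cents[1], axis=1)
        return d0 - d1  # larger = closer to the positive class


class _KNNWrapper(_ProbaWrapper):
    """kNN with the neighbour count clipped to the training-fold size."""

    def fit(self, X, y):
        self.est.n_neighbors = min(self.est.n_neighbors, len(X))
        return super().fit(X, y)


class _TreeWrapper(_ProbaWrapper):
    """Tree with the leaf-size floor adapted to small training folds."""

    def fit(self, X, y):
        self.est.min_samples_leaf = max(1, min(self.est.min_samples_leaf,
                                               len(X) // 5))
        return super().fit(X, y)


@dataclass(frozen=True)
class ModelConfiguration:
    """One zoo entry: model class + preprocessing flags.

    The default hyperparameters are deliberately strongly regularized: the
    zoo is built for small stage strata (~150 patients) where an
    under-regularized model exploits chance structure in uninformative
    features, which both degrades prediction and de-calibrates the paired
    with/without-glycans comparison.
    """

    name: str
    model_class: str
    filter_k: int | None = None  # top-k glycan features on training folds
    log_transform: bool = False

    def make(self, seed: int):
        mc = self.model_class
        if mc == "l1_logistic":
            return _ProbaWrapper(LogisticRegression(
                penalty="l1", C=0.05, solver="liblinear", random_state=seed))
        if mc == "knn":
            return _KNNWrapper(KNeighborsClassifier(n_neighbors=60))
        if mc == "shrunken_centroids":
            return _CentroidWrapper(shrink_threshold=1.8)
        if mc.startswith("svm"):
            degree = {"svm_linear": 1, "svm_quadratic": 2, "svm_cubic": 3}[mc]
            kernel = "linear" if degree == 1 else "poly"
            return _DecisionWrapper(SVC(kernel=kernel, degree=degree, C=0.03,
                                        random_state=seed))
        if mc == "kde_naive_bayes":
            return KDENaiveBayes()
        if mc == "decision_tree":
            return _TreeWrapper(DecisionTreeClassifier(
                max_depth=1, min_samples_leaf=30, random_state=seed))
        if mc == "boosted_stumps":
            return _ProbaWrapper(GradientBoostingClassifier(
                max_depth=1, n_estimators=8, learning_rate=0.1,
                random_state=seed))
        raise ProgressionError(f"unknown model class {self.model_class!r}")


def default_zoo(extended: bool = False) -> list[ModelConfiguration]:
    """Seven disparate model classes; ``extended`` adds the SVM variants."""
    classes = [
        "l1_logistic", "knn", "shrunken_centroids", "svm_linear",
        "kde_naive_bayes", "decision_tree", "boosted_stumps",
    ]
    zoo = [ModelConfiguration(c, c) for c in classes]
    if extended:
        zoo += [ModelConfiguration(c, c) for c in ("svm_quadratic", "svm_cubic")]
    return zoo


def disparate_subset(zoo: list[ModelConfiguration]) -> list[ModelConfiguration]:
    """One configuration per model class; among SVMs keep the linear one."""
    out, seen = [], set()
    for cfg in zoo:
        cls = "svm" if cfg.model_class.startswith("svm") else cfg.model_class
        if cls == "svm" and cfg.model_class != "svm_linear" and any(
            c.model_class == "svm_linear" for c in zoo
        ):
            continue
        if cls not in seen:
            seen.add(cls)
            out.append(cfg)
    return out


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


def _preprocess(train_X, test_X, y_train, clinical_cols, glycan_cols, cfg):
    """Train-fold-only preprocessing: log transform, filtering, scaling."""
    tr, te = train_X.copy(), test_X.copy()
    if cfg.log_transform:
        for c in tr.columns:
            lo = min(tr[c].min(), te[c].min())
            shift = -lo + 1.0 if lo <= 0 else 0.0
            tr[c], te[c] = np.log(tr[c] + shift), np.log(te[c] + shift)
    cols = list(clinical_cols)
    gly = [c for c in glycan_cols if c in tr.columns]
    if gly and cfg.filter_k is not None and cfg.filter_k < len(gly):
        # rank glycan features by point-biserial correlation on training data
        scores = {
            c: abs(np.corrcoef(tr[c], y_train)[0, 1]) if tr[c].std() > 0 else 0.0
            for c in gly
        }
        gly = sorted(gly, key=lambda c: (-scores[c], c))[: cfg.filter_k]
    cols += gly
    mu, sd = tr[cols].mean(), tr[cols].std().replace(0.0, 1.0)
    return ((tr[cols] - mu) / sd).to_numpy(), ((te[cols] - mu) / sd).to_numpy()


@dataclass
class CVResult:
    configuration: ModelConfiguration
    feature_set: str  # "clinical" or "clinical_glycans"
    run_aucs: np.ndarray  # merged AUC of pooled validation predictions, per run
    predictions: pd.DataFrame  # run, index, score, label

    @property
    def merged_auc(self) -> float:
        return float(self.run_aucs.mean())


def run_cv(
    configurations: list[ModelConfiguration],
    features: pd.DataFrame,
    labels,
    clinical_cols,
    glycan_cols,
    n_runs: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> list[CVResult]:
    """Repeated stratified CV of every configuration on both feature sets.

    Per run, validation predictions are pooled over the folds and scored as
    one merged AUC; the per-configuration result averages over runs.  All
    preprocessing (log transform, glycan filtering, standardization) is fit
    on training folds only.
    """
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ProgressionError("both classes required")
    if n_folds < 2:
        raise ProgressionError("n_folds must be >= 2")
    feature_sets = {"clinical": [], "clinical_glycans": list(glycan_cols)}
    results = []
    for cfg in configurations:
        for fs_name, gly in feature_sets.items():
            cfg_tag = zlib.crc32(cfg.name.encode()) % 2**31  # stable across runs
            rng = np.random.default_rng([seed, cfg_tag,
                                         fs_name == "clinical_glycans"])
            run_aucs, preds = [], []
            for run in range(n_runs):
                skf = StratifiedKFold(
                    n_splits=n_folds, shuffle=True,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                scores = np.full(len(y), np.nan)
                for tr, va in skf.split(features, y):
                    if len(np.unique(y[tr])) < 2:
                        raise ProgressionError("training fold with one class")
                    Xtr, Xva = _preprocess(
                        features.iloc[tr], features.iloc[va], y[tr],
                        clinical_cols, gly, cfg,
                    )
                    model = cfg.make(int(rng.integers(2**31 - 1)))
                    model.fit(Xtr, y[tr])
                    scores[va] = model.decision_scores(Xva)
                run_aucs.append(roc_auc_score(y, scores))
                preds.append(pd.DataFrame(
                    {"run": run, "index": np.arange(len(y)),
                     "score": scores, "label": y}
                ))
            results.append(CVResult(
                cfg, fs_name, np.asarray(run_aucs), pd.concat(preds),
            ))
    return results


# ---------------------------------------------------------------------------
# With/without-glycans comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    table: pd.DataFrame  # per configuration: auc_without, auc_with, difference
    p_w: float  # Wilcoxon over all configurations
    p_wd: float  # Wilcoxon over the disparate subset
    median_gain: float
    warning: str = ""

    def to_dict(self) -> dict:
        return {
            "per_configuration": self.table.to_dict(orient="records"),
            "p_W": self.p_w, "p_Wd": self.p_wd,
            "median_auc_gain": self.median_gain, "warning": self.warning,
        }


def _signed_rank_p(diff: np.ndarray) -> tuple[float, str]:
    d = diff[diff != 0.0]  # standard convention: drop zero differences
    if d.size == 0:
        return 1.0, "all paired differences are zero"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    except ValueError:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.pvalue), ""


def compare_with_without_glycans(
    cv_results: list[CVResult],
    zoo: list[ModelConfiguration] | None = None,
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank of with- vs without-glycans merged AUCs.

    Exact two-sided p for <= 25 tie-free pairs (normal approximation
    otherwise); identical AUC vectors give p = 1 with a warning.  ``p_Wd``
    repeats the test on the disparate subset (one configuration per model
    class).
    """
    by_cfg: dict[str, dict[str, float]] = {}
    cfg_obj: dict[str, ModelConfiguration] = {}
    for r in cv_results:
        by_cfg.setdefault(r.configuration.name, {})[r.feature_set] = r.merged_auc
        cfg_obj[r.configuration.name] = r.configuration
    rows = []
    for name, aucs in by_cfg.items():
        if {"clinical", "clinical_glycans"} <= set(aucs):
            rows.append({
                "configuration": name,
                "auc_without": aucs["clinical"],
                "auc_with": aucs["clinical_glycans"],
                "difference": aucs["clinical_glycans"] - aucs["clinical"],
            })
    if not rows:
        raise ProgressionError("no matched configuration pairs")
    table = pd.DataFrame(rows)
    diffs = table["difference"].to_numpy()
    p_w, warn = _signed_rank_p(diffs)
    subset = disparate_subset(zoo or [cfg_obj[n] for n in table["configuration"]])
    names_d = {c.name for c in subset}
    p_wd, _ = _signed_rank_p(
        table.loc[table["configuration"].isin(names_d), "difference"].to_numpy()
    )
    if warn:
        logger.warning("signed-rank statistic undefined: %s", warn)
    return ComparisonResult(table, p_w, p_wd, float(np.median(diffs)), warn)


def ppv_at_threshold(predictions, labels, threshold: float = 0.5) -> float:
    """Positive predictive value (precision) at a probability threshold."""
    p = np.asarray(predictions, float)
    y = np.asarray(labels, bool)
    pos = p >= threshold
    if not pos.any():
        raise ProgressionError("no predicted positives at this threshold")
    return float((pos & y).sum() / pos.sum())
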