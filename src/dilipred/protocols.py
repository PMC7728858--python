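"""Model-evaluation protocols: MCCV grid search, final fit, Y-scrambling,
and the two robustness resampling schemes.

The backbone is Monte Carlo cross-validation (MCCV): each iteration draws a
fresh stratified 80/20 split of the training set, fits the candidate
configuration on the 80% and scores the held-out 20%, recording a full
metrics report.  Grid search ranks hyperparameter combinations by their mean
V score across iterations (ties: higher mean AUC, then lexical config label).

Y-scrambling forms the no-information null: the training labels are permuted
uniformly at random, one inner 80/20 fit-and-score is performed per scramble,
and the real-data MCCV metric distribution is compared to the scrambled one
per metric with a Welch two-sample t-test (Benjamini-Hochberg adjusted across
the eight metrics) plus Cohen's d, the standardized mean difference over the
pooled standard deviation.

All randomness fans out from one master seed through per-iteration integer
seeds, so every protocol is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classifiers import (ClassifierConfig, predict_scores, train_classifier,
                          with_seed)
from .exceptions import LeakageError, TrainingError
from .metrics import METRIC_NAMES, MetricsReport, evaluate_predictions
from .profiles import ProfileSet
from .selection import (balanced_downsample, drug_overlap,
                        stratified_split_drugs, stratified_split_profiles)

logger = logging.getLogger(__name__)

ALL_METRICS = METRIC_NAMES + ("v_score",)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def reports_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def summarize_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """mean/sd per metric over a list of reports."""
    df = reports_frame(reports)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


@dataclass
class MccvResult:
    """Iteration-level reports of one MCCV run plus any logged failures."""

    reports: list[MetricsReport]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self.reports)

    def summary(self) -> pd.DataFrame:
        return summarize_reports(self.reports)


def _fit_score_split(config: ClassifierConfig, data: ProfileSet,
                     train_fraction: float, seed: int) -> MetricsReport:
    plan = stratified_split_profiles(data, train_fraction, seed)
    inner_train = data.subset(plan.train_ids)
    inner_valid = data.subset(plan.validation_ids)
    model = train_classifier(with_seed(config, seed), inner_train)
    scores = predict_scores(model, inner_valid)
    return evaluate_predictions(inner_valid.labels, scores)


def mccv(train: ProfileSet, config: ClassifierConfig, n_iter: int = 100,
         inner_train_fraction: float = 0.8, seed: int = 0) -> MccvResult:
    """Monte Carlo cross-validation of one configuration."""
    seeds = _child_seeds(seed, n_iter)
    result = MccvResult(reports=[])
    for i, s in enumerate(seeds):
        try:
            result.reports.append(
                _fit_score_split(config, train, inner_train_fraction, int(s))
            )
        except TrainingError as exc:  # logged and excluded, never imputed
            logger.warning("MCCV iteration %d failed: %s", i, exc)
            result.failures.append((i, str(exc)))
    return result


@dataclass
class GridSearchResult:
    """Per-combination MCCV summaries and the selected configuration."""

    table: pd.DataFrame = field(repr=False)  # one row per combination
    per_config: dict[str, MccvResult] = field(repr=False, default_factory=dict)
    best_config: ClassifierConfig | None = None

    def best_label(self) -> str:
        return self.best_config.label()


def grid_search(train: ProfileSet, grid: list[ClassifierConfig],
                n_iter: int = 100, inner_train_fraction: float = 0.8,
                seed: int = 0) -> GridSearchResult:
    """Rank a hyperparameter grid by mean V over MCCV iterations."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    per_config: dict[str, MccvResult] = {}
    configs_by_label = {}
    for config in grid:
        res = mccv(train, config, n_iter, inner_train_fraction, seed)
        label = config.label()
        per_config[label] = res
        configs_by_label[label] = config
        summ = res.summary()
        row = {"config": label, "n_completed": res.n_completed,
               "n_failed": len(res.failures)}
        for m in ALL_METRICS:
            row[f"mean_{m}"] = summ.loc[m, "mean"]
            row[f"sd_{m}"] = summ.loc[m, "sd"]
        rows.append(row)
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_v_score", "mean_auc", "config"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = configs_by_label[ranked.iloc[0]["config"]]
    return GridSearchResult(table=ranked.reset_index(drop=True),
                            per_config=per_config, best_config=best)


@dataclass
class FinalEvaluation:
    """Final-fit reports on training and independent validation sets."""

    train_report: MetricsReport
    validation_report: MetricsReport
    abs_differences: dict[str, float]


def final_evaluate(best_config: ClassifierConfig, train: ProfileSet,
                   validation: ProfileSet,
                   allow_overlap: bool = False) -> FinalEvaluation:
    """Fit once on the full training set, score both sets, and report the
    per-metric |train - validation| differences (the overfitting check)."""
    overlap = set(train.profile_ids) & set(validation.profile_ids)
    if overlap and not allow_overlap:
        raise LeakageError(f"train/validation share {len(overlap)} profiles")
    model = train_classifier(best_config, train)
    train_rep = evaluate_predictions(train.labels, predict_scores(model, train))
    valid_rep = evaluate_predictions(validation.labels, predict_scores(model, validation))
    diffs = {
        m: abs(getattr(train_rep, m) - getattr(valid_rep, m)) for m in ALL_METRICS
    }
    return FinalEvaluation(train_rep, valid_rep, diffs)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled sd."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled_var = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled_var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class PermutationResult:
    """Y-scrambling outcome: real vs scrambled metric distributions and the
    per-metric Welch t, raw/BH-adjusted p, and Cohen's d."""

    real: pd.DataFrame = field(repr=False)       # iteration x metric
    scrambled: pd.DataFrame = field(repr=False)  # scramble x metric
    tests: pd.DataFrame = field(repr=False)      # metric x (t, p, p_adj, cohens_d)
    n_scrambles: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)


def _scrambled_profile_set(train: ProfileSet, rng: np.random.Generator) -> ProfileSet:
    scrambled = train.copy()
    y = scrambled.metadata["dili_label"].to_numpy(dtype=int)
    scrambled.metadata["dili_label"] = rng.permutation(y)  # features untouched
    return scrambled


def y_scramble_test(train: ProfileSet, best_config: ClassifierConfig,
                    n_scrambles: int = 100, seed: int = 0,
                    real_reports: list[MetricsReport] | None = None,
                    n_real_iter: int = 100,
                    inner_train_fraction: float = 0.8) -> PermutationResult:
    """Permutation (Y-scrambling) significance test of a configuration.

    Labels are permuted ``n_scrambles`` times; each pseudo training set gets
    one stratified inner fit-and-score.  The scrambled metric distribution is
    compared to the real-data MCCV distribution (supplied or computed here).
    """
    if real_reports is None:
        real_reports = mccv(train, best_config, n_real_iter,
                            inner_train_fraction, seed).reports
    rng = np.random.default_rng(seed + 1)
    seeds = _child_seeds(seed + 2, n_scrambles)
    scrambled_reports: list[MetricsReport] = []
    failures: list[tuple[int, str]] = []
    for i, s in enumerate(seeds):
        pseudo = _scrambled_profile_set(train, rng)
        try:
            scrambled_reports.append(
                _fit_score_split(best_config, pseudo, inner_train_fraction, int(s))
            )
        except TrainingError as exc:
            logger.warning("scramble %d failed: %s", i, exc)
            failures.append((i, str(exc)))

    real_df = reports_frame(real_reports)[list(ALL_METRICS)]
    scr_df = reports_frame(scrambled_reports)[list(ALL_METRICS)]
    rows = {}
    pvals = []
    for m in METRIC_NAMES:
        t, p = stats.ttest_ind(real_df[m], scr_df[m], equal_var=False)
        rows[m] = {"t": float(t), "p": float(p),
                   "cohens_d": cohens_d(real_df[m], scr_df[m])}
        pvals.append(float(p))
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    tests = pd.DataFrame(rows).T
    tests["p_adj"] = p_adj
    return PermutationResult(real=real_df, scrambled=scr_df,
                             tests=tests[["t", "p", "p_adj", "cohens_d"]],
                             n_scrambles=len(scrambled_reports), failures=failures)


@dataclass
class RobustnessSummary:
    """Per-rep validation reports and their mean/sd summary."""

    reports: list[MetricsReport]
    summary: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = summarize_reports(self.reports)


def robustness_balanced(profiles: ProfileSet, best_config: ClassifierConfig,
                        reps: int = 50, train_fraction: float = 0.8,
                        seed: int = 0) -> RobustnessSummary:
    """Downsample to class balance, split 80/20, fit, validate; repeat."""
    seeds = _child_seeds(seed, reps)
    reports = []
    for s in seeds:
        balanced = balanced_downsample(profiles, int(s))
        plan = stratified_split_profiles(balanced, train_fraction, int(s) + 1)
        ev = final_evaluate(with_seed(best_config, int(s)),
                            balanced.subset(plan.train_ids),
                            balanced.subset(plan.validation_ids))
        reports.append(ev.validation_report)
    return RobustnessSummary(reports)


def robustness_drug_split(profiles: ProfileSet, best_config: ClassifierConfig,
                          reps: int = 50, train_fraction: float = 0.8,
                          seed: int = 0) -> RobustnessSummary:
    """Drug-held-out evaluation: split by drugs so no drug spans both sides,
    fit on the training drugs' profiles, validate on held-out drugs; repeat."""
    seeds = _child_seeds(seed, reps)
    reports = []
    for s in seeds:
        plan = stratified_split_drugs(profiles, train_fraction, int(s))
        shared = drug_overlap(plan, profiles)
        if shared:  # hard failure: the whole point is zero leakage
            raise LeakageError(f"drugs on both sides of the split: {sorted(shared)[:5]}")
        ev = final_evaluate(with_seed(best_config, int(s)),
                            profiles.subset(plan.train_ids),
                            profiles.subset(plan.validation_ids))
        reports.append(ev.validation_report)
    return RobustnessSummary(reports)
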