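"""Method-comparison statistics for paired cadence measurements.

Implements the device-validation analysis for a criterion/test device pair:

* **Equivalence by CI containment** (dual to two one-sided t tests, TOST):
  the devices are declared equivalent when the two-sided ``1 − 2α``
  confidence interval for the mean difference (criterion − test) is strictly
  contained in ``(−margin, +margin)``; the default margin of ±1.5 RPM is 3 %
  of a 50 RPM self-selected pace.  Trial-level data use a paired t; pooled
  minute-level data use a random-intercept (per-subject) mixed model fitted
  by REML.
* **Error metrics**: mean absolute percent error
  ``MAPE = mean(|criterion − test| / criterion) × 100``, the percentage of
  pairs with absolute error strictly under 1/3/5 RPM, and Pearson r.
* **Bland–Altman agreement**: bias and 95 % limits of agreement
  ``bias ± 1.96·SD``.  With several minutes per subject the differences are
  *linked replicates* — the underlying cadence varies within a subject — so
  the SD combines within- and between-subject variance components from a
  one-way method-of-moments ANOVA on the differences (unbalanced group sizes
  handled via the usual m₀ divisor; a negative between estimate truncates to
  zero).  Proportional bias is checked by regressing the difference on the
  pair mean.

``build_report`` chains the aggregation pipeline and all of the above into
one report per resolution (minute, trial).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import (
    PairedSeries,
    align,
    events_to_seconds,
    minutes_to_trial,
    seconds_to_minutes,
)
from .config import RunConfig
from .events import EventStream

logger = logging.getLogger(__name__)

PairsLike = PairedSeries | Sequence[PairedSeries] | pd.DataFrame


@dataclass(frozen=True)
class EquivalenceResult:
    """Mean difference, its CI, and the containment verdict."""

    mean_difference: float
    se: float
    ci_low: float
    ci_high: float
    margin: float
    alpha_one_sided: float
    equivalent: bool
    method: str  # paired_t | random_intercept
    df: float
    n: int


@dataclass(frozen=True)
class ErrorMetrics:
    """MAPE, within-threshold percentages, and Pearson correlation.

    ``pearson_r`` is NaN when either device shows zero variance (the
    correlation is undefined, not zero).
    """

    mape: float
    mape_se: float
    pct_within: dict[float, float]
    pearson_r: float

    @property
    def pct_within_1(self) -> float:
        return self.pct_within[1.0]

    @property
    def pct_within_3(self) -> float:
        return self.pct_within[3.0]

    @property
    def pct_within_5(self) -> float:
        return self.pct_within[5.0]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, limits of agreement, variance components, proportional-bias test."""

    bias: float
    sd_difference: float
    loa_low: float
    loa_high: float
    variance_within: float
    variance_between: float
    slope: float
    slope_p: float
    mode: str  # simple | linked_replicates
    n_subjects: int
    n_pairs: int


@dataclass(frozen=True)
class AgreementReport:
    """Everything the validation tables report, for one resolution."""

    resolution: str
    n_subjects: int
    n_pairs: int
    criterion_mean: float
    criterion_se: float
    test_mean: float
    test_se: float
    equivalence: EquivalenceResult
    errors: ErrorMetrics
    bland_altman: BlandAltmanResult

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj


def to_frame(pairs: PairsLike) -> pd.DataFrame:
    """Pool paired series into a tidy frame (subject_id, time, criterion, test)."""
    if isinstance(pairs, pd.DataFrame):
        return pairs
    if isinstance(pairs, PairedSeries):
        pairs = [pairs]
    frames = [
        pd.DataFrame(
            {
                "subject_id": p.subject_id,
                "time": p.times,
                "criterion": p.criterion,
                "test": p.test,
            }
        )
        for p in pairs
    ]
    if not frames:
        return pd.DataFrame(columns=["subject_id", "time", "criterion", "test"])
    return pd.concat(frames, ignore_index=True)


def differences(pairs: PairsLike) -> pd.DataFrame:
    """Per-pair differences, criterion − test, with subject labels retained."""
    df = to_frame(pairs).copy()
    if df.empty:
        raise ValueError("no pairs: cannot compute differences")
    df["diff"] = df["criterion"] - df["test"]
    return df


def equivalence_t(
    d: np.ndarray,
    margin: float = 1.5,
    alpha: float = 0.025,
    df: float | None = None,
    method: str = "paired_t",
) -> EquivalenceResult:
    """CI-containment equivalence verdict from raw differences.

    The two-sided ``1 − 2α`` t interval must fall strictly inside
    ``(−margin, +margin)``; an endpoint exactly on the margin fails.
    ``df`` defaults to ``len(d) − 1``.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 differences for a t interval")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(n))
    dof = float(n - 1 if df is None else df)
    tcrit = float(stats.t.ppf(1.0 - alpha, dof))
    ci_low, ci_high = mean - tcrit * se, mean + tcrit * se
    return EquivalenceResult(
        mean_difference=mean,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        margin=margin,
        alpha_one_sided=alpha,
        equivalent=bool(ci_low > -margin and ci_high < margin),
        method=method,
        df=dof,
        n=n,
    )


def equivalence_paired_t(
    pairs: PairsLike, margin: float = 1.5, alpha: float = 0.025
) -> EquivalenceResult:
    """Trial-level equivalence: paired t on one difference per subject."""
    df = differences(pairs)
    if df["subject_id"].duplicated().any():
        raise ValueError(
            "paired t expects one pair per subject; "
            "use equivalence_random_intercept for replicated data"
        )
    return equivalence_t(df["diff"].to_numpy(), margin, alpha, method="paired_t")


def equivalence_random_intercept(
    pairs: PairsLike, margin: float = 1.5, alpha: float = 0.025
) -> EquivalenceResult:
    """Minute-level equivalence from a random-intercept mixed model (REML).

    The minute differences d_ij = μ + b_i + e_ij share a per-subject random
    intercept b_i; μ̂ and its SE come from the REML fit.  The CI uses a t
    distribution on ``n_subjects − 1`` degrees of freedom (conservative).
    In a balanced design this reproduces the t interval on subject means.
    """
    df = differences(pairs)
    groups = df["subject_id"].to_numpy()
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError(
            "random-intercept model needs ≥2 subjects; use equivalence_paired_t"
        )
    d = df["diff"].to_numpy(dtype=float)
    dof = n_subjects - 1
    if np.ptp(d) == 0.0:  # all differences identical: model is degenerate
        mean, se = float(d[0]), 0.0
    else:
        mean, se = _fit_random_intercept(d, groups)
    tcrit = float(stats.t.ppf(1.0 - alpha, dof))
    ci_low, ci_high = mean - tcrit * se, mean + tcrit * se
    return EquivalenceResult(
        mean_difference=mean,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        margin=margin,
        alpha_one_sided=alpha,
        equivalent=bool(ci_low > -margin and ci_high < margin),
        method="random_intercept",
        df=float(dof),
        n=int(d.size),
    )


def _fit_random_intercept(d: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    # Balanced designs admit the exact REML solution in closed form (the
    # interior optimum): μ̂ is the grand mean and Var(μ̂) = MSB/(m·n).  Use it
    # when applicable; otherwise fit iteratively.
    s = pd.Series(d).groupby(pd.Series(groups))
    sizes = s.size().to_numpy()
    if np.all(sizes == sizes[0]) and sizes[0] > 1:
        means = s.mean().to_numpy()
        n, m = means.size, int(sizes[0])
        msb = m * means.var(ddof=1)
        msw = float(sum(((x - x.mean()) ** 2).sum() for _, x in s)) / (n * (m - 1))
        if msb >= msw:  # variance estimate interior, closed form is the optimum
            return float(means.mean()), float(math.sqrt(msb / (m * n)))
    import statsmodels.api as sm

    exog = np.ones((d.size, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(d, exog, groups=groups).fit(reml=True)
        mean, se = float(res.fe_params[0]), float(res.bse_fe[0])
        if math.isfinite(mean) and math.isfinite(se):
            return mean, se
    except Exception:
        pass
    # near-singular / boundary fits: fall back to the subject-means t estimator
    logger.warning("mixed-model fit degenerate; using subject-mean t approximation")
    means = pd.Series(d).groupby(pd.Series(groups)).mean().to_numpy()
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(means.size))


def error_metrics(
    pairs: PairsLike, thresholds: Sequence[float] = (1.0, 3.0, 5.0)
) -> ErrorMetrics:
    """MAPE ± SE, %-within-threshold (strict |error| < k), and Pearson r."""
    df = differences(pairs)
    c = df["criterion"].to_numpy(dtype=float)
    t = df["test"].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("criterion values must be positive for percent error")
    ape = np.abs(df["diff"].to_numpy()) / c * 100.0
    n = ape.size
    mape = float(ape.mean())
    mape_se = float(ape.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    pct = {
        float(k): float(100.0 * np.mean(np.abs(df["diff"].to_numpy()) < k))
        for k in thresholds
    }
    if n > 1 and c.std() > 0 and t.std() > 0:
        r = float(stats.pearsonr(c, t).statistic)
    else:
        r = float("nan")
    return ErrorMetrics(mape=mape, mape_se=mape_se, pct_within=pct, pearson_r=r)


def bland_altman(
    pairs: PairsLike,
    mode: str = "simple",
    bias_mode: str = "grand",
    cluster_robust_slope: bool = False,
) -> BlandAltmanResult:
    """Bias and 95 % limits of agreement, optionally for linked replicates.

    ``mode="simple"``: SD is the plain sample SD of the differences (one
    pair per subject).  ``mode="linked_replicates"``: differences grouped by
    subject feed a one-way ANOVA; ``σ²_w = MSW`` and
    ``σ²_b = max(0, (MSB − MSW)/m₀)`` with ``m₀ = (N − Σm_i²/N)/(n − 1)``,
    and ``SD = √(σ²_b + σ²_w)``.  Limits are ``bias ± 1.96·SD``.

    The bias line is the grand mean of all differences by default
    (``bias_mode="subject_means"`` weights subjects equally instead).  The
    proportional-bias slope comes from ordinary least squares of difference
    on pair mean; ``cluster_robust_slope=True`` swaps in cluster-robust
    (by subject) standard errors for its p value.
    """
    if mode not in ("simple", "linked_replicates"):
        raise ValueError(f"unknown mode {mode!r}")
    df = differences(pairs)
    d = df["diff"].to_numpy(dtype=float)
    pair_mean = ((df["criterion"] + df["test"]) / 2.0).to_numpy(dtype=float)
    n_pairs = d.size
    n_subjects = int(df["subject_id"].nunique())

    if bias_mode == "grand":
        bias = float(d.mean())
    elif bias_mode == "subject_means":
        bias = float(df.groupby("subject_id")["diff"].mean().mean())
    else:
        raise ValueError(f"unknown bias_mode {bias_mode!r}")

    if mode == "simple":
        var_w = float(np.var(d, ddof=1)) if n_pairs > 1 else 0.0
        var_b = 0.0
        sd = math.sqrt(var_w)
    else:
        if n_subjects < 2:
            raise ValueError("linked_replicates mode needs ≥2 subjects")
        g = df.groupby("subject_id")["diff"]
        m_i = g.size().to_numpy(dtype=float)
        means_i = g.mean().to_numpy(dtype=float)
        N = float(m_i.sum())
        grand = float(d.mean())
        ssw = float(sum(((x - x.mean()) ** 2).sum() for _, x in g))
        msw = ssw / (N - n_subjects)
        ssb = float((m_i * (means_i - grand) ** 2).sum())
        msb = ssb / (n_subjects - 1)
        m0 = (N - (m_i**2).sum() / N) / (n_subjects - 1)
        var_w = msw
        var_b = max(0.0, (msb - msw) / m0)
        sd = math.sqrt(var_b + var_w)

    if n_pairs > 1 and np.ptp(pair_mean) > 0:
        slope, slope_p = _slope_test(
            pair_mean, d, df["subject_id"].to_numpy(), cluster_robust_slope
        )
    else:
        slope, slope_p = float("nan"), float("nan")

    return BlandAltmanResult(
        bias=bias,
        sd_difference=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        variance_within=var_w,
        variance_between=var_b,
        slope=slope,
        slope_p=slope_p,
        mode=mode,
        n_subjects=n_subjects,
        n_pairs=n_pairs,
    )


def _slope_test(
    x: np.ndarray, y: np.ndarray, groups: np.ndarray, cluster_robust: bool
) -> tuple[float, float]:
    if not cluster_robust:
        fit = stats.linregress(x, y)
        return float(fit.slope), float(fit.pvalue)
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return float(res.params[1]), float(res.pvalues[1])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _by_subject(streams: EventStream | Iterable[EventStream]) -> dict[str, EventStream]:
    if isinstance(streams, EventStream):
        streams = [streams]
    out: dict[str, EventStream] = {}
    for s in streams:
        if s.subject_id in out:
            raise ValueError(f"duplicate stream for subject {s.subject_id}")
        out[s.subject_id] = s
    return out


def build_report(
    criterion: EventStream | Iterable[EventStream],
    test: EventStream | Iterable[EventStream],
    config: RunConfig | None = None,
) -> dict[str, AgreementReport]:
    """Aggregate, align, and analyse two device stream collections.

    Returns one :class:`AgreementReport` per resolution (``"minute"`` and
    ``"trial"``).  Trial values are means of each subject's aligned minutes,
    so the trial rows summarize exactly the minutes the two devices share.
    """
    cfg = config or RunConfig()
    crit, tst = _by_subject(criterion), _by_subject(test)
    subjects = sorted(set(crit) & set(tst))
    if not subjects:
        raise ValueError("criterion and test share no subjects")

    minute_pairs: list[PairedSeries] = []
    trial_rows: list[tuple[str, float, float]] = []
    for subj in subjects:
        sec_c = events_to_seconds(crit[subj], cfg.gap_seconds)
        sec_t = events_to_seconds(tst[subj], cfg.gap_seconds)
        min_c = seconds_to_minutes(sec_c, cfg.min_coverage)
        min_t = seconds_to_minutes(sec_t, cfg.min_coverage)
        if len(min_c) == 0 or len(min_t) == 0:
            logger.warning("subject %s: no usable minutes; skipped", subj)
            continue
        paired = align(min_c, min_t)
        if len(paired) == 0:
            logger.warning("subject %s: no aligned minutes; skipped", subj)
            continue
        minute_pairs.append(paired)
        trial_rows.append(
            (subj, float(paired.criterion.mean()), float(paired.test.mean()))
        )
    if not minute_pairs:
        raise ValueError("no aligned pairs between criterion and test streams")

    reports: dict[str, AgreementReport] = {}

    minute_df = to_frame(minute_pairs)
    n_subj = len(trial_rows)
    if n_subj >= 2:
        eq_min = equivalence_random_intercept(minute_df, cfg.margin, cfg.alpha_one_sided)
    else:  # single subject: minutes are the only replication available
        eq_min = equivalence_t(
            (minute_df["criterion"] - minute_df["test"]).to_numpy(),
            cfg.margin,
            cfg.alpha_one_sided,
            method="paired_t",
        )
    ba_mode = "linked_replicates" if n_subj >= 2 else "simple"
    reports["minute"] = AgreementReport(
        resolution="minute",
        n_subjects=n_subj,
        n_pairs=len(minute_df),
        criterion_mean=float(minute_df["criterion"].mean()),
        criterion_se=_se(minute_df["criterion"].to_numpy()),
        test_mean=float(minute_df["test"].mean()),
        test_se=_se(minute_df["test"].to_numpy()),
        equivalence=eq_min,
        errors=error_metrics(minute_df, cfg.thresholds),
        bland_altman=bland_altman(
            minute_df, ba_mode, cfg.bias_mode, cfg.cluster_robust_slope
        ),
    )

    trial_df = pd.DataFrame(trial_rows, columns=["subject_id", "criterion", "test"])
    trial_df["time"] = 0
    if n_subj >= 2:
        eq_tr = equivalence_paired_t(trial_df, cfg.margin, cfg.alpha_one_sided)
    else:
        logger.warning("single subject: trial-level SE and verdict are undefined")
        d0 = float(trial_df["criterion"].iloc[0] - trial_df["test"].iloc[0])
        eq_tr = EquivalenceResult(
            d0, float("nan"), float("nan"), float("nan"),
            cfg.margin, cfg.alpha_one_sided, False, "paired_t", float("nan"), 1,
        )
    reports["trial"] = AgreementReport(
        resolution="trial",
        n_subjects=n_subj,
        n_pairs=len(trial_df),
        criterion_mean=float(trial_df["criterion"].mean()),
        criterion_se=_se(trial_df["criterion"].to_numpy()),
        test_mean=float(trial_df["test"].mean()),
        test_se=_se(trial_df["test"].to_numpy()),
        equivalence=eq_tr,
        errors=error_metrics(trial_df, cfg.thresholds),
        bland_altman=bland_altman(trial_df, "simple", cfg.bias_mode, False),
    )
    return reports


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")


def write_report_json(
    reports: Mapping[str, AgreementReport], path, config: RunConfig | None = None
) -> None:
    """Nested machine-readable report (NaN rendered as null)."""
    payload = {
        "config": (config or RunConfig()).model_dump(),
        "reports": {k: v.to_dict() for k, v in reports.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def write_report_csv(reports: Mapping[str, AgreementReport], path) -> None:
    """One row per resolution, mirroring the validation table columns."""
    rows = []
    for res, r in reports.items():
        rows.append(
            {
                "resolution": res,
                "n_subjects": r.n_subjects,
                "n_pairs": r.n_pairs,
                "criterion_mean": r.criterion_mean,
                "criterion_se": r.criterion_se,
                "test_mean": r.test_mean,
                "test_se": r.test_se,
                "mean_difference": r.equivalence.mean_difference,
                "diff_se": r.equivalence.se,
                "ci_low": r.equivalence.ci_low,
                "ci_high": r.equivalence.ci_high,
                "equivalent": r.equivalence.equivalent,
                "mape": r.errors.mape,
                "mape_se": r.errors.mape_se,
                **{
                    f"pct_within_{k:g}": v for k, v in r.errors.pct_within.items()
                },
                "pearson_r": r.errors.pearson_r,
                "bias": r.bland_altman.bias,
                "loa_low": r.bland_altman.loa_low,
                "loa_high": r.bland_altman.loa_high,
                "slope": r.bland_altman.slope,
                "slope_p": r.bland_altman.slope_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
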