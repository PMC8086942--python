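"""Method-agreement and cohort statistics.

Mirrors the comparison machinery used for HFD method agreement and
per-quadrant mixing: paired and one-sample t-tests, Bland-Altman limits of
agreement, the intraclass correlation coefficient (two-way mixed effects,
single measure, absolute agreement — the standard choice when comparing a
fixed set of measurement methods), the mean absolute inter-method
difference with a 1.96 SEM interval, repeated-measures one-way ANOVA with
Tukey post hoc tests, and Pearson correlation.

Degenerate zero-variance inputs return flagged limit values instead of
raising so cohort loops never abort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Matched measurements of the same subjects under two conditions."""

    a: np.ndarray
    b: np.ndarray
    name_a: str = "method_a"
    name_b: str = "method_b"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired sample requires two equal-length 1-d vectors")
        if self.a.size < 2:
            raise ValueError("paired sample requires n >= 2")
        if np.any(~np.isfinite(self.a)) or np.any(~np.isfinite(self.b)):
            raise ValueError("paired sample must be complete (no missing pairs)")

    @property
    def diffs(self) -> np.ndarray:
        return self.a - self.b

    @property
    def n(self) -> int:
        return self.a.size


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Classical paired t-test on the differences; two-sided p."""
    d = sample.diffs
    if np.std(d, ddof=1) == 0:
        # degenerate: all differences identical
        p = 1.0 if d.mean() == 0 else 0.0
        log.warning("paired t on zero-variance differences; returning limit p=%g", p)
        return (0.0 if d.mean() == 0 else np.inf * np.sign(d.mean()), p)
    t, p = sps.ttest_rel(sample.a, sample.b)
    return float(t), float(p)


def one_sample_t(values, mu0: float = 0.9) -> tuple[float, float]:
    """Two-sided one-sample t-test of a mean against mu0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one-sample t requires n >= 2")
    if np.std(v, ddof=1) == 0:
        p = 1.0 if v.mean() == mu0 else 0.0
        log.warning("one-sample t on zero-variance data; returning limit p=%g", p)
        return (0.0 if v.mean() == mu0 else np.inf * np.sign(v.mean() - mu0), p)
    t, p = sps.ttest_1samp(v, mu0)
    return float(t), float(p)


@dataclass
class BlandAltman:
    mean_difference: float
    sd: float
    loa_lower: float
    loa_upper: float


def bland_altman(sample: PairedSample) -> BlandAltman:
    """Mean inter-method difference and 95% limits of agreement.

    LoA are the mean difference +/- 1.96 sample standard deviations of the
    differences (n - 1 denominator).
    """
    d = sample.diffs
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd)


def icc(sample: PairedSample) -> float:
    """Intraclass correlation: two-way mixed, single measure, absolute agreement.

    Computed with pingouin (ICC2 in the Shrout-Fleiss numbering).  NaN with
    a warning when the between-subject variance is zero.
    """
    if sample.n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    subj_means = (sample.a + sample.b) / 2
    if np.std(subj_means, ddof=1) == 0 and np.std(sample.diffs, ddof=1) == 0:
        log.warning("ICC undefined: no between-subject variance")
        return float("nan")
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(sample.n), 2),
            "rater": np.repeat([sample.name_a, sample.name_b], sample.n),
            "score": np.concatenate([sample.a, sample.b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    return _icc_row(table, ("ICC2", "ICC(A,1)"))


def icc_consistency(sample: PairedSample) -> float:
    """Consistency variant (ICC3): insensitive to a fixed offset between methods."""
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(sample.n), 2),
            "rater": np.repeat([sample.name_a, sample.name_b], sample.n),
            "score": np.concatenate([sample.a, sample.b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    return _icc_row(table, ("ICC3", "ICC(C,1)"))


def _icc_row(table: pd.DataFrame, aliases) -> float:
    # pingouin's Type labels changed across versions (ICC2 vs ICC(A,1))
    hit = table[table["Type"].isin(aliases)]
    if hit.empty:  # pragma: no cover
        raise RuntimeError(f"no ICC row matching {aliases} in pingouin output")
    return float(hit["ICC"].iloc[0])


def mean_absolute_difference(sample: PairedSample) -> tuple[float, tuple[float, float]]:
    """Mean of |differences| with a +/- 1.96 SEM interval.

    The SEM is that of the absolute differences, quantifying how much one
    method over- or underestimates the other in absolute terms.
    """
    ad = np.abs(sample.diffs)
    mad = float(ad.mean())
    sem = float(np.std(ad, ddof=1) / np.sqrt(ad.size))
    return mad, (mad - 1.96 * sem, mad + 1.96 * sem)


@dataclass
class RMAnovaResult:
    f: float
    df_condition: float
    df_error: float
    p: float
    ms_error: float
    tukey: pd.DataFrame  # condition_a, condition_b, mean_diff, q, p


def rm_anova_tukey(data, condition_names=None) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Tukey HSD post hoc tests.

    ``data`` is (n_subjects, k_conditions), complete.  Subjects enter as a
    blocking factor; the Tukey tests use the repeated-measures residual
    mean square and the studentized-range distribution, matching the
    conventional RM-ANOVA + Tukey workflow.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a complete (>=3 subjects) x (>=2 conditions) table")
    if np.any(~np.isfinite(x)):
        raise ValueError("repeated-measures table must be complete")
    n, k = x.shape
    if condition_names is None:
        condition_names = [f"cond{i + 1}" for i in range(k)]
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    tol = 1e-12 * max(float(ss_tot), 1e-30)
    if ss_cond < tol:
        ss_cond = 0.0
    if ss_err < tol:
        ss_err = 0.0
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else float("inf")
        p = 1.0 if ms_cond == 0 else 0.0
        log.warning("RM-ANOVA with zero residual variance; returning limit values")
    else:
        f = float(ms_cond / ms_err)
        p = float(sps.f.sf(f, df_cond, df_err))

    rows = []
    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = cond_means[i] - cond_means[j]
            if se > 0:
                q = abs(diff) / se
                p_ij = float(sps.studentized_range.sf(q, k, df_err))
            else:
                q = 0.0 if diff == 0 else float("inf")
                p_ij = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "condition_a": condition_names[i],
                    "condition_b": condition_names[j],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p": p_ij,
                }
            )
    return RMAnovaResult(f=f, df_condition=df_cond, df_error=df_err, p=p, ms_error=float(ms_err), tukey=pd.DataFrame(rows))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("Pearson correlation requires matched vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("Pearson correlation undefined for zero-variance input")
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AgreementReport:
    """Pairwise agreement between two HFD quantification methods."""

    comparison: str
    p_value: float
    mean_difference: float
    loa_lower: float
    loa_upper: float
    icc: float
    mad: float
    mad_lower: float
    mad_upper: float

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "icc": self.icc,
            "mad": self.mad,
            "mad_lower": self.mad_lower,
            "mad_upper": self.mad_upper,
        }


def agreement_report(sample: PairedSample) -> AgreementReport:
    """Full pairwise agreement panel for one method pair."""
    _, p = paired_t(sample)
    ba = bland_altman(sample)
    mad, (lo, hi) = mean_absolute_difference(sample)
    return AgreementReport(
        comparison=f"{sample.name_a} vs {sample.name_b}",
        p_value=p,
        mean_difference=ba.mean_difference,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        icc=icc(sample),
        mad=mad,
        mad_lower=lo,
        mad_upper=hi,
    )


def method_comparison_table(hfd_wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise agreement rows for the three HFD methods.

    ``hfd_wide`` holds one row per patient with columns ``HV``,
    ``caudal_conduit`` and ``cranial_conduit`` (HFD in %).
    """
    pairs = [("HV", "caudal_conduit"), ("HV", "cranial_conduit"), ("caudal_conduit", "cranial_conduit")]
    rows = []
    for na, nb in pairs:
        sample = PairedSample(hfd_wide[na].to_numpy(), hfd_wide[nb].to_numpy(), na, nb)
        rows.append(agreement_report(sample).as_row())
    return pd.DataFrame(rows)


def bland_altman_plot(sample: PairedSample, path) -> None:
    """Write a Bland-Altman plot for one method pair (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(sample)
    means = (sample.a + sample.b) / 2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, sample.diffs, s=18)
    for yv, style in ((ba.mean_difference, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {sample.name_a} and {sample.name_b} (%)")
    ax.set_ylabel(f"{sample.name_a} - {sample.name_b} (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
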