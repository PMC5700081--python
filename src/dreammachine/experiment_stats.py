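"""Bayes-factor t-tests and the questionnaire / timing analyses.

The centrepiece is the JZS (Jeffreys–Zellner–Siow) default Bayes factor for
a t-test: a Cauchy(0, r) prior on the standardized effect delta (default
half-width r = sqrt(1/2) ~ 0.707), evaluated as a scale-mixture-of-normals
integral by adaptive quadrature in log space.  BF10 > 3 is read as evidence
for a difference, BF10 < 1/3 as evidence for no difference, anything between
as insensitive.  Effect sizes follow the t-to-d identities (d = t / sqrt(n)
paired; d = t * sqrt(1/n1 + 1/n2) for pooled independent groups), so the
whole analysis can be reproduced from published (t, n) summaries alone.

Also here: Bonferroni correction, the classical two-way repeated-measures
ANOVA used for the temporal-production task, and the screening rules for
that task (practice-block correlation criterion; exclusion of temporally
inverted producers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .fixtures import ASCQ_DIMENSIONS

__all__ = [
    "BFConfig",
    "TTestResult",
    "AnovaResult",
    "jzs_bf10",
    "cohens_d_paired",
    "cohens_d_independent",
    "paired_ttest",
    "independent_ttest",
    "summary_ttest",
    "bonferroni",
    "interpret_bf",
    "rm_anova_2way",
    "practice_criterion",
    "inversion_exclusion",
    "ascq_compare",
]


@dataclass(frozen=True)
class BFConfig:
    """Cauchy prior scale on the standardized effect (JASP default 0.707)."""

    prior_scale: float = math.sqrt(0.5)

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    cohens_d: float
    bf10: float
    design: str  # "paired(n)" or "independent(n1, n2)"

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def jzs_bf10(t: float, df: float, n_eff: float, config: BFConfig = BFConfig()) -> float:
    """JZS default Bayes factor BF10 for an observed t statistic.

    ``n_eff`` is the effective sample size multiplying the squared effect in
    the noncentrality: n for a paired design, n1*n2/(n1+n2) for independent
    groups.  Under H1 the standardized effect has a Cauchy(0, r) prior,
    written as delta | g ~ N(0, g r^2) with g ~ InverseGamma(1/2, 1/2); the
    marginal likelihood is then a one-dimensional integral over g, evaluated
    on (0, 1) after the substitution g = u / (1 - u) with the integrand kept
    in log space.  The null marginal is the central Student density, so BF10
    depends on the data only through t.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if n_eff <= 0:
        raise ValueError("n_eff must be > 0")
    r = config.prior_scale
    t = float(t)

    def log_integrand(g: float) -> float:
        c = 1.0 + n_eff * g * r * r
        log_lik = -0.5 * math.log(c) - 0.5 * (df + 1) * math.log1p(t * t / (df * c))
        # InverseGamma(1/2, 1/2) density
        log_prior = -0.5 * math.log(2 * math.pi) - 1.5 * math.log(g) - 1.0 / (2 * g)
        return log_lik + log_prior

    # shift by the null log-likelihood so the integral directly yields BF10
    log_null = -0.5 * (df + 1) * math.log1p(t * t / df)

    def f(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        g = u / (1.0 - u)
        return math.exp(log_integrand(g) - log_null) / (1.0 - u) ** 2

    bf, err = integrate.quad(f, 0.0, 1.0, limit=200, epsabs=0.0, epsrel=1e-8)
    if not math.isfinite(bf) or bf <= 0 or (err > 1e-4 * bf):
        raise ArithmeticError(
            f"Bayes-factor quadrature did not converge: value={bf}, abs err={err}"
        )
    return bf


def interpret_bf(bf10: float) -> Literal["supports_H1", "supports_H0", "insensitive"]:
    """Evidence thresholds: > 3 supports a difference, < 1/3 supports none."""
    if bf10 <= 0:
        raise ValueError("bf10 must be > 0")
    if bf10 > 3.0:
        return "supports_H1"
    if bf10 < 1.0 / 3.0:
        return "supports_H0"
    return "insensitive"


# ---------------------------------------------------------------------------
# Effect sizes and t-tests
# ---------------------------------------------------------------------------

def cohens_d_paired(t: float, n: int) -> float:
    """d = t / sqrt(n) for a paired design."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t) / math.sqrt(n)


def cohens_d_independent(t: float, n1: int, n2: int) -> float:
    """d = t * sqrt(1/n1 + 1/n2) for pooled independent groups."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t) * math.sqrt(1.0 / n1 + 1.0 / n2)


def paired_ttest(
    x: Sequence[float], y: Sequence[float], config: BFConfig = BFConfig()
) -> TTestResult:
    """Two-tailed paired t-test with Cohen's d and JZS BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0 and d.mean() != 0:
        raise ZeroDivisionError("zero variance of differences with nonzero mean")
    if sd == 0:
        t = 0.0
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        t=t, df=df, p_two_tailed=float(p),
        cohens_d=cohens_d_paired(t, n),
        bf10=jzs_bf10(t, df, n, config),
        design=f"paired({n})",
    )


def independent_ttest(
    x: Sequence[float], y: Sequence[float], config: BFConfig = BFConfig()
) -> TTestResult:
    """Two-tailed pooled (equal-variance) independent-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = x.size, y.size
    res = stats.ttest_ind(x, y, equal_var=True)
    t = float(res.statistic)
    if not math.isfinite(t):
        raise ZeroDivisionError("zero pooled variance")
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    return TTestResult(
        t=t, df=df, p_two_tailed=float(res.pvalue),
        cohens_d=cohens_d_independent(t, n1, n2),
        bf10=jzs_bf10(t, df, n_eff, config),
        design=f"independent({n1}, {n2})",
    )


def summary_ttest(
    t: float,
    n: int | tuple[int, int],
    design: Literal["paired", "independent"],
    config: BFConfig = BFConfig(),
) -> TTestResult:
    """Recompute p, d and BF10 from a published (t, n) summary alone."""
    if design == "paired":
        if not isinstance(n, int):
            raise ValueError("paired design takes a single n")
        df = n - 1
        n_eff = float(n)
        d = cohens_d_paired(t, n)
        desc = f"paired({n})"
    elif design == "independent":
        n1, n2 = n  # type: ignore[misc]
        df = n1 + n2 - 2
        n_eff = n1 * n2 / (n1 + n2)
        d = cohens_d_independent(t, n1, n2)
        desc = f"independent({n1}, {n2})"
    else:
        raise ValueError(f"unknown design {design!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=df, p_two_tailed=float(p), cohens_d=d,
        bf10=jzs_bf10(t, df, n_eff, config), design=desc,
    )


def bonferroni(
    p_values: Sequence[float], m: int | None = None, cap: bool = True
) -> np.ndarray:
    """Bonferroni adjustment p * m, capped at 1 unless ``cap`` is False
    (published tables sometimes print the uncapped product)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = p * m
    return np.minimum(adj, 1.0) if cap else adj


# ---------------------------------------------------------------------------
# Two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: int
    ss_error: float
    df_error: int
    F: float
    p: float
    eta_sq_partial: float
    eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]
    ss_total: float
    ss_subjects: float

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def rm_anova_2way(
    table: pd.DataFrame,
    dv: str = "produced_s",
    within: tuple[str, str] = ("target_s", "video_type"),
    subject: str = "subject",
) -> AnovaResult:
    """Classical two-factor fully-within-subject ANOVA on cell means.

    Each subject x A-level x B-level cell is averaged first (one value per
    cell; missing cells are an error, no imputation).  Sums of squares follow
    the standard within-subject decomposition with a separate subject-by-
    effect error stratum per effect; partial eta^2 = SS_effect /
    (SS_effect + SS_error_stratum), with classical eta^2 (over total SS)
    reported alongside.
    """
    fa, fb = within
    cells = table.groupby([subject, fa, fb], sort=True)[dv].mean()
    subjects = cells.index.get_level_values(0).unique()
    a_levels = cells.index.get_level_values(1).unique()
    b_levels = cells.index.get_level_values(2).unique()
    s, a, b = len(subjects), len(a_levels), len(b_levels)
    if len(cells) != s * a * b:
        raise ValueError(
            f"unbalanced design: {len(cells)} cells, expected {s}*{a}*{b}"
        )
    y = cells.to_numpy().reshape(s, a, b)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_total = float(np.sum((y - grand) ** 2))
    ss_subj = float(a * b * np.sum((m_s - grand) ** 2))
    ss_a = float(s * b * np.sum((m_a - grand) ** 2))
    ss_b = float(s * a * np.sum((m_b - grand) ** 2))
    ss_ab = float(s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2))
    ss_as = float(b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2))
    ss_bs = float(a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2))
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    def effect(name: str, ss: float, df: int, ss_err: float, df_err: int) -> AnovaEffect:
        if ss_err <= 0 or df_err <= 0:
            f_val, p = math.inf if ss > 0 else 0.0, 0.0
        else:
            f_val = (ss / df) / (ss_err / df_err)
            p = float(stats.f.sf(f_val, df, df_err))
        return AnovaEffect(
            name=name, ss=ss, df=df, ss_error=ss_err, df_error=df_err,
            F=float(f_val), p=p,
            eta_sq_partial=ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
            eta_sq=ss / ss_total if ss_total > 0 else 0.0,
        )

    effects = (
        effect(fa, ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        effect(fb, ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        effect(f"{fa}*{fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1)),
    )
    return AnovaResult(effects=effects, ss_total=ss_total, ss_subjects=ss_subj)


# ---------------------------------------------------------------------------
# Temporal-production screening rules
# ---------------------------------------------------------------------------

def practice_criterion(
    targets: Sequence[float], produced: Sequence[float]
) -> tuple[bool, str]:
    """Practice-block inclusion: Pearson r(target, produced) >= 0.5 passes."""
    targets = np.asarray(targets, dtype=float)
    produced = np.asarray(produced, dtype=float)
    if targets.size != produced.size or targets.size < 3:
        raise ValueError("need >= 3 matched trials")
    if np.std(produced) == 0 or np.std(targets) == 0:
        return False, "zero variance in produced or target intervals"
    r = float(np.corrcoef(targets, produced)[0, 1])
    return (r >= 0.5), f"r = {r:.3f}"


def inversion_exclusion(mean_produced_by_target: Sequence[float]) -> bool:
    """True (keep) iff the three per-target means are strictly increasing
    with target duration; ties count as inverted (conservative)."""
    m = np.asarray(mean_produced_by_target, dtype=float)
    if m.size != 3:
        raise ValueError("expected three per-target means")
    return bool(np.all(np.diff(m) > 0))


# ---------------------------------------------------------------------------
# Questionnaire comparison report
# ---------------------------------------------------------------------------

def ascq_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    design: Literal["paired", "independent"],
    config: BFConfig = BFConfig(),
    bonferroni_m: int | None = None,
    dimensions: Sequence[str] = ASCQ_DIMENSIONS,
) -> pd.DataFrame:
    """Per-dimension t-test report mirroring the published table layout.

    ``table_a`` / ``table_b`` are long-format (subject, condition, dimension,
    rating) slices for the two conditions being compared; paired designs
    match subjects across tables.  Output columns: dimension, bf10, t, df,
    p, p_bonferroni, cohens_d, interpretation.
    """
    if bonferroni_m is None:
        bonferroni_m = len(dimensions)
    rows = []
    for dim in dimensions:
        xa = table_a[table_a["dimension"] == dim].sort_values("subject")["rating"].to_numpy()
        xb = table_b[table_b["dimension"] == dim].sort_values("subject")["rating"].to_numpy()
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"dimension {dim!r} missing from a table")
        if design == "paired":
            res = paired_ttest(xa, xb, config)
        else:
            res = independent_ttest(xa, xb, config)
        rows.append(
            {
                "dimension": dim,
                "bf10": res.bf10,
                "t": res.t,
                "df": res.df,
                "p": res.p_two_tailed,
                "cohens_d": res.cohens_d,
                "interpretation": interpret_bf(res.bf10),
            }
        )
    report = pd.DataFrame(rows)
    report.insert(5, "p_bonferroni", bonferroni(report["p"].to_numpy(), bonferroni_m))
    return report
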