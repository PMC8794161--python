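"""Replication-evaluation metrics for correlations.

Given an original and a replication study summarized as ``(r, n, k)`` —
correlation, sample size, number of partialled covariates — this module
implements the battery of replication statistics used to judge whether a
small crossover-tDCS correlation replicated:

* :func:`sesoi_r33` — the "small telescopes" smallest effect size of
  interest: the correlation the original study had 33% power to detect.
* :func:`inferiority_test` — one-sided test that the replication correlation
  is significantly less negative than the negated SESOI (equivalence-style
  inferiority test on the Fisher-z scale).
* :func:`prediction_interval` — the range of correlations a replication of
  the original study should produce under sampling error alone.
* :func:`likelihood_r` / :func:`replication_bf` — the exact sampling density
  of the Pearson correlation and the replication Bayes factor BF_0r that
  contrasts a skeptic's null (rho = 0) with a proponent's prior equal to the
  original study's posterior.
* :func:`meta_fixed` — fixed-effects inverse-variance meta-analysis in
  Fisher-z space.
* :func:`pooled_analysis` — re-estimates the partial correlation on the
  concatenated trial-level data of several studies.
* :func:`full_report` — runs the whole battery and returns a
  :class:`ReplicationReport`.

Effective-sample-size convention: wherever a study adjusted for k covariates,
Fisher-z variances use ``1 / (n - 3 - k)`` and the exact r-density uses
``n_eff = n - k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .correlation import (
    CorrelationEstimate,
    correlation_ci,
    estimate_from_summary,
    fisher_z,
    inv_fisher,
    partial_correlation,
)
from .pipeline import ab_change_scores, cell_accuracy, harmonize_lags

__all__ = [
    "StudySummary",
    "ReplicationReport",
    "sesoi_r33",
    "inferiority_test",
    "prediction_interval",
    "log_likelihood_r",
    "likelihood_r",
    "replication_bf",
    "meta_fixed",
    "change_scores_correlation",
    "pooled_analysis",
    "full_report",
    "report_table",
    "forest_text",
]


@dataclass(frozen=True)
class StudySummary:
    """Summary-level input to the replication metrics."""

    label: str
    r: float
    n: int
    k: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"r = {self.r} outside (-1, 1)")
        if self.n - 3 - self.k < 1:
            raise ValueError(
                f"study {self.label!r}: need n - 3 - k >= 1 (n={self.n}, k={self.k})"
            )


@dataclass
class ReplicationReport:
    """Composite outcome of the replication battery."""

    orig: CorrelationEstimate
    rep: CorrelationEstimate
    sesoi_r33: float
    inferiority_p: float
    rep_ci90: tuple[float, float]
    pi_lo: float
    pi_hi: float
    pi_method: str
    bf_0r: float
    meta: CorrelationEstimate
    pooled: CorrelationEstimate | None = None
    notes: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# small telescopes SESOI and the inferiority test


def _power_fisher(zeta: float, nu: float, alpha: float) -> float:
    """Power of the two-sided level-alpha correlation test at Fisher-z effect
    ``zeta`` with effective df ``nu = n - 3 - k`` (normal approximation)."""
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    lam = zeta * np.sqrt(nu)
    return float(stats.norm.sf(z_crit - lam) + stats.norm.cdf(-z_crit - lam))


def sesoi_r33(
    n_orig: int, k: int = 0, alpha: float = 0.05, power: float = 1.0 / 3.0
) -> float:
    """Correlation the original study could detect with the given power.

    Solves ``power(r; n_orig, k, two-sided alpha) = power`` for r > 0 under
    the Fisher-z normal approximation, including the far-tail rejection
    region. With n = 34 and one covariate the 33%-power solution rounds to
    .27, the "small telescopes" bound.
    """
    nu = n_orig - 3 - k
    if nu < 1:
        raise ValueError(f"need n - 3 - k >= 1 (n={n_orig}, k={k})")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if power <= alpha or power >= 1.0:
        raise ValueError(
            f"target power must lie in (alpha, 1); got power={power}, alpha={alpha}"
        )

    def f(zeta: float) -> float:
        return _power_fisher(zeta, nu, alpha) - power

    zeta = optimize.brentq(f, 1e-12, 10.0, xtol=1e-14, rtol=1e-15)
    assert abs(f(zeta)) < 1e-8
    return float(np.tanh(zeta))


def inferiority_test(
    r_rep: float, n_rep: int, k: int = 0, sesoi: float = 0.27
) -> float:
    """One-sided p-value that ``r_rep`` is less negative than ``-sesoi``.

    The null hypothesis is that the replication correlation is at least as
    negative as the negated SESOI; the test statistic is the Fisher-z
    distance ``(arctanh(r_rep) - arctanh(-sesoi)) * sqrt(n - 3 - k)``.
    Equivalently, the test is significant at alpha when the
    ``1 - 2*alpha`` (e.g. 90%) CI around ``r_rep`` excludes ``-sesoi``.
    """
    if not 0.0 < sesoi < 1.0:
        raise ValueError(f"sesoi must be in (0, 1), got {sesoi}")
    nu = n_rep - 3 - k
    if nu < 1:
        raise ValueError(f"need n - 3 - k >= 1 (n={n_rep}, k={k})")
    z = (fisher_z(r_rep) - fisher_z(-sesoi)) * np.sqrt(nu)
    return float(stats.norm.sf(z))


# --------------------------------------------------------------------------
# prediction interval


def _sample_r_bvn(rho: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """One sample correlation of n bivariate-normal observations per rho."""
    m = rho.size
    out = np.empty(m)
    chunk = max(1, int(4e6) // n)
    for lo in range(0, m, chunk):
        rr = rho[lo : lo + chunk, None]
        x = rng.standard_normal((rr.size, n))
        y = rr * x + np.sqrt(1.0 - rr**2) * rng.standard_normal((rr.size, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        out[lo : lo + chunk] = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
    return out


def prediction_interval(
    r_orig: float,
    n_orig: int,
    n_rep: int,
    level: float = 0.95,
    method: str = "fisher",
    n_draws: int = 200_000,
    seed: int | None = 2026,
) -> tuple[float, float]:
    """Interval expected to contain a replication's correlation.

    method="fisher"
        Closed form on the Fisher-z scale: the replication estimate differs
        from the original by sampling error of both studies, so
        ``arctanh(r_orig) +/- z_crit * sqrt(1/(n_orig-3) + 1/(n_rep-3))``
        back-transformed.
    method="simulation"
        Propagates the original's uncertainty (Fisher-z normal posterior
        draw), then simulates a replication sample correlation from the
        exact finite-sample distribution at that population value;
        returns empirical quantiles over ``n_draws`` seeded draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_orig <= 3 or n_rep <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if method == "fisher":
        z_crit = stats.norm.ppf(0.5 + level / 2.0)
        half = z_crit * np.sqrt(1.0 / (n_orig - 3) + 1.0 / (n_rep - 3))
        z0 = fisher_z(r_orig)
        return inv_fisher(z0 - half), inv_fisher(z0 + half)
    if method == "simulation":
        rng = np.random.default_rng(seed)
        z_star = rng.normal(fisher_z(r_orig), 1.0 / np.sqrt(n_orig - 3), n_draws)
        r_rep = _sample_r_bvn(np.tanh(z_star), n_rep, rng)
        lo, hi = np.quantile(r_rep, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# exact sampling density of Pearson r and the replication Bayes factor


def log_likelihood_r(r, rho, n) -> np.ndarray | float:
    """Log of the exact sampling density of the Pearson correlation.

    For n bivariate-normal observations with population correlation rho the
    density of the sample correlation r is, in Gaussian-hypergeometric form,

        f(r | rho, n) = (n-2) Gamma(n-1) / (sqrt(2 pi) Gamma(n-1/2))
                        * (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
                        * (1-rho*r)^(-(n-3/2))
                        * 2F1(1/2, 1/2; n-1/2; (rho*r+1)/2).

    Evaluated in log space; broadcasts over ``r`` and ``rho``. ``n`` may be
    non-integer (effective sample sizes after covariate adjustment).
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1.0) or np.any(np.abs(rho) >= 1.0):
        raise ValueError("likelihood_r requires |r| < 1 and |rho| < 1")
    if np.any(np.asarray(n) < 4):
        raise ValueError("likelihood_r requires n >= 4")
    out = (
        np.log(n - 2.0)
        + special.gammaln(n - 1.0)
        - 0.5 * np.log(2.0 * np.pi)
        - special.gammaln(n - 0.5)
        + (n - 1.0) / 2.0 * np.log1p(-(rho**2))
        + (n - 4.0) / 2.0 * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    )
    return float(out) if np.ndim(out) == 0 else out


def likelihood_r(r, rho, n):
    """Exact sampling density of Pearson r (integrates to 1 over (-1, 1))."""
    return np.exp(log_likelihood_r(r, rho, n))


def _posterior_breakpoints(r_mode: float, n: float) -> list[float]:
    # quadrature hints around the posterior spike for large n
    sd = (1.0 - r_mode**2) / np.sqrt(max(n - 3.0, 1.0))
    pts = [r_mode + f * sd for f in (-10, -3, 0, 3, 10)]
    return sorted(p for p in pts if -1.0 < p < 1.0)


def replication_bf(
    orig: StudySummary,
    rep: StudySummary,
    method: str = "quad",
    grid_size: int = 4097,
) -> float:
    """Replication Bayes factor BF_0r for correlations.

    Contrasts H0 ("the correlation is zero") against Hr ("the correlation is
    as the original study estimated"), where the proponent's prior on rho is
    the original study's posterior under a uniform(-1, 1) initial prior:

        BF_0r = f(r_rep | rho = 0, n_rep)
                / Integral f(r_rep | rho, n_rep) p(rho | r_orig, n_orig) drho

    with f the exact sampling density of Pearson r. Covariate adjustment
    enters through effective sample sizes ``n - k``. BF_0r > 1 favors the
    skeptic's null; BF_0r < 1 favors the original effect.

    ``method="quad"`` uses adaptive quadrature (relative tolerance 1e-6 or
    better); ``method="grid"`` uses a fixed Simpson grid, used for bulk
    simulation where thousands of factors are needed.
    """
    n_o = orig.n - orig.k
    n_r = rep.n - rep.k
    if min(n_o, n_r) < 4:
        raise ValueError("effective sample sizes must be >= 4")

    log_post_un = lambda rho: log_likelihood_r(orig.r, rho, n_o)

    if method == "grid":
        rho = np.linspace(-1.0 + 1e-9, 1.0 - 1e-9, grid_size)
        post = np.exp(log_post_un(rho))
        post /= integrate.simpson(post, x=rho)
        den = integrate.simpson(likelihood_r(rep.r, rho, n_r) * post, x=rho)
        num = likelihood_r(rep.r, 0.0, n_r)
        bf = num / den
    elif method == "quad":
        pts = _posterior_breakpoints(orig.r, n_o)
        z_norm, _ = integrate.quad(
            lambda rho: np.exp(log_post_un(rho)), -1.0, 1.0,
            points=pts, limit=400, epsabs=0.0, epsrel=1e-10,
        )
        den, _ = integrate.quad(
            lambda rho: likelihood_r(rep.r, rho, n_r) * np.exp(log_post_un(rho)) / z_norm,
            -1.0, 1.0, points=pts, limit=400, epsabs=0.0, epsrel=1e-10,
        )
        num = likelihood_r(rep.r, 0.0, n_r)
        bf = num / den
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(bf) or bf <= 0.0:
        raise ArithmeticError(
            f"non-finite replication BF (num={num!r}, den={den!r}); "
            "check the study summaries"
        )
    return float(bf)


# --------------------------------------------------------------------------
# combining the studies


def meta_fixed(
    studies: list[StudySummary], ci_level: float = 0.95
) -> CorrelationEstimate:
    """Fixed-effects meta-analysis of correlations in Fisher-z space.

    Inverse-variance pooling with weights ``w_i = n_i - 3 - k_i`` (the
    reciprocal Fisher-z variances, i.e. sample-size weighting), pooled
    standard error ``1/sqrt(sum w_i)``, two-sided normal p, all
    back-transformed to the r scale.
    """
    if not studies:
        raise ValueError("meta_fixed needs at least one study")
    z = np.array([fisher_z(s.r) for s in studies])
    w = np.array([s.n - 3 - s.k for s in studies], dtype=float)
    z_pool = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / np.sqrt(np.sum(w))
    z_crit = stats.norm.ppf(0.5 + ci_level / 2.0)
    n_tot = int(sum(s.n for s in studies))
    k_tot = int(sum(s.k for s in studies))
    return CorrelationEstimate(
        r=inv_fisher(z_pool),
        n=n_tot,
        k=k_tot,
        df=n_tot - 2 * len(studies) - k_tot,
        ci_level=ci_level,
        ci_lo=inv_fisher(z_pool - z_crit * se),
        ci_hi=inv_fisher(z_pool + z_crit * se),
        p=float(2.0 * stats.norm.sf(abs(z_pool) / se)),
        method="meta-fixed",
    )


def change_scores_correlation(
    change_scores: pd.DataFrame,
    score: str = "delta_tdcs",
    ci_level: float = 0.95,
    report_p: bool = True,
) -> CorrelationEstimate:
    """Partial correlation of anodal vs cathodal change scores.

    Pivots the tidy change-score table to one row per participant, then
    correlates the anodal and cathodal deltas adjusting for session order
    (a single binary covariate).
    """
    wide = change_scores.pivot_table(
        index="participant", columns="polarity", values=score, aggfunc="first"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete change scores: every participant needs both polarities")
    order = (
        change_scores.groupby("participant")["session_order"].first().reindex(wide.index)
    )
    cov = (order == "anodal_first").astype(float).to_numpy()
    est = partial_correlation(
        wide["anodal"].to_numpy(), wide["cathodal"].to_numpy(), cov, ci_level
    )
    if not report_p:
        est = CorrelationEstimate(
            r=est.r, n=est.n, k=est.k, df=est.df, ci_level=est.ci_level,
            ci_lo=est.ci_lo, ci_hi=est.ci_hi, p=None, method="pooled",
        )
    return est


def pooled_analysis(
    datasets: list[tuple[pd.DataFrame, str]], ci_level: float = 0.95
) -> CorrelationEstimate:
    """Partial correlation on the concatenated trial data of several studies.

    Each dataset (a validated trial table with its lag dialect) is reduced to
    change scores — harmonizing three-lag designs onto the lag-3/8 scheme
    first — and the participants are concatenated. Participant labels must be
    disjoint across datasets. No p-value is reported: re-testing a pooled
    sample after seeing the per-study results would invalidate it.
    """
    if not datasets:
        raise ValueError("pooled_analysis needs at least one dataset")
    tables = []
    seen: set = set()
    for trials, dialect in datasets:
        acc = harmonize_lags(cell_accuracy(trials), dialect)
        cs = ab_change_scores(acc)
        labels = set(cs["participant"])
        clash = labels & seen
        if clash:
            raise ValueError(
                f"participant labels collide across datasets: {sorted(clash)[:10]}; "
                "use a study prefix"
            )
        seen |= labels
        tables.append(cs)
    pooled = pd.concat(tables, ignore_index=True)
    return change_scores_correlation(pooled, ci_level=ci_level, report_p=False)


# --------------------------------------------------------------------------
# composite report


def full_report(
    orig: StudySummary,
    rep: StudySummary,
    rep_trials: pd.DataFrame | None = None,
    orig_trials: pd.DataFrame | None = None,
    orig_dialect: str = "study1",
    rep_dialect: str = "study2",
    alpha: float = 0.05,
    power_target: float = 1.0 / 3.0,
    ci_level: float = 0.95,
    sesoi_decimals: int | None = 2,
    pi_method: str = "fisher",
    pi_seed: int | None = 2026,
) -> ReplicationReport:
    """Run the full replication battery and return a composite report.

    ``sesoi_decimals`` rounds the small-telescopes bound before the
    inferiority test (default 2, the precision at which such bounds are
    conventionally reported); pass ``None`` to use the unrounded solution.
    The pooled re-analysis is included only when both trial tables are given.
    """
    sesoi = sesoi_r33(orig.n, orig.k, alpha, power_target)
    sesoi_used = round(sesoi, sesoi_decimals) if sesoi_decimals is not None else sesoi
    p_inf = inferiority_test(rep.r, rep.n, rep.k, sesoi_used)
    ci90 = correlation_ci(rep.r, rep.n, rep.k, 1.0 - 2.0 * alpha)
    pi_lo, pi_hi = prediction_interval(
        orig.r, orig.n, rep.n, ci_level, method=pi_method, seed=pi_seed
    )
    bf = replication_bf(orig, rep)
    meta = meta_fixed([orig, rep], ci_level)
    pooled = None
    if rep_trials is not None and orig_trials is not None:
        pooled = pooled_analysis(
            [(orig_trials, orig_dialect), (rep_trials, rep_dialect)], ci_level
        )
    return ReplicationReport(
        orig=estimate_from_summary(orig.r, orig.n, orig.k, ci_level, orig.label),
        rep=estimate_from_summary(rep.r, rep.n, rep.k, ci_level, rep.label),
        sesoi_r33=sesoi,
        inferiority_p=p_inf,
        rep_ci90=ci90,
        pi_lo=pi_lo,
        pi_hi=pi_hi,
        pi_method=pi_method,
        bf_0r=bf,
        meta=meta,
        pooled=pooled,
        notes={"sesoi_used": sesoi_used, "alpha": alpha, "power_target": power_target},
    )


def report_table(report: ReplicationReport) -> pd.DataFrame:
    """Tidy summary table: one row per replication quantity.

    Columns ``quantity, estimate, lo, hi, p, method``, mirroring a forest
    plot of the battery (per-study correlations, the 90% CI vs the
    equivalence bound, the prediction interval, the meta-analytic and pooled
    estimates, and the replication Bayes factor).
    """
    rows = [
        dict(quantity="original r", estimate=report.orig.r, lo=report.orig.ci_lo,
             hi=report.orig.ci_hi, p=report.orig.p, method=f"partial correlation, n={report.orig.n}"),
        dict(quantity="replication r", estimate=report.rep.r, lo=report.rep.ci_lo,
             hi=report.rep.ci_hi, p=report.rep.p, method=f"partial correlation, n={report.rep.n}"),
        dict(quantity="inferiority vs -r33%", estimate=-report.notes["sesoi_used"],
             lo=report.rep_ci90[0], hi=report.rep_ci90[1], p=report.inferiority_p,
             method="small telescopes, 90% CI"),
        dict(quantity="95% prediction interval", estimate=report.orig.r,
             lo=report.pi_lo, hi=report.pi_hi, p=np.nan, method=report.pi_method),
        dict(quantity="replication BF_0r", estimate=report.bf_0r, lo=np.nan,
             hi=np.nan, p=np.nan, method="exact r-density, uniform prior"),
        dict(quantity="meta-analytic r", estimate=report.meta.r, lo=report.meta.ci_lo,
             hi=report.meta.ci_hi, p=report.meta.p, method="fixed effects, Fisher z"),
    ]
    if report.pooled is not None:
        rows.append(
            dict(quantity="pooled r", estimate=report.pooled.r, lo=report.pooled.ci_lo,
                 hi=report.pooled.ci_hi, p=np.nan, method=f"pooled trials, n={report.pooled.n}")
        )
    return pd.DataFrame(rows, columns=["quantity", "estimate", "lo", "hi", "p", "method"])


def _bar(lo: float, hi: float, est: float, lo_ax: float, hi_ax: float, width: int = 57) -> str:
    def pos(v: float) -> int:
        frac = (v - lo_ax) / (hi_ax - lo_ax)
        return int(round(np.clip(frac, 0.0, 1.0) * (width - 1)))

    chars = [" "] * width
    if np.isfinite(lo) and np.isfinite(hi):
        for i in range(pos(lo), pos(hi) + 1):
            chars[i] = "-"
    if np.isfinite(est):
        chars[pos(est)] = "x"
    zero = pos(0.0)
    if chars[zero] == " ":
        chars[zero] = "|"
    return "".join(chars)


def forest_text(report: ReplicationReport) -> str:
    """Plain-text forest rendering of the replication battery."""
    tab = report_table(report)
    tab = tab[tab["quantity"] != "replication BF_0r"]
    lo_ax = min(-1.0, float(np.nanmin(tab["lo"])))
    hi_ax = max(1.0, float(np.nanmax(tab["hi"])))
    lines = ["Replication summary (x = estimate, --- = interval, | = 0)", ""]
    for _, row in tab.iterrows():
        lines.append(
            f"{row['quantity']:<24s} {_bar(row['lo'], row['hi'], row['estimate'], lo_ax, hi_ax)} "
            f"[{row['lo']:+.2f}, {row['hi']:+.2f}] est {row['estimate']:+.2f}"
        )
    lines.append("")
    lines.append(
        f"BF_0r = {report.bf_0r:.2f} (evidence for rho = 0 over the original posterior); "
        f"r33% = {report.sesoi_r33:.2f}, inferiority p = {report.inferiority_p:.3f}"
    )
    return "\n".join(lines)
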