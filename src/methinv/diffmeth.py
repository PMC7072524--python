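"""Differential methylation: empirical-Bayes moderated t and SAM permutations.

Both engines operate on M-values, M = log2((beta + eps) / (1 - beta + eps)),
the log-scale representation under which methylation differences are
approximately homoscedastic and linear-model machinery applies.

Engine 1 (moderated t) fits a per-probe two-group mean model, shrinks the
per-probe residual variances s_g^2 toward a common prior by empirical Bayes
-- the prior (d0, s0^2) is estimated by moment matching of log s_g^2 against
a scaled-F marginal, via digamma/trigamma inversion -- and tests the group
contrast with a t statistic on d0 + d_g degrees of freedom.  The robust
variant winsorizes the log-variances before moment matching and gives
large-variance outlier probes a down-weighted per-probe prior df so they are
not over-shrunk.

Engine 2 (SAM) scores each probe with d = (mean1 - mean2) / (s + s0), where s
is the pooled standard error of the mean difference and s0 a stabilizing
constant, then compares the descending-ordered observed d against the
expected order statistics dE averaged over label permutations; delta =
|d - dE| and a pooled permutation p-value complete the result.

Site selection applies the common thresholds |logFC| >= 1.5, p < 0.01 and
BH FDR q <= 0.01, and candidate lists from the two engines are intersected
to suppress false positives.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class EBHyperparams:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float
    robust: bool


@dataclass
class SelectionConfig:
    logfc_threshold: float = 1.5
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    delta_threshold: float | None = None
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.logfc_threshold, self.p_threshold, self.fdr_threshold) <= 0:
            raise ValueError("selection thresholds must be positive")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


@dataclass
class SamResult:
    """Per-probe SAM output plus the permutation bookkeeping."""

    table: pd.DataFrame  # columns: logFC, d, dE, delta, p, q
    M: int
    s0_sam: float
    exhaustive: bool


def beta_to_m(beta, epsilon: float = 1e-6) -> np.ndarray:
    """M-value transform, monotone in beta; epsilon guards the endpoints."""
    b = beta.values if isinstance(beta, BetaMatrix) else np.asarray(beta, dtype=float)
    return np.log2((b + epsilon) / (1.0 - b + epsilon))


def m_value_frame(m: BetaMatrix, epsilon: float = 1e-6) -> pd.DataFrame:
    return pd.DataFrame(beta_to_m(m, epsilon), index=m.probe_ids, columns=m.sample_ids)


def _two_group(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    return (groups == levels[0]), levels


def _group_moments(x: np.ndarray, in1: np.ndarray):
    """Per-probe means and pooled variance for a two-group split."""
    n1 = int(in1.sum())
    n2 = int((~in1).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")
    x1, x2 = x[:, in1], x[:, ~in1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    return m1, m2, ss / df, df, n1, n2


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: int) -> tuple[float, float, np.ndarray]:
    """Moment-match log s2 to a scaled-F marginal; returns (d0, s0_sq, e)."""
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all probes have zero within-group variance; degenerate fit")
    e_ok = np.log(s2[ok]) - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e_ok.mean())
    evar = float(e_ok.var(ddof=1)) if len(e_ok) > 1 else 0.0
    evar_prior = evar - float(special.polygamma(1, df / 2.0))
    if evar_prior <= 0:
        d0 = math.inf
        s0_sq = math.exp(emean)
    else:
        d0 = 2.0 * trigamma_inverse(evar_prior)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    e = np.full(len(s2), emean)
    e[ok] = np.log(s2[ok]) - special.digamma(df / 2.0) + math.log(df / 2.0)
    return d0, s0_sq, e


def fit_moderated_t(
    mvals: pd.DataFrame,
    groups,
    robust: bool = True,
    winsor_quantiles: tuple[float, float] = (0.05, 0.95),
    d0_override: float | None = None,
    s0_override: float | None = None,
) -> tuple[pd.DataFrame, EBHyperparams]:
    """Per-probe moderated two-sample t between the two levels of ``groups``.

    logFC is mean(level_a) - mean(level_b) with levels in sorted order.
    ``d0_override=0`` disables shrinkage (ordinary pooled t);
    ``d0_override=inf`` shrinks every variance fully to the prior
    (``s0_override`` when given, else the median residual variance).
    """
    x = mvals.to_numpy(dtype=float)
    in1, levels = _two_group(groups)
    m1, m2, s2, df, n1, n2 = _group_moments(x, in1)
    logfc = m1 - m2

    if d0_override is not None:
        d0 = float(d0_override)
        if s0_override is not None:
            s0_sq = float(s0_override)
        else:
            s0_sq = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
        e = None
    elif robust:
        ok = s2 > 0
        if not ok.any():
            raise ValueError("all probes have zero within-group variance; degenerate fit")
        e_all = np.where(ok, np.log(np.where(ok, s2, 1.0)), 0.0)
        e_all = e_all - special.digamma(df / 2.0) + math.log(df / 2.0)
        lo, hi = np.quantile(e_all[ok], winsor_quantiles)
        wins = np.clip(np.where(ok, e_all, lo), lo, hi)
        emean = float(wins[ok].mean())
        evar = float(wins[ok].var(ddof=1))
        evar_prior = evar - float(special.polygamma(1, df / 2.0))
        if evar_prior <= 0:
            d0, s0_sq = math.inf, math.exp(emean)
        else:
            d0 = 2.0 * trigamma_inverse(evar_prior)
            s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        e = np.where(ok, e_all, lo)
    else:
        d0, s0_sq, e = _fit_f_dist(s2, df)

    # per-probe prior df: outliers above the winsorization bound get less shrinkage
    if robust and d0_override is None and np.isfinite(d0):
        d0_g = np.where(e > hi, d0 * np.exp(-(e - hi)), d0)
    else:
        d0_g = np.full(len(s2), d0)

    if d0_override == 0:
        s2_post = s2.copy()
        df_total = np.full(len(s2), float(df))
    else:
        with np.errstate(invalid="ignore"):
            s2_post = np.where(
                np.isinf(d0_g), s0_sq, (d0_g * s0_sq + df * s2) / (d0_g + df)
            )
        df_total = np.where(np.isinf(d0_g), 1e12, d0_g + df)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), np.minimum(df_total, 1e12))
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "q": q, "s2": s2, "df_prior": d0_g},
        index=mvals.index,
    )
    hyper = EBHyperparams(d0=float(d0), s0_sq=float(s0_sq), robust=robust)
    logger.info(
        "moderated t (%s vs %s): d0=%.3g s0^2=%.3g robust=%s", levels[0], levels[1], d0, s0_sq, robust
    )
    return table, hyper


def _sam_d_parts(x: np.ndarray, in1: np.ndarray):
    m1, m2, s2, df, n1, n2 = _group_moments(x, in1)
    s = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return m1 - m2, s


def sam_d_statistic(mvals, groups, s0_sam: float = 0.0) -> np.ndarray:
    """SAM d = (mean1 - mean2) / (pooled SE + s0); group levels in sorted order."""
    x = mvals.to_numpy(dtype=float) if isinstance(mvals, pd.DataFrame) else np.asarray(mvals, float)
    in1, _ = _two_group(groups)
    num, s = _sam_d_parts(x, in1)
    return num / (s + s0_sam)


def default_s0(mvals, groups) -> float:
    """Default fudge constant: median of the per-probe pooled SEs."""
    x = mvals.to_numpy(dtype=float) if isinstance(mvals, pd.DataFrame) else np.asarray(mvals, float)
    in1, _ = _two_group(groups)
    _, s = _sam_d_parts(x, in1)
    return float(np.median(s))


def percentile_s0(mvals, groups, n_quantiles: int = 20) -> float:
    """Percentile-search fudge constant: the s-quantile minimizing the
    coefficient of variation of mad(d) across s-strata (Tusher-style)."""
    x = mvals.to_numpy(dtype=float) if isinstance(mvals, pd.DataFrame) else np.asarray(mvals, float)
    in1, _ = _two_group(groups)
    num, s = _sam_d_parts(x, in1)
    edges = np.quantile(s, np.linspace(0, 1, n_quantiles + 1))
    strata = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_quantiles - 1)
    best, best_cv = float(np.median(s)), np.inf
    for alpha in np.linspace(0.0, 1.0, 21):
        s0 = float(np.quantile(s, alpha))
        d = num / (s + s0)
        mads = [
            stats.median_abs_deviation(d[strata == g])
            for g in range(n_quantiles)
            if (strata == g).sum() > 1
        ]
        if len(mads) < 2:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads) if np.mean(mads) > 0 else np.inf
        if cv < best_cv:
            best_cv, best = cv, s0
    return best


def _permutation_masks(n: int, n1: int, M: int, rng: np.random.Generator):
    """Group-1 membership masks for M permutations; exhaustive when possible."""
    total = math.comb(n, n1)
    if total <= M:
        masks = np.zeros((total, n), dtype=bool)
        for r, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[r, list(idx)] = True
        return masks, True
    masks = np.zeros((M, n), dtype=bool)
    for r in range(M):
        masks[r, rng.choice(n, size=n1, replace=False)] = True
    return masks, False


def sam_permutation(
    mvals: pd.DataFrame,
    groups,
    cfg: SelectionConfig | None = None,
    s0_sam: float | None = None,
) -> SamResult:
    """SAM permutation analysis.

    For each of M label permutations the d statistics are recomputed and
    sorted descending; dE(i) is the rank-wise mean over permutations, aligned
    against the descending-sorted observed d, and delta(i) = |d(i) - dE(i)|.
    The permutation p-value pools |d| over all probes and permutations with
    an add-one correction: p_i = (1 + #{|d_null| >= |d_i|}) / (1 + M*G).
    """
    cfg = cfg or SelectionConfig()
    x = mvals.to_numpy(dtype=float)
    in1, _ = _two_group(groups)
    if s0_sam is None:
        s0_sam = default_s0(mvals, groups)
    num, s = _sam_d_parts(x, in1)
    d_obs = num / (s + s0_sam)
    logfc = num
    g = len(d_obs)
    n = x.shape[1]
    n1 = int(in1.sum())

    rng = np.random.default_rng(cfg.seed)
    masks, exhaustive = _permutation_masks(n, n1, cfg.permutations, rng)
    M = masks.shape[0]
    if exhaustive and M < cfg.permutations:
        logger.info("sam_permutation: truncated to %d exhaustive permutations", M)

    abs_sorted = np.sort(np.abs(d_obs))
    # tolerance-lowered thresholds so a permutation reproducing an observed
    # d counts as a tie despite last-ulp summation differences
    abs_thresh = abs_sorted * (1.0 - 1e-9) - 1e-12
    ge_counts = np.zeros(g, dtype=np.int64)
    de_sum = np.zeros(g)
    x2 = x**2
    row_sum = x.sum(axis=1)
    row_sq = x2.sum(axis=1)
    df = n - 2
    inv = 1.0 / n1 + 1.0 / (n - n1)
    chunk = max(1, int(2e7) // max(g, 1))
    for start in range(0, M, chunk):
        b = masks[start : start + chunk].astype(float)  # (c, n)
        s1 = x @ b.T  # (g, c) group-1 sums
        q1 = x2 @ b.T
        m1 = s1 / n1
        m2 = (row_sum[:, None] - s1) / (n - n1)
        ss = (q1 - n1 * m1**2) + ((row_sq[:, None] - q1) - (n - n1) * m2**2)
        sp = np.sqrt(np.maximum(ss / df, 0.0) * inv)
        dperm = (m1 - m2) / (sp + s0_sam)
        de_sum += np.sort(dperm, axis=0)[::-1].sum(axis=1)
        # pooled null counts: each null |d| >= abs_sorted[r] for all ranks
        # r < searchsorted(abs_sorted, |d|, side="right"); accumulate via
        # a suffix sum over the bincount of those positions
        pos = np.searchsorted(abs_thresh, np.abs(dperm).ravel(), side="right")
        cnt = np.bincount(pos, minlength=g + 1)
        suffix = cnt[::-1].cumsum()[::-1]  # suffix[j] = sum_{i >= j} cnt[i]
        ge_counts += suffix[1:]

    de = de_sum / M
    order = np.argsort(-d_obs, kind="stable")
    delta = np.empty(g)
    delta[order] = np.abs(d_obs[order] - de)
    # map pooled counts (indexed by rank in abs_sorted) back to probes
    rank_in_abs = np.searchsorted(abs_sorted, np.abs(d_obs), side="left")
    # ge_counts[r] = # null values >= abs_sorted[r] is what we accumulated per rank
    p = (1.0 + ge_counts[rank_in_abs]) / (1.0 + M * g)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"logFC": logfc, "d": d_obs, "dE": _aligned_de(d_obs, de), "delta": delta, "p": p, "q": q},
        index=mvals.index,
    )
    return SamResult(table=table, M=M, s0_sam=float(s0_sam), exhaustive=exhaustive)


def _aligned_de(d_obs: np.ndarray, de_sorted_desc: np.ndarray) -> np.ndarray:
    """Scatter rank-wise dE back onto probes by each probe's descending rank."""
    out = np.empty_like(de_sorted_desc)
    out[np.argsort(-d_obs, kind="stable")] = de_sorted_desc
    return out


def select_sites(table: pd.DataFrame, cfg: SelectionConfig | None = None) -> pd.Index:
    """Probes passing |logFC| >= threshold, p < threshold, q <= FDR (and
    delta > delta_threshold when set and available), in input order."""
    cfg = cfg or SelectionConfig()
    passed = (
        (table["logFC"].abs() >= cfg.logfc_threshold)
        & (table["p"] < cfg.p_threshold)
        & (table["q"] <= cfg.fdr_threshold)
    )
    if cfg.delta_threshold is not None and "delta" in table.columns:
        passed &= table["delta"] > cfg.delta_threshold
    return table.index[passed]


def intersect_sites(a: pd.Index, b) -> pd.Index:
    """Set intersection ordered by ``a``'s ordering."""
    bset = set(b)
    return pd.Index([x for x in a if x in bset])


def add_passed(table: pd.DataFrame, cfg: SelectionConfig | None = None) -> pd.DataFrame:
    out = table.copy()
    out["passed"] = out.index.isin(select_sites(table, cfg))
    return out
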