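"""Differential-enrichment engine.

Ratio assembly for forward/reverse SILAC designs, group-wise quantile
normalization, the study-specific imputation rules, an empirical-Bayes
moderated t-test (one-sample on log-ratios, or two-group on log
intensities), Benjamini–Hochberg adjustment, the two-tier significance
call (log2FC > 1 with adjusted p < 0.01 / < 0.1) and Fisher's exact test.

The moderation follows the classical closed-form moment matching on log
sample variances: the prior (d0, s0^2) of a scaled inverse-chi-square law
is fitted by equating the empirical mean and variance of log s^2 to their
digamma/trigamma expressions, the posterior variance of each feature is
s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), and the moderated t statistic is
referred to a t distribution on d0 + d degrees of freedom (normal when
d0 is infinite).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

TIER_HIGH = "highly_significant"
TIER_SIG = "significant"
TIER_NS = "not_significant"


@dataclass(frozen=True)
class EBHyperparams:
    """Prior of the variance model: d0 degrees of freedom, s0^2 variance.

    ``d0 = inf`` means all features share the prior variance exactly (no
    excess dispersion of the sample variances beyond chi-square sampling);
    ``d0 = 0`` is the no-moderation limit where the ordinary t-test is
    recovered.
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ConfigurationError("d0 must be >= 0 or infinite")
        if not self.s0sq > 0:
            raise ConfigurationError("s0sq must be > 0")


def assemble_log_ratios(table, design: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-experiment log2(crosslinked / non-crosslinked) from SILAC ratios.

    ``design`` pairs each ratio column of the table with its orientation:
    a forward experiment (heavy channel crosslinked) contributes
    ``log2(H/L)``, a reverse experiment contributes ``-log2(H/L)``.
    Missing ratios stay missing.
    """
    matrix = {}
    for column, orientation in design:
        if orientation not in ("forward", "reverse"):
            raise ConfigurationError(f"unknown orientation {orientation!r} for {column}")
        if column not in table.data.columns:
            raise ConfigurationError(f"ratio column {column!r} not in table")
        values = np.log2(table.data[column].astype(float))
        matrix[column] = values if orientation == "forward" else -values
    return pd.DataFrame(matrix, index=table.data.index)


def filter_min_evidence(
    matrix: pd.DataFrame,
    rule: str = "forward_and_reverse",
    orientations: dict[str, str] | None = None,
    min_k: int = 2,
) -> pd.DataFrame:
    """Drop features without the required replicate evidence.

    ``forward_and_reverse`` keeps features observed in at least one forward
    and one reverse experiment (hence >= 2 assays); ``min_k_replicates``
    keeps features observed in at least ``min_k`` columns.
    """
    observed = matrix.notna()
    if rule == "forward_and_reverse":
        if not orientations:
            raise ConfigurationError("forward_and_reverse rule needs column orientations")
        fwd = [c for c in matrix.columns if orientations.get(c) == "forward"]
        rev = [c for c in matrix.columns if orientations.get(c) == "reverse"]
        keep = observed[fwd].any(axis=1) & observed[rev].any(axis=1)
    elif rule == "min_k_replicates":
        keep = observed.sum(axis=1) >= min_k
    else:
        raise ConfigurationError(f"unknown evidence rule {rule!r}")
    removed = int((~keep).sum())
    logger.info("filter_min_evidence(%s): removed %d of %d features",
                rule, removed, len(matrix))
    return matrix[keep]


def quantile_normalize(
    matrix: pd.DataFrame, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Quantile-normalize intensity columns within each condition group.

    Within a group, each column's observed values are replaced by a common
    reference distribution (the per-rank mean of the sorted columns, with
    linear interpolation when columns have unequal numbers of observed
    values, as happens with missing cells).  Missing cells remain missing;
    each column's rank order is preserved.  Columns with fewer than two
    observed values are left unchanged with a warning.
    """
    if groups is None:
        groups = {c: "all" for c in matrix.columns}
    out = matrix.astype(float).copy()
    for group in sorted(set(groups.values())):
        cols = [c for c in matrix.columns if groups.get(c) == group]
        if not cols:
            continue
        sorted_obs = {}
        for c in cols:
            v = out[c].dropna().sort_values().to_numpy()
            if len(v) < 2:
                logger.warning("quantile_normalize: column %r has <2 observed values, left unchanged", c)
            else:
                sorted_obs[c] = v
        if len(sorted_obs) < 2:
            continue  # single usable column: reference is itself
        # common quantile grid: per-rank mean of sorted columns, interpolated
        # onto the finest grid present in the group
        grid_n = max(len(v) for v in sorted_obs.values())
        grid = np.linspace(0.0, 1.0, grid_n)
        curves = []
        for v in sorted_obs.values():
            q = np.linspace(0.0, 1.0, len(v))
            curves.append(np.interp(grid, q, v))
        reference = np.mean(curves, axis=0)
        for c, v in sorted_obs.items():
            q = np.linspace(0.0, 1.0, len(v))
            ref_vals = np.interp(q, grid, reference)
            observed_idx = out.index[out[c].notna()]
            order = np.argsort(out.loc[observed_idx, c].to_numpy(), kind="stable")
            ranked_index = observed_idx[order]
            out.loc[ranked_index, c] = ref_vals
    return out


def impute(
    matrix: pd.DataFrame,
    rule: str,
    groups: dict[str, str],
    control_group: str | None = None,
    max_missing_for_mean: int = 2,
) -> pd.DataFrame:
    """Apply the study's imputation rules to an intensity matrix.

    ``sicap_protein``: per feature and condition, if at most
    ``max_missing_for_mean`` replicates are missing they are imputed with
    the mean of the observed replicates; if *all* replicates of the
    ``control_group`` condition are missing they are imputed with each
    column's observed minimum (a per-sample sensitivity floor); with more
    missing than that the cells stay missing and the feature is left to
    the evidence filter.

    ``spacemap_peptide``: per feature, a fraction whose replicates are all
    missing is imputed with each column's observed minimum; partial
    missingness is left as is (the moderated test handles unbalanced n).
    """
    if rule not in ("sicap_protein", "spacemap_peptide"):
        raise ConfigurationError(f"unknown imputation rule {rule!r}")
    out = matrix.astype(float).copy()
    col_min = out.min(axis=0, skipna=True)

    def _minimum(column):
        if np.isnan(col_min[column]):
            raise DataError(
                f"column {column!r} is entirely missing, no minimum defined"
            )
        return col_min[column]

    condition_cols = {}
    for c in matrix.columns:
        condition_cols.setdefault(groups[c], []).append(c)

    for cond, cols in condition_cols.items():
        block = out[cols]
        n_missing = block.isna().sum(axis=1)
        if rule == "sicap_protein":
            fillable = (n_missing > 0) & (n_missing <= max_missing_for_mean)
            row_means = block.mean(axis=1, skipna=True)
            for c in cols:
                mask = fillable & block[c].isna()
                out.loc[mask, c] = row_means[mask]
            if control_group is not None and cond == control_group:
                all_missing = n_missing == len(cols)
                for c in cols:
                    if all_missing.any():
                        out.loc[all_missing, c] = _minimum(c)
        else:  # spacemap_peptide
            all_missing = n_missing == len(cols)
            for c in cols:
                if all_missing.any():
                    out.loc[all_missing, c] = _minimum(c)
    return out


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing convexity of trigamma; the Newton update
    in 1/x space converges from the standard starting value 0.5 + 1/y.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < tol:
            break
    return x


def fit_eb_hyperparams(s2: np.ndarray, df) -> EBHyperparams:
    """Fit the variance prior by moment matching on log sample variances.

    Given sample variances ``s2`` with residual degrees of freedom ``df``
    (scalar or per-feature), matches the mean and dispersion of
    ``log(s2)`` to the digamma/trigamma expressions implied by a scaled
    inverse-chi-square prior.  If there is no excess dispersion beyond
    chi-square sampling noise, returns ``d0 = inf`` with the geometric-mean
    based variance estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise DataError(
            "need >= 2 features with positive variance and df; "
            "supply fixed EBHyperparams instead"
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    # subtract the expected sampling variance of log s^2 given df
    excess = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess > 0:
        half_d0 = trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        # no excess dispersion: all features share one variance, estimated
        # by the geometric mean of the sample variances
        d0 = math.inf
        s0sq = float(np.exp(np.mean(z)))
    return EBHyperparams(d0=d0, s0sq=s0sq)


def _posterior_variance(s2: np.ndarray, d: np.ndarray, hyper: EBHyperparams):
    if math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0sq, dtype=float)
        df_total = np.full_like(s2, np.inf, dtype=float)
    else:
        s2_post = (hyper.d0 * hyper.s0sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d
    return s2_post, df_total


def _t_pvalue(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = np.full_like(t, np.nan, dtype=float)
    finite_df = np.isfinite(df)
    ok = np.isfinite(t)
    p[ok & finite_df] = 2.0 * stats.t.sf(np.abs(t[ok & finite_df]), df[ok & finite_df])
    p[ok & ~finite_df] = 2.0 * stats.norm.sf(np.abs(t[ok & ~finite_df]))
    return p


def moderated_t_test(
    data: pd.DataFrame,
    mode: str = "one_sample_ratio",
    groups: dict[str, str] | None = None,
    hyper: EBHyperparams | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per feature.

    ``one_sample_ratio``: rows of ``data`` are log2 ratios tested against
    mean 0.  ``two_group``: rows are log2 intensities and ``groups`` maps
    each column to one of exactly two condition labels; log2FC is the
    first-minus-second group mean difference with groups ordered so the
    crosslinked/treatment label (first label encountered in column order)
    comes first.  Features with insufficient observations are reported
    untested (p = NA).  If ``hyper`` is None the prior is fitted from the
    data's sample variances.
    """
    x = data.astype(float).to_numpy()
    n_features = x.shape[0]
    if mode == "one_sample_ratio":
        n_obs = np.sum(~np.isnan(x), axis=1).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            estimate = np.nanmean(x, axis=1)
            s2 = np.nanvar(x, axis=1, ddof=1)
        d = np.maximum(n_obs - 1.0, 0.0)
        v = np.where(n_obs > 0, 1.0 / n_obs, np.nan)
        testable = n_obs >= 2
        n_obs_frame = pd.DataFrame({"n_obs": n_obs.astype(int)}, index=data.index)
    elif mode == "two_group":
        if not groups:
            raise ConfigurationError("two_group mode needs a column->group mapping")
        labels = []
        for c in data.columns:
            g = groups.get(c)
            if g is None:
                raise ConfigurationError(f"column {c!r} has no group label")
            if g not in labels:
                labels.append(g)
        if len(labels) != 2:
            raise ConfigurationError(f"two_group mode needs exactly 2 groups, got {labels}")
        g1_cols = [i for i, c in enumerate(data.columns) if groups[c] == labels[0]]
        g2_cols = [i for i, c in enumerate(data.columns) if groups[c] == labels[1]]
        x1, x2 = x[:, g1_cols], x[:, g2_cols]
        n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
        n2 = np.sum(~np.isnan(x2), axis=1).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(x1, axis=1)
            m2 = np.nanmean(x2, axis=1)
            ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
            ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
        estimate = m1 - m2
        d = np.maximum(n1 + n2 - 2.0, 0.0)
        s2 = np.where(d > 0, (ss1 + ss2) / np.where(d > 0, d, 1.0), np.nan)
        with np.errstate(divide="ignore"):
            v = 1.0 / n1 + 1.0 / n2
        testable = (n1 >= 1) & (n2 >= 1) & (d >= 1)
        n_obs_frame = pd.DataFrame(
            {"n_obs_group1": n1.astype(int), "n_obs_group2": n2.astype(int)},
            index=data.index,
        )
    else:
        raise ConfigurationError(f"unknown test mode {mode!r}")

    if hyper is None:
        hyper = fit_eb_hyperparams(s2[testable], d[testable])

    s2_clean = np.where(np.isfinite(s2), s2, 0.0)
    s2_post, df_total = _posterior_variance(s2_clean, d, hyper)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(s2_post * v)
        t_mod = np.where(denom > 0, estimate / denom, 0.0)
    t_mod = np.where(testable, t_mod, np.nan)
    p = _t_pvalue(t_mod, df_total)
    # a feature whose every observation equals the null exactly
    zero = testable & (np.abs(estimate) == 0) & (s2_clean == 0)
    t_mod[zero] = 0.0
    p[zero] = 1.0

    result = pd.DataFrame(index=data.index)
    result["log2fc"] = estimate
    result["t_mod"] = t_mod
    result["df_total"] = np.where(testable, df_total, np.nan)
    result["s2"] = s2
    result["s2_post"] = np.where(testable, s2_post, np.nan)
    result["p"] = p
    result = pd.concat([n_obs_frame, result], axis=1)
    result["adj_p"] = adjust_bh(result["p"].to_numpy())
    return result


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NA entries are excluded from the ranking and stay NA.  The adjusted
    value of p_(i) is min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def classify_tiers(
    results: pd.DataFrame,
    fc_threshold: float = 1.0,
    tier1_alpha: float = 0.01,
    tier2_alpha: float = 0.1,
    tier2_only: bool = False,
) -> pd.Series:
    """Two-tier significance call with strict inequalities.

    ``highly_significant``: log2FC > fc_threshold and adj p < tier1_alpha;
    ``significant``: log2FC > fc_threshold and adj p < tier2_alpha (but not
    tier 1); otherwise ``not_significant``.  ``tier2_only`` collapses the
    tiers to a single significant/not call at tier2_alpha, the convention
    of the comparative and two-group modes.
    """
    fc = results["log2fc"]
    adj = results["adj_p"]
    enriched = (fc > fc_threshold) & adj.notna()
    tier = pd.Series(TIER_NS, index=results.index, dtype=object)
    if tier2_only:
        tier[enriched & (adj < tier2_alpha)] = TIER_SIG
    else:
        tier[enriched & (adj < tier2_alpha)] = TIER_SIG
        tier[enriched & (adj < tier1_alpha)] = TIER_HIGH
    counts = tier.value_counts().to_dict()
    logger.info("classify_tiers: %s", counts)
    return tier


def fisher_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Sums hypergeometric probabilities at most that of the observed table.
    A zero row or column margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not float(t.sum()) > 0:
        raise DataError("fisher_2x2 needs a non-negative 2x2 table with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_2x2: degenerate margin, p = 1")
        return 1.0
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)
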