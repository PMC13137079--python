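"""Validation statistics for eDNA-derived hybrid-index estimates.

Deviations HI_obs - HI_exp reject normality in this kind of data, so the
toolkit is non-parametric throughout: rank correlation for concordance,
Kruskal-Wallis and Wilcoxon signed-rank for profile-wise bias,
Fligner-Killeen for variance homogeneity, a permutation ANCOVA for the
sampling-regime effect, a bootstrap CI of the median for per-SNP bias
screening, and Bland-Altman limits of agreement for population-scale
accuracy and precision.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "holm",
    "BlandAltmanResult",
    "bland_altman",
    "SnpBiasResult",
    "snp_bias",
    "concordance",
    "AncovaResult",
    "permutation_ancova",
    "profile_bias_tests",
    "variance_homogeneity",
    "biomass_effect_test",
]


def holm(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values; NaN entries pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    """Mean bias and 95% limits of agreement of paired differences."""

    mean_bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(differences: Sequence[float], z: float = 1.96) -> BlandAltmanResult:
    """Limits of agreement: mean +/- z * SD of the differences.

    SD uses the n-1 denominator (sample SD, the Bland & Altman convention);
    about 95% of differences are expected inside the interval for z = 1.96.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman requires at least two differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_bias=mean, sd=sd, loa_low=mean - z * sd, loa_high=mean + z * sd, n=d.size
    )


# ---------------------------------------------------------------------------
# Per-SNP bias screening
# ---------------------------------------------------------------------------

@dataclass
class SnpBiasResult:
    """Median bias of one SNP with a bootstrap CI and the retention call."""

    snp_id: str
    median_bias: float
    ci_low: float
    ci_high: float
    retained: bool
    n: int
    evaluable: bool = True


def snp_bias(
    deviations: Mapping[str, Sequence[float]],
    B: int = 2000,
    tol: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[SnpBiasResult]:
    """Systematic per-SNP bias from confirmed-genotype swab deviations.

    For each SNP the bias is the median deviation (HI_obs - HI_exp) with a
    percentile bootstrap 95% CI (B resamples with replacement).  A SNP is
    retained only when the entire CI lies within +/- ``tol`` HI units — a
    conservative 5%-of-scale tolerance by default.  SNPs with fewer than two
    deviations are unevaluable (reported, not retained).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for snp_id in sorted(deviations):
        d = np.asarray(deviations[snp_id], dtype=float)
        if d.size < 2:
            out.append(
                SnpBiasResult(
                    snp_id=snp_id,
                    median_bias=float(np.median(d)) if d.size else math.nan,
                    ci_low=math.nan, ci_high=math.nan,
                    retained=False, n=int(d.size), evaluable=False,
                )
            )
            continue
        idx = rng.integers(0, d.size, size=(B, d.size))
        boot_medians = np.median(d[idx], axis=1)
        lo, hi = np.percentile(boot_medians, [2.5, 97.5])
        retained = (-tol <= lo) and (hi <= tol)
        out.append(
            SnpBiasResult(
                snp_id=snp_id,
                median_bias=float(np.median(d)),
                ci_low=float(lo),
                ci_high=float(hi),
                retained=bool(retained),
                n=int(d.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Concordance (Spearman)
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n, full enumeration)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def concordance(
    hi_obs: Sequence[float],
    hi_exp: Sequence[float],
    regimes: Sequence[str],
) -> pd.DataFrame:
    """Spearman rank correlation of HI_obs vs HI_exp, per sampling regime.

    Average ranks for ties; two-sided p via exact permutation enumeration for
    n <= 8 and the t-approximation above.  A regime with constant HI_exp has
    undefined rho and is reported as such.
    """
    df = pd.DataFrame({"obs": hi_obs, "exp": hi_exp, "regime": regimes})
    rows = []
    for regime, grp in df.groupby("regime", sort=True):
        n = len(grp)
        if n < 3 or grp["exp"].nunique() < 2 or grp["obs"].nunique() < 2:
            rows.append(dict(regime=regime, rho=math.nan, p=math.nan, n=n,
                             note="undefined (constant input or n < 3)"))
            continue
        rho, p = sps.spearmanr(grp["obs"], grp["exp"])
        if n <= 8:
            p = _spearman_exact_p(grp["obs"].to_numpy(), grp["exp"].to_numpy(), rho)
        rows.append(dict(regime=regime, rho=float(rho), p=float(p), n=n, note=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation ANCOVA (Freedman-Lane)
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    """Observed F statistics and permutation p-values for the regime model."""

    f_covariate: float
    f_regime: float
    f_interaction: float
    p_regime: float
    p_interaction: float
    n_perm: int
    n: int


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of columns of Y after projection onto span(Q)."""
    fitted_sq = np.sum((Q.T @ Y) ** 2, axis=0)
    return np.sum(Y**2, axis=0) - fitted_sq


def permutation_ancova(
    hi_obs: Sequence[float],
    hi_exp: Sequence[float],
    regimes: Sequence[str],
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> AncovaResult:
    """Permutation-based ANCOVA of HI_obs ~ HI_exp * regime.

    A linear model with the expected HI as covariate, sampling regime as a
    two-level factor, and their interaction.  P-values for the regime and
    interaction terms use the Freedman-Lane scheme: for each term, the
    reduced model (without that term) is fitted, its residuals are permuted
    and added back to the reduced fit, and the term's partial F is recomputed
    on each synthetic response.  p = (1 + #{F* >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(hi_obs, dtype=float)
    x = np.asarray(hi_exp, dtype=float)
    g_labels = pd.unique(np.asarray(regimes))
    if len(g_labels) != 2:
        raise ValueError("exactly two regime levels are required")
    g = (np.asarray(regimes) == g_labels[1]).astype(float)
    n = y.size

    X_full = np.column_stack([np.ones(n), x, g, x * g])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design (regimes confounded with HI_exp)")
    df_resid = n - X_full.shape[1]
    term_cols = {"covariate": 1, "regime": 2, "interaction": 3}

    Q_full, _ = np.linalg.qr(X_full)
    f_obs: dict[str, float] = {}
    p_val: dict[str, float] = {}
    for term, col in term_cols.items():
        X_red = np.delete(X_full, col, axis=1)
        Q_red, _ = np.linalg.qr(X_red)
        rss_full = float(_rss(Q_full, y[:, None])[0])
        rss_red = float(_rss(Q_red, y[:, None])[0])
        f_obs[term] = (rss_red - rss_full) / (rss_full / df_resid)
        if term == "covariate":
            continue  # covariate significance is not part of the regime question
        fitted_red = Q_red @ (Q_red.T @ y)
        resid_red = y - fitted_red
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        Y_star = fitted_red[:, None] + resid_red[perm_idx].T  # (n, n_perm)
        rss_full_s = _rss(Q_full, Y_star)
        rss_red_s = _rss(Q_red, Y_star)
        f_star = (rss_red_s - rss_full_s) / (rss_full_s / df_resid)
        p_val[term] = float((1 + np.sum(f_star >= f_obs[term])) / (n_perm + 1))

    return AncovaResult(
        f_covariate=f_obs["covariate"],
        f_regime=f_obs["regime"],
        f_interaction=f_obs["interaction"],
        p_regime=p_val["regime"],
        p_interaction=p_val["interaction"],
        n_perm=n_perm,
        n=n,
    )


# ---------------------------------------------------------------------------
# Profile-wise bias and variance tests
# ---------------------------------------------------------------------------

def _wilcoxon_p(d: np.ndarray) -> float:
    """One-sample Wilcoxon signed-rank p vs 0, with the zero-discard rule.

    Zeros are discarded (Wilcoxon's treatment); exact distribution for
    n <= 25 without ties, normal approximation with continuity correction
    otherwise.  All-zero input is degenerate and reported as p = 1.
    """
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def profile_bias_tests(
    deviations: pd.DataFrame,
    alpha_col: str = "deviation",
    profile_col: str = "profile",
    regime_col: str = "regime",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile-wise bias screening within each sampling regime.

    Returns ``(kw, wilcoxon)``:

    * ``kw`` — one Kruskal-Wallis test per regime across the genotypic
      profiles (are the deviation distributions exchangeable across
      profiles?);
    * ``wilcoxon`` — per (regime, profile) one-sample Wilcoxon signed-rank
      test of the median deviation against zero, Holm-adjusted across the
      profiles within each regime.
    """
    kw_rows, w_rows = [], []
    for regime, grp in deviations.groupby(regime_col, sort=True):
        groups = [g[alpha_col].to_numpy() for _, g in grp.groupby(profile_col, sort=True)]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            try:
                stat, p = sps.kruskal(*groups)
            except ValueError:  # all values identical across every group
                stat, p = math.nan, 1.0
            kw_rows.append(dict(regime=regime, statistic=float(stat), p=float(p),
                                n_profiles=len(groups), n=len(grp)))
        else:
            kw_rows.append(dict(regime=regime, statistic=math.nan, p=math.nan,
                                n_profiles=len(groups), n=len(grp)))
        profs, raw_p = [], []
        for profile, sub in grp.groupby(profile_col, sort=True):
            d = sub[alpha_col].to_numpy(dtype=float)
            profs.append(dict(regime=regime, profile=profile,
                              median_deviation=float(np.median(d)), n=len(d)))
            raw_p.append(_wilcoxon_p(d))
        adj = holm(raw_p)
        for row, p, pa in zip(profs, raw_p, adj):
            row["p"] = p
            row["p_adj"] = float(pa)
            w_rows.append(row)
    return pd.DataFrame(kw_rows), pd.DataFrame(w_rows)


def variance_homogeneity(
    deviations: pd.DataFrame,
    alpha_col: str = "deviation",
    profile_col: str = "profile",
) -> pd.DataFrame:
    """Pairwise Fligner-Killeen variance-homogeneity tests across profiles.

    All profile pairs are tested and Holm-adjusted as one family.  A pair
    with a constant group (zero spread) is untestable and reported with
    p = NaN; it does not enter the Holm family.
    """
    groups = {
        prof: g[alpha_col].to_numpy(dtype=float)
        for prof, g in deviations.groupby(profile_col, sort=True)
    }
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        da, db = groups[a], groups[b]
        if len(da) < 2 or len(db) < 2 or (np.ptp(da) == 0 and np.ptp(db) == 0):
            rows.append(dict(profile_a=a, profile_b=b, statistic=math.nan,
                             p=math.nan, n_a=len(da), n_b=len(db),
                             note="untestable (degenerate group)"))
            continue
        stat, p = sps.fligner(da, db)
        rows.append(dict(profile_a=a, profile_b=b, statistic=float(stat),
                         p=float(p), n_a=len(da), n_b=len(db), note=""))
    out = pd.DataFrame(rows)
    out["p_adj"] = holm(out["p"].to_numpy())
    return out


def biomass_effect_test(
    pairs_by_profile: Mapping[float, tuple[Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """Does biomass correction reduce |HI_obs - HI_exp| in mixed profiles?

    For each mixed-genotype profile, pairs the absolute deviations under the
    uncorrected vs biomass-corrected expected HI and applies a paired
    Wilcoxon signed-rank test, Holm-adjusted across the profiles.  A profile
    with fewer than two pairs (or all-tied pairs) is degenerate: a single
    pair is untestable, ties-only yields p = 1.
    """
    rows, raw_p = [], []
    for profile in sorted(pairs_by_profile):
        unc, cor = pairs_by_profile[profile]
        unc = np.asarray(unc, dtype=float)
        cor = np.asarray(cor, dtype=float)
        if unc.shape != cor.shape:
            raise ValueError(f"profile {profile}: paired vectors differ in length")
        diff = unc - cor
        if diff.size == 0:
            rows.append(dict(profile=profile, median_paired_diff=math.nan,
                             n=0, note="untestable (no pairs)"))
            raw_p.append(math.nan)
            continue
        if diff.size == 1:
            rows.append(dict(profile=profile, median_paired_diff=float(diff[0]),
                             n=1, note="untestable (single pair)"))
            raw_p.append(math.nan)
            continue
        rows.append(dict(profile=profile, median_paired_diff=float(np.median(diff)),
                         n=int(diff.size), note=""))
        raw_p.append(_wilcoxon_p(diff))
    out = pd.DataFrame(rows)
    out["p"] = raw_p
    out["p_adj"] = holm(out["p"].to_numpy())
    return out
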