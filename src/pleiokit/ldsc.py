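"""Unstratified LD score regression: SNP heritability and genetic correlation.

Single trait: E[chi2_j] = 1 + N h2 ell_j / M (+ intercept excess), so the
weighted regression of chi-squared statistics on LD scores yields
h2 = slope * M / N, with the intercept absorbing confounding inflation.

Cross-trait: E[z1_j z2_j] = sqrt(N1 N2) rho_g ell_j / M + cross-intercept,
where rho_g is the genetic covariance and the free cross-intercept absorbs
sample overlap; the genetic correlation is r_g = rho_g / sqrt(h2_1 h2_2).

Both fits use the standard two-step heteroskedasticity/overcounting weights
and report standard errors from a delete-one block jackknife over contiguous
SNP blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

DEFAULT_N_BLOCKS = 200
DEFAULT_CHI2_MAX = 80.0


def _block_edges(n: int, n_blocks: int) -> np.ndarray:
    n_blocks = max(1, min(n_blocks, n))
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _weighted_line(x, y, w, n_blocks):
    """Weighted least-squares line with delete-one-block jackknife SEs.

    Returns (slope, intercept, slope_se, intercept_se, per-block slope and
    intercept jackknife replicates).
    """
    terms = np.column_stack([w, w * x, w * y, w * x * x, w * x * y])
    edges = _block_edges(len(x), n_blocks)
    block_sums = np.add.reduceat(terms, edges[:-1], axis=0)
    tot = block_sums.sum(axis=0)

    def solve(s):
        sw, swx, swy, swxx, swxy = s
        d = sw * swxx - swx * swx
        if d <= 0:
            return np.nan, np.nan
        slope = (sw * swxy - swx * swy) / d
        return slope, (swy - slope * swx) / sw

    slope, intercept = solve(tot)
    reps = np.array([solve(tot - bs) for bs in block_sums])
    nb = len(block_sums)
    if nb > 1 and np.all(np.isfinite(reps)):
        mean_rep = reps.mean(axis=0)
        se = np.sqrt((nb - 1) / nb * ((reps - mean_rep) ** 2).sum(axis=0))
    else:
        se = np.array([np.nan, np.nan])
    return slope, intercept, se[0], se[1], reps


@dataclass
class LdscFit:
    """Single-trait LD score regression fit."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    h2: float
    h2_se: float
    M: int
    N: float
    n_snps: int
    slope_reps: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        flag = "" if 0 <= self.h2 <= 1 else "  [outside [0,1]]"
        return (f"LD score regression (single trait)\n"
                f"  SNPs used:  {self.n_snps} (M = {self.M})\n"
                f"  intercept:  {self.intercept:.4f} ({self.intercept_se:.4f})\n"
                f"  h2:         {self.h2:.4f} ({self.h2_se:.4f}){flag}")


@dataclass
class RgFit:
    """Cross-trait fit: genetic covariance and correlation with jackknife SE."""

    rg: float
    rg_se: float
    gencov: float
    gencov_intercept: float
    fit1: LdscFit
    fit2: LdscFit
    n_snps: int

    def summary(self) -> str:
        return (f"Cross-trait LD score regression\n"
                f"  SNPs used:        {self.n_snps}\n"
                f"  h2 trait 1:       {self.fit1.h2:.4f} ({self.fit1.h2_se:.4f})\n"
                f"  h2 trait 2:       {self.fit2.h2:.4f} ({self.fit2.h2_se:.4f})\n"
                f"  genetic covariance: {self.gencov:.4f}\n"
                f"  cross intercept:  {self.gencov_intercept:.4f}\n"
                f"  r_g:              {self.rg:.4f} ({self.rg_se:.4f})")


def _h2_weights(ell, N, M, h2, intercept):
    e = intercept + N * np.clip(h2, 0, None) * ell / M
    return 1.0 / (np.maximum(ell, 1.0) * e ** 2)


def fit_h2(z: np.ndarray, ell: np.ndarray, N: float, M: int | None = None,
           n_blocks: int = DEFAULT_N_BLOCKS, chi2_max: float = DEFAULT_CHI2_MAX,
           min_snps: int = 200, weighting: str = "ldsc") -> LdscFit:
    """Estimate SNP heritability by regressing chi-squared on LD scores.

    Parameters
    ----------
    z, ell
        Per-SNP z-scores and matching LD scores, position-ordered.
    N
        GWAS sample size; ``M`` (default: number of SNPs supplied) is the
    number of SNPs the heritability refers to.
    weighting
        "ldsc" for the standard two-step weights, "ols" for an unweighted fit.
    """
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if len(z) != len(ell):
        raise ValueError("z and LD scores differ in length")
    if len(z) < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs for LD score regression")
    M = int(M) if M is not None else len(z)
    chi2 = z ** 2
    keep = chi2 <= chi2_max
    n_out = int((~keep).sum())
    if n_out:
        logger.info("excluding %d SNPs with chi2 > %g", n_out, chi2_max)
    x, y = ell[keep], chi2[keep]

    if weighting == "ols":
        w = np.ones(len(x))
        slope, intercept, s_se, i_se, reps = _weighted_line(x, y, w, n_blocks)
    else:
        w = _h2_weights(x, N, M, 0.0, 1.0)
        slope, intercept, *_ = _weighted_line(x, y, w, n_blocks)
        for _ in range(2):
            h2_cur = slope * M / N
            w = _h2_weights(x, N, M, h2_cur, max(intercept, 0.1))
            slope, intercept, s_se, i_se, reps = _weighted_line(x, y, w, n_blocks)

    h2 = slope * M / N
    h2_se = s_se * M / N
    if not 0 <= h2 <= 1:
        logger.warning("h2 estimate %.4f outside [0, 1]", h2)
    return LdscFit(slope, intercept, s_se, i_se, h2, h2_se, M, N, int(keep.sum()),
                   slope_reps=reps[:, 0] if reps is not None else None)


def fit_rg(z1: np.ndarray, z2: np.ndarray, ell: np.ndarray, N1: float, N2: float,
           M: int | None = None, n_blocks: int = DEFAULT_N_BLOCKS,
           chi2_max: float = DEFAULT_CHI2_MAX, min_snps: int = 200) -> RgFit:
    """Genetic correlation between two traits sharing a SNP set.

    Fits both single-trait regressions, then regresses z1*z2 on LD scores
    with a free cross-intercept (sample overlap is estimated, not assumed
    absent).  The jackknife recomputes all three regressions per deleted
    block, so the r_g standard error reflects the heritability uncertainty.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if not (len(z1) == len(z2) == len(ell)):
        raise ValueError("inputs differ in length")
    fit1 = fit_h2(z1, ell, N1, M, n_blocks, chi2_max, min_snps)
    fit2 = fit_h2(z2, ell, N2, M, n_blocks, chi2_max, min_snps)
    if fit1.h2 <= 0 or fit2.h2 <= 0:
        raise ValueError("nonpositive heritability estimate; r_g undefined")
    M = int(M) if M is not None else len(z1)

    keep = (z1 ** 2 <= chi2_max) & (z2 ** 2 <= chi2_max)
    x = ell[keep]
    y = (z1 * z2)[keep]
    rootN = np.sqrt(N1 * N2)

    # two-step weights from the product-moment variance approximation
    e1 = 1.0 + N1 * fit1.h2 * x / M
    e2 = 1.0 + N2 * fit2.h2 * x / M
    w = 1.0 / (np.maximum(x, 1.0) * (e1 * e2))
    slope, icpt, *_ = _weighted_line(x, y, w, n_blocks)
    ec = icpt + rootN * slope * x / M
    w = 1.0 / (np.maximum(x, 1.0) * (e1 * e2 + ec ** 2))
    slope, icpt, s_se, i_se, reps_x = _weighted_line(x, y, w, n_blocks)

    gencov = slope * M / rootN
    rg = gencov / np.sqrt(fit1.h2 * fit2.h2)

    # jackknife r_g: combine per-block slope replicates of all three fits
    r1, r2 = fit1.slope_reps, fit2.slope_reps
    rx = reps_x[:, 0]
    nb = min(len(r1), len(r2), len(rx))
    if nb > 1:
        h2_1r = r1[:nb] * fit1.M / N1
        h2_2r = r2[:nb] * fit2.M / N2
        gcr = rx[:nb] * M / rootN
        with np.errstate(invalid="ignore"):
            rg_reps = gcr / np.sqrt(np.clip(h2_1r, 1e-12, None)
                                    * np.clip(h2_2r, 1e-12, None))
        rg_se = float(np.sqrt((nb - 1) / nb * ((rg_reps - rg_reps.mean()) ** 2).sum()))
    else:
        rg_se = np.nan
    return RgFit(float(rg), rg_se, float(gencov), float(icpt), fit1, fit2,
                 int(keep.sum()))


# --- model/results interface ------------------------------------------------

class LdscModel:
    """LD score regression over a harmonized pair and its panel LD scores.

    Parameters
    ----------
    pair
        :class:`HarmonizedPair` (or DataFrame with beta/se/n columns per trait).
    ell
        Per-SNP LD scores aligned with the pair's rows.
    M
        SNP count the heritability refers to (default: rows of the pair).
    """

    def __init__(self, pair, ell: np.ndarray, M: int | None = None):
        self.df = pair.df if isinstance(pair, HarmonizedPair) else pair
        self.ell = np.asarray(ell, dtype=float)
        if len(self.ell) != len(self.df):
            raise ValueError("LD scores must align with the pair")
        self.M = M

    def fit(self, **kwargs) -> RgFit:
        df = self.df
        z1 = df["beta1"].to_numpy() / df["se1"].to_numpy()
        z2 = df["beta2"].to_numpy() / df["se2"].to_numpy()
        return fit_rg(z1, z2, self.ell, float(df["n1"].mean()),
                      float(df["n2"].mean()), self.M, **kwargs)
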