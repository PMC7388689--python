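"""Two-sample summary-data Mendelian randomization.

Instruments are exposure SNPs below a genome-wide p-value threshold, LD-pruned
against the reference panel, and harmonized with the outcome statistics.  The
primary estimator is fixed-effect inverse-variance weighting of per-SNP Wald
ratios, inflated multiplicatively when Cochran heterogeneity exceeds its
degrees of freedom; MR-Egger (weighted regression with a free intercept)
serves as the directional-pleiotropy sensitivity analysis.  The estimators
here are the field-standard reconstruction for this design; they are not tied
to any particular published protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ld import prune_mask
from .panel import GenotypePanel
from .sumstats import harmonize

logger = logging.getLogger(__name__)


@dataclass
class MrResult:
    """Pooled causal-effect estimate from one MR estimator."""

    method: str
    estimate: float
    se: float
    pvalue: float
    n_instruments: int
    heterogeneity_q: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_pvalue: float = np.nan

    def summary(self) -> str:
        lines = [
            f"Mendelian randomization ({self.method})",
            f"  instruments: {self.n_instruments}",
            f"  estimate:    {self.estimate:.4f} (se {self.se:.4f}, p {self.pvalue:.3g})",
        ]
        if np.isfinite(self.heterogeneity_q):
            lines.append(f"  Cochran Q:   {self.heterogeneity_q:.2f}")
        if self.method == "Egger":
            lines.append(f"  intercept:   {self.intercept:.4f} "
                         f"(se {self.intercept_se:.4f}, p {self.intercept_pvalue:.3g})")
        return "\n".join(lines)


def select_instruments(exposure: pd.DataFrame, panel: GenotypePanel,
                       alpha: float = 5e-8, window: int = 50, step: int = 5,
                       r2_max: float = 0.2) -> list[str]:
    """Genome-wide-significant, LD-pruned instrument SNP ids for the exposure."""
    sig = exposure[exposure["pvalue"] < alpha]
    if len(sig) == 0:
        raise ValueError(f"no exposure SNP below alpha = {alpha:g}; cannot instrument")
    sig = sig.sort_values(["chrom", "pos"], kind="stable")
    kept = prune_mask(panel, sig["snp_id"].to_numpy(), window, step, r2_max)
    ids = sig["snp_id"].to_numpy()[kept].tolist()
    logger.info("selected %d instruments from %d significant SNPs", len(ids), len(sig))
    return ids


def ivw(beta_x, se_x, beta_y, se_y) -> MrResult:
    """Fixed-effect inverse-variance-weighted causal estimate.

    estimate = sum(bx * by / sey^2) / sum(bx^2 / sey^2); with a single
    instrument this reduces to the Wald ratio by/bx.  When Cochran's
    Q/(n-1) exceeds 1 the standard error is inflated by sqrt(Q/(n-1))
    (multiplicative random effects).
    """
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    n = len(bx)
    if n == 0:
        raise ValueError("no instruments")
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero; Wald ratios undefined")
    w = bx ** 2 / sy ** 2
    est = float(np.sum(bx * by / sy ** 2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = np.nan
    if n > 1:
        ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
        q = float(np.sum(w * (ratios - est) ** 2))
        if q / (n - 1) > 1:
            se *= np.sqrt(q / (n - 1))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return MrResult("IVW", est, se, p, n, heterogeneity_q=q)


def egger(beta_x, se_x, beta_y, se_y) -> MrResult:
    """MR-Egger: weighted regression of outcome on exposure effects.

    The slope is the causal estimate; a nonzero intercept indicates
    directional pleiotropy.  Weights are 1/se_y^2.  Requires >= 3 instruments.
    """
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy ** 2).fit()
    icpt, slope = fit.params
    icpt_se, slope_se = fit.bse
    return MrResult("Egger", float(slope), float(slope_se),
                    float(fit.pvalues[1]), n,
                    intercept=float(icpt), intercept_se=float(icpt_se),
                    intercept_pvalue=float(fit.pvalues[0]))


# --- model/results interface ------------------------------------------------

class MrModel:
    """Two-sample MR of an exposure on an outcome with a reference panel.

    Harmonizes exposure and outcome tables, selects genome-wide significant
    pruned instruments from the exposure, and pools Wald ratios.
    """

    def __init__(self, exposure: pd.DataFrame, outcome: pd.DataFrame,
                 panel: GenotypePanel, alpha: float = 5e-8,
                 window: int = 50, step: int = 5, r2_max: float = 0.2):
        self.exposure = exposure
        self.outcome = outcome
        self.panel = panel
        self.alpha = alpha
        self.prune_params = (window, step, r2_max)

    def instrument_table(self) -> pd.DataFrame:
        ids = select_instruments(self.exposure, self.panel, self.alpha,
                                 *self.prune_params)
        pair = harmonize(self.exposure[self.exposure["snp_id"].isin(ids)],
                         self.outcome)
        df = pair.df
        if len(df) == 0:
            raise ValueError("no instrument survives harmonization with the outcome")
        out = df[["snp_id", "chrom", "pos"]].copy()
        out["beta_x"] = df["beta1"].to_numpy()
        out["se_x"] = df["se1"].to_numpy()
        out["beta_y"] = df["beta2"].to_numpy()
        out["se_y"] = df["se2"].to_numpy()
        bx = out["beta_x"].to_numpy()
        out["wald_ratio"] = np.divide(out["beta_y"], bx,
                                      out=np.full(len(out), np.nan), where=bx != 0)
        return out

    def fit(self, method: str = "ivw") -> MrResult | dict[str, MrResult]:
        inst = self.instrument_table()
        args = (inst["beta_x"], inst["se_x"], inst["beta_y"], inst["se_y"])
        if method == "ivw":
            return ivw(*args)
        if method == "egger":
            return egger(*args)
        if method == "both":
            return {"ivw": ivw(*args), "egger": egger(*args)}
        raise ValueError(f"unknown MR method {method!r}")
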