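"""Linkage-disequilibrium utilities computed on a reference panel.

r-squared is the squared Pearson correlation of genotype dosages.  Pruning
follows the classic windowed greedy recipe (window of 50 SNPs, step 5,
r2 > 0.2 removes the lower-MAF member of the pair), iterated to a fixed
point.  LD scores sum bias-adjusted r-squared over a physical window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)


def _std_dosages(panel: GenotypePanel) -> np.ndarray:
    """Column-standardized dosage matrix; monomorphic columns become 0."""
    X = panel.dosages
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[:, sd == 0] = 0.0
    return Z


def r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared dosage correlation between panel SNPs i and j.

    Monomorphic SNPs have undefined correlation; it is reported as 0 with a
    warning so downstream pruning treats them as unlinked.
    """
    n = panel.n_snps
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("SNP index out of range")
    if i == j:
        return 1.0
    x, y = panel.dosages[:, i], panel.dosages[:, j]
    if x.std() == 0 or y.std() == 0:
        logger.warning("monomorphic SNP in r2(%d, %d); returning 0", i, j)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _prune_window(r2mat: np.ndarray, mafs: np.ndarray, kept: np.ndarray,
                  r2_max: float) -> bool:
    """Greedy in-place pruning of one window; pairs scanned in position order.

    Returns True if any SNP was removed.  Ties on MAF remove the later SNP.
    """
    w = len(mafs)
    changed = False
    for i in range(w):
        if not kept[i]:
            continue
        for j in range(i + 1, w):
            if not kept[j] or r2mat[i, j] <= r2_max:
                continue
            if mafs[i] < mafs[j]:
                kept[i] = False
                changed = True
                break
            else:  # equal MAFs drop the later (j) SNP
                kept[j] = False
                changed = True
        if not kept[i]:
            continue
    return changed


def prune_mask(panel: GenotypePanel, snp_ids, window: int = 50, step: int = 5,
               r2_max: float = 0.2) -> np.ndarray:
    """Boolean keep-mask over ``snp_ids`` after windowed LD pruning.

    ``snp_ids`` must be ordered by position within chromosome.  SNPs absent
    from the panel pass through untouched (with a warning).  The window scan
    is repeated until no pair of retained SNPs inside any window exceeds
    ``r2_max`` (fixed point).
    """
    snp_ids = np.asarray(snp_ids, dtype=object)
    cols = panel.indices_of(snp_ids)
    covered = cols >= 0
    if not covered.all():
        logger.warning("%d SNPs absent from panel pass through pruning",
                       int((~covered).sum()))
    kept = np.ones(len(snp_ids), dtype=bool)
    if covered.sum() < 2:
        return kept

    sub = np.flatnonzero(covered)          # indices into snp_ids
    Z = _std_dosages(panel)[:, cols[sub]]  # individuals x covered SNPs
    n = Z.shape[0]
    mafs = panel.maf[cols[sub]]
    chroms = panel.chrom[cols[sub]]

    while True:
        changed = False
        for c in pd.unique(chroms):
            on_c = np.flatnonzero(chroms == c)
            alive = on_c[kept[sub[on_c]]]
            if len(alive) < 2:
                continue
            for start in range(0, len(alive), step):
                widx = alive[start:start + window]
                if len(widx) < 2:
                    break
                Zw = Z[:, widx]
                r2mat = (Zw.T @ Zw / n) ** 2
                wkept = np.ones(len(widx), dtype=bool)
                if _prune_window(r2mat, mafs[widx], wkept, r2_max):
                    kept[sub[widx[~wkept]]] = False
                    changed = True
                if start + window >= len(alive):
                    break
        if not changed:
            break
    return kept


def ld_prune(pair: HarmonizedPair, panel: GenotypePanel, window: int = 50,
             step: int = 5, r2_max: float = 0.2) -> HarmonizedPair:
    """Prune a harmonized pair with the windowed lower-MAF-exclusion rule."""
    if len(pair) == 0:
        return pair
    kept = prune_mask(panel, pair.df["snp_id"].to_numpy(), window, step, r2_max)
    out = pair.subset(kept)
    out.audit["n_pruned_out"] = int((~kept).sum())
    out.audit["n_after_prune"] = int(kept.sum())
    logger.info("ld_prune: kept %d of %d SNPs", kept.sum(), len(kept))
    return out


def ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000) -> np.ndarray:
    """Per-SNP LD score: sum of adjusted r2 to all SNPs within ``window_bp``.

    The small-sample bias adjustment ``r2_adj = r2 - (1 - r2)/(n - 2)`` keeps
    the score unbiased for the population LD score; the self term contributes
    exactly 1.  Requires at least 3 panel individuals.
    """
    n = panel.n_individuals
    if n < 3:
        raise ValueError("LD scores need at least 3 panel individuals")
    Z = _std_dosages(panel)
    m = panel.n_snps
    ell = np.ones(m)  # self term: r2 = 1, adjustment vanishes
    chroms, pos = panel.chrom, panel.pos
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        p = pos[idx]
        Zc = Z[:, idx]
        mc = len(idx)
        d = 1
        while d < mc:
            lag_ok = p[d:] - p[:-d] <= window_bp
            if not lag_ok.any():
                break
            r = (Zc[:, :-d] * Zc[:, d:]).sum(axis=0) / n
            r2v = r * r
            r2adj = np.where(lag_ok, r2v - (1 - r2v) / (n - 2), 0.0)
            ell[idx[:-d]] += r2adj
            ell[idx[d:]] += r2adj
            d += 1
    # negative adjusted terms can push the sum below the self term; a score
    # under 1 is impossible in the population, so floor at the self term
    return np.maximum(ell, 1.0)
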