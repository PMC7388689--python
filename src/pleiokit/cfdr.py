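"""Conditional and conjunction FDR from two traits' p-values.

The conditional FDR of SNP i for a principal trait given a conditional trait
is the empirical dominance-count ratio

    cFDR_i = min(1, p1_i * #{j : p2_j <= p2_i} / #{j : p1_j <= p1_i, p2_j <= p2_i})

with counts inclusive of SNP i itself, so the denominator is at least 1.  The
conjunction FDR is the maximum of the two directional cFDRs and flags SNPs
associated with both traits.  Significance cutoffs are data-driven: the
largest cFDR among SNPs that are genome-wide significant in the principal
trait.

The fast path counts two-dimensional dominance with a Fenwick tree in
O(N log N); an O(N^2) brute-force oracle lives in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

#: conditional-trait p-value strata used for QQ and enrichment diagnostics
DEFAULT_CUTOFFS = (1.0, 0.1, 0.01, 0.001, 0.0001)

GW_ALPHA = 5e-8


class _Fenwick:
    """Binary indexed tree over ranks 1..n for prefix counts."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:
        t = self.tree
        while i <= self.n:
            t[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        t = self.tree
        s = 0
        while i > 0:
            s += t[i]
            i -= i & (-i)
        return int(s)


def _dominance_counts(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """#{j : p1_j <= p1_i and p2_j <= p2_i} for every i, ties inclusive."""
    n = len(p1)
    # rank p2 with ties sharing the highest rank so <= comparisons are exact
    uniq2 = np.unique(p2)
    rank2 = np.searchsorted(uniq2, p2) + 1
    order = np.argsort(p1, kind="stable")
    p1s = p1[order]
    bit = _Fenwick(len(uniq2))
    both = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and p1s[j] == p1s[i]:
            j += 1
        for k in range(i, j):          # insert the whole p1-tie group first
            bit.add(int(rank2[order[k]]))
        for k in range(i, j):
            both[order[k]] = bit.prefix(int(rank2[order[k]]))
        i = j
    return both


def cfdr_values(p_principal: np.ndarray, p_conditional: np.ndarray) -> np.ndarray:
    """Per-SNP conditional FDR of the principal trait given the conditional one."""
    p1 = np.asarray(p_principal, dtype=float)
    p2 = np.asarray(p_conditional, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must have equal length")
    if len(p1) == 0:
        raise ValueError("cannot compute cFDR on an empty SNP set")
    if len(p1) == 1:
        return np.minimum(1.0, p1.copy())
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n2 = np.searchsorted(np.sort(p2), p2, side="right")
    both = _dominance_counts(p1, p2)
    return np.minimum(1.0, p1 * n2 / both)


def ccfdr_values(cfdr_1g2: np.ndarray, cfdr_2g1: np.ndarray) -> np.ndarray:
    """Conjunction FDR: maximum of the two directional cFDRs, SNP-wise."""
    a = np.asarray(cfdr_1g2, dtype=float)
    b = np.asarray(cfdr_2g1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("directional cFDRs computed on mismatched SNP sets")
    return np.maximum(a, b)


def cfdr_threshold(cfdr: np.ndarray, p_principal: np.ndarray,
                   gw_alpha: float = GW_ALPHA) -> float:
    """Data-driven significance cutoff for cFDR.

    The cutoff is the maximum cFDR among SNPs whose principal-trait p-value
    is below ``gw_alpha``; SNPs with cFDR strictly below it are then called
    significant.
    """
    cfdr = np.asarray(cfdr, dtype=float)
    p = np.asarray(p_principal, dtype=float)
    qual = p < gw_alpha
    if not qual.any():
        raise ValueError(
            "no SNP reaches genome-wide significance in the principal trait; "
            "supply a manual cFDR cutoff instead")
    return float(cfdr[qual].max())


def stratified_qq(p_principal: np.ndarray, p_conditional: np.ndarray,
                  cutoffs=DEFAULT_CUTOFFS) -> dict[float, pd.DataFrame]:
    """Stratified QQ data: one ECDF curve per conditional-trait stratum.

    For each cutoff t, SNPs with conditional p <= t form a stratum; the curve
    gives (empirical CDF position, -log10 principal p) sorted by ascending
    principal p-value.  Leftward deflection of strict strata from the t = 1
    baseline indicates pleiotropic enrichment.  Empty strata are skipped.
    """
    p1 = np.asarray(p_principal, dtype=float)
    p2 = np.asarray(p_conditional, dtype=float)
    out: dict[float, pd.DataFrame] = {}
    for t in cutoffs:
        sel = p2 <= t
        k = int(sel.sum())
        if k == 0:
            logger.warning("stratum p2 <= %g is empty; skipped", t)
            continue
        ps = np.sort(p1[sel])
        out[t] = pd.DataFrame({
            "ecdf": np.arange(1, k + 1) / k,
            "neglog10_p": -np.log10(ps),
        })
    return out


def fold_enrichment(p_principal: np.ndarray, p_conditional: np.ndarray,
                    cutoffs=DEFAULT_CUTOFFS, gw_alpha: float = GW_ALPHA,
                    x_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Fold enrichment of principal-trait tail probability within strata.

    enrichment(t, x) = [#{p1 <= 10^-x, p2 <= t} / #{p2 <= t}]
                       / [#{p1 <= 10^-x} / N].

    The t = 1 stratum is identically 1.  Grid points with an empty stratum or
    an empty overall tail are omitted.  Returns a long-format table with
    columns cutoff, x, enrichment.
    """
    p1 = np.asarray(p_principal, dtype=float)
    p2 = np.asarray(p_conditional, dtype=float)
    if x_grid is None:
        x_grid = np.arange(0.0, -np.log10(gw_alpha) + 0.05, 0.25)
    N = len(p1)
    rows = []
    for t in cutoffs:
        sel = p2 <= t
        denom_strat = int(sel.sum())
        if denom_strat == 0:
            continue
        for x in x_grid:
            thr = 10.0 ** (-x)
            overall = int((p1 <= thr).sum())
            if overall == 0:
                continue
            inside = int((p1[sel] <= thr).sum())
            rows.append((t, float(x), (inside / denom_strat) / (overall / N)))
    return pd.DataFrame(rows, columns=["cutoff", "x", "enrichment"])


def conjunction_manhattan_data(ccfdr: np.ndarray, chrom, pos,
                               cutoff: float) -> tuple[pd.DataFrame, float]:
    """Plot-ready conjunction Manhattan table with cumulative coordinates.

    Returns (table, threshold_y) where the table carries the genomic x offset
    (chromosomes laid end to end in sorted order) and y = -log10 ccFDR, and
    threshold_y = -log10 of the significance cutoff.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    ccfdr = np.asarray(ccfdr, dtype=float)

    def chrom_key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    x = np.empty(len(pos), dtype=np.int64)
    offset = 0
    for c in sorted(set(chrom), key=chrom_key):
        sel = chrom == c
        x[sel] = pos[sel] + offset
        offset += int(pos[sel].max()) + 1
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "x": x,
                       "neglog10_ccfdr": -np.log10(ccfdr)})
    return df, float(-np.log10(cutoff))


# --- model/results interface ------------------------------------------------

@dataclass
class CfdrResults:
    """Fitted conditional-FDR analysis of a harmonized trait pair.

    ``table`` has one row per SNP with both directional cFDRs, the
    conjunction FDR and significance flags.  ``cutoff_1g2``/``cutoff_2g1``
    are the data-driven directional thresholds; ``cutoff_cc`` is applied to
    the conjunction FDR.
    """

    table: pd.DataFrame
    cutoff_1g2: float
    cutoff_2g1: float
    cutoff_cc: float
    gw_alpha: float
    model: "CfdrModel" = field(repr=False, default=None)

    @property
    def n_sig_1g2(self) -> int:
        return int(self.table["sig_1g2"].sum())

    @property
    def n_sig_2g1(self) -> int:
        return int(self.table["sig_2g1"].sum())

    @property
    def n_sig_cc(self) -> int:
        return int(self.table["sig_cc"].sum())

    def manhattan_data(self):
        t = self.table
        return conjunction_manhattan_data(t["ccfdr"].to_numpy(),
                                          t["chrom"].to_numpy(),
                                          t["pos"].to_numpy(), self.cutoff_cc)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Conditional FDR analysis",
            "========================",
            f"SNPs analysed:                 {len(t)}",
            f"genome-wide alpha:             {self.gw_alpha:g}",
            f"cFDR cutoff trait1|trait2:     {self.cutoff_1g2:.3g}"
            f"  ({self.n_sig_1g2} significant)",
            f"cFDR cutoff trait2|trait1:     {self.cutoff_2g1:.3g}"
            f"  ({self.n_sig_2g1} significant)",
            f"ccFDR cutoff:                  {self.cutoff_cc:.3g}"
            f"  ({self.n_sig_cc} significant)",
        ]
        return "\n".join(lines)


class CfdrModel:
    """Conditional/conjunction FDR model over a harmonized pair of GWAS.

    Parameters
    ----------
    pair
        :class:`~pleiokit.sumstats.HarmonizedPair` (ideally LD-pruned) or a
        DataFrame with at least snp_id, chrom, pos, p1, p2 columns.
    gw_alpha
        Genome-wide significance level defining the data-driven cutoffs.
    """

    def __init__(self, pair, gw_alpha: float = GW_ALPHA):
        self.df = pair.df if isinstance(pair, HarmonizedPair) else pair
        self.gw_alpha = float(gw_alpha)

    def fit(self, cc_cutoff: str | float = "max",
            manual_cutoffs: tuple[float, float] | None = None) -> CfdrResults:
        """Compute both directional cFDRs, the ccFDR, cutoffs and flags.

        ``cc_cutoff``: "max" (default) applies max(cutoff_1g2, cutoff_2g1)
        to the conjunction FDR; a float overrides it; "1g2"/"2g1" use a
        single direction's cutoff.  ``manual_cutoffs`` bypasses the
        data-driven rule entirely (needed when no SNP is genome-wide
        significant).
        """
        df = self.df
        p1 = df["p1"].to_numpy(dtype=float)
        p2 = df["p2"].to_numpy(dtype=float)
        c12 = cfdr_values(p1, p2)
        c21 = cfdr_values(p2, p1)
        cc = ccfdr_values(c12, c21)
        if manual_cutoffs is not None:
            cut12, cut21 = map(float, manual_cutoffs)
        else:
            cut12 = cfdr_threshold(c12, p1, self.gw_alpha)
            cut21 = cfdr_threshold(c21, p2, self.gw_alpha)
        if cc_cutoff == "max":
            cutcc = max(cut12, cut21)
        elif cc_cutoff == "1g2":
            cutcc = cut12
        elif cc_cutoff == "2g1":
            cutcc = cut21
        else:
            cutcc = float(cc_cutoff)

        table = df[["snp_id", "chrom", "pos"]].copy()
        table["p1"] = p1
        table["p2"] = p2
        table["cfdr_1g2"] = c12
        table["cfdr_2g1"] = c21
        table["ccfdr"] = cc
        table["sig_1g2"] = c12 < cut12
        table["sig_2g1"] = c21 < cut21
        table["sig_cc"] = cc < cutcc
        return CfdrResults(table, cut12, cut21, cutcc, self.gw_alpha, model=self)

    def stratified_qq(self, principal: int = 1, cutoffs=DEFAULT_CUTOFFS):
        p1 = self.df["p1"].to_numpy(dtype=float)
        p2 = self.df["p2"].to_numpy(dtype=float)
        pp, pc = (p1, p2) if principal == 1 else (p2, p1)
        return stratified_qq(pp, pc, cutoffs)

    def fold_enrichment(self, principal: int = 1, cutoffs=DEFAULT_CUTOFFS,
                        gw_alpha: float | None = None, x_grid=None):
        p1 = self.df["p1"].to_numpy(dtype=float)
        p2 = self.df["p2"].to_numpy(dtype=float)
        pp, pc = (p1, p2) if principal == 1 else (p2, p1)
        return fold_enrichment(pp, pc, cutoffs,
                               gw_alpha or self.gw_alpha, x_grid)
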