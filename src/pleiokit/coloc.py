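"""Pairwise regional Bayesian colocalization over five hypotheses.

Each genomic region is scored under five mutually exclusive models:

* model 0 — no association with either trait,
* model 1 — one causal SNP for trait 1 only,
* model 2 — one causal SNP for trait 2 only,
* model 3 — a single causal SNP shared by both traits,
* model 4 — two distinct causal SNPs, one per trait.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from the
effect estimate and its standard error under a Gaussian effect prior
(variance averaged over a small grid).  Regional Bayes factors average the
per-SNP (or per-SNP-pair) ABFs assuming each causal configuration within the
region is a priori equally likely.  Genome-wide model weights are estimated
by empirical-Bayes EM across regions, and per-region posterior probabilities
PP0-PP4 follow.  All arithmetic is on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel import BlockPartition, assign_blocks
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)


@dataclass
class AbfConfig:
    """Gaussian effect-size prior for the Wakefield ABF.

    ``prior_variances`` are averaged (mixture of equally weighted priors);
    the defaults suit continuous traits on a standardized scale.
    """

    prior_variances: tuple[float, ...] = (0.01, 0.1, 0.5)

    def __post_init__(self):
        if any(w <= 0 for w in self.prior_variances):
            raise ValueError("prior variances must be positive")


@dataclass
class ModelPriors:
    """Genome-wide prior weights of the five regional models (5-simplex)."""

    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (5,) or np.any(self.pi < 0) or abs(self.pi.sum() - 1) > 1e-9:
            raise ValueError("priors must be 5 nonnegative weights summing to 1")

    @classmethod
    def flat(cls) -> "ModelPriors":
        return cls(np.full(5, 0.2))


def wakefield_log_abf(beta, se, cfg: AbfConfig | None = None) -> np.ndarray:
    """Log approximate Bayes factor for association, per SNP.

    With V = se^2, z = beta/se and r = W/(V+W):

        ABF_W = sqrt(1 - r) * exp(r * z^2 / 2)

    averaged over the prior-variance grid W, stably on the log scale.
    """
    cfg = cfg or AbfConfig()
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("non-finite effect estimate or standard error")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se ** 2
    z2 = (beta / se) ** 2
    parts = []
    for W in cfg.prior_variances:
        r = W / (V + W)
        parts.append(0.5 * np.log1p(-r) + 0.5 * r * z2)
    stacked = np.stack(parts, axis=0)
    return logsumexp(stacked, axis=0) - np.log(len(cfg.prior_variances))


def regional_log_bfs(labf1: np.ndarray, labf2: np.ndarray) -> np.ndarray:
    """Log regional Bayes factors (models 1-4) from per-SNP log ABF pairs.

    With k SNPs and per-SNP ABFs a_i (trait 1) and b_i (trait 2):

        RBF1 = mean_i a_i            RBF2 = mean_i b_i
        RBF3 = mean_i a_i b_i        RBF4 = mean_{i != j} a_i b_j

    A single-SNP region cannot host two distinct causal SNPs, so its
    log-RBF4 is -inf.
    """
    a = np.asarray(labf1, dtype=float)
    b = np.asarray(labf2, dtype=float)
    k = len(a)
    if k == 0:
        raise ValueError("empty region")
    if len(b) != k:
        raise ValueError("trait ABF vectors differ in length")
    logk = np.log(k)
    lsa = logsumexp(a)
    lsb = logsumexp(b)
    lrbf1 = lsa - logk
    lrbf2 = lsb - logk
    s = logsumexp(a + b)
    lrbf3 = s - logk
    if k == 1:
        lrbf4 = -np.inf
    else:
        t = lsa + lsb
        if s < t - 1e-10:
            lrbf4 = t + np.log1p(-np.exp(s - t)) - np.log(k * (k - 1))
        else:  # near-cancellation: sum the off-diagonal pair matrix directly
            M = a[:, None] + b[None, :]
            np.fill_diagonal(M, -np.inf)
            lrbf4 = logsumexp(M) - np.log(k * (k - 1))
    return np.array([lrbf1, lrbf2, lrbf3, lrbf4])


def estimate_priors(log_rbfs: np.ndarray, max_iter: int = 1000,
                    tol: float = 1e-8, dirichlet_alpha: float = 1.1
                    ) -> tuple[ModelPriors, np.ndarray]:
    """Empirical-Bayes genome-wide model weights by EM over regions.

    Maximizes sum_r log(sum_m pi_m RBF_{m,r}) (RBF0 = 1) over the 5-simplex,
    with a symmetric Dirichlet(``dirichlet_alpha``) penalty keeping weights
    off the boundary.  Returns the priors and the per-iteration penalized
    objective trace (nondecreasing by the EM property).
    """
    lB = np.asarray(log_rbfs, dtype=float)
    if lB.ndim != 2 or lB.shape[1] != 4:
        raise ValueError("log_rbfs must be (n_regions, 4)")
    R = lB.shape[0]
    if R < 10:
        logger.warning("estimating priors from only %d regions", R)
    lB5 = np.column_stack([np.zeros(R), lB])
    a = dirichlet_alpha - 1.0
    pi = np.full(5, 0.2)
    trace = []
    prev = -np.inf
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            lw = np.log(pi)[None, :] + lB5
        norm = logsumexp(lw, axis=1)
        obj = float(norm.sum() + a * np.sum(np.log(np.maximum(pi, 1e-300))))
        trace.append(obj)
        gamma = np.exp(lw - norm[:, None])
        pi = (gamma.sum(axis=0) + a) / (R + 5 * a)
        if obj - prev < tol and it > 0:
            break
        prev = obj
    else:
        logger.warning("prior EM did not converge in %d iterations", max_iter)
    return ModelPriors(pi), np.asarray(trace)


def region_posteriors(log_rbfs: np.ndarray, priors: ModelPriors) -> np.ndarray:
    """Posterior probabilities PP0-PP4 for one region or a stack of regions."""
    lB = np.asarray(log_rbfs, dtype=float)
    single = lB.ndim == 1
    lB = np.atleast_2d(lB)
    lB5 = np.column_stack([np.zeros(lB.shape[0]), lB])
    with np.errstate(divide="ignore"):
        lw = np.log(priors.pi)[None, :] + lB5
    pp = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    return pp[0] if single else pp


def top_snp(labf1: np.ndarray, labf2: np.ndarray, model: int,
            snp_ids) -> tuple | None:
    """Putative causal SNP under the best-supported single-causal model.

    Per-SNP weights are proportional to ABF1 (model 1), ABF2 (model 2) or
    ABF1*ABF2 (model 3), normalized within the region; the argmax SNP and
    its within-region posterior are returned.  Ties take the first SNP in
    input (position) order.  Models 0 and 4 have no single shared causal
    SNP and return None; callers report model 4 per trait via models 1 and 2.
    """
    if model not in (1, 2, 3):
        return None
    snp_ids = np.asarray(snp_ids, dtype=object)
    if model == 1:
        lw = np.asarray(labf1, dtype=float)
    elif model == 2:
        lw = np.asarray(labf2, dtype=float)
    else:
        lw = np.asarray(labf1, dtype=float) + np.asarray(labf2, dtype=float)
    post = np.exp(lw - logsumexp(lw))
    i = int(np.argmax(post))
    return str(snp_ids[i]), float(post[i])


def classify_regions(pp: np.ndarray, pp_cutoff: float = 0.9) -> np.ndarray:
    """Assign each region to the model whose posterior strictly exceeds the cutoff.

    Returns -1 for unclassified regions (no model above the cutoff).
    """
    pp = np.atleast_2d(np.asarray(pp, dtype=float))
    best = pp.argmax(axis=1)
    assigned = np.where(pp[np.arange(len(pp)), best] > pp_cutoff, best, -1)
    return assigned


# --- model/results interface ------------------------------------------------

@dataclass
class ColocResults:
    """Per-region colocalization evidence and genome-wide priors.

    ``regions`` has one row per region: SNP count, log regional Bayes
    factors, posteriors PP0-PP4, the maximum-a-posteriori model and the
    putative causal SNP (with its within-region posterior) when the MAP
    model is 1, 2 or 3; for model 4, per-trait top SNPs.
    """

    regions: pd.DataFrame
    priors: ModelPriors
    em_trace: np.ndarray = field(repr=False, default=None)

    def classify(self, pp_cutoff: float = 0.9) -> dict[int, list]:
        """Region ids per model at the posterior cutoff (strict inequality)."""
        pp = self.regions[[f"pp{m}" for m in range(5)]].to_numpy()
        assigned = classify_regions(pp, pp_cutoff)
        return {m: self.regions["region"].to_numpy()[assigned == m].tolist()
                for m in range(5)}

    def summary(self, pp_cutoff: float = 0.9) -> str:
        counts = {m: len(v) for m, v in self.classify(pp_cutoff).items()}
        lines = [
            "Regional colocalization (five hypotheses)",
            "=========================================",
            f"regions analysed:       {len(self.regions)}",
            "priors (PI0..PI4):      " + " ".join(f"{p:.4f}" for p in self.priors.pi),
            f"regions with PP_m > {pp_cutoff:g}:",
        ]
        for m in range(5):
            lines.append(f"  model {m}: {counts[m]}")
        return "\n".join(lines)


class ColocModel:
    """Five-hypothesis regional colocalization of a harmonized trait pair.

    Parameters
    ----------
    pair
        Harmonized pair (unpruned by default: the regional model wants the
        dense signal) or a DataFrame with beta1/se1/beta2/se2 columns and
        either a precomputed ``region`` column or chrom/pos for assignment.
    blocks
        Optional :class:`BlockPartition`; required unless ``pair`` already
        carries a ``region`` column.
    """

    def __init__(self, pair, blocks: BlockPartition | None = None,
                 abf_config: AbfConfig | None = None):
        df = pair.df if isinstance(pair, HarmonizedPair) else pair
        df = df.copy()
        if "region" not in df.columns:
            if blocks is None:
                raise ValueError("need a BlockPartition or a 'region' column")
            df["region"] = assign_blocks(df, blocks)
            df = df[df["region"] >= 0]
        self.df = df.reset_index(drop=True)
        self.abf_config = abf_config or AbfConfig()

    def fit(self, priors: ModelPriors | None = None) -> ColocResults:
        """Score every region; estimate priors by EM unless fixed ones are given.

        Regions with a single SNP are reported but excluded from prior
        estimation (their model-4 Bayes factor is degenerate).
        """
        df = self.df
        labf1 = wakefield_log_abf(df["beta1"].to_numpy(), df["se1"].to_numpy(),
                                  self.abf_config)
        labf2 = wakefield_log_abf(df["beta2"].to_numpy(), df["se2"].to_numpy(),
                                  self.abf_config)
        region_ids = df["region"].to_numpy()
        uniq = pd.unique(region_ids)
        rows = []
        per_region = {}
        for r in uniq:
            sel = np.flatnonzero(region_ids == r)
            lr = regional_log_bfs(labf1[sel], labf2[sel])
            per_region[r] = (sel, lr)
            rows.append(lr)
        lrbfs = np.vstack(rows)
        multi = np.array([len(per_region[r][0]) > 1 for r in uniq])

        em_trace = None
        if priors is None:
            priors, em_trace = estimate_priors(lrbfs[multi]) if multi.any() \
                else (ModelPriors.flat(), None)
        pp = region_posteriors(lrbfs, priors)

        out = []
        snp_ids = df["snp_id"].to_numpy()
        for i, r in enumerate(uniq):
            sel, lr = per_region[r]
            map_model = int(pp[i].argmax())
            rec = {"region": r, "n_snps": len(sel),
                   **{f"log_rbf{m}": lr[m - 1] for m in range(1, 5)},
                   **{f"pp{m}": pp[i, m] for m in range(5)},
                   "map_model": map_model,
                   "top_snp": None, "top_posterior": np.nan,
                   "top_snp_t1": None, "top_snp_t2": None}
            if map_model in (1, 2, 3):
                sid, post = top_snp(labf1[sel], labf2[sel], map_model, snp_ids[sel])
                rec["top_snp"], rec["top_posterior"] = sid, post
            elif map_model == 4:
                rec["top_snp_t1"] = top_snp(labf1[sel], labf2[sel], 1, snp_ids[sel])[0]
                rec["top_snp_t2"] = top_snp(labf1[sel], labf2[sel], 2, snp_ids[sel])[0]
            out.append(rec)
        return ColocResults(pd.DataFrame(out), priors, em_trace)
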