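"""Synthetic GWAS data with known pleiotropy structure.

Emulates the inputs of a two-trait pleiotropy analysis end to end: a reference
haplotype panel with block-diagonal LD (latent-Gaussian AR(1) within blocks,
independence across blocks), paired summary statistics drawn from a
four-component effect mixture (null / trait-1-only / trait-2-only / shared),
and an outcome trait causally downstream of trait 1 for Mendelian
randomization.  Every generator is a pure function of the configuration and
its seed.

Effect sizes are drawn on the standardized-genotype scale (``b``; per-allele
``beta = b / sqrt(2 f (1-f))``) and rescaled so each trait's realized
heritability ``sum(b^2)`` matches its target exactly.  Observed z-scores are
``sqrt(N) * (R b) + N(0, 1)`` where ``R`` is the within-block panel
correlation, so marginal associations are LD-smeared exactly as a GWAS sees
them, and reported standard errors follow the quantitative-trait
approximation ``se = 1 / sqrt(2 N f (1-f))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .panel import BlockPartition, GenotypePanel
from .sumstats import MIN_PVALUE

_STREAMS = {"panel": 1, "effects": 2, "sumstats1": 3, "sumstats2": 4,
            "outcome": 5, "regions": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the paired-GWAS simulation.

    The defaults describe a modestly powered pair of quantitative-trait GWAS:
    20,000 SNPs in 50-SNP LD blocks, 50,000 samples per trait, 30% SNP
    heritability each, 5% of SNPs affecting both traits with effect-size
    correlation 0.5, and a downstream outcome with causal effect 0.5 of
    trait 1.
    """

    m_snps: int = 20_000
    n1: int = 50_000
    n2: int = 50_000
    n_outcome: int = 50_000
    n_panel: int = 400            # haplotypes; individuals = n_panel // 2
    block_sizes: list[int] | None = None   # default: equal blocks of 50
    rho_ld: float = 0.8
    pi: tuple[float, float, float, float] = (0.85, 0.05, 0.05, 0.05)
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg_shared: float = 0.5
    gamma_causal: float = 0.5
    pleiotropy_sd: float = 0.0    # direct outcome effects unrelated to trait 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_spacing: int = 5_000
    block_gap_bp: int = 1_100_000   # keeps distinct LD blocks out of each
                                    # other's 1 Mb LD-score windows
    n_chrom: int = 2
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ValueError("mixture proportions pi must sum to 1")
        if any(p < 0 for p in self.pi):
            raise ValueError("mixture proportions must be nonnegative")
        for name in ("m_snps", "n1", "n2", "n_outcome", "n_panel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.rho_ld < 1):
            raise ValueError("rho_ld must lie in [0, 1)")
        if not (0 <= self.h2_1 < 1 and 0 <= self.h2_2 < 1):
            raise ValueError("heritabilities must lie in [0, 1)")
        if not (-1 <= self.rg_shared <= 1):
            raise ValueError("rg_shared must lie in [-1, 1]")
        self.resolved_block_sizes()

    def resolved_block_sizes(self) -> np.ndarray:
        if self.block_sizes is not None:
            sizes = np.asarray(self.block_sizes, dtype=int)
            if sizes.sum() != self.m_snps:
                raise ValueError("block_sizes must sum to m_snps")
            return sizes
        full, rem = divmod(self.m_snps, 50)
        sizes = [50] * full + ([rem] if rem else [])
        return np.asarray(sizes, dtype=int)

    def block_index(self) -> np.ndarray:
        sizes = self.resolved_block_sizes()
        return np.repeat(np.arange(len(sizes)), sizes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-SNP components/effects, per-block model.

    ``df`` columns: snp_id, chrom, pos, freq, block, component (0 null,
    1 trait-1-only, 2 trait-2-only, 3 shared), per-allele true effects
    beta1/beta2, standardized effects b1/b2 and their LD-smeared marginal
    counterparts b1_marg/b2_marg.  ``region_model`` holds, per block, the
    colocalization hypothesis the block truly realizes (0-4).
    """

    df: pd.DataFrame
    region_model: np.ndarray = field(default=None)


def simulate_panel(cfg: SimulationConfig) -> GenotypePanel:
    """Draw a reference panel with AR(1) latent-Gaussian LD within blocks.

    Haplotype alleles are thresholded latent Gaussians: within a block the
    latents follow an AR(1) chain with parameter ``rho_ld``; across blocks
    they are independent.  Allele frequencies are Uniform over ``maf_range``.
    Pairs of haplotypes form diploid dosages.
    """
    rng = _rng(cfg.seed, "panel")
    sizes = cfg.resolved_block_sizes()
    m = cfg.m_snps
    n_hap = cfg.n_panel
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresholds = stats.norm.ppf(freqs)

    hap = np.empty((n_hap, m), dtype=np.int8)
    col = 0
    for size in sizes:
        latent = np.empty((n_hap, size))
        latent[:, 0] = rng.standard_normal(n_hap)
        innov = rng.standard_normal((n_hap, size - 1)) if size > 1 else None
        for t in range(1, size):
            latent[:, t] = cfg.rho_ld * latent[:, t - 1] + \
                np.sqrt(1 - cfg.rho_ld ** 2) * innov[:, t - 1]
        hap[:, col:col + size] = latent < thresholds[col:col + size][None, :]
        col += size

    # guard against sample-monomorphic columns (maf invariant requires > 0)
    mono = hap.min(axis=0) == hap.max(axis=0)
    if mono.any():
        for j in np.flatnonzero(mono):
            hap[0, j] = 1 - hap[0, j]

    dos = hap[0::2].astype(np.float64) + hap[1::2].astype(np.float64)

    blocks = cfg.block_index()
    n_blocks = blocks.max() + 1
    chrom_of_block = (np.arange(n_blocks) * cfg.n_chrom // max(n_blocks, 1)) + 1
    chroms = np.array([str(chrom_of_block[b]) for b in blocks], dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        cursor = cfg.bp_spacing
        prev_block = blocks[sel[0]]
        for j in sel:
            if blocks[j] != prev_block:
                cursor += cfg.block_gap_bp
                prev_block = blocks[j]
            pos[j] = cursor
            cursor += cfg.bp_spacing
    ids = np.array([f"rs{j + 1:07d}" for j in range(m)], dtype=object)
    a1 = np.full(m, "A", dtype=object)
    a2 = np.full(m, "G", dtype=object)
    return GenotypePanel(ids, chroms, pos, a1, a2, dos)


def simulate_blocks(cfg: SimulationConfig, panel: GenotypePanel) -> BlockPartition:
    """Block partition whose intervals wrap the simulated LD blocks."""
    blocks = cfg.block_index()
    chrom, start, end = [], [], []
    for b in range(blocks.max() + 1):
        sel = blocks == b
        chrom.append(panel.chrom[sel][0])
        start.append(panel.pos[sel][0])
        end.append(panel.pos[sel][-1] + cfg.bp_spacing)
    return BlockPartition(np.array(chrom, dtype=object), np.array(start), np.array(end))


def _region_labels(components: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    n_blocks = blocks.max() + 1
    labels = np.zeros(n_blocks, dtype=np.int64)
    for b in range(n_blocks):
        comp = components[blocks == b]
        if (comp == 3).any():
            labels[b] = 3
        elif (comp == 1).any() and (comp == 2).any():
            labels[b] = 4
        elif (comp == 1).any():
            labels[b] = 1
        elif (comp == 2).any():
            labels[b] = 2
    return labels


def simulate_effects(cfg: SimulationConfig, panel: GenotypePanel) -> TruthTable:
    """Assign mixture components and draw true effects for both traits.

    Standardized effects on each trait's causal set are zero-mean Gaussian,
    rescaled so the realized heritability ``sum(b^2)`` equals the target
    exactly; shared-component effects are bivariate with correlation
    ``rg_shared``.  Per-block colocalization labels derive from the member
    components (shared SNP -> model 3; both trait-specific kinds -> model 4).
    """
    rng = _rng(cfg.seed, "effects")
    m = cfg.m_snps
    comp = rng.choice(4, size=m, p=list(cfg.pi))
    b1 = np.zeros(m)
    b2 = np.zeros(m)

    only1, only2, shared = comp == 1, comp == 2, comp == 3
    b1[only1] = rng.standard_normal(only1.sum())
    b2[only2] = rng.standard_normal(only2.sum())
    k = int(shared.sum())
    if k:
        cov = np.array([[1.0, cfg.rg_shared], [cfg.rg_shared, 1.0]])
        bs = rng.multivariate_normal([0.0, 0.0], cov, size=k, method="svd")
        b1[shared] = bs[:, 0]
        b2[shared] = bs[:, 1]

    for b, h2, causal in ((b1, cfg.h2_1, only1 | shared), (b2, cfg.h2_2, only2 | shared)):
        tot = float(np.sum(b ** 2))
        if causal.any() and h2 == 0:
            b[:] = 0.0
        elif tot > 0:
            b *= np.sqrt(h2 / tot)

    freq = panel.freq
    het = np.sqrt(2 * freq * (1 - freq))
    blocks = cfg.block_index()

    # LD-smeared marginal standardized effects, blockwise: b_marg = R b
    b1_marg = np.zeros(m)
    b2_marg = np.zeros(m)
    from .ld import _std_dosages
    Z = _std_dosages(panel)
    n_ind = Z.shape[0]
    for blk in range(blocks.max() + 1):
        sel = blocks == blk
        if not (b1[sel].any() or b2[sel].any()):
            continue
        R = Z[:, sel].T @ Z[:, sel] / n_ind
        b1_marg[sel] = R @ b1[sel]
        b2_marg[sel] = R @ b2[sel]

    df = pd.DataFrame({
        "snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
        "freq": freq, "block": blocks, "component": comp,
        "beta1": b1 / het, "beta2": b2 / het,
        "b1": b1, "b2": b2, "b1_marg": b1_marg, "b2_marg": b2_marg,
    })
    return TruthTable(df, _region_labels(comp, blocks))


def _sumstats_from_marginals(b_marg: np.ndarray, n: int, panel: GenotypePanel,
                             rng: np.random.Generator) -> pd.DataFrame:
    freq = panel.freq
    se = 1.0 / np.sqrt(2 * n * freq * (1 - freq))
    z = np.sqrt(n) * b_marg + rng.standard_normal(len(b_marg))
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), MIN_PVALUE)
    return pd.DataFrame({
        "snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos,
        "a1": panel.a1, "a2": panel.a2,
        "beta": z * se, "se": se, "pvalue": p,
        "n": np.full(panel.n_snps, n), "freq": freq,
    })


def simulate_sumstats(truth: TruthTable, panel: GenotypePanel,
                      cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed summary statistics for both traits (independent noise streams)."""
    s1 = _sumstats_from_marginals(truth.df["b1_marg"].to_numpy(), cfg.n1, panel,
                                  _rng(cfg.seed, "sumstats1"))
    s2 = _sumstats_from_marginals(truth.df["b2_marg"].to_numpy(), cfg.n2, panel,
                                  _rng(cfg.seed, "sumstats2"))
    return s1, s2


def simulate_outcome_sumstats(truth: TruthTable, cfg: SimulationConfig,
                              panel: GenotypePanel) -> pd.DataFrame:
    """Summary statistics for an outcome causally downstream of trait 1.

    The outcome's standardized genetic effects are ``gamma_causal`` times
    trait 1's (optionally plus direct pleiotropic effects of scale
    ``pleiotropy_sd``), so every SNP's Wald ratio against the trait-1
    marginal effect is centered on ``gamma_causal``.
    """
    rng = _rng(cfg.seed, "outcome")
    b_out = cfg.gamma_causal * truth.df["b1_marg"].to_numpy()
    if cfg.pleiotropy_sd > 0:
        b_out = b_out + rng.normal(0.0, cfg.pleiotropy_sd, size=len(b_out))
    return _sumstats_from_marginals(b_out, cfg.n_outcome, panel, rng)


def simulate_regions(n_regions: int, snps_per_region: int = 50,
                     model_probs=(0.70, 0.10, 0.10, 0.08, 0.02),
                     z_mean: float = 6.0, z_sd: float = 1.0,
                     n: int = 50_000, seed: int = 0,
                     models: np.ndarray | None = None):
    """Independent regional association statistics for colocalization checks.

    Each region realizes one of the five regional hypotheses (no signal /
    trait-1 causal / trait-2 causal / one shared causal / two distinct
    causals) with a causal |z| drawn Normal(``z_mean``, ``z_sd``) — median
    ``z_mean`` — and random sign.  SNPs are unlinked; standard errors follow
    the sample-size/frequency approximation.  Returns ``(df, models)`` where
    ``df`` has columns region, snp_id, beta1, se1, beta2, se2.
    """
    rng = np.random.default_rng([int(seed), _STREAMS["regions"]])
    if models is None:
        models = rng.choice(5, size=n_regions, p=list(model_probs))
    else:
        models = np.asarray(models, dtype=int)
        if len(models) != n_regions:
            raise ValueError("models must have length n_regions")
    k = snps_per_region
    rows = []
    for r in range(n_regions):
        freq = rng.uniform(0.05, 0.5, size=k)
        se1 = 1.0 / np.sqrt(2 * n * freq * (1 - freq))
        se2 = 1.0 / np.sqrt(2 * n * freq * (1 - freq))
        z1t = np.zeros(k)
        z2t = np.zeros(k)
        mdl = models[r]

        def draw_z():
            return rng.choice([-1.0, 1.0]) * abs(rng.normal(z_mean, z_sd))

        if mdl == 1:
            z1t[rng.integers(k)] = draw_z()
        elif mdl == 2:
            z2t[rng.integers(k)] = draw_z()
        elif mdl == 3:
            i = rng.integers(k)
            z1t[i] = draw_z()
            z2t[i] = draw_z()
        elif mdl == 4:
            i, j = rng.choice(k, size=2, replace=False)
            z1t[i] = draw_z()
            z2t[j] = draw_z()

        z1 = z1t + rng.standard_normal(k)
        z2 = z2t + rng.standard_normal(k)
        rows.append(pd.DataFrame({
            "region": r,
            "snp_id": [f"r{r}_s{j}" for j in range(k)],
            "beta1": z1 * se1, "se1": se1,
            "beta2": z2 * se2, "se2": se2,
        }))
    return pd.concat(rows, ignore_index=True), models


def ebmd_from_qus(bua: float, sos: float) -> float:
    """Heel-ultrasound estimated BMD from BUA and SOS.

    Linear combination of broadband ultrasound attenuation (dB/MHz) and speed
    of sound (m/s): ``0.002592 * (BUA + SOS) - 3.687``.
    """
    return 0.002592 * (bua + sos) - 3.687
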