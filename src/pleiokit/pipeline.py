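"""End-to-end orchestration: harmonize -> prune -> cFDR -> enrichment ->
colocalization -> LD score regression -> MR, from one structured config.

Every stage writes its TSV artifacts into the output directory and the run
ends with a ``manifest.json`` capturing all parameters, the seed, per-stage
row counts and computed thresholds — enough to re-create every number in the
outputs.  Stages communicate through files only, and a demo mode generates
all inputs synthetically so the pipeline is runnable with no external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfdr as cfdr_mod
from . import simulate as sim_mod
from .coloc import AbfConfig, ColocModel
from .ld import ld_prune, ld_scores
from .ldsc import LdscModel
from .mr import MrModel
from .panel import BlockPartition, GenotypePanel
from .sumstats import HarmonizedPair, harmonize, read_sumstats, write_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or parameters)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the failing stage is named in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


#: demo-mode simulation overrides; empty = the generator's default study
#: conditions (20,000 SNPs in 50-SNP blocks, N = 50,000, h2 = 0.3 per trait)
DEMO_SIM: dict = {}


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run.

    In demo mode all inputs are simulated from ``sim`` (seed-controlled); in
    real mode the four input paths must exist.  Stage parameters default to
    the standard values: pruning (50, 5, 0.2), genome-wide alpha 5e-8, QQ
    strata {1, 0.1, 0.01, 0.001, 0.0001}, ABF prior variances
    {0.01, 0.1, 0.5}, posterior cutoff 0.9.
    """

    outdir: str = "pleio_out"
    mode: str = "demo"
    seed: int = 0
    sim: dict = field(default_factory=lambda: dict(DEMO_SIM))
    sumstats1: str | None = None
    sumstats2: str | None = None
    panel_vcf: str | None = None
    blocks_bed: str | None = None
    outcome: str | None = None
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    gw_alpha: float = 5e-8
    qq_cutoffs: tuple = cfdr_mod.DEFAULT_CUTOFFS
    prior_variances: tuple = (0.01, 0.1, 0.5)
    pp_cutoff: float = 0.9
    mr_alpha: float = 5e-8
    coloc_use_pruned: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("demo", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for name in ("sumstats1", "sumstats2", "panel_vcf", "blocks_bed"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"real mode requires existing path for {name}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["qq_cutoffs"] = list(self.qq_cutoffs)
        d["prior_variances"] = list(self.prior_variances)
        # the manifest lives inside outdir; recording the path would make
        # otherwise-identical runs differ
        d.pop("outdir", None)
        return d


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.mode == "demo":
        sim_cfg = sim_mod.SimulationConfig(seed=cfg.seed, **cfg.sim)
        panel = sim_mod.simulate_panel(sim_cfg)
        truth = sim_mod.simulate_effects(sim_cfg, panel)
        s1, s2 = sim_mod.simulate_sumstats(truth, panel, sim_cfg)
        outcome = sim_mod.simulate_outcome_sumstats(truth, sim_cfg, panel)
        blocks = sim_mod.simulate_blocks(sim_cfg, panel)
        write_table(s1, out / "sumstats1.tsv")
        write_table(s2, out / "sumstats2.tsv")
        write_table(outcome, out / "outcome.tsv")
        write_table(truth.df, out / "truth.tsv")
        panel.to_vcf(out / "panel.vcf")
        blocks.to_bed(out / "blocks.bed")
        return s1, s2, panel, blocks, outcome
    s1 = read_sumstats(cfg.sumstats1)
    s2 = read_sumstats(cfg.sumstats2)
    panel = GenotypePanel.from_vcf(cfg.panel_vcf)
    blocks = BlockPartition.from_bed(cfg.blocks_bed)
    outcome = read_sumstats(cfg.outcome) if cfg.outcome else None
    return s1, s2, panel, blocks, outcome


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    A stage failure raises :class:`StageError` naming the stage; artifacts
    written by earlier stages are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("inputs")
        s1, s2, panel, blocks, outcome = _load_inputs(cfg, out)
        manifest["stages"]["inputs"] = {"n_snps_1": len(s1), "n_snps_2": len(s2),
                                        "n_panel_snps": panel.n_snps,
                                        "n_blocks": len(blocks)}

        name = stage("harmonize")
        pair = harmonize(s1, s2)
        write_table(pair.df, out / "harmonized.tsv")
        manifest["stages"]["harmonize"] = pair.audit

        name = stage("prune")
        pruned = ld_prune(pair, panel, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
        write_table(pruned.df, out / "pruned.tsv")
        (out / "prune.in").write_text("\n".join(pruned.df["snp_id"]) + "\n")
        manifest["stages"]["prune"] = {
            "n_in": len(pair), "n_kept": len(pruned),
            "window": cfg.prune_window, "step": cfg.prune_step, "r2_max": cfg.prune_r2}

        name = stage("cfdr")
        cres = cfdr_mod.CfdrModel(pruned, cfg.gw_alpha).fit()
        write_table(cres.table, out / "cfdr.tsv")
        manifest["stages"]["cfdr"] = {
            "cutoff_1g2": cres.cutoff_1g2, "cutoff_2g1": cres.cutoff_2g1,
            "cutoff_cc": cres.cutoff_cc, "n_sig_1g2": cres.n_sig_1g2,
            "n_sig_2g1": cres.n_sig_2g1, "n_sig_cc": cres.n_sig_cc}

        name = stage("enrichment")
        model = cfdr_mod.CfdrModel(pruned, cfg.gw_alpha)
        qq_rows = []
        for principal in (1, 2):
            for t, curve in model.stratified_qq(principal, cfg.qq_cutoffs).items():
                c = curve.copy()
                c.insert(0, "cutoff", t)
                c.insert(0, "principal", principal)
                qq_rows.append(c)
        write_table(pd.concat(qq_rows, ignore_index=True), out / "qq.tsv")
        enr = []
        for principal in (1, 2):
            e = model.fold_enrichment(principal, cfg.qq_cutoffs)
            e.insert(0, "principal", principal)
            enr.append(e)
        write_table(pd.concat(enr, ignore_index=True), out / "enrichment.tsv")
        manhattan, thr_y = cres.manhattan_data()
        write_table(manhattan, out / "manhattan.tsv")
        manifest["stages"]["enrichment"] = {"manhattan_threshold_y": thr_y}

        name = stage("coloc")
        coloc_pair = pruned if cfg.coloc_use_pruned else pair
        colres = ColocModel(coloc_pair, blocks,
                            AbfConfig(tuple(cfg.prior_variances))).fit()
        write_table(colres.regions, out / "coloc_regions.tsv")
        counts = {m: len(v) for m, v in colres.classify(cfg.pp_cutoff).items()}
        manifest["stages"]["coloc"] = {
            "priors": [float(p) for p in colres.priors.pi],
            "pp_cutoff": cfg.pp_cutoff,
            "regions_per_model": {str(m): counts[m] for m in range(5)}}

        name = stage("ldsc")
        ell_panel = ld_scores(panel)
        idx = panel.indices_of(pair.df["snp_id"].to_numpy())
        ok = idx >= 0
        ell = ell_panel[idx[ok]]
        write_table(pd.DataFrame({"snp_id": panel.snp_id, "ld_score": ell_panel}),
                    out / "ld_scores.tsv")
        rg_fit = LdscModel(pair.subset(ok), ell).fit()
        manifest["stages"]["ldsc"] = {
            "h2_1": rg_fit.fit1.h2, "h2_1_se": rg_fit.fit1.h2_se,
            "h2_2": rg_fit.fit2.h2, "h2_2_se": rg_fit.fit2.h2_se,
            "rg": rg_fit.rg, "rg_se": rg_fit.rg_se,
            "intercept_1": rg_fit.fit1.intercept, "intercept_2": rg_fit.fit2.intercept}
        (out / "ldsc_summary.txt").write_text(rg_fit.summary() + "\n")

        name = stage("mr")
        if outcome is not None:
            mr_model = MrModel(s1, outcome, panel, cfg.mr_alpha,
                               cfg.prune_window, cfg.prune_step, cfg.prune_r2)
            inst = mr_model.instrument_table()
            write_table(inst, out / "mr_instruments.tsv")
            res = mr_model.fit("both")
            manifest["stages"]["mr"] = {
                "n_instruments": res["ivw"].n_instruments,
                "ivw_estimate": res["ivw"].estimate, "ivw_se": res["ivw"].se,
                "ivw_p": res["ivw"].pvalue,
                "egger_estimate": res["egger"].estimate,
                "egger_intercept": res["egger"].intercept,
                "egger_intercept_p": res["egger"].intercept_pvalue}
        else:
            logger.warning("no outcome statistics supplied; MR stage skipped")
            manifest["stages"]["mr"] = {"skipped": True}
    except ConfigError:
        raise
    except Exception as e:  # noqa: BLE001 - stage reporting contract
        raise StageError(name, e) from e

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n")
    return out


def make_figures(outdir) -> list[Path]:
    """Render stratified QQ, fold-enrichment and conjunction Manhattan figures.

    Reads the stage TSVs from ``outdir``; missing stages are skipped with a
    warning.  Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    written = []

    qq_path = out / "qq.tsv"
    if qq_path.exists():
        qq = pd.read_csv(qq_path, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        for ax, principal in zip(axes, (1, 2)):
            sub = qq[qq["principal"] == principal]
            for t, curve in sub.groupby("cutoff"):
                ax.plot(-np.log10(1 - curve["ecdf"] + 1 / (len(curve) + 1)),
                        curve["neglog10_p"], label=f"p2 <= {t:g}", lw=1)
            ax.set_xlabel("-log10 empirical quantile")
            ax.set_ylabel("-log10 nominal p")
            ax.set_title(f"trait {principal} | other")
            ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "qq.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("qq.tsv missing; QQ figure skipped")

    enr_path = out / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        for ax, principal in zip(axes, (1, 2)):
            sub = enr[enr["principal"] == principal]
            for t, curve in sub.groupby("cutoff"):
                if len(curve):
                    ax.plot(curve["x"], curve["enrichment"], label=f"p2 <= {t:g}", lw=1)
            ax.set_xlabel("-log10 nominal p")
            ax.set_ylabel("fold enrichment")
            ax.set_title(f"trait {principal} | other")
            ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "enrichment.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("enrichment.tsv missing; enrichment figure skipped")

    man_path = out / "manhattan.tsv"
    if man_path.exists():
        man = pd.read_csv(man_path, sep="\t")
        thr_y = None
        mpath = out / "manifest.json"
        if mpath.exists():
            thr_y = json.loads(mpath.read_text())["stages"].get(
                "enrichment", {}).get("manhattan_threshold_y")
        fig, ax = plt.subplots(figsize=(10, 3.5))
        for i, (c, sub) in enumerate(man.groupby("chrom", sort=False)):
            ax.scatter(sub["x"], sub["neglog10_ccfdr"], s=4,
                       color=["#4477AA", "#66CCEE"][i % 2])
        if thr_y is not None:
            ax.axhline(thr_y, color="red", lw=1)
        ax.set_xlabel("genomic position")
        ax.set_ylabel("-log10 ccFDR")
        fig.tight_layout()
        p = out / "manhattan.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("manhattan.tsv missing; Manhattan figure skipped")
    return written
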