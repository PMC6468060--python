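"""End-to-end pipeline: mtDNA -> summary stats -> ABC -> migration fit.

A single :class:`RunConfig` (loadable from YAML) drives all four stages;
one master seed deterministically derives per-stage seeds, so re-running
the same configuration reproduces every output byte for byte.  Each stage
writes its own CSV/JSON artifacts into the output directory and a combined
``report.json`` records configuration, seeds and headline numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import mtdna as mtdna_mod
from . import sumstats as ss
from .io import read_fasta_alignment, read_genepop
from .migration_graph import (allele_frequencies, covariance_entry_sd,
                              covariance_matrix, fit_graph,
                              likelihood_ratio_test, variance_explained)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("mtdna", "sumstats", "abc", "migfit")


@dataclass
class RunConfig:
    """Inputs, stage toggles, stage parameters and the master seed."""

    genepop: str
    mtdna_alignment: str | None = None
    mtdna_references: str | None = None
    annotations: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # population roles (native parent, hybrid, donor parent)
    parent1: str = "SFL"
    hybrid: str = "MIA"
    parent2: str = "WCU"
    # sumstats
    rarefaction_g: int | None = None
    hwe_reps: int = 2_000
    repeat_length: int = 1
    # abc
    abc_sims: int = 2_000
    abc_keep: int = 100
    abc_loci: int | None = None
    abc_mu: float = 5e-4
    abc_gsm_p: float = 1.0
    ppc_draws: int = 50
    regression_adjust: bool = False
    # migration graph
    migfit_restarts: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2**31 - 1))


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> str:
    frame.to_csv(path, float_format="%.10g", **kw)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the report dictionary.

    Stage order is mtdna, sumstats, abc, migfit; disabled stages are
    simply absent from the report.  All artifacts land in
    ``config.out_dir``; the report is also written as ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}, "checksums": {}}
    table = read_genepop(config.genepop)

    if "mtdna" in config.stages:
        if not (config.mtdna_alignment and config.mtdna_references):
            raise ValueError("mtdna stage requires alignment and reference paths")
        hz = read_fasta_alignment(config.mtdna_alignment, config.annotations)
        refs = read_fasta_alignment(config.mtdna_references, config.annotations)
        haps = mtdna_mod.collapse_haplotypes(hz)
        reports = mtdna_mod.nearest_reference(haps, refs)
        div = pd.DataFrame([{
            "haplotype": r.query, "n_members": len(haps.members[r.query]),
            "best_reference": ";".join(r.best_refs), "clade": r.clade,
            "differences": r.differences, "divergence_pct": r.divergence_pct,
            "n_compared_sites": r.n_compared_sites,
        } for r in reports]).set_index("haplotype")
        clades = mtdna_mod.clade_frequencies(
            [r.clade for r in reports],
            [len(haps.members[r.query]) for r in reports])
        hap_frame = pd.DataFrame(
            [{"haplotype": h, "count": c, "members": ";".join(haps.members[h])}
             for h, c in haps.counts.items()]).set_index("haplotype")
        report["checksums"]["haplotypes.csv"] = _write_csv(hap_frame, out / "haplotypes.csv")
        report["checksums"]["divergence.csv"] = _write_csv(div, out / "divergence.csv")
        report["checksums"]["clades.csv"] = _write_csv(clades, out / "clades.csv")
        donor = [c for c in clades.index if c not in ("native", "ambiguous")]
        report["stages"]["mtdna"] = {
            "n_sequences": len(hz), "n_haplotypes": len(haps),
            "clade_percent": {str(k): int(v) for k, v in clades["percent"].items()},
            "mean_divergence_pct": round(float(div["divergence_pct"].mean()), 2),
        }

    if "sumstats" in config.stages:
        seed = config.stage_seed("sumstats")
        stats = ss.pop_stats(table, config.rarefaction_g, config.repeat_length)
        pops = table.pop_labels
        fst_rows = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                _, theta = ss.wc_fst(table, pops[i], pops[j])
                fst_rows.append({"pop_a": pops[i], "pop_b": pops[j],
                                 "fst": theta})
        fst = pd.DataFrame(fst_rows).set_index(["pop_a", "pop_b"])
        hwe_rows = []
        for k, pop in enumerate(pops):
            for locus in table.loci:
                p = ss.hwe_exact_test(table, pop, locus, reps=config.hwe_reps,
                                      seed=seed + 31 * k + table.loci.index(locus))
                hwe_rows.append({"pop": pop, "locus": locus, "p_value": p,
                                 "deviates_p05": p < 0.05})
        hwe = pd.DataFrame(hwe_rows).set_index(["pop", "locus"])
        lam = ss.lambda_admixture(table, config.parent1, config.parent2,
                                  config.hybrid)
        report["checksums"]["popstats.csv"] = _write_csv(stats, out / "popstats.csv")
        report["checksums"]["fst.csv"] = _write_csv(fst, out / "fst.csv")
        report["checksums"]["hwe.csv"] = _write_csv(hwe, out / "hwe.csv")
        report["stages"]["sumstats"] = {
            "seed": seed,
            "mean_AR": round(float(stats["A_R"].mean()), 2),
            "mean_Ho": round(float(stats["H_o"].mean()), 2),
            "mean_He": round(float(stats["H_e"].mean()), 2),
            "mean_pairwise_fst": round(float(fst["fst"].mean()), 2),
            "lambda": round(lam, 4),
            "n_hwe_deviations_p05": int(hwe["deviates_p05"].sum()),
            "gene_diversity_definition": "per-population unbiased expected "
                                         "heterozygosity (not pooled)",
        }

    if "abc" in config.stages:
        seed = config.stage_seed("abc")
        samples = table.population_map()
        n_loci = config.abc_loci or len(table.loci)
        observed = abc_mod.observed_stats(table, config.parent1,
                                          config.parent2, config.hybrid)
        prior = abc_mod.default_priors()
        ref = abc_mod.build_reference_table(
            prior, samples, n_loci=n_loci, n_sims=config.abc_sims,
            seed=seed, mu=config.abc_mu, gsm_p=config.abc_gsm_p)
        post = abc_mod.reject(ref, observed, n_keep=config.abc_keep,
                              regression_adjust=config.regression_adjust)
        summ = abc_mod.posterior_summary(post)
        ppc = abc_mod.posterior_predictive_check(
            post, samples, n_loci=n_loci, n_draws=config.ppc_draws, seed=seed,
            mu=config.abc_mu, gsm_p=config.abc_gsm_p)
        report["checksums"]["abc_table.csv"] = _write_csv(
            pd.concat([ref.params, ref.stats], axis=1),
            out / "abc_table.csv", index=False)
        report["checksums"]["abc_posterior.csv"] = _write_csv(summ, out / "abc_posterior.csv")
        report["checksums"]["abc_ppc.csv"] = _write_csv(ppc, out / "abc_ppc.csv")
        report["stages"]["abc"] = {
            "seed": seed, "n_sims": config.abc_sims, "n_keep": config.abc_keep,
            "prior_note": "admixture-rate prior U(0,1); "
                          "lambda oriented as proportion from donor",
            "posterior": {p: {k: float(v) for k, v in row.items()}
                          for p, row in summ.iterrows()},
        }

    if "migfit" in config.stages:
        seed = config.stage_seed("migfit")
        freq = allele_frequencies(
            table, [config.parent1, config.hybrid, config.parent2])
        cov = covariance_matrix(freq)
        esd = covariance_entry_sd(freq)
        fit1 = fit_graph(cov, True, config.migfit_restarts, seed, error_sd=esd)
        fit0 = fit_graph(cov, False, config.migfit_restarts, seed, error_sd=esd)
        stat, p = likelihood_ratio_test(fit0, fit1)
        resid = pd.DataFrame(fit1.residuals, index=fit1.pops, columns=fit1.pops)
        report["checksums"]["migfit_residuals.csv"] = _write_csv(
            resid, out / "migfit_residuals.csv")
        migfit = {
            "seed": seed, "topology": fit1.topology,
            "migration_weight": round(fit1.w, 4),
            "loglik_migration": fit1.loglik, "loglik_tree": fit0.loglik,
            "lrt_statistic": round(stat, 4), "lrt_p_value": p,
            "var_explained_migration": round(variance_explained(fit1, cov), 4),
            "var_explained_tree": round(variance_explained(fit0, cov), 4),
            "drift": {k: float(v) for k, v in fit1.drift.items()},
            "root_var": fit1.root_var,
        }
        (out / "migfit.json").write_text(
            json.dumps(migfit, indent=2, sort_keys=True))
        report["checksums"]["migfit.json"] = hashlib.sha256(
            (out / "migfit.json").read_bytes()).hexdigest()
        report["stages"]["migfit"] = migfit

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
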