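"""End-to-end orchestration: genotypes + phenotypes -> reports.

Stage order: (optional synthetic data) -> genotype QC -> clonal identity
verification and MLG collapsing -> genomic relationships / inbreeding ->
phenotype correction and clonal BLUPs -> GBLUP cross-validation.  Every
output table carries the run's config hash so reports are traceable to
their exact parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clonecheck, genio, gpred, pheno, relate, syndata

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "pinebreed_out"
    # input paths; ignored when simulate=True
    vcf: str | None = None
    metadata: str | None = None
    phenotypes: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)     # SimConfig overrides
    error_threshold: float = 0.025
    mlg_cutoff: str | float = "auto"
    min_maf: float = 0.0
    k_folds: int = 9
    n_permutations: int = 200
    top_fraction: float = 0.10
    relatedness_factor: float = 0.0001
    fis_bootstraps: int = 1000
    seed: int = 1

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if not self.simulate:
            for name in ("vcf", "metadata", "phenotypes"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config missing input path {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and write reports; returns the run summary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    timings: dict[str, float] = {}
    summary: dict = {"config_hash": h, "version": __version__, "seed": cfg.seed}

    def tick(stage):
        timings[stage] = time.perf_counter()

    def tock(stage):
        timings[stage] = round(time.perf_counter() - timings[stage], 3)
        logger.info("stage %s: %.2fs", stage, timings[stage])

    # ------------------------------------------------ data
    tick("data")
    if cfg.simulate:
        sim_cfg = syndata.SimConfig(**{"seed": cfg.seed, **cfg.sim})
        ds = syndata.simulate_dataset(sim_cfg)
        syndata.write_dataset(ds, out / "data")
        g = ds.ramets
        meta = ds.sample_meta
        pheno_tbl = pheno.validate_phenotypes(ds.phenotypes)
    else:
        g = genio.read_vcf(cfg.vcf)
        meta = pd.read_csv(cfg.metadata, sep="\t", comment="#")
        pheno_tbl = pheno.validate_phenotypes(
            pd.read_csv(cfg.phenotypes, sep="\t", comment="#")
        )
    tock("data")

    # ------------------------------------------------ QC
    tick("qc")
    per_locus, per_sample = genio.completeness(g)
    stats = genio.locus_stats(g)
    _write_tsv(stats, out / "locus_stats.tsv", h)
    _write_tsv(per_sample.to_frame(), out / "sample_completeness.tsv", h)
    summary["n_samples"] = g.n_samples
    summary["n_loci"] = g.n_loci
    summary["mean_locus_completeness"] = float(per_locus.mean())
    tock("qc")

    # ------------------------------------------------ identity
    tick("identity")
    registry = clonecheck.CloneRegistry.from_metadata(meta)
    reports, registry = clonecheck.verify_ramets(g, registry, cfg.error_threshold)
    _write_tsv(reports.set_index("sample_id"), out / "mismatch_reports.tsv", h)
    _write_tsv(clonecheck.clone_summary(reports, g), out / "clone_summary.tsv", h)
    _write_tsv(clonecheck.snp_error_rates(g, registry), out / "snp_error_rates.tsv", h)
    n_excluded = int(reports["excluded"].sum())
    summary["n_excluded_ramets"] = n_excluded
    multi = reports.groupby("clone_id")["sample_id"].size()
    pooled = reports[~reports["excluded"] & reports["clone_id"].isin(multi.index[multi > 1])]
    summary["mean_sample_error_rate"] = float(pooled["error_rate"].mean())

    dist = clonecheck.nei_distance_matrix(g)
    lk_all = clonecheck.collapse_mlg(dist, 0.0, g.sample_ids)
    if cfg.mlg_cutoff == "auto":
        cutoff = clonecheck.predict_cutoff(lk_all.merge_distances)
    else:
        cutoff = float(cfg.mlg_cutoff)
    mlg = clonecheck.collapse_mlg(dist, cutoff, g.sample_ids)
    _write_tsv(mlg.assignment.to_frame(), out / "mlg_assignment.tsv", h)
    summary["mlg_cutoff"] = cutoff
    summary["n_lineages"] = mlg.n_lineages
    _write_tsv(clonecheck.pca_coordinates(g), out / "pca_coordinates.tsv", h)
    tock("identity")

    # ------------------------------------------------ relatedness
    tick("relate")
    clone_ids = sorted(registry.clones)
    consensus_calls = np.stack([registry.clones[c].consensus for c in clone_ids])
    g_clones = type(g)(clone_ids, g.locus_ids, consensus_calls)
    grm = relate.compute_grm(g_clones, min_maf=cfg.min_maf)
    groups = pd.Series({c: registry.clones[c].region for c in clone_ids})
    _write_tsv(grm.to_frame(), out / "grm.tsv", h)
    inb = relate.inbreeding_from_grm(grm, groups)
    _write_tsv(inb, out / "inbreeding_summary.tsv", h)
    _write_tsv(
        relate.fis(g_clones, groups, n_boot=cfg.fis_bootstraps, seed=cfg.seed),
        out / "fis.tsv", h,
    )
    edges, degree = relate.ibd_network_edges(grm, cfg.relatedness_factor, groups)
    _write_tsv(edges, out / "ibd_edges.tsv", h, index=False)
    _write_tsv(degree, out / "ibd_degree.tsv", h)
    summary["grm_mean_diagonal"] = float(np.diag(grm.values).mean())
    tock("relate")

    # ------------------------------------------------ phenotypes + prediction
    tick("pheno")
    sites = sorted(pheno_tbl["site"].unique())
    registered = [c for c in clone_ids if registry.clones[c].registered]
    pred_rows, h2_rows, gain_rows = [], [], []
    blup_frames = []
    for site in sites:
        for trait in ("NC", "MCW"):
            try:
                tbl = pheno.site_trait_blups(pheno_tbl, site, trait)
            except ValueError as exc:
                logger.warning("pheno %s/%s skipped: %s", site, trait, exc)
                continue
            h2_rows.append(
                {"site": site, "trait": trait,
                 "H2": pheno.broad_sense_h2(tbl.components),
                 **{k: v for k, v in tbl.components.items() if k != "beta"}}
            )
            blups = tbl.blups.rename(f"{site}:{trait}")
            blup_frames.append(blups)
            observed = tbl.mean + blups
            common = [c for c in grm.clone_ids if c in observed.index]
            if len(observed) >= 10 and observed.mean() > 0:
                top = gpred.selection_gain(observed, cfg.top_fraction)
                gain_rows.append({"site": site, "trait": trait, **asdict(top)})
                reg_here = [c for c in registered if c in observed.index]
                if reg_here:
                    reg = gpred.selection_gain(observed, subset_ids=reg_here, label="registered")
                    gain_rows.append({"site": site, "trait": trait, **asdict(reg)})
            if len(common) >= 3 * cfg.k_folds:
                sub = grm.values[np.ix_(
                    [grm.clone_ids.index(c) for c in common],
                    [grm.clone_ids.index(c) for c in common],
                )]
                res = gpred.permutation_null(
                    blups.loc[common], sub, B=cfg.n_permutations,
                    seed=cfg.seed, k=cfg.k_folds,
                )
                pred_rows.append(
                    {"site": site, "trait": trait, "r_mean": res.r_mean,
                     "r_sd": res.r_sd, "pooled_r": res.pooled_r,
                     "p_value": res.p_value, "n_clones": res.n_clones}
                )
                np.savetxt(out / f"null_r_{site}_{trait}.tsv",
                           res.null_distribution, header=f"config_hash={h}")
    if blup_frames:
        _write_tsv(pd.concat(blup_frames, axis=1), out / "clonal_blups.tsv", h)
    _write_tsv(pd.DataFrame(h2_rows), out / "heritability.tsv", h, index=False)
    if gain_rows:
        _write_tsv(pd.DataFrame(gain_rows), out / "selection_gains.tsv", h, index=False)
    if pred_rows:
        _write_tsv(pd.DataFrame(pred_rows), out / "predictive_ability.tsv", h, index=False)
    summary["heritability"] = h2_rows
    summary["predictive_ability"] = pred_rows
    tock("pheno")

    summary["timings_s"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
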