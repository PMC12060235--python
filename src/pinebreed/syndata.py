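"""Synthetic clone/ramet cohorts with the structure the pipeline assumes.

The generator emulates a Mediterranean stone pine breeding cohort: ~99
clones from 4 differentiated provenance regions (ES1, ES2, ES3, ES6)
genotyped at ~2,245 biallelic SNPs, with multiple ramets per registered
clone, per-genotype call errors (~0.5%), missing calls (~1%), mislabelled
ramets (~10%), and repeated-measure cone phenotypes with strong masting
(calendar-year) effects, site effects and an allometric diameter covariate.

Model choices:

* Regional differentiation follows the Balding-Nichols model: ancestral
  frequency p0 ~ Uniform(0.05, 0.95) per locus, region frequency
  ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F the target FST.
* Within-region inbreeding enters the genotype draw through
  P(het) = 2p(1-p)(1-F_region).
* Cone counts (NC) are negative-binomial with a log link; cone weight
  (MCW) is Gaussian on the identity scale, truncated at zero.
* Mislabels are clone-label swaps among ramets of registered clones
  (the real failure mode of grafting mix-ups), never novel genotypes.

All randomness flows from one root seed through named spawned streams, so
every stage is independently re-runnable and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genio
from .gmatrix import MISSING, GenotypeMatrix

_STREAMS = {"freqs": 0, "clones": 1, "ramets": 2, "pheno": 3}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_loci: int = 2245
    regions: dict = field(
        default_factory=lambda: {"ES1": 32, "ES2": 20, "ES3": 22, "ES6": 25}
    )
    fst: float = 0.10
    region_selfing: dict = field(
        default_factory=lambda: {"ES1": 0.0, "ES2": 0.20, "ES3": 0.15, "ES6": 0.50}
    )
    n_registered: int = 15
    ramets_per_registered: tuple = (10, 11)
    geno_error_rate: float = 0.005
    missing_rate: float = 0.01
    mislabel_rate: float = 0.10
    h2_nc: float = 0.45
    h2_mcw: float = 0.30
    n_sites: int = 3
    test_ramets_per_clone: int = 6
    years: tuple = tuple(range(2008, 2018))
    masting_sd: float = 0.8
    nb_dispersion: float = 1.5
    nb_base_mean: float = 2.0
    dag_beta: float = 0.7
    dropout_rate: float = 0.10
    mcw_mean: float = 267.0
    mcw_scale: float = 30.0
    seed: int = 0

    @property
    def n_clones(self) -> int:
        return int(sum(self.regions.values()))

    def validate(self) -> None:
        for name in ("geno_error_rate", "missing_rate", "mislabel_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        for r, f in self.region_selfing.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"region_selfing[{r}]={f} not in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(n < 1 for n in self.regions.values()):
            raise ValueError("every region needs at least 1 clone")
        for name in ("h2_nc", "h2_mcw"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be strictly inside (0, 1)")
        if self.mislabel_rate > 0 and self.n_registered < 2:
            raise ValueError("mislabels need at least 2 registered clones")
        if self.n_registered > self.n_clones:
            raise ValueError("more registered clones than clones")
        lo, hi = self.ramets_per_registered
        if not 1 <= lo <= hi:
            raise ValueError("invalid ramets_per_registered range")
        if len(self.years) < 1:
            raise ValueError("need at least one year")


@dataclass
class SimTruth:
    """Ground-truth record for parameter-recovery tests."""

    true_clone_genotypes: GenotypeMatrix | None = None
    true_snp_effects: dict = field(default_factory=dict)
    true_clonal_values: pd.DataFrame | None = None
    mislabelled_samples: list = field(default_factory=list)   # (sample_id, true_clone)
    injected_error_positions: list = field(default_factory=list)  # (sample_id, locus_id)
    true_h2: dict = field(default_factory=dict)


@dataclass
class FounderFrequencies:
    p0: np.ndarray
    by_region: dict


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def simulate_founder_frequencies(cfg: SimConfig) -> FounderFrequencies:
    """Ancestral + per-region allele frequencies (Balding-Nichols)."""
    cfg.validate()
    rng = _rng(cfg, "freqs")
    p0 = rng.uniform(0.05, 0.95, cfg.n_loci)
    by_region = {}
    for region in cfg.regions:
        if cfg.fst == 0.0:
            by_region[region] = p0.copy()
        else:
            a = p0 * (1.0 - cfg.fst) / cfg.fst
            b = (1.0 - p0) * (1.0 - cfg.fst) / cfg.fst
            by_region[region] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    return FounderFrequencies(p0=p0, by_region=by_region)


def _clone_ids(cfg: SimConfig) -> pd.DataFrame:
    """Clone labels, regions and registered flags (round-robin registration)."""
    rows = []
    i = 1
    for region, n in cfg.regions.items():
        for _ in range(n):
            rows.append({"clone_id": f"c{i:03d}", "region": region})
            i += 1
    meta = pd.DataFrame(rows)
    meta["registered"] = False
    # spread registered clones across regions: take clones region by region
    order = []
    by_region = {r: list(meta.index[meta["region"] == r]) for r in cfg.regions}
    while len(order) < cfg.n_registered:
        for r in cfg.regions:
            if by_region[r]:
                order.append(by_region[r].pop(0))
            if len(order) == cfg.n_registered:
                break
    meta.loc[order, "registered"] = True
    return meta


def simulate_clones(
    cfg: SimConfig, freqs: FounderFrequencies
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Draw one true genotype per clone with inbreeding-adjusted HWE probabilities."""
    cfg.validate()
    rng = _rng(cfg, "clones")
    meta = _clone_ids(cfg)
    calls = np.empty((cfg.n_clones, cfg.n_loci), dtype=np.int8)
    for region in cfg.regions:
        rows = meta.index[meta["region"] == region].to_numpy()
        p = freqs.by_region[region]
        f = cfg.region_selfing.get(region, 0.0)
        p_hom_ref = (1.0 - p) ** 2 + f * p * (1.0 - p)
        p_het = 2.0 * p * (1.0 - p) * (1.0 - f)
        u = rng.random((len(rows), cfg.n_loci))
        geno = np.full((len(rows), cfg.n_loci), 2, dtype=np.int8)
        geno[u < p_hom_ref + p_het] = 1
        geno[u < p_hom_ref] = 0
        calls[rows] = geno
    locus_ids = [f"SNP{j + 1:05d}" for j in range(cfg.n_loci)]
    g = GenotypeMatrix(list(meta["clone_id"]), locus_ids, calls)
    truth = SimTruth(true_clone_genotypes=g)
    return g, meta, truth


def simulate_ramets(
    clones: GenotypeMatrix,
    clone_meta: pd.DataFrame,
    cfg: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Copy clone genotypes into ramets and inject errors, missingness, mislabels."""
    cfg.validate()
    if clones.n_samples == 0:
        raise ValueError("no clones to replicate")
    if truth is None:
        truth = SimTruth(true_clone_genotypes=clones)
    rng = _rng(cfg, "ramets")
    lo, hi = cfg.ramets_per_registered

    sample_ids, true_clone, label_clone = [], [], []
    for _, row in clone_meta.iterrows():
        n_r = int(rng.integers(lo, hi + 1)) if row["registered"] else 1
        for j in range(n_r):
            sample_ids.append(f"{row['clone_id']}_r{j + 1:02d}")
            true_clone.append(row["clone_id"])
            label_clone.append(row["clone_id"])

    clone_row = {c: i for i, c in enumerate(clones.sample_ids)}
    calls = np.stack([clones.calls[clone_row[c]] for c in true_clone]).astype(np.int8)

    # genotyping errors: flip to one of the two other valid genotypes
    err_mask = rng.random(calls.shape) < cfg.geno_error_rate
    shift = rng.integers(1, 3, size=calls.shape)
    calls[err_mask] = ((calls[err_mask].astype(int) + shift[err_mask]) % 3).astype(np.int8)
    # missing calls
    miss_mask = rng.random(calls.shape) < cfg.missing_rate
    calls[miss_mask] = MISSING

    for i, j in zip(*np.nonzero(err_mask)):
        truth.injected_error_positions.append((sample_ids[i], clones.locus_ids[j]))

    # clone-label swaps among registered-clone ramets
    registered = list(clone_meta.loc[clone_meta["registered"], "clone_id"])
    if cfg.mislabel_rate > 0:
        if len(registered) < 2:
            raise ValueError("mislabels impossible with < 2 registered clones")
        for i, c in enumerate(true_clone):
            if c in registered and rng.random() < cfg.mislabel_rate:
                others = [r for r in registered if r != c]
                label_clone[i] = others[int(rng.integers(len(others)))]
                truth.mislabelled_samples.append((sample_ids[i], c))

    info = clone_meta.set_index("clone_id")
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "clone_id": label_clone,
            "region": [info.loc[c, "region"] for c in label_clone],
            "registered": [bool(info.loc[c, "registered"]) for c in label_clone],
        }
    )
    return GenotypeMatrix(sample_ids, clones.locus_ids, calls), meta, truth


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def simulate_phenotypes(
    clones: GenotypeMatrix,
    cfg: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Repeated-measure NC/MCW records for a clonal test per site.

    Clonal genetic values are sums of per-locus additive effects over
    centered dosages, standardised so that the clone-level variance of the
    Gaussian trait (MCW) equals ``h2`` of the ramet-level corrected
    variance.  NC heritability is imposed on the log-mean scale and is
    therefore only approximate on the count scale.
    """
    cfg.validate()
    if truth is None:
        truth = SimTruth(true_clone_genotypes=clones)
    rng = _rng(cfg, "pheno")
    n_clones, n_loci = clones.n_samples, clones.n_loci
    years = np.asarray(cfg.years)
    n_years = len(years)

    dos = clones.dosages_float()
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    dos_c = dos - dos.mean(axis=0)

    g_std = {}
    for trait, h2 in (("nc", cfg.h2_nc), ("mcw", cfg.h2_mcw)):
        eff = rng.normal(size=n_loci)
        raw = dos_c @ eff
        sd = raw.std()
        if sd == 0:
            raise ValueError("degenerate genotypes: zero genetic variance")
        g_std[trait] = (raw - raw.mean()) / sd * np.sqrt(h2)
        truth.true_snp_effects[trait] = eff * np.sqrt(h2) / sd
    truth.true_clonal_values = pd.DataFrame(g_std, index=clones.sample_ids)
    truth.true_h2 = {"nc": cfg.h2_nc, "mcw": cfg.h2_mcw}

    sites = [f"S{i + 1}" for i in range(cfg.n_sites)]
    site_eff = {t: dict(zip(sites, rng.normal(0.0, 0.3, cfg.n_sites))) for t in ("nc", "mcw")}
    frames = []
    for site in sites:
        year_nc = rng.normal(0.0, cfg.masting_sd, n_years)
        year_mcw = rng.normal(0.0, cfg.masting_sd, n_years)
        n_r = cfg.test_ramets_per_clone
        total = n_clones * n_r
        ramet_idx = np.repeat(np.arange(n_clones), n_r)
        ramet_nc = rng.normal(0.0, np.sqrt(0.5 * (1.0 - cfg.h2_nc)), total)
        ramet_mcw = rng.normal(0.0, np.sqrt(0.5 * (1.0 - cfg.h2_mcw)), total)
        age0 = rng.integers(4, 9, total)
        dag_base = rng.uniform(1.0, 3.0, total)
        dag_slope = rng.uniform(1.0, 1.4, total)

        # records: total ramets x n_years
        age = age0[:, None] + np.arange(n_years)[None, :]
        dag = dag_base[:, None] + dag_slope[:, None] * age
        logdag_c = np.log(dag) - np.log(dag).mean()
        keep = rng.random((total, n_years)) >= cfg.dropout_rate

        log_mu = (
            np.log(cfg.nb_base_mean)
            + site_eff["nc"][site]
            + year_nc[None, :]
            + cfg.dag_beta * logdag_c
            + (g_std["nc"][ramet_idx] + ramet_nc)[:, None]
        )
        mu = np.exp(log_mu)
        k = cfg.nb_dispersion
        nc = rng.negative_binomial(k, k / (k + mu))

        # observation noise scaled so the ramet-mean residual matches 1 - h2
        m_bar = max(float((keep & (nc > 0)).sum(axis=1).mean()), 1.0)
        obs_sd = np.sqrt(0.5 * (1.0 - cfg.h2_mcw) * m_bar)
        mcw_unit = (
            site_eff["mcw"][site]
            + year_mcw[None, :]
            + (g_std["mcw"][ramet_idx] + ramet_mcw)[:, None]
            + rng.normal(0.0, obs_sd, (total, n_years))
        )
        mcw = np.clip(cfg.mcw_mean + cfg.mcw_scale * mcw_unit, 0.0, None)
        mcw = np.where(nc > 0, mcw, np.nan)  # no unspoiled cones -> no weight

        clone_per_ramet = np.asarray(clones.sample_ids)[ramet_idx]
        ramet_ids = np.array(
            [f"{site}_{c}_t{i % n_r + 1}" for i, c in enumerate(clone_per_ramet)]
        )
        frame = pd.DataFrame(
            {
                "site": site,
                "clone": np.repeat(clone_per_ramet, n_years),
                "ramet": np.repeat(ramet_ids, n_years),
                "year": np.tile(years, total),
                "age": age.ravel(),
                "nc": nc.ravel().astype(float),
                "mcw": mcw.ravel(),
                "dag": np.round(dag.ravel(), 2),
            }
        )
        frames.append(frame[keep.ravel()])
    tbl = pd.concat(frames, ignore_index=True)
    return tbl, truth


# ----------------------------------------------------------------------
# bundle + writers
# ----------------------------------------------------------------------
@dataclass
class SimDataset:
    cfg: SimConfig
    freqs: FounderFrequencies
    clones: GenotypeMatrix
    clone_meta: pd.DataFrame
    ramets: GenotypeMatrix
    sample_meta: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator: frequencies -> clones -> ramets -> phenotypes."""
    freqs = simulate_founder_frequencies(cfg)
    clones, clone_meta, truth = simulate_clones(cfg, freqs)
    ramets, sample_meta, truth = simulate_ramets(clones, clone_meta, cfg, truth)
    phenotypes, truth = simulate_phenotypes(clones, cfg, truth)
    return SimDataset(cfg, freqs, clones, clone_meta, ramets, sample_meta, phenotypes, truth)


def write_dataset(ds: SimDataset, outdir) -> dict:
    """Write genotypes (VCF + call codes), metadata, phenotypes and truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "ramets.vcf",
        "callcodes": out / "ramets_callcodes.tsv",
        "metadata": out / "metadata.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    genio.write_vcf(ds.ramets, paths["vcf"])
    genio.write_callcodes(ds.ramets, paths["callcodes"])
    ds.sample_meta.to_csv(paths["metadata"], sep="\t", index=False)
    ds.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    truth = {
        "true_h2": ds.truth.true_h2,
        "mislabelled_samples": ds.truth.mislabelled_samples,
        "injected_error_positions": ds.truth.injected_error_positions,
        "true_clonal_values": ds.truth.true_clonal_values.to_dict(orient="index"),
        "true_snp_effects": {t: list(map(float, v)) for t, v in ds.truth.true_snp_effects.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(ds.cfg).items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return {k: str(v) for k, v in paths.items()}
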