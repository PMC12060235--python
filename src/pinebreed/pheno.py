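"""Phenotype correction: ramet values, clonal BLUPs and broad-sense heritability.

Cone production in stone pine is measured repeatedly (site x ramet x year)
and is dominated by masting, i.e. very strong calendar-year effects, so raw
means are poor genetic signals.  Two traits are handled differently:

* MCW (mean cone weight, g): a repeated Gaussian measure.  One value per
  ramet is obtained from a linear mixed model with calendar year and ramet
  as crossed random effects (REML); the ramet value is the fitted mean plus
  the ramet BLUP.
* NC (number of cones): one value per ramet is the total over years, after
  correcting each yearly record for calendar year and tree diameter (DAG,
  log scale by default, for allometry) by ordinary least squares.

Clonal BLUPs then come from a one-way random-clone model on the ramet
values (with number of measured years as a covariate for NC only), and
broad-sense heritability is H2 = s2_clone / (s2_clone + s2_residual) on the
ramet-level corrected values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._reml import reml_identity

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["site", "clone", "ramet", "year", "age", "nc", "mcw", "dag"]


def validate_phenotypes(tbl: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype table and normalise dtypes."""
    missing = [c for c in PHENO_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    tbl = tbl.copy()
    dup = tbl.duplicated(subset=["site", "clone", "ramet", "year"])
    if dup.any():
        raise ValueError(f"{dup.sum()} duplicate (site, clone, ramet, year) records")
    for col in ("nc", "mcw", "dag", "age", "year"):
        tbl[col] = pd.to_numeric(tbl[col], errors="coerce")
    if (tbl["nc"].dropna() < 0).any():
        raise ValueError("negative cone counts")
    return tbl


def _ramet_key(df: pd.DataFrame) -> pd.Series:
    return df["clone"].astype(str) + "/" + df["ramet"].astype(str)


def _onehot(labels: pd.Series) -> tuple[sp.csr_matrix, list]:
    cats = pd.Categorical(labels)
    Z = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), cats.codes)),
        shape=(len(labels), len(cats.categories)),
    )
    return Z, list(cats.categories)


# ----------------------------------------------------------------------
# stage 1: one value per ramet
# ----------------------------------------------------------------------
def ramet_blup_mcw(tbl: pd.DataFrame, site: str) -> tuple[pd.DataFrame, dict]:
    """Per-ramet corrected MCW at one site (year + ramet random, REML).

    Returns a table (clone, ramet, value, n_years) where value = fitted
    mean + ramet BLUP, and the variance components
    {sigma2_year, sigma2_ramet, sigma2_e}.
    """
    sub = tbl[(tbl["site"] == site) & tbl["mcw"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no MCW records at site {site!r}")
    if sub["year"].nunique() < 2:
        raise ValueError(f"need >= 2 years with MCW data at site {site!r}")
    dropped = set(_ramet_key(tbl[tbl["site"] == site])) - set(_ramet_key(sub))
    if dropped:
        logger.info("ramet_blup_mcw[%s]: %d ramets without MCW records", site, len(dropped))
    key = _ramet_key(sub)
    Z_year, _ = _onehot(sub["year"].astype(int).astype(str))
    Z_ramet, ramets = _onehot(key)
    y = sub["mcw"].to_numpy(float)
    X = np.ones((len(y), 1))
    fit = reml_identity(y, X, [Z_year, Z_ramet])
    mean = float(fit.beta[0])
    values = mean + fit.blups[1]
    n_years = key.groupby(key.values).size()
    clone_of = sub.groupby(key.values)["clone"].first()
    ramet_of = sub.groupby(key.values)["ramet"].first()
    out = pd.DataFrame(
        {
            "clone": clone_of.loc[ramets].to_numpy(),
            "ramet": ramet_of.loc[ramets].to_numpy(),
            "value": values,
            "n_years": n_years.loc[ramets].to_numpy(),
        }
    )
    comps = {
        "sigma2_year": fit.sigma2[0],
        "sigma2_ramet": fit.sigma2[1],
        "sigma2_e": fit.sigma2_e,
        "mean": mean,
    }
    return out, comps


def accumulate_nc(
    tbl: pd.DataFrame, site: str, dag_transform: str = "log"
) -> pd.DataFrame:
    """Per-ramet corrected total cone count at one site.

    Each yearly record is corrected for calendar year (factor) and tree
    diameter (linear in log DAG by default, ``dag_transform='linear'`` for
    the identity scale) by OLS; the corrected record is the grand mean plus
    the residual.  Corrected records are summed per ramet (negative totals
    floored at zero, logged) and the number of measured years retained.
    """
    sub = tbl[(tbl["site"] == site) & tbl["nc"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no NC records at site {site!r}")
    n_nodag = int(sub["dag"].isna().sum())
    if n_nodag:
        logger.info("accumulate_nc[%s]: dropped %d records without DAG", site, n_nodag)
        sub = sub[sub["dag"].notna()]
    if (sub["dag"] <= 0).any():
        raise ValueError("DAG must be positive")
    dag = np.log(sub["dag"].to_numpy(float)) if dag_transform == "log" else sub[
        "dag"
    ].to_numpy(float)
    year_d = pd.get_dummies(sub["year"].astype(int), drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(sub)), year_d.to_numpy(), dag])
    y = sub["nc"].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    corrected = y.mean() + resid
    key = _ramet_key(sub)
    total = pd.Series(corrected).groupby(key.values).sum()
    n_years = key.groupby(key.values).size()
    clone_of = sub.groupby(key.values)["clone"].first()
    ramet_of = sub.groupby(key.values)["ramet"].first()
    n_floor = int((total < 0).sum())
    if n_floor:
        logger.info("accumulate_nc[%s]: floored %d negative totals at 0", site, n_floor)
    out = pd.DataFrame(
        {
            "clone": clone_of,
            "ramet": ramet_of,
            "value": total.clip(lower=0.0),
            "n_years": n_years,
        }
    ).reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# stage 2: clonal BLUPs + heritability
# ----------------------------------------------------------------------
@dataclass
class ClonalBLUPTable:
    """Clone-level genetic values and the variance components behind them."""

    site: str
    trait: str
    blups: pd.Series                 # clone_id -> BLUP (deviation from mean)
    mean: float
    components: dict                 # sigma2_clone, sigma2_e (+ covariate betas)
    n_ramets: pd.Series
    low_support: list[str]           # clones represented by a single ramet


def clonal_blups(
    ramet_values: pd.DataFrame,
    site: str = "",
    trait: str = "",
    covariate_nyears: bool = False,
) -> ClonalBLUPTable:
    """One-way random-clone REML fit on per-ramet values.

    ``value ~ mean (+ n_years covariate when requested, i.e. for NC) +
    clone (random) + residual``.  BLUPs are deviations around the fitted
    mean; clones with a single ramet are still predicted (shrunken) but
    flagged low-support.
    """
    if not {"clone", "value", "n_years"}.issubset(ramet_values.columns):
        raise ValueError("ramet_values needs columns clone, value, n_years")
    y = ramet_values["value"].to_numpy(float)
    X = np.ones((len(y), 1))
    if covariate_nyears:
        X = np.column_stack([X, ramet_values["n_years"].to_numpy(float)])
    Z, clones = _onehot(ramet_values["clone"].astype(str))
    fit = reml_identity(y, X, [Z])
    counts = ramet_values.groupby("clone").size()
    return ClonalBLUPTable(
        site=site,
        trait=trait,
        blups=pd.Series(fit.blups[0], index=clones, name="blup"),
        mean=float(fit.beta[0]),
        components={
            "sigma2_clone": fit.sigma2[0],
            "sigma2_e": fit.sigma2_e,
            "beta": [float(b) for b in fit.beta],
        },
        n_ramets=counts,
        low_support=sorted(counts.index[counts == 1]),
    )


def broad_sense_h2(components: dict) -> float:
    """Broad-sense heritability H2 = s2_clone / (s2_clone + s2_residual).

    Computed on ramet-level corrected values (year variance already removed
    upstream).  Returns NaN when both components are zero.
    """
    s2c = components["sigma2_clone"]
    s2e = components["sigma2_e"]
    if s2c < 0 or s2e < 0:
        raise ValueError("variance components must be non-negative")
    if s2c + s2e == 0:
        logger.warning("broad_sense_h2: both components zero; undefined")
        return float("nan")
    return float(s2c / (s2c + s2e))


def site_trait_blups(tbl: pd.DataFrame, site: str, trait: str) -> ClonalBLUPTable:
    """End-to-end per-site pipeline: records -> ramet values -> clonal BLUPs."""
    trait = trait.lower()
    if trait == "mcw":
        ramet_vals, _ = ramet_blup_mcw(tbl, site)
        return clonal_blups(ramet_vals, site, "MCW", covariate_nyears=False)
    if trait == "nc":
        ramet_vals = accumulate_nc(tbl, site)
        return clonal_blups(ramet_vals, site, "NC", covariate_nyears=True)
    raise ValueError(f"unknown trait {trait!r}")
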