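"""Genomic relationships, inbreeding and relatedness-network edges.

The genomic relationship matrix (GRM) follows VanRaden's first method:
with dosage matrix M (one row per clone), per-locus ALT frequencies p and
Z = M - 2p,

    G = Z Z' / (2 * sum_l p_l (1 - p_l))

Missing dosages are mean-imputed before centering; monomorphic loci are
dropped.  The diagonal of G averages 1 + f where f is the genomic
inbreeding coefficient; F_IS = 1 - Ho/Hs gives a within-group alternative
based on heterozygosity.  A plain mean-IBS matrix is available for
comparison with the ambiguity-free "probability of identity by state"
reading of the estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmatrix import GenotypeMatrix
from . import genio

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Clone x clone genomic relationship matrix."""

    clone_ids: list[str]
    values: np.ndarray
    allele_freqs_used: np.ndarray
    loci_used: list[str]

    @property
    def n(self) -> int:
        return len(self.clone_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.clone_ids, columns=self.clone_ids)


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    x = g.dosages_float()
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    return x


def compute_grm(
    g: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    min_maf: float = 0.0,
    method: str = "vanraden",
) -> GRM:
    """Compute the GRM (VanRaden method 1, or plain mean-IBS with ``method='ibs'``).

    Parameters
    ----------
    g :
        Genotypes, typically one consensus row per clone.
    freqs :
        Optional external per-locus ALT frequencies; defaults to in-sample
        frequencies (with which every row of G sums to zero).
    min_maf :
        Loci with MAF <= min_maf are dropped (default drops monomorphic loci).
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = _imputed_dosages(g)
    p = np.asarray(freqs, dtype=float) if freqs is not None else x.mean(axis=0) / 2.0
    if p.shape != (g.n_loci,):
        raise ValueError("freqs length does not match number of loci")
    maf = np.minimum(p, 1.0 - p)
    keep = maf > min_maf
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("compute_grm: dropped %d loci with maf <= %g", n_drop, min_maf)
    if not keep.any():
        raise ValueError("zero denominator: all loci monomorphic")
    x = x[:, keep]
    p = p[keep]
    if method == "vanraden":
        z = x - 2.0 * p
        denom = 2.0 * float(np.sum(p * (1.0 - p)))
        values = (z @ z.T) / denom
    elif method == "ibs":
        # mean per-locus probability that a randomly drawn allele from each
        # individual is identical by state, rescaled to [-1, 1]-ish range
        xa = x / 2.0
        s = (xa @ xa.T + (1 - xa) @ (1 - xa).T) / x.shape[1]
        values = 2.0 * s - 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    values = (values + values.T) / 2.0
    return GRM(
        clone_ids=list(g.sample_ids),
        values=values,
        allele_freqs_used=p,
        loci_used=[l for l, k in zip(g.locus_ids, keep) if k],
    )


def inbreeding_from_grm(grm: GRM, groups: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Per-group genomic inbreeding and mean IBD relationships.

    For each group (provenance region): ``f_grm`` = mean(G_ii) - 1 with SD;
    ``ibd_within`` = mean off-diagonal G_ij over within-group pairs;
    ``ibd_between`` = mean G_ij over pairs (i in group, j outside), with the
    number of clones compared against (``n2``).  Singleton groups get NaN
    within-group IBD (flagged by n1 = 1).
    """
    groups = pd.Series(groups)
    missing = [c for c in grm.clone_ids if c not in groups.index]
    if missing:
        raise ValueError(f"groups do not cover clones: {missing[:5]}")
    lab = groups.loc[grm.clone_ids].to_numpy()
    G = grm.values
    rows = []
    for region in pd.unique(lab):
        inside = lab == region
        n1 = int(inside.sum())
        diag = np.diag(G)[inside]
        sub = G[np.ix_(inside, inside)]
        off = sub[np.triu_indices(n1, k=1)]
        cross = G[np.ix_(inside, ~inside)].ravel()
        rows.append(
            {
                "region": region,
                "n1": n1,
                "f_grm": float(diag.mean() - 1.0),
                "f_grm_sd": float(diag.std(ddof=1)) if n1 > 1 else np.nan,
                "ibd_within": float(off.mean()) if n1 > 1 else np.nan,
                "ibd_within_sd": float(off.std(ddof=1)) if len(off) > 1 else np.nan,
                "n2": int((~inside).sum()),
                "ibd_between": float(cross.mean()) if cross.size else np.nan,
                "ibd_between_sd": float(cross.std(ddof=1)) if cross.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def fis(
    g: GenotypeMatrix,
    groups: dict[str, str] | pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-group F_IS = 1 - Ho/Hs with a percentile bootstrap CI over loci.

    Ho and Hs are averaged over the loci polymorphic within the group; the
    ratio of averages matches the standard multilocus estimator.  Groups
    where every locus is monomorphic get NaN (flagged ``defined=False``).
    """
    groups = pd.Series(groups)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for region in pd.unique(groups.loc[g.sample_ids]):
        members = [s for s in g.sample_ids if groups.loc[s] == region]
        stats = genio.locus_stats(g.subset(samples=members))
        poly = stats[(stats["Hs"] > 0) & stats["defined"]]
        if poly.empty:
            rows.append({"region": region, "n": len(members), "fis": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "defined": False})
            continue
        ho = poly["Ho"].to_numpy()
        hs = poly["Hs"].to_numpy()
        point = 1.0 - ho.mean() / hs.mean()
        L = len(ho)
        picks = rng.integers(0, L, size=(n_boot, L))
        boots = 1.0 - ho[picks].mean(axis=1) / hs[picks].mean(axis=1)
        rows.append(
            {
                "region": region,
                "n": len(members),
                "fis": float(point),
                "ci_low": float(np.quantile(boots, alpha)),
                "ci_high": float(np.quantile(boots, 1.0 - alpha)),
                "defined": True,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def ibd_network_edges(
    grm: GRM,
    relatedness_factor: float = 0.0001,
    groups: dict[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relatedness-network edges: undirected pairs with G_ij > relatedness_factor.

    Returns the edge list (clone_i, clone_j, weight) and a per-node degree
    report (with region labels when ``groups`` is given).
    """
    G = grm.values
    n = grm.n
    iu = np.triu_indices(n, k=1)
    mask = G[iu] > relatedness_factor
    edges = pd.DataFrame(
        {
            "clone_i": [grm.clone_ids[i] for i in iu[0][mask]],
            "clone_j": [grm.clone_ids[j] for j in iu[1][mask]],
            "weight": G[iu][mask],
        }
    )
    degree = pd.Series(0, index=grm.clone_ids, name="degree")
    for col in ("clone_i", "clone_j"):
        counts = edges[col].value_counts()
        degree.loc[counts.index] += counts
    report = degree.to_frame()
    if groups is not None:
        report["region"] = pd.Series(groups).loc[report.index].to_numpy()
    return edges, report
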