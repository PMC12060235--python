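"""Clonal identity verification and multilocus-lineage (MLG) collapsing.

Each named clone in a breeding archive is represented by one or more ramets
(grafted copies).  Genotyping replicate ramets lets us (i) build a consensus
genotype per clone, (ii) estimate per-sample and per-SNP genotyping error
rates from ramet-vs-consensus mismatches, (iii) flag and exclude mislabelled
ramets whose error rate exceeds a threshold, and (iv) collapse samples into
multilocus lineages by complete-linkage clustering of Nei's genetic distance
with an automatically predicted similarity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gmatrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default per-sample error-rate threshold above which a ramet is excluded.
DEFAULT_ERROR_THRESHOLD = 0.025


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------
@dataclass
class CloneRecord:
    clone_id: str
    region: str
    registered: bool
    members: list[str]
    retained: list[str] = field(default_factory=list)
    consensus: np.ndarray | None = None
    support: np.ndarray | None = None
    unverifiable: bool = False


@dataclass
class CloneRegistry:
    """Sample -> clone -> region map plus per-clone consensus genotypes."""

    clones: dict[str, CloneRecord]

    @classmethod
    def from_metadata(cls, meta: pd.DataFrame) -> "CloneRegistry":
        """Build from a metadata table with columns sample_id, clone_id, region, registered."""
        required = {"sample_id", "clone_id", "region", "registered"}
        if not required.issubset(meta.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        clones: dict[str, CloneRecord] = {}
        for clone_id, grp in meta.groupby("clone_id", sort=True):
            regions = grp["region"].unique()
            clones[str(clone_id)] = CloneRecord(
                clone_id=str(clone_id),
                region=str(regions[0]),
                registered=bool(grp["registered"].iloc[0]),
                members=[str(s) for s in grp["sample_id"]],
            )
        return cls(clones)

    def sample_to_clone(self) -> dict[str, str]:
        return {s: rec.clone_id for rec in self.clones.values() for s in rec.members}


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------
def mismatch_count(a: np.ndarray, b: np.ndarray, allele_level: bool = False) -> tuple[int, int]:
    """Mismatches between two genotype vectors, ignoring missing data.

    Returns ``(mismatches, compared)`` where ``compared`` counts loci
    non-missing in both vectors.  By default any dosage difference counts as
    one mismatch (genotype-level); with ``allele_level=True`` the absolute
    dosage difference is summed instead (0 vs 2 counts twice).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    both = (a != MISSING) & (b != MISSING)
    compared = int(both.sum())
    if allele_level:
        mm = int(np.abs(a[both].astype(int) - b[both].astype(int)).sum())
    else:
        mm = int((a[both] != b[both]).sum())
    return mm, compared


def build_consensus(g: GenotypeMatrix, members: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus majority call over the member samples.

    Ties and all-missing loci yield MISSING (no call is invented).  Returns
    the consensus vector and the per-locus majority support count.
    """
    if not members:
        raise ValueError("need at least one member sample")
    rows = np.array([g.sample_index(s) for s in members])
    calls = g.calls[rows]
    counts = np.stack([(calls == k).sum(axis=0) for k in (0, 1, 2)])  # 3 x loci
    top = counts.max(axis=0)
    is_tie = (counts == top[None, :]).sum(axis=0) > 1
    consensus = np.argmax(counts, axis=0).astype(np.int8)
    consensus[(top == 0) | is_tie] = MISSING
    support = top.astype(int)
    support[consensus == MISSING] = 0
    return consensus, support


# ----------------------------------------------------------------------
# verification
# ----------------------------------------------------------------------
def verify_ramets(
    g: GenotypeMatrix,
    registry: CloneRegistry,
    error_threshold: float = DEFAULT_ERROR_THRESHOLD,
    allele_level: bool = False,
) -> tuple[pd.DataFrame, CloneRegistry]:
    """Two-pass identity check of every ramet against its clone's consensus.

    Pass 1 builds consensus genotypes from all labelled members and excludes
    members whose mismatch rate exceeds ``error_threshold``.  Pass 2 rebuilds
    the consensus from the retained members only and recomputes the final
    per-sample rates (reported for excluded samples too, against the clean
    consensus).

    Returns
    -------
    (reports, registry) :
        ``reports`` has one row per sample: clone_id, region, mismatches,
        compared, error_rate (NaN when nothing could be compared), excluded.
        The registry is updated in place with retained members, final
        consensus vectors and support counts.
    """
    if not 0 <= error_threshold < 1:
        raise ValueError("error_threshold must be in [0, 1)")
    rows = []
    for rec in registry.clones.values():
        consensus, _ = build_consensus(g, rec.members)
        retained = []
        for s in rec.members:
            mm, comp = mismatch_count(g.calls[g.sample_index(s)], consensus, allele_level)
            rate = mm / comp if comp else np.nan
            if comp and rate > error_threshold:
                continue
            retained.append(s)
        if not retained:
            logger.warning("clone %s: all members excluded; flagged unverifiable", rec.clone_id)
            rec.unverifiable = True
            rec.retained = []
            rec.consensus, rec.support = consensus, np.zeros(g.n_loci, dtype=int)
            final_consensus = consensus
        else:
            rec.unverifiable = False
            rec.retained = retained
            rec.consensus, rec.support = build_consensus(g, retained)
            final_consensus = rec.consensus
        for s in rec.members:
            mm, comp = mismatch_count(g.calls[g.sample_index(s)], final_consensus, allele_level)
            rate = mm / comp if comp else np.nan
            rows.append(
                {
                    "sample_id": s,
                    "clone_id": rec.clone_id,
                    "region": rec.region,
                    "mismatches": mm,
                    "compared": comp,
                    "error_rate": rate,
                    "excluded": s not in retained,
                }
            )
    return pd.DataFrame(rows), registry


def snp_error_rates(g: GenotypeMatrix, registry: CloneRegistry) -> pd.DataFrame:
    """Per-SNP genotyping error rate from retained ramets vs consensus.

    For each locus: (number of ramet calls discordant with their clone's
    consensus) / (number of ramet-consensus pairs with both non-missing),
    pooled over all clones with >= 2 retained ramets.  Requires
    :func:`verify_ramets` to have populated the registry.
    """
    mism = np.zeros(g.n_loci)
    pairs = np.zeros(g.n_loci)
    for rec in registry.clones.values():
        if rec.consensus is None:
            raise ValueError("run verify_ramets first")
        if len(rec.retained) < 2:
            continue
        for s in rec.retained:
            calls = g.calls[g.sample_index(s)]
            both = (calls != MISSING) & (rec.consensus != MISSING)
            pairs += both
            mism += both & (calls != rec.consensus)
    with np.errstate(invalid="ignore"):
        rate = np.where(pairs > 0, mism / np.maximum(pairs, 1), np.nan)
    return pd.DataFrame(
        {"locus_id": g.locus_ids, "mismatches": mism.astype(int), "compared": pairs.astype(int),
         "error_rate": rate, "defined": pairs > 0}
    ).set_index("locus_id")


def clone_summary(reports: pd.DataFrame, g: GenotypeMatrix) -> pd.DataFrame:
    """Per-clone summary of the verification stage (registered-clone table shape).

    Columns: number of retained genotypes, mean proportion of complete
    genotypes, total mismatches among retained ramets, pooled error rate and
    region of provenance.
    """
    ok = g.calls != MISSING
    comp = pd.Series(ok.mean(axis=1), index=g.sample_ids)
    rows = []
    for clone_id, grp in reports.groupby("clone_id", sort=True):
        kept = grp[~grp["excluded"]]
        compared = kept["compared"].sum()
        rows.append(
            {
                "clone_id": clone_id,
                "n_genotypes": len(kept),
                "prop_complete": comp.loc[kept["sample_id"]].mean() if len(kept) else np.nan,
                "mismatches": int(kept["mismatches"].sum()),
                "error_rate": kept["mismatches"].sum() / compared if compared else np.nan,
                "region": grp["region"].iloc[0],
            }
        )
    return pd.DataFrame(rows).set_index("clone_id")


# ----------------------------------------------------------------------
# Nei distance + MLG collapsing
# ----------------------------------------------------------------------
def nei_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise Nei (1972) standard genetic distance between individuals.

    Each individual is treated as a per-locus 2-allele frequency vector
    ``(x, 1 - x)`` with ``x = dosage / 2``; missing dosages are replaced by
    the locus mean (average allele count) first.  With per-locus identities
    summed over loci,

        D(i, j) = -ln( S_ij / sqrt(S_ii * S_jj) ),
        S_ij    = sum_l [ x_il x_jl + (1 - x_il)(1 - x_jl) ]

    Pairs with zero shared identity get ``inf`` (logged).
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = g.dosages_float() / 2.0
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)  # all-missing locus
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    s = x @ x.T + (1.0 - x) @ (1.0 - x).T
    diag = np.sqrt(np.diag(s))
    with np.errstate(divide="ignore"):
        identity = s / np.outer(diag, diag)
        d = -np.log(np.clip(identity, 0.0, 1.0))
    if np.isinf(d).any():
        logger.warning("nei_distance_matrix: %d pairs with zero shared identity",
                       int(np.isinf(d).sum() // 2))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


@dataclass
class MLGResult:
    """Multilocus-lineage assignment from complete-linkage clustering."""

    assignment: pd.Series       # sample_id -> lineage label (int)
    merge_distances: np.ndarray  # sorted heights of the dendrogram merges
    threshold: float
    n_lineages: int


def collapse_mlg(
    dist: np.ndarray,
    threshold: float,
    sample_ids: list[str] | None = None,
) -> MLGResult:
    """Collapse samples into lineages by complete-linkage ("farthest
    neighbour") clustering cut at ``threshold``.

    Two samples share a lineage iff the maximum pairwise distance within
    their cluster is <= threshold (the cophenetic distance of complete
    linkage).  Ties are broken deterministically by scipy's ordering
    (distance, then lowest observation index).
    """
    dist = np.asarray(dist, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be a square matrix")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("dist must be symmetric")
    n = dist.shape[0]
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    lk = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(lk, t=threshold, criterion="distance")
    assignment = pd.Series(labels, index=ids, name="lineage")
    return MLGResult(
        assignment=assignment,
        merge_distances=np.sort(lk[:, 2]),
        threshold=float(threshold),
        n_lineages=int(assignment.nunique()),
    )


def predict_cutoff(merge_distances: np.ndarray, fraction: float = 0.5) -> float:
    """Predict a lineage-collapsing cutoff from the dendrogram merge heights.

    Sorts the distinct merge distances, finds the largest gap between
    consecutive values (the separation between within-clone noise and
    between-clone divergence) and returns the point ``fraction`` of the way
    into that gap.
    """
    vals = np.unique(np.asarray(merge_distances, dtype=float))
    if len(vals) < 2:
        raise ValueError("need at least 2 distinct merge distances")
    gaps = np.diff(vals)
    if np.all(gaps == 0):
        raise ValueError("no gap: all distances equal")
    i = int(np.argmax(gaps))
    return float(vals[i] + fraction * gaps[i])


def pca_coordinates(g: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Plain PCA coordinates of samples (mean-imputed, centered dosages).

    Emitted for visual inspection of clonal groupings; no curation logic.
    """
    x = g.dosages_float()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    x -= x.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(sv))
    return pd.DataFrame(
        u[:, :k] * sv[:k], index=g.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
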