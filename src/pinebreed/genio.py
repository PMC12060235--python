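"""Genotype file input/output and per-locus / per-sample QC summaries.

Supported formats:

* VCF 4.x with diploid ``GT`` calls (only the GT field is consumed;
  ``0/0 -> 0``, ``0/1`` or ``1/0 -> 1``, ``1/1 -> 2``, ``./. -> MISSING``;
  phased ``|`` separators are treated like ``/``).
* Axiom-style call-code tables: TSV with one row per sample, one column per
  probe, cells in ``{AA, AB, BB, NoCall}`` mapped to dosages under a declared
  A/B -> ref/alt orientation.

QC summaries follow standard population-genetic definitions: completeness
(fraction of non-missing calls), minor allele frequency, observed
heterozygosity Ho and unbiased expected heterozygosity Hs with Nei's
``2n/(2n-1)`` small-sample correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .gmatrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

CALLCODE_TO_DOSAGE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2, "NoCall": MISSING}
DOSAGE_TO_CALLCODE = {0: "AA", 1: "AB", 2: "BB", MISSING: "NoCall"}


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(path, drop_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a diploid biallelic VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path :
        Path to a (plain or bgzipped) VCF file with a GT FORMAT field.
    drop_multiallelic :
        If True, records with more than one ALT allele are skipped with a
        logged count instead of raising.

    Raises
    ------
    ValueError
        On multiallelic records (unless dropped), haploid/odd-ploidy calls,
        or a VCF without genotypes.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples / no GT field")
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        name = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            if drop_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"{path}: record {name} is not biallelic (ALT={var.ALT})")
        if var.ploidy != 2:
            raise ValueError(f"{path}: record {name} has ploidy {var.ploidy}, need diploid")
        # with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gts = var.gt_types.astype(np.int8)
        gts[gts == 3] = MISSING
        locus_ids.append(name)
        rows.append(gts)
    if n_multi:
        logger.info("read_vcf: dropped %d multiallelic records", n_multi)
    if not rows:
        raise ValueError(f"{path}: no biallelic records found")
    calls = np.stack(rows, axis=1)  # samples x loci
    return GenotypeMatrix(samples, locus_ids, calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path, ref: str = "A", alt: str = "G") -> None:
    """Write a minimal biallelic GT-only VCF (one pseudo-contig, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------------
# Axiom-style call codes
# ----------------------------------------------------------------------
def read_callcodes(path, b_is_ref: set[str] | None = None) -> GenotypeMatrix:
    """Read a call-code TSV (samples in rows, probes in columns).

    Parameters
    ----------
    path :
        TSV with a leading sample-id column, header of locus ids and cells
        in ``{AA, AB, BB, NoCall}``.
    b_is_ref :
        Loci for which the array's B allele is the reference allele; their
        dosages are flipped (AA -> 2, BB -> 0) so that dosage always counts
        ALT alleles.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = values[i, j]
            try:
                calls[i, j] = CALLCODE_TO_DOSAGE[tok]
            except KeyError:
                raise ValueError(
                    f"{path}: unknown call code {tok!r} at sample "
                    f"{df.index[i]!r}, locus {df.columns[j]!r}"
                ) from None
    if b_is_ref:
        flip = [j for j, l in enumerate(df.columns) if l in b_is_ref]
        sub = calls[:, flip]
        sub[sub == 0] = 3
        sub[sub == 2] = 0
        sub[sub == 3] = 2
        calls[:, flip] = sub
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_callcodes(g: GenotypeMatrix, path, b_is_ref: set[str] | None = None) -> None:
    """Write the matrix as a call-code TSV (inverse of :func:`read_callcodes`)."""
    flip = b_is_ref or set()
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(g.locus_ids) + "\n")
        for i, sample in enumerate(g.sample_ids):
            toks = []
            for j, locus in enumerate(g.locus_ids):
                c = int(g.calls[i, j])
                if locus in flip and c in (0, 2):
                    c = 2 - c
                toks.append(DOSAGE_TO_CALLCODE[c])
            fh.write(sample + "\t" + "\t".join(toks) + "\n")


# ----------------------------------------------------------------------
# QC summaries
# ----------------------------------------------------------------------
def completeness(g: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Fraction of non-missing calls per locus and per sample.

    Returns
    -------
    (per_locus, per_sample) :
        Two float Series indexed by locus id and sample id respectively.
    """
    if g.n_samples == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    ok = g.calls != MISSING
    per_locus = pd.Series(ok.mean(axis=0), index=g.locus_ids, name="completeness")
    per_sample = pd.Series(ok.mean(axis=1), index=g.sample_ids, name="completeness")
    return per_locus, per_sample


def locus_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus completeness, MAF, observed and unbiased expected heterozygosity.

    For each locus with ``n`` non-missing diploid calls and ALT-allele
    frequency ``p`` (mean dosage / 2):

    * ``maf = min(p, 1 - p)``
    * ``Ho  = freq(dosage == 1)``
    * ``Hs  = 2n/(2n-1) * (1 - p^2 - (1-p)^2)`` (Nei's unbiased gene diversity)

    Loci with zero non-missing calls get ``NaN`` stats and ``defined=False``
    rather than silent zeros.
    """
    if g.n_samples == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    d = g.dosages_float()
    n = np.sum(~np.isnan(d), axis=0).astype(float)
    safe_n = np.maximum(n, 1.0)
    p = np.nansum(d, axis=0) / (2.0 * safe_n)
    ho = np.nansum(d == 1, axis=0) / safe_n
    maf = np.minimum(p, 1.0 - p)
    h_exp = 1.0 - p**2 - (1.0 - p) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        hs = np.where(n > 0.5, 2.0 * n / (2.0 * n - 1.0) * h_exp, np.nan)
    defined = n > 0
    out = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "n_called": n.astype(int),
            "completeness": n / g.n_samples,
            "maf": np.where(defined, maf, np.nan),
            "Ho": np.where(defined, ho, np.nan),
            "Hs": np.where(defined, hs, np.nan),
            "defined": defined,
        }
    )
    return out.set_index("locus_id")
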