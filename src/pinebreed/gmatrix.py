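"""Core genotype container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing (no-call) genotype.  Distinct from dosage 0.
MISSING: int = -1

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


@dataclass(eq=False)
class GenotypeMatrix:
    """Samples x loci matrix of diploid biallelic genotypes.

    Calls are alternate-allele dosages: ``0`` (hom ref), ``1`` (het),
    ``2`` (hom alt) or :data:`MISSING` for a no-call.

    Parameters
    ----------
    sample_ids :
        Ordered, unique sample labels (rows).
    locus_ids :
        Ordered, unique locus labels (columns).
    calls :
        ``(n_samples, n_loci)`` integer array with values in {0, 1, 2, -1}.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def dosages_float(self) -> np.ndarray:
        """Calls as float with MISSING mapped to ``nan``."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset(
        self,
        samples: list[str] | None = None,
        loci: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given samples and/or loci (order kept)."""
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.sample_index(s) for s in samples])
        )
        if loci is None:
            cols = np.arange(self.n_loci)
        else:
            lut = {l: j for j, l in enumerate(self.locus_ids)}
            missing = [l for l in loci if l not in lut]
            if missing:
                raise KeyError(f"unknown locus ids: {missing[:5]}")
            cols = np.array([lut[l] for l in loci])
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )
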