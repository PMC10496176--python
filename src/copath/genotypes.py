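"""Dosage-matrix container shared by QC, PCA and association stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

_VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "imputation_r2"]


@dataclass
class GenotypeMatrix:
    """Variants x individuals dosages with per-variant metadata.

    ``dosages`` holds alt-allele dose in [0, 2] with NaN for missing calls;
    ``hard_genotypes`` (optional) holds called genotypes {0, 1, 2} with NaN
    for missing.  ``variants`` carries id/chrom/pos/ref/alt and
    ``imputation_r2`` (NaN means directly genotyped).
    """

    variants: pd.DataFrame
    samples: list
    dosages: np.ndarray
    hard_genotypes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in _VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        if self.hard_genotypes is not None:
            self.hard_genotypes = np.asarray(self.hard_genotypes, dtype=float)
            if self.hard_genotypes.shape != self.dosages.shape:
                raise ValueError("hard_genotypes shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from exc

    def subset_samples(self, ids: Sequence) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            hard_genotypes=None
            if self.hard_genotypes is None
            else self.hard_genotypes[:, idx].copy(),
        )

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            dosages=self.dosages[index].copy(),
            hard_genotypes=None
            if self.hard_genotypes is None
            else self.hard_genotypes[index].copy(),
        )
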