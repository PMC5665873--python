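"""Count-matrix container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("source", "group", "subject")


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus optional per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame with gene ids in the index and sample ids in the columns.
        Entries must be finite, non-negative integers (or integral floats).
    samples
        Optional DataFrame indexed by sample id with columns ``source``,
        ``group`` and ``subject``.  When given, its index must cover every
        column of ``counts``.
    """

    counts: pd.DataFrame
    samples: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("counts contain non-finite values")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        if self.samples is not None:
            missing = set(self.counts.columns) - set(self.samples.index)
            if missing:
                raise ValueError(
                    f"samples metadata missing entries for: {sorted(missing)}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)

    def groups(self) -> pd.Series:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        return self.samples.loc[self.counts.columns, "group"]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        samples = None
        if self.samples is not None:
            samples = self.samples.loc[sample_ids]
        return CountMatrix(self.counts[list(sample_ids)], samples)
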