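"""Count tables and depth normalization by downsampling.

The raw input to screen scoring is an elements x samples matrix of integer
read counts with per-sample condition/replicate metadata.  Samples are
equalized to a common depth by exact subsampling without replacement
(multivariate hypergeometric draw per column), so every downsampled column
sums to the target exactly and no entry exceeds its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ScreenStateError
from .library import SgRNALibrary

__all__ = ["CountTable", "downsample_counts"]

CONDITIONS = ("T0", "vehicle", "drug")


@dataclass
class CountTable:
    """Elements x samples integer counts plus per-sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Rows indexed by element id, columns by sample id, nonnegative ints.
    sample_meta : DataFrame
        Indexed by sample id with columns ``condition`` (one of T0 /
        vehicle / drug) and ``replicate`` (arbitrary hashable id).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not set(self.counts.columns) <= set(self.sample_meta.index):
            missing = sorted(set(self.counts.columns) - set(self.sample_meta.index))
            raise ScreenStateError(f"samples without metadata: {missing}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ScreenStateError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ScreenStateError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ScreenStateError(
                f"negative count at element {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ScreenStateError(f"duplicate element ids in counts: {dupes[:5]}")

    @property
    def element_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def conditions_present(self) -> set[str]:
        return set(self.sample_meta.loc[self.sample_ids, "condition"])

    def samples_of(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["condition"] == condition])

    def condition_sum(self, condition: str) -> pd.Series:
        """Replicates of one condition summed into a single pseudo-sample."""
        samples = self.samples_of(condition)
        if not samples:
            raise ScreenStateError(f"no samples for condition {condition!r}")
        return self.counts[samples].sum(axis=1)

    def aligned_to(self, library: SgRNALibrary) -> "CountTable":
        """Reindex rows to the library order; absent elements become count 0."""
        unknown = sorted(set(self.counts.index) - set(library.element_ids))
        counts = self.counts.reindex(library.element_ids, fill_value=0)
        table = CountTable(counts=counts, sample_meta=self.sample_meta)
        table.unknown_elements = unknown  # type: ignore[attr-defined]
        return table


def downsample_counts(table: CountTable, target_depth: int, seed: int) -> CountTable:
    """Subsample every column without replacement to exactly ``target_depth``.

    Each column is an independent multivariate-hypergeometric draw: pick
    ``target_depth`` reads uniformly from the column's reads.  Deterministic
    under ``seed``.

    Raises
    ------
    ScreenStateError
        If ``target_depth`` exceeds any column sum (names the sample).
    """
    if target_depth < 0:
        raise ScreenStateError("target_depth must be nonnegative")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if target_depth > total:
            raise ScreenStateError(
                f"target_depth {target_depth} exceeds column sum {total} "
                f"of sample {sample!r}"
            )
        out[sample] = rng.multivariate_hypergeometric(col, target_depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    return CountTable(counts=counts, sample_meta=table.sample_meta)
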