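"""In-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`: a probes x samples table of
non-negative linear-scale intensities plus a sample -> group assignment.
Intensities are assumed to be the output of upstream array summarization and
normalization; this package starts from the normalized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Probe-level expression matrix with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample, float
        intensities. No missing values; intensities must be >= 0.
    groups
        Series indexed by sample id mapping each sample to its group label
        (e.g. ``"ACR"`` / ``"LH"``). Must cover exactly the columns of
        ``values``, with at least two samples per group.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dupes[:5]}")
        if v.isna().any().any():
            bad = v.columns[v.isna().any()].tolist()
            raise ValueError(f"missing values in sample column(s) {bad[:5]}")
        if (v.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        g = pd.Series(self.groups)
        missing = [s for s in v.columns if s not in g.index]
        if missing:
            raise ValueError(f"sample(s) missing from sample sheet: {missing}")
        extra = [s for s in g.index if s not in v.columns]
        if extra:
            raise ValueError(f"sample sheet has sample(s) absent from matrix: {extra}")
        self.groups = g.loc[v.columns]
        counts = self.groups.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"every group needs >=2 samples; got {small.to_dict()}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_means(self, group: str) -> pd.Series:
        """Arithmetic per-probe mean over the samples of one group."""
        cols = self.samples_in_group(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, groups=self.groups.copy())

    def scaled(self, k: float) -> "ExpressionMatrix":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return self.copy_with(self.values * float(k))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.groups.equals(other.groups)

    def allclose(self, other: "ExpressionMatrix", rtol: float = 1e-12) -> bool:
        return (
            self.values.shape == other.values.shape
            and list(self.probe_ids) == list(other.probe_ids)
            and list(self.sample_ids) == list(other.sample_ids)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(), rtol=rtol)
            and self.groups.equals(other.groups)
        )
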