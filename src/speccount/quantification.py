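"""Spectral-count matrices and between-sample normalization.

Relative quantification is by spectral counting: the raw count of a protein
group in a sample is the number of accepted PSMs whose peptide is
razor-assigned to the group. Normalized spectral counts (N-SC) rescale each
sample so all sample totals equal the grand mean of the raw totals
(total-spectral-count scaling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PsmRecord, SampleInfo, ValidationError
from .identification import ProteinGroup

__all__ = ["CountMatrix", "count_spectra", "normalize_counts", "read_count_matrix", "write_count_matrix"]


@dataclass
class CountMatrix:
    """Protein-group x sample spectral counts.

    ``data`` is indexed by group_id with one column per sample_id;
    ``scale_factors`` holds the per-sample multipliers applied during
    normalization (all 1.0 while raw).
    """

    data: pd.DataFrame
    scale_factors: pd.Series
    normalized: bool = False

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    @classmethod
    def from_frame(cls, data: pd.DataFrame, normalized: bool = False,
                   scale_factors: pd.Series | None = None) -> "CountMatrix":
        if scale_factors is None:
            scale_factors = pd.Series(1.0, index=data.columns)
        return cls(data=data, scale_factors=scale_factors, normalized=normalized)


def count_spectra(
    psms: Sequence[PsmRecord],
    groups: Sequence[ProteinGroup],
    samples: Sequence[SampleInfo],
) -> CountMatrix:
    """Count accepted PSMs per (razor-assigned protein group, sample).

    PSMs whose peptide belongs to no retained group's razor set are not
    counted; a PSM naming an unknown sample raises.
    """
    sample_ids = [s.sample_id for s in samples]
    sample_pos = {sid: j for j, sid in enumerate(sample_ids)}
    group_ids = [g.group_id for g in groups]
    group_pos = {gid: i for i, gid in enumerate(group_ids)}
    razor_group: dict[str, str] = {}
    for g in groups:
        for pep in g.razor_peptides:
            razor_group[pep] = g.group_id

    counts = np.zeros((len(group_ids), len(sample_ids)), dtype=np.int64)
    for p in psms:
        gid = razor_group.get(p.peptide)
        if gid is None:
            continue
        j = sample_pos.get(p.sample_id)
        if j is None:
            raise ValidationError(f"PSM sample {p.sample_id!r} not in the sample table")
        counts[group_pos[gid], j] += 1

    data = pd.DataFrame(counts, index=group_ids, columns=sample_ids)
    return CountMatrix.from_frame(data)


def normalize_counts(matrix: CountMatrix) -> CountMatrix:
    """Total-spectral-count normalization to the grand mean of sample totals.

    scale_factor(s) = mean(raw totals) / raw_total(s); the grand total is
    conserved and within-sample rank order of proteins is unchanged.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    totals = matrix.totals()
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"sample(s) with zero total counts: {zero}")
    factors = totals.mean() / totals
    data = matrix.data * factors
    return CountMatrix(data=data, scale_factors=factors.astype(float), normalized=True)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "group_id"
    df.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path, normalized: bool = False) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="group_id")
    df.index = df.index.astype(str)
    return CountMatrix.from_frame(df, normalized=normalized)
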