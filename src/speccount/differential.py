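"""Three-filter differential-abundance calling and cross-depot concordance.

A protein is called differentially abundant between diabetic and nondiabetic
patients within one fat depot only if all three filters pass:

1. commonality — observed (>= 1 raw spectrum) in strictly more than 50% of
   the samples of at least one group;
2. Wilcoxon — two-sided rank-sum p-value on N-SC at or below alpha (0.05);
3. fold change — |signed fold change| of the pseudocount-adjusted group
   means of N-SC at or above the cutoff (1.5, or the calibrated value).

The signed fold change is +r when the diabetic mean is higher and -r when
the nondiabetic mean is higher, where r >= 1 is the ratio of the larger to
the smaller adjusted mean, so the value never falls in the open interval
(-1, 1). No multiple-testing correction is applied: the
per-protein alpha together with the fold-change and commonality guards is
the operating rule of this design.

The Wilcoxon p-value is exact by full enumeration of group assignments of
the observed multiset (midranks, so ties are handled exactly) up to 14
observations total, and the tie-corrected normal approximation without
continuity correction above that.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import PipelineConfig, SampleInfo, ValidationError
from .quantification import CountMatrix

__all__ = [
    "DifferentialCall",
    "DepotOverlap",
    "commonality_filter",
    "wilcoxon_test",
    "signed_fold_change",
    "call_differential",
    "depot_overlap",
]

EXACT_MAX_N = 14


@dataclass(frozen=True)
class DifferentialCall:
    group_id: str
    fold_change: float
    p_value: float
    commonality_diabetic: float
    commonality_nondiabetic: float
    passes_commonality: bool
    passes_wilcoxon: bool
    passes_fc: bool
    significant: bool
    total_peptides: int = 0
    name: str = ""


@dataclass(frozen=True)
class DepotOverlap:
    identified_sc: frozenset[str]
    identified_om: frozenset[str]
    identified_both: frozenset[str]
    differential_sc: frozenset[str]
    differential_om: frozenset[str]
    differential_both: frozenset[str]
    concordant: frozenset[str]


def commonality_filter(
    raw_counts: Sequence[float],
    groups: Sequence[str],
    fraction: float,
) -> tuple[float, float, bool]:
    """Fraction of samples with >= 1 spectrum per group; pass if either
    fraction is strictly greater than ``fraction``."""
    counts = np.asarray(raw_counts, dtype=float)
    labels = np.asarray(groups)
    frac = {}
    for g in ("diabetic", "nondiabetic"):
        mask = labels == g
        if not mask.any():
            raise ValidationError(f"group {g!r} has zero samples")
        frac[g] = float(np.mean(counts[mask] > 0))
    passed = frac["diabetic"] > fraction or frac["nondiabetic"] > fraction
    return frac["diabetic"], frac["nondiabetic"], passed


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments of
    the pooled multiset (midranks)."""
    pooled = np.concatenate([x, y])
    n = pooled.size
    nx = x.size
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = 0
    hits = 0
    for idx in itertools.combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration for <= 14 total observations; otherwise the
    tie-corrected normal approximation without continuity correction.
    Identical values across both groups give p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if pooled.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    p = float(res.pvalue)
    if math.isnan(p):  # zero tie-corrected variance
        return 1.0
    return min(p, 1.0)


def signed_fold_change(mean_a: float, mean_b: float, pseudocount: float) -> float:
    """Signed ratio of pseudocount-adjusted means (a = diabetic, b = nondiabetic).

    Returns +r if r = (mean_a + c)/(mean_b + c) >= 1, else -1/r, so the
    magnitude is always >= 1 and the sign marks the higher group.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("means must be nonnegative")
    if pseudocount == 0 and (mean_a == 0 or mean_b == 0):
        raise ValidationError("undefined ratio: zero mean with zero pseudocount")
    r = (mean_a + pseudocount) / (mean_b + pseudocount)
    return r if r >= 1.0 else -1.0 / r


def call_differential(
    matrix: CountMatrix,
    raw: CountMatrix,
    samples: Sequence[SampleInfo],
    depot: str,
    config: PipelineConfig,
    peptide_counts: Mapping[str, int] | None = None,
    names: Mapping[str, str] | None = None,
) -> list[DifferentialCall]:
    """Apply the three-filter test per protein within one depot.

    Commonality is evaluated on raw counts (a protein is "observed" when a
    spectrum was seen); Wilcoxon and fold change on N-SC. QC injections are
    excluded. Output is sorted by fold change descending.
    """
    depot_samples = [s for s in samples if s.depot == depot and not s.is_qc]
    if not depot_samples:
        raise ValidationError(f"depot {depot!r} absent from the sample metadata")
    ids = [s.sample_id for s in depot_samples]
    labels = np.array([s.group for s in depot_samples])
    for g in ("diabetic", "nondiabetic"):
        if int((labels == g).sum()) < 2:
            raise ValidationError(f"depot {depot!r}: need >= 2 samples in group {g!r}")

    nsc = matrix.data[ids]
    rawc = raw.data[ids]
    dia = labels == "diabetic"
    non = labels == "nondiabetic"

    calls: list[DifferentialCall] = []
    for gid in matrix.proteins:
        raw_row = rawc.loc[gid].to_numpy(dtype=float)
        nsc_row = nsc.loc[gid].to_numpy(dtype=float)
        com_d, com_n, passes_com = commonality_filter(raw_row, labels, config.commonality_fraction)
        p = wilcoxon_test(nsc_row[dia], nsc_row[non])
        fc = signed_fold_change(
            float(nsc_row[dia].mean()), float(nsc_row[non].mean()), config.pseudocount
        )
        passes_w = p <= config.alpha
        passes_fc = abs(fc) >= config.fc_cutoff
        calls.append(
            DifferentialCall(
                group_id=gid,
                fold_change=fc,
                p_value=p,
                commonality_diabetic=com_d,
                commonality_nondiabetic=com_n,
                passes_commonality=passes_com,
                passes_wilcoxon=passes_w,
                passes_fc=passes_fc,
                significant=passes_com and passes_w and passes_fc,
                total_peptides=(peptide_counts or {}).get(gid, 0),
                name=(names or {}).get(gid, ""),
            )
        )
    calls.sort(key=lambda c: -c.fold_change)
    return calls


def depot_overlap(
    calls_sc: Sequence[DifferentialCall],
    calls_om: Sequence[DifferentialCall],
    identified_sc: set[str] | frozenset[str],
    identified_om: set[str] | frozenset[str],
) -> DepotOverlap:
    """Identified/differential overlap between depots plus sign concordance."""
    diff_sc = {c.group_id: c for c in calls_sc if c.significant}
    diff_om = {c.group_id: c for c in calls_om if c.significant}
    both_diff = frozenset(diff_sc) & frozenset(diff_om)
    concordant = frozenset(
        g for g in both_diff
        if math.copysign(1, diff_sc[g].fold_change) == math.copysign(1, diff_om[g].fold_change)
    )
    return DepotOverlap(
        identified_sc=frozenset(identified_sc),
        identified_om=frozenset(identified_om),
        identified_both=frozenset(identified_sc) & frozenset(identified_om),
        differential_sc=frozenset(diff_sc),
        differential_om=frozenset(diff_om),
        differential_both=both_diff,
        concordant=concordant,
    )
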