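"""Run-to-run reproducibility metrics and empirical fold-change calibration.

Technical reproducibility of repeated QC injections is summarized on the
natural-log normalized spectral counts (ln N-SC): pairwise Pearson R of
ln-ln scatter, and the average relative standard deviation (RSD%) of ln N-SC
across runs. The differential fold-change cutoff is calibrated from replicate
runs of a control experiment: over the inner-quartile proteins (those whose
mean ln N-SC lies in the IQR of that distribution), the absolute ln-ratio d
between run pairs is collected and the cutoff is exp of the smallest d
covering at least the requested fraction of points (99% by default). For
pure Gaussian ln-noise with per-run sd sigma this converges to
exp(z * sigma * sqrt(2)) with z the two-sided coverage quantile.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quantification import CountMatrix

__all__ = [
    "QcError",
    "QcReport",
    "FcCalibration",
    "ln_ln_pearson",
    "average_ln_rsd",
    "qc_report",
    "calibrate_fc_cutoff",
]


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class QcReport:
    pairwise_R: tuple[tuple[str, str, float], ...]
    mean_R: float
    average_ln_rsd_percent: float
    n_proteins_used: int


@dataclass(frozen=True)
class FcCalibration:
    cutoff: float
    coverage_at_cutoff: float
    coverage_at_1p5: float
    pearson_R: float
    n_points: int


def ln_ln_pearson(matrix: CountMatrix, sample_a: str, sample_b: str) -> float:
    """Pearson R of (ln N-SC_a, ln N-SC_b) over proteins nonzero in both."""
    a = matrix.data[sample_a].to_numpy(dtype=float)
    b = matrix.data[sample_b].to_numpy(dtype=float)
    mask = (a > 0) & (b > 0)
    if int(mask.sum()) < 3:
        raise QcError(
            f"insufficient overlap between {sample_a!r} and {sample_b!r}: "
            f"{int(mask.sum())} common nonzero proteins (need >= 3)"
        )
    la, lb = np.log(a[mask]), np.log(b[mask])
    if la.std() == 0 or lb.std() == 0:
        return 1.0 if np.allclose(la - la.mean(), lb - lb.mean()) else 0.0
    return float(np.corrcoef(la, lb)[0, 1])


def average_ln_rsd(matrix: CountMatrix, qc_samples: Sequence[str]) -> float:
    """Mean per-protein RSD% of ln N-SC across QC runs.

    Uses proteins nonzero in every QC run with positive mean ln N-SC;
    RSD% = 100 * sd(ln N-SC) / mean(ln N-SC) with sample (n-1) sd.
    """
    if len(qc_samples) < 2:
        raise QcError("need >= 2 QC samples")
    sub = matrix.data[list(qc_samples)].to_numpy(dtype=float)
    mask = (sub > 0).all(axis=1)
    ln = np.log(sub[mask])
    means = ln.mean(axis=1)
    use = means > 0
    if not use.any():
        raise QcError("no protein has nonzero N-SC in all QC runs with positive mean ln N-SC")
    sds = ln[use].std(axis=1, ddof=1)
    return float(np.mean(100.0 * sds / means[use]))


def qc_report(matrix: CountMatrix, qc_samples: Sequence[str]) -> QcReport:
    """Pairwise ln-ln Pearson R over all QC run pairs plus the average RSD%."""
    if len(qc_samples) < 2:
        raise QcError("need >= 2 QC samples")
    pairs = []
    for a, b in itertools.combinations(qc_samples, 2):
        pairs.append((a, b, ln_ln_pearson(matrix, a, b)))
    sub = matrix.data[list(qc_samples)].to_numpy(dtype=float)
    n_used = int(((sub > 0).all(axis=1)).sum())
    return QcReport(
        pairwise_R=tuple(pairs),
        mean_R=float(np.mean([r for _, _, r in pairs])),
        average_ln_rsd_percent=average_ln_rsd(matrix, qc_samples),
        n_proteins_used=n_used,
    )


def calibrate_fc_cutoff(
    matrix: CountMatrix,
    calibration_samples: Sequence[str],
    coverage: float = 0.99,
    iqr_restrict: bool = True,
) -> FcCalibration:
    """Calibrate the fold-change cutoff from replicate control runs.

    Eligible proteins have nonzero N-SC in every calibration run and (with
    ``iqr_restrict``) a mean ln N-SC inside the interquartile range of the
    per-protein mean ln N-SC distribution. Points are d = |ln ratio| over all
    unordered run pairs; the cutoff is exp of the inclusive empirical
    quantile (smallest d with >= coverage of points <= d), so the achieved
    coverage is never below the request.
    """
    if len(calibration_samples) < 2:
        raise QcError("need >= 2 calibration samples")
    if not 0.5 < coverage < 1.0:
        raise QcError("coverage must lie in (0.5, 1)")
    sub = matrix.data[list(calibration_samples)].to_numpy(dtype=float)
    nonzero_all = (sub > 0).all(axis=1)
    ln = np.log(sub[nonzero_all])
    if ln.shape[0] == 0:
        raise QcError("insufficient calibration data: no protein nonzero in all runs")
    means = ln.mean(axis=1)
    if iqr_restrict:
        q1, q3 = np.percentile(means, [25, 75])
        eligible = (means >= q1) & (means <= q3)
    else:
        eligible = np.ones_like(means, dtype=bool)
    ln_e = ln[eligible]

    n_runs = ln_e.shape[1]
    ds = []
    for i, j in itertools.combinations(range(n_runs), 2):
        ds.append(np.abs(ln_e[:, i] - ln_e[:, j]))
    d = np.concatenate(ds) if ds else np.array([])
    if d.size < 20:
        raise QcError(f"insufficient calibration data: {d.size} points (need >= 20)")

    d_sorted = np.sort(d)
    k = max(0, math.ceil(coverage * d.size) - 1)
    ln_cut = float(d_sorted[k])
    cutoff = float(np.exp(ln_cut))
    coverage_at_cutoff = float(np.mean(d <= ln_cut))
    coverage_at_1p5 = float(np.mean(d <= math.log(1.5)))

    # mean pairwise ln-ln Pearson R over the eligible proteins
    rs = []
    for i, j in itertools.combinations(range(n_runs), 2):
        x, y = ln_e[:, i], ln_e[:, j]
        if x.std() == 0 or y.std() == 0:
            rs.append(1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0)
        else:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    return FcCalibration(
        cutoff=cutoff,
        coverage_at_cutoff=coverage_at_cutoff,
        coverage_at_1p5=coverage_at_1p5,
        pearson_R=float(np.mean(rs)),
        n_points=int(d.size),
    )
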