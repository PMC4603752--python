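"""Peptide filtering, target-decoy FDR estimation, and protein-group inference.

The identification stage mirrors the usual spectral-counting workflow:

1. PSMs are kept only with charge state >= 2 and peptide length >= 6.
2. A score threshold is chosen by the concatenated target-decoy estimate
   FDR(s) = #decoys(score >= s) / #targets(score >= s); q-values are the
   monotonized running minimum of that raw FDR, and the threshold is the
   lowest score whose q-value is strictly below the configured cutoff
   (default < 1%).
3. Accepted peptides are grouped into protein groups: proteins sharing an
   identical distinct-peptide set are merged; each shared peptide is counted
   toward exactly one group (the razor rule: the group with more distinct
   peptides, ties to the lexicographically smaller group id); the group
   probability is the noisy-OR of its peptides' best PSM probabilities; and
   groups must reach >= 2 peptides and probability >= 0.7 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PipelineConfig, PsmRecord, ValidationError

__all__ = [
    "QvalueTable",
    "ProteinGroup",
    "IdentificationError",
    "filter_psms",
    "compute_qvalues",
    "accepted_target_psms",
    "group_proteins",
]


class IdentificationError(ValueError):
    pass


@dataclass(frozen=True)
class QvalueTable:
    """Per-PSM q-values plus the accepted score threshold.

    ``qvalues`` is aligned with the PSM list passed to :func:`compute_qvalues`.
    ``score_threshold`` is the lowest accepted score (``inf`` if nothing
    passes); ties at the threshold are accepted together.
    """

    qvalues: np.ndarray
    score_threshold: float
    n_targets_accepted: int
    n_decoys_accepted: int


def filter_psms(psms: Sequence[PsmRecord], config: PipelineConfig) -> list[PsmRecord]:
    """Keep PSMs with charge >= min_charge and peptide length >= min length."""
    return [
        p
        for p in psms
        if p.charge >= config.min_charge and len(p.peptide) >= config.min_peptide_length
    ]


def compute_qvalues(psms: Sequence[PsmRecord], config: PipelineConfig) -> QvalueTable:
    """Estimate target-decoy q-values and the accepted score threshold.

    Raw FDR at score s is #decoys(>= s) / max(1, #targets(>= s)); q-values
    are its running minimum taken from the bottom of the score ranking
    upward, so they never increase with score.
    """
    scores = np.array([p.score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    if scores.size == 0 or not (~decoy).any():
        raise IdentificationError("no target identifications")

    # distinct scores descending; cumulative counts at "score >= s"
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoy[order]
    cum_decoys = np.cumsum(d_sorted)
    cum_targets = np.cumsum(~d_sorted)
    # index of the last PSM at each distinct score block
    is_block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    block_idx = np.flatnonzero(is_block_end)
    block_scores = s_sorted[block_idx]
    block_d = cum_decoys[block_idx]
    block_t = cum_targets[block_idx]
    raw_fdr = block_d / np.maximum(1, block_t)
    # monotonize from the lowest score upward
    q_blocks = np.minimum.accumulate(raw_fdr[::-1])[::-1]

    passing = q_blocks < config.fdr_cutoff
    if passing.any():
        k = int(np.max(np.flatnonzero(passing)))
        score_threshold = float(block_scores[k])
        n_targets_accepted = int(block_t[k])
        n_decoys_accepted = int(block_d[k])
    else:
        score_threshold = float("inf")
        n_targets_accepted = 0
        n_decoys_accepted = 0

    # map each PSM's score to its block q-value (blocks sorted descending)
    idx = np.searchsorted(-block_scores, -scores, side="left")
    qvalues = q_blocks[idx]
    return QvalueTable(
        qvalues=qvalues,
        score_threshold=score_threshold,
        n_targets_accepted=n_targets_accepted,
        n_decoys_accepted=n_decoys_accepted,
    )


def accepted_target_psms(psms: Sequence[PsmRecord], qtable: QvalueTable) -> list[PsmRecord]:
    """Target PSMs at or above the accepted score threshold."""
    return [p for p in psms if not p.is_decoy and p.score >= qtable.score_threshold]


@dataclass(frozen=True)
class ProteinGroup:
    """An inferred protein group.

    ``peptides`` is the full distinct-peptide set supporting the group;
    ``razor_peptides`` the subset counted toward this group under the razor
    partition (every accepted peptide belongs to exactly one group's razor
    set). ``probability`` is the noisy-OR of the peptides' best PSM
    probabilities: 1 - prod(1 - p_i).
    """

    group_id: str
    accessions: tuple[str, ...]
    peptides: frozenset[str]
    razor_peptides: frozenset[str]
    probability: float


def group_proteins(
    psms: Sequence[PsmRecord],
    config: PipelineConfig,
    apply_filters: bool = True,
) -> list[ProteinGroup]:
    """Group accepted target PSMs into protein groups.

    With ``apply_filters`` (the default), groups failing the minimum-peptide
    or minimum-probability rule are dropped; the razor partition is computed
    over all groups beforehand, so a peptide stays with its razor group even
    if that group is later filtered out.
    """
    peptide_best_prob: dict[str, float] = {}
    accession_peptides: dict[str, set[str]] = {}
    for p in psms:
        if not p.accessions:
            raise ValidationError(f"PSM {p.spectrum_id!r} has no accessions")
        prev = peptide_best_prob.get(p.peptide, 0.0)
        if p.probability > prev:
            peptide_best_prob[p.peptide] = p.probability
        for acc in p.accessions:
            accession_peptides.setdefault(acc, set()).add(p.peptide)

    # merge accessions with identical distinct-peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in accession_peptides.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)

    prelim: list[tuple[str, tuple[str, ...], frozenset[str]]] = []
    for pepset, accs in by_pepset.items():
        accs_sorted = tuple(sorted(accs))
        group_id = ";".join(accs_sorted)
        prelim.append((group_id, accs_sorted, pepset))
    prelim.sort(key=lambda t: t[0])

    # razor partition: each peptide to the group with the larger peptide set,
    # ties to the lexicographically smallest group_id
    razor_of: dict[str, str] = {}
    for peptide in peptide_best_prob:
        best: tuple[int, str] | None = None
        for group_id, _accs, pepset in prelim:
            if peptide in pepset:
                key = (-len(pepset), group_id)
                if best is None or key < best:
                    best = key
        assert best is not None
        razor_of[peptide] = best[1]

    groups: list[ProteinGroup] = []
    for group_id, accs, pepset in prelim:
        probs = np.array([peptide_best_prob[pep] for pep in pepset])
        probability = float(1.0 - np.prod(1.0 - probs))
        razor = frozenset(pep for pep in pepset if razor_of[pep] == group_id)
        g = ProteinGroup(
            group_id=group_id,
            accessions=accs,
            peptides=pepset,
            razor_peptides=razor,
            probability=probability,
        )
        if apply_filters:
            if len(g.peptides) < config.min_peptides_per_protein:
                continue
            if g.probability < config.min_protein_probability:
                continue
        groups.append(g)
    return groups
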