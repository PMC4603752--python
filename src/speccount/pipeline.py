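"""End-to-end orchestration: filter -> FDR -> group -> count -> normalize ->
QC/calibrate -> differential per depot -> depot overlap.

Identification and quantification run independently per depot (each depot's
PSMs are searched and thresholded on their own), mirroring a per-tissue
analysis. The fold-change calibration runs on the configured control depot:
QC injections there when present (replicate injections of one specimen),
otherwise the control group's biological samples. The calibrated cutoff is
reported and only replaces the operational 1.5-fold cutoff when
``use_calibrated_fc`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .differential import DepotOverlap, call_differential, depot_overlap
from .identification import (
    accepted_target_psms,
    compute_qvalues,
    filter_psms,
    group_proteins,
)
from .io import (
    PipelineConfig,
    SampleInfo,
    ValidationError,
    read_psm_table,
    read_sample_table,
    write_results_table,
)
from .qc import QcError, calibrate_fc_cutoff, qc_report
from .quantification import count_spectra, normalize_counts, write_count_matrix

logger = logging.getLogger("speccount")

__all__ = ["RunManifest", "run_pipeline", "PipelineResult"]


@dataclass
class RunManifest:
    """Bookkeeping of one pipeline run: config, input digests, stage counts."""

    config: dict
    input_digests: dict[str, str]
    version: str
    rng_seed: int
    n_psms_in: int = 0
    n_psms_filtered: int = 0
    n_psms_accepted: dict[str, int] = field(default_factory=dict)
    n_proteins_identified: dict[str, int] = field(default_factory=dict)
    n_differential: dict[str, int] = field(default_factory=dict)
    n_identified_both: int = 0
    n_differential_both: int = 0
    n_concordant: int = 0
    fc_cutoff_used: float = 1.5
    calibration: dict | None = None
    qc: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    calls: dict[str, list]
    overlap: DepotOverlap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _calibration_samples(samples: Sequence[SampleInfo], config: PipelineConfig) -> list[str]:
    qc = [s.sample_id for s in samples if s.is_qc and s.depot == config.calibration_depot]
    if len(qc) >= 2:
        return qc
    return [
        s.sample_id
        for s in samples
        if s.depot == config.calibration_depot and s.group == config.calibration_group
        and not s.is_qc
    ]


def run_pipeline(
    psms_path: str | Path,
    samples_path: str | Path,
    config_path: str | Path | None,
    out_dir: str | Path,
) -> RunManifest:
    """Run the whole cascade and write all result tables under ``out_dir``."""
    psms_path, samples_path = Path(psms_path), Path(samples_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()

    psms = read_psm_table(psms_path, decoy_prefix=config.decoy_prefix)
    samples = read_sample_table(samples_path)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_digests={psms_path.name: _sha256(psms_path), samples_path.name: _sha256(samples_path)},
        version=__version__,
        rng_seed=config.rng_seed,
        n_psms_in=len(psms),
    )

    filtered = filter_psms(psms, config)
    manifest.n_psms_filtered = len(filtered)
    logger.info("filter: %d -> %d PSMs", len(psms), len(filtered))

    depots_present = sorted({s.depot for s in samples})
    sample_by_id = {s.sample_id: s for s in samples}
    matrices_raw: dict[str, object] = {}
    matrices_nsc: dict[str, object] = {}
    identified: dict[str, set[str]] = {}
    pepcounts: dict[str, dict[str, int]] = {}

    for depot in depots_present:
        depot_samples = [s for s in samples if s.depot == depot]
        ids = {s.sample_id for s in depot_samples}
        depot_psms = [p for p in filtered if p.sample_id in ids]
        unknown = {p.sample_id for p in psms if p.sample_id not in sample_by_id}
        if unknown:
            raise ValidationError(f"PSM sample(s) missing from metadata: {sorted(unknown)}")
        qtable = compute_qvalues(depot_psms, config)
        accepted = accepted_target_psms(depot_psms, qtable)
        manifest.n_psms_accepted[depot] = len(accepted)
        groups = group_proteins(accepted, config)
        manifest.n_proteins_identified[depot] = len(groups)
        logger.info(
            "%s: accepted %d PSMs at score >= %.3g; %d protein groups",
            depot, len(accepted), qtable.score_threshold, len(groups),
        )
        raw = count_spectra(accepted, groups, depot_samples)
        nsc = normalize_counts(raw)
        matrices_raw[depot] = raw
        matrices_nsc[depot] = nsc
        identified[depot] = set(raw.proteins)
        pepcounts[depot] = {g.group_id: len(g.peptides) for g in groups}
        write_count_matrix(raw, out / f"counts_{depot}_raw.tsv")
        write_count_matrix(nsc, out / f"counts_{depot}_nsc.tsv")

    # QC reproducibility on the depot carrying QC injections
    qc_samples = [s for s in samples if s.is_qc]
    if len(qc_samples) >= 2:
        depot = qc_samples[0].depot
        try:
            report = qc_report(matrices_nsc[depot], [s.sample_id for s in qc_samples])
            manifest.qc = {
                "depot": depot,
                "mean_R": report.mean_R,
                "min_R": min(r for _, _, r in report.pairwise_R),
                "max_R": max(r for _, _, r in report.pairwise_R),
                "average_ln_rsd_percent": report.average_ln_rsd_percent,
                "n_proteins_used": report.n_proteins_used,
            }
            pd.DataFrame(
                [{"sample_a": a, "sample_b": b, "pearson_R": r} for a, b, r in report.pairwise_R]
            ).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        except QcError as exc:
            logger.warning("QC report skipped: %s", exc)

    # fold-change calibration on the control depot
    fc_cutoff = config.fc_cutoff
    cal_ids = _calibration_samples(samples, config)
    if len(cal_ids) >= 2 and config.calibration_depot in matrices_nsc:
        try:
            cal = calibrate_fc_cutoff(
                matrices_nsc[config.calibration_depot], cal_ids, config.calibration_coverage
            )
            manifest.calibration = dataclasses.asdict(cal)
            pd.DataFrame([dataclasses.asdict(cal)]).to_csv(
                out / "calibration.tsv", sep="\t", index=False
            )
            if config.use_calibrated_fc:
                fc_cutoff = max(1.0, cal.cutoff)
        except QcError as exc:
            logger.warning("calibration skipped: %s", exc)
    manifest.fc_cutoff_used = fc_cutoff
    diff_config = dataclasses.replace(config, fc_cutoff=fc_cutoff)

    calls = {}
    for depot in depots_present:
        depot_calls = call_differential(
            matrices_nsc[depot], matrices_raw[depot], samples, depot, diff_config,
            peptide_counts=pepcounts[depot],
        )
        calls[depot] = depot_calls
        manifest.n_differential[depot] = sum(c.significant for c in depot_calls)
        write_results_table(
            [c for c in depot_calls if c.significant], out / f"differential_{depot}.tsv"
        )
        write_results_table(depot_calls, out / f"differential_{depot}_all.tsv")
        logger.info("%s: %d differential proteins", depot, manifest.n_differential[depot])

    overlap = None
    if "subcutaneous" in calls and "omentum" in calls:
        overlap = depot_overlap(
            calls["subcutaneous"], calls["omentum"],
            identified["subcutaneous"], identified["omentum"],
        )
        manifest.n_identified_both = len(overlap.identified_both)
        manifest.n_differential_both = len(overlap.differential_both)
        manifest.n_concordant = len(overlap.concordant)
        rows = [
            {
                "group_id": g,
                "differential_sc": g in overlap.differential_sc,
                "differential_om": g in overlap.differential_om,
                "concordant": g in overlap.concordant,
            }
            for g in sorted(overlap.differential_sc | overlap.differential_om)
        ]
        pd.DataFrame(
            rows, columns=["group_id", "differential_sc", "differential_om", "concordant"]
        ).to_csv(out / "overlap.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
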