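"""Reading and writing of PSM tables, sample metadata, count matrices and result tables.

All on-disk formats are tab-separated UTF-8 text with a header row. The PSM
table carries one row per peptide-spectrum match; the sample table one row per
LC-MS injection. Decoy status may be given as an explicit boolean column or
inferred from an accession prefix (``DECOY_`` by default), the usual
target-decoy file convention.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "PsmRecord",
    "SampleInfo",
    "PipelineConfig",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "read_psm_table",
    "write_psm_table",
    "read_sample_table",
    "write_sample_table",
    "write_results_table",
    "read_results_table",
    "DEPOTS",
    "GROUPS",
]

DEPOTS = ("subcutaneous", "omentum")
GROUPS = ("diabetic", "nondiabetic")

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

_TRUE_STRINGS = {"true", "1", "t", "yes", "y"}
_FALSE_STRINGS = {"false", "0", "f", "no", "n", ""}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A field value violates its declared invariant."""


class ParseError(ValueError):
    """A cell could not be converted to its declared type."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``score`` is the search-engine score (higher = better); ``probability`` is
    the peptide-level confidence in [0, 1] assigned upstream. ``accessions``
    lists every protein the peptide maps to.
    """

    spectrum_id: str
    sample_id: str
    peptide: str
    charge: int
    score: float
    is_decoy: bool
    probability: float
    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValidationError(f"invalid peptide sequence {self.peptide!r}")
        if not self.accessions:
            raise ValidationError(f"PSM {self.spectrum_id!r} has no accessions")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"PSM {self.spectrum_id!r} probability {self.probability} outside [0, 1]"
            )
        if self.charge < 1:
            raise ValidationError(f"PSM {self.spectrum_id!r} charge {self.charge} < 1")


@dataclass(frozen=True)
class SampleInfo:
    """One LC-MS injection of one tissue specimen.

    QC injections repeat the same ``subject_id`` with increasing
    ``injection_index``; biological samples are single injections.
    """

    sample_id: str
    subject_id: str
    depot: str
    group: str
    is_qc: bool = False
    injection_index: int = 1

    def __post_init__(self) -> None:
        if self.depot not in DEPOTS:
            raise ValidationError(f"unknown depot {self.depot!r}; expected one of {DEPOTS}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.injection_index < 1:
            raise ValidationError(f"injection_index must be >= 1, got {self.injection_index}")


@dataclass
class PipelineConfig:
    """Thresholds and options for the full filter cascade.

    Defaults are the operational values of the study design this pipeline
    implements: peptides with charge >= 2 and length >= 6, target-decoy FDR
    < 1%, protein group probability >= 0.7 with >= 2 peptides, commonality
    strictly greater than 50% of either group, Wilcoxon alpha 0.05 and a
    1.5-fold-change cutoff (optionally replaced by the empirically calibrated
    one).
    """

    min_charge: int = 2
    min_peptide_length: int = 6
    fdr_cutoff: float = 0.01
    min_protein_probability: float = 0.7
    min_peptides_per_protein: int = 2
    commonality_fraction: float = 0.5
    alpha: float = 0.05
    fc_cutoff: float = 1.5
    pseudocount: float = 0.5
    calibration_coverage: float = 0.99
    calibration_depot: str = "omentum"
    calibration_group: str = "nondiabetic"
    use_calibrated_fc: bool = False
    decoy_prefix: str = "DECOY_"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_charge < 1:
            raise ValidationError("min_charge must be >= 1")
        if self.min_peptide_length < 1:
            raise ValidationError("min_peptide_length must be >= 1")
        if not 0.0 < self.fdr_cutoff <= 1.0:
            raise ValidationError("fdr_cutoff must lie in (0, 1]")
        if not 0.0 <= self.min_protein_probability <= 1.0:
            raise ValidationError("min_protein_probability must lie in [0, 1]")
        if self.min_peptides_per_protein < 1:
            raise ValidationError("min_peptides_per_protein must be >= 1")
        if not 0.0 <= self.commonality_fraction < 1.0:
            raise ValidationError("commonality_fraction must lie in [0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must lie in (0, 1]")
        if self.fc_cutoff < 1.0:
            raise ValidationError("fc_cutoff must be >= 1")
        if self.pseudocount < 0.0:
            raise ValidationError("pseudocount must be >= 0")
        if not 0.5 < self.calibration_coverage < 1.0:
            raise ValidationError("calibration_coverage must lie in (0.5, 1)")
        if self.calibration_depot not in DEPOTS:
            raise ValidationError(f"calibration_depot must be one of {DEPOTS}")
        if self.calibration_group not in GROUPS:
            raise ValidationError(f"calibration_group must be one of {GROUPS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config; keys are the field names."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _parse_bool(value: str, *, row: int, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ParseError(f"row {row}: cannot parse {column}={value!r} as a boolean")


_PSM_REQUIRED = ("spectrum_id", "sample_id", "peptide", "charge", "score", "probability", "accessions")


def read_psm_table(path: str | Path, decoy_prefix: str = "DECOY_") -> list[PsmRecord]:
    """Read a tab-separated PSM table into records, preserving row order.

    The ``is_decoy`` column is optional: when absent, a PSM is a decoy iff
    every accession starts with ``decoy_prefix``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSM table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"PSM table {path} missing required column(s): {', '.join(missing)}")
    has_decoy_col = "is_decoy" in df.columns

    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            charge = int(d["charge"])
            score = float(d["score"])
            probability = float(d["probability"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: non-numeric charge/score/probability ({exc})") from exc
        acc_cell = d["accessions"].strip()
        if not acc_cell:
            raise ValidationError(f"row {i}: empty accessions cell")
        accessions = tuple(a.strip() for a in acc_cell.split(";") if a.strip())
        if not accessions:
            raise ValidationError(f"row {i}: empty accessions cell")
        if has_decoy_col:
            is_decoy = _parse_bool(d["is_decoy"], row=i, column="is_decoy")
        else:
            is_decoy = all(a.startswith(decoy_prefix) for a in accessions)
        records.append(
            PsmRecord(
                spectrum_id=d["spectrum_id"],
                sample_id=d["sample_id"],
                peptide=d["peptide"],
                charge=charge,
                score=score,
                is_decoy=is_decoy,
                probability=probability,
                accessions=accessions,
            )
        )
    return records


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "sample_id": p.sample_id,
            "peptide": p.peptide,
            "charge": p.charge,
            "score": repr(p.score),
            "is_decoy": str(p.is_decoy).lower(),
            "probability": repr(p.probability),
            "accessions": ";".join(p.accessions),
        }
        for p in psms
    ]
    df = pd.DataFrame(rows, columns=["spectrum_id", "sample_id", "peptide", "charge",
                                     "score", "is_decoy", "probability", "accessions"])
    df.to_csv(path, sep="\t", index=False)


_SAMPLE_REQUIRED = ("sample_id", "subject_id", "depot", "group")


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read the sample metadata table; depot/group are case-normalized."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SAMPLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table {path} missing required column(s): {', '.join(missing)}")

    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id(s): {sorted(set(dup))}")

    bad_depot = sorted({d for d in df["depot"] if d.strip().lower() not in DEPOTS})
    bad_group = sorted({g for g in df["group"] if g.strip().lower() not in GROUPS})
    if bad_depot or bad_group:
        parts = []
        if bad_depot:
            parts.append(f"unknown depot value(s): {bad_depot}")
        if bad_group:
            parts.append(f"unknown group value(s): {bad_group}")
        raise ValidationError("; ".join(parts))

    records: list[SampleInfo] = []
    seen_key: set[tuple[str, str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        is_qc = _parse_bool(d.get("is_qc", "false"), row=i, column="is_qc")
        try:
            injection_index = int(d.get("injection_index") or 1)
        except ValueError as exc:
            raise ParseError(f"row {i}: non-integer injection_index") from exc
        rec = SampleInfo(
            sample_id=d["sample_id"].strip(),
            subject_id=d["subject_id"].strip(),
            depot=d["depot"].strip().lower(),
            group=d["group"].strip().lower(),
            is_qc=is_qc,
            injection_index=injection_index,
        )
        key = (rec.subject_id, rec.depot, rec.injection_index)
        if key in seen_key:
            raise ValidationError(f"row {i}: duplicate (subject_id, depot, injection_index) {key}")
        seen_key.add(key)
        records.append(rec)
    return records


def write_sample_table(samples: Iterable[SampleInfo], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "depot": s.depot,
            "group": s.group,
            "is_qc": str(s.is_qc).lower(),
            "injection_index": s.injection_index,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "depot", "group",
                                     "is_qc", "injection_index"])
    df.to_csv(path, sep="\t", index=False)


_RESULT_COLUMNS = [
    "accession",
    "name",
    "total_peptides",
    "fold_change",
    "p_value",
    "passes_commonality",
    "passes_wilcoxon",
    "passes_fc",
    "significant",
]


def write_results_table(calls: Sequence, path: str | Path) -> None:
    """Write differential calls as a tab-separated table.

    Fold changes are rendered to 2 decimals with a leading ``-`` for
    decreases, p-values to 3 decimals; rows appear in the given order
    (callers sort by fold change descending).
    """
    rows = [
        {
            "accession": c.group_id,
            "name": c.name,
            "total_peptides": c.total_peptides,
            "fold_change": f"{c.fold_change:.2f}",
            "p_value": f"{c.p_value:.3f}",
            "passes_commonality": str(c.passes_commonality).lower(),
            "passes_wilcoxon": str(c.passes_wilcoxon).lower(),
            "passes_fc": str(c.passes_fc).lower(),
            "significant": str(c.significant).lower(),
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results table back as a DataFrame (numbers to printed precision)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "name": str})
    for col in ("passes_commonality", "passes_wilcoxon", "passes_fc", "significant"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.lower().isin(_TRUE_STRINGS)
    return df
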