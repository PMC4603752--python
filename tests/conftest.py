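import pytest

from speccount.io import PipelineConfig, PsmRecord, SampleInfo


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def permissive_config():
    """Identification config with non-binding protein-level filters."""
    return PipelineConfig(min_peptides_per_protein=1, min_protein_probability=0.0)


def make_psm(
    spectrum_id="s1",
    sample_id="A",
    peptide="PEPTIDEK",
    charge=2,
    score=5.0,
    is_decoy=False,
    probability=0.95,
    accessions=("P1",),
):
    return PsmRecord(
        spectrum_id=spectrum_id,
        sample_id=sample_id,
        peptide=peptide,
        charge=charge,
        score=score,
        is_decoy=is_decoy,
        probability=probability,
        accessions=tuple(accessions),
    )


@pytest.fixture
def psm_factory():
    return make_psm


@pytest.fixture
def two_group_samples():
    """4 diabetic + 4 nondiabetic subcutaneous samples."""
    out = []
    for i in range(1, 5):
        out.append(SampleInfo(f"D{i}_sc", f"D{i}", "subcutaneous", "diabetic"))
    for i in range(1, 5):
        out.append(SampleInfo(f"N{i}_sc", f"N{i}", "subcutaneous", "nondiabetic"))
    return out
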