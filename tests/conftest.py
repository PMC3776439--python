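import pytest

from feedprot import (
    InferenceConfig,
    PSMRecord,
    ProteinEntry,
    SyntheticConfig,
    generate_proteome,
    simulate_report,
)


def make_psm(
    peptide,
    proteins,
    prob=0.99,
    sp=100.0,
    spectrum="s.1.1.2",
    mass=1000.0,
):
    return PSMRecord(
        spectrum_id=spectrum,
        peptide_sequence=peptide,
        sp_score=sp,
        initial_probability=prob,
        assigned_proteins=tuple(proteins),
        peptide_mass=mass,
    )


@pytest.fixture
def elimination_instance():
    """Present protein A (3 unique peptides + 1 shared) vs absent protein B.

    B's only high-probability evidence is the peptide shared with A, so it can
    enter the putative list only through A — the oscillation the elimination
    rule is designed to stop.
    """
    # SSSSK's intensity (70) is far from A's sibling mean (100), so once B's
    # probability collapses the shared peptide's recomputed x falls below the
    # selection threshold and B drops off the putative list
    psms = [
        make_psm("AAAAK", ["A"], prob=0.99, sp=100.0, spectrum="s.1"),
        make_psm("CCCCK", ["A"], prob=0.98, sp=80.0, spectrum="s.2"),
        make_psm("DDDDK", ["A"], prob=0.97, sp=120.0, spectrum="s.3"),
        make_psm("SSSSK", ["A", "B"], prob=0.96, sp=70.0, spectrum="s.4"),
        make_psm("EEEEK", ["B"], prob=0.30, sp=20.0, spectrum="s.5"),
        make_psm("FFFFK", ["B"], prob=0.20, sp=15.0, spectrum="s.6"),
    ]
    proteins = [ProteinEntry("A", "M" * 30), ProteinEntry("B", "M" * 30)]
    counts = {"A": 10, "B": 10}
    return psms, proteins, counts


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-condition synthetic dataset shared across tests."""
    config = SyntheticConfig(seed=7)
    proteins, truth = generate_proteome(config)
    psms, truth = simulate_report(proteins, truth, config)
    return config, proteins, psms, truth
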