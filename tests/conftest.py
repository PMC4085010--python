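import pytest

from radox import peptides, synth


@pytest.fixture(scope="session")
def lysozyme():
    """(ProteinRecord, [FragmentSpec]) for the 129-residue mature chain."""
    return synth.lysozyme_fixture()


@pytest.fixture(scope="session")
def detected(lysozyme):
    """The ten detected tryptic peptides (8 carbamidomethylated + 2 oxidized)."""
    protein, _ = lysozyme
    return synth.detected_peptides(protein)


@pytest.fixture(scope="session")
def srm_rules():
    """Transition rules with the validated ion panel."""
    return peptides.TransitionRules(ion_selection=synth.SRM_ION_PANEL)
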