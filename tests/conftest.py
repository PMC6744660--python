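import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from musavar import CULTIVAR_PANEL

    return list(CULTIVAR_PANEL.values())


@pytest.fixture(scope="session")
def reference():
    from musavar import generate_reference_cds

    return generate_reference_cds(600, seed=7)


@pytest.fixture(scope="session")
def implanted(reference):
    """Per-cultivar (alignment, truth) pairs against a shared reference."""
    from musavar import AlignmentSet, SUBSTITUTION_PROFILES, implant_variants

    out = {}
    for name, prof in SUBSTITUTION_PROFILES.items():
        mutant, truth = implant_variants(reference, prof, seed=11)
        aln = AlignmentSet(
            sequences={"Ancestral": reference, name: mutant},
            reference_label="Ancestral",
        )
        out[name] = (aln, truth)
    return out
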