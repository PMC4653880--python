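import pytest

from pamscan import ReadEmissionProfile, t1_scheme
from pamscan.assay_sim import example_amplicon, example_indel_spectrum
from pamscan.indel_caller import AmpliconTarget
from pamscan.library_design import T1_SPACER
from pamscan.variants import Edit


@pytest.fixture(scope="session")
def scheme5():
    return t1_scheme(pam_len=5)


@pytest.fixture(scope="session")
def scheme7():
    return t1_scheme(pam_len=7)


@pytest.fixture(scope="session")
def clean_profile():
    """Error-free sequencing: exact truth recovery expected."""
    return ReadEmissionProfile(substitution_error_rate=0.0,
                               mean_quality=40.0, quality_sd=0.0)


@pytest.fixture(scope="session")
def noisy_profile():
    """Realistic sequencing noise (Q33 +/- 3, 0.2 % substitutions)."""
    return ReadEmissionProfile()


@pytest.fixture(scope="session")
def amplicon():
    """(reference, cut_site, prefix, target, spectrum, artifact_edit).

    The artifact edit is planted in both treatment and control runs and
    must be subtracted by the caller.
    """
    reference, cut, prefix = example_amplicon()
    p_start = reference.index(T1_SPACER)
    target = AmpliconTarget(
        reference=reference,
        protospacer=(p_start, p_start + 20),
        pam=(p_start + 20, p_start + 28),
        prefix=prefix,
        min_len=len(reference) - 6,
        max_len=len(reference) + 6,
        name="example",
    )
    assert target.expected_cut == cut
    spectrum = example_indel_spectrum(cut, reference)
    artifact = Edit("ins", cut + 4, 1, "A").left_aligned(reference)
    return reference, cut, prefix, target, spectrum, artifact
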