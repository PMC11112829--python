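import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    from cdh_prospector.curation import default_reference
    return default_reference()


@pytest.fixture(scope="session")
def small_family():
    """Two classes, three members each, rooted in the reference."""
    from cdh_prospector.synthetic_data import FamilySpec, generate_family
    spec = FamilySpec(n_classes=2, members_per_class=3,
                      within_identity=0.92, between_identity=0.80, seed=101)
    return generate_family(spec)
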