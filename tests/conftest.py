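import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stilsagree import (  # noqa: E402
    AnnotationRecord,
    SyntheticConfig,
    simulate_study,
)


def make_record(
    reader_id="R1",
    roi_id="C01-ROI01",
    roi_label="intratumoral stroma",
    density=10.0,
    **kwargs,
):
    """A well-formed record with overridable fields for compact test setup."""
    defaults = dict(
        platform="PathPresenter",
        case_id=roi_id.split("-")[0],
        batch_id="B1",
        duration_s=30.0,
        timestamp=None,
    )
    defaults.update(kwargs)
    return AnnotationRecord(
        reader_id=reader_id, roi_id=roi_id, roi_label=roi_label,
        density=density, **defaults,
    )


def two_reader_records(values_a, values_b, labels_a=None, labels_b=None):
    """Two readers' records over a shared ROI list from density lists.

    A None density means the reader labeled the ROI non-evaluable (unless an
    explicit label is given).
    """
    def build(reader, values, labels):
        recs = []
        for i, v in enumerate(values):
            label = labels[i] if labels else (
                "intratumoral stroma" if v is not None else "other region"
            )
            recs.append(
                make_record(reader, roi_id=f"C01-ROI{i + 1:02d}",
                            roi_label=label, density=v)
            )
        return recs

    return build("RA", values_a, labels_a), build("RB", values_b, labels_b)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (10 readers, 640 ROIs)."""
    return simulate_study(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def two_reader_study():
    """A two-reader synthetic study for pairwise agreement tests."""
    return simulate_study(SyntheticConfig(n_readers=2, seed=7))
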