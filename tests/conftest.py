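import pandas as pd
import pytest

from dxtrust import (
    CaseRecord,
    TransparencyLevel,
    batch_decide,
    default_config,
    default_profiles,
    generate_cohort,
)
from dxtrust.stats import confidence_range


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture
def case_factory():
    """Build a valid case with sensible defaults, overridable per test."""

    def make(
        case_id="C1",
        ai_dx="acute exacerbation of chronic systolic heart failure",
        human_dx="chronic systolic heart failure",
        confidence_pct=85.0,
        transparency=TransparencyLevel.MODERATE,
        similarity_override=None,
    ):
        return CaseRecord(
            case_id=case_id,
            ai_dx=ai_dx,
            human_dx=human_dx,
            confidence_pct=confidence_pct,
            transparency=transparency,
            similarity_override=similarity_override,
        )

    return make


@pytest.fixture(scope="session")
def study_cohort():
    """One seeded cohort with the study's stratified structure."""
    return generate_cohort(default_config(seed=20240901))


@pytest.fixture(scope="session")
def study_decisions(study_cohort):
    return batch_decide([lc.case for lc in study_cohort])


@pytest.fixture(scope="session")
def study_decision_frame(study_decisions):
    return pd.DataFrame(
        {
            "override": [d.override for d in study_decisions],
            "transparency": [
                d.case.transparency.name for d in study_decisions
            ],
            "confidence_range": [
                confidence_range(d.case.confidence_pct) or ""
                for d in study_decisions
            ],
        }
    )
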