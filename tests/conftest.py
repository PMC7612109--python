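import numpy as np
import pandas as pd
import pytest

from narfcs_sa import (
    BivariatePrior,
    ExpertResponse,
    MarginalPrior,
    TrialDataset,
    generate_trial,
    iqip_like_config,
    mnar_config,
    sample_prior,
)


@pytest.fixture(scope="session")
def mnar_trial():
    """Trial-sized dataset with a known MNAR mechanism plus its truth sidecar."""
    return generate_trial(mnar_config(seed=20))


@pytest.fixture(scope="session")
def mcar_trial():
    """Same structure but outcome-independent missingness."""
    return generate_trial(iqip_like_config(seed=21))


@pytest.fixture()
def tiny_dataset():
    """Hand-built 8-participant dataset with nonmonotone missingness."""
    frame = pd.DataFrame({
        "id": range(8),
        "arm": [0, 0, 0, 0, 1, 1, 1, 1],
        "y1": [1, 0, np.nan, 1, 0, 1, np.nan, 0],
        "y2": [0, np.nan, 1, 1, np.nan, 1, 0, 0],
    })
    return TrialDataset(frame)


@pytest.fixture(scope="session")
def example_prior():
    """Truncated bivariate normal typical of an elicited expert."""
    return BivariatePrior(MarginalPrior(20.0, 10.0), MarginalPrior(25.0, 10.0), 0.7)


@pytest.fixture(scope="session")
def prior_samples(example_prior):
    return sample_prior(example_prior, 100_000, seed=11)


@pytest.fixture()
def five_experts():
    """Five questionnaire responses spanning the observed spread of opinion:
    three near missing=smoking, two near the observed quit rates, one with
    zero correlation and one at the clip."""
    specs = [
        ("black", {"1C": 10, "1E": 12, "2C": 8, "2E": 10}, 80, "upper"),
        ("red", {"1C": 15, "1E": 15, "2C": 10, "2E": 12}, 70, 0.7),
        ("green", {"1C": 18, "1E": 20, "2C": 12, "2E": 14}, 75, 0.74),
        ("blue", {"1C": 45, "1E": 48, "2C": 35, "2E": 38}, 30, 0.0),
        ("purple", {"1C": 40, "1E": 42, "2C": 30, "2E": 32}, 60, 0.6),
    ]
    from narfcs_sa.elicitation import Z_UPPER_QUARTILE, certainty_to_sd

    out = []
    for name, modes, cert, rho in specs:
        sd = certainty_to_sd(cert)
        shift = Z_UPPER_QUARTILE * sd * (1.0 if rho == "upper" else rho)
        out.append(ExpertResponse(
            expert_id=name,
            modes={k: float(v) for k, v in modes.items()},
            certainties={k: float(cert) for k in modes},
            updated_mode_1C=modes["1C"] + shift,
            rationale=f"synthetic response emulating the {name} expert",
        ))
    return out
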