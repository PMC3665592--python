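import numpy as np
import pytest

from sigma54scan import (
    ScanConfig,
    build_pwm,
    consensus_pwm,
    generate_genome,
    survey_spec,
)


@pytest.fixture(scope="session")
def pwm():
    return consensus_pwm()


@pytest.fixture(scope="session")
def soft_pwm():
    """A deliberately noisy matrix: sites sampled around the consensus
    with 25% per-base error, so sampled sites span a wide score range."""
    rng = np.random.default_rng(2024)
    consensus = "TGGCACGAAAATTGCA"
    bases = "ACGT"
    sites = []
    for _ in range(40):
        site = [
            bases[rng.integers(4)] if rng.random() < 0.25 else b for b in consensus
        ]
        sites.append("".join(site))
    return build_pwm(sites)


@pytest.fixture(scope="session")
def config():
    return ScanConfig()


@pytest.fixture(scope="session")
def survey(pwm):
    """Seeded 100-kb benchmark genome: 20 genes, 10 pwm_sample + 5 modal
    implants, 5 far + 5 wrong-strand decoys."""
    spec = survey_spec(seed=11)
    return generate_genome(spec, pwm)
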