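import numpy as np
import pytest

import specunmix as su


@pytest.fixture(scope="session")
def thymidine_pair() -> su.ReferencePair:
    """Thymidine/thymine-like synthetic pair (iso 278 nm, fit 250-320 nm)."""
    return su.generate_reference_pair(su.thymidine_like_scenario())


@pytest.fixture(scope="session")
def uridine_pair() -> su.ReferencePair:
    """Uridine/uracil-like pair (iso 271 nm, extension 310 nm)."""
    return su.generate_reference_pair(su.uridine_like_scenario())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_scenario(rng: np.random.Generator) -> su.SyntheticScenario:
    """A random but physically sane two-band scenario with a crossing.

    The nucleoside band sits shortward of the nucleobase band and the
    isosbestic target is placed between the two maxima, which guarantees
    one crossing after the generator's rescaling.
    """
    c_n = float(rng.uniform(258, 272))
    c_b = float(c_n + rng.uniform(14, 26))
    iso = float(0.5 * (c_n + c_b) + rng.uniform(-2, 2))
    return su.SyntheticScenario(
        nucleoside_bands=(su.GaussianBand(c_n, float(rng.uniform(9, 13)), float(rng.uniform(0.6, 1.1))),),
        nucleobase_bands=(su.GaussianBand(c_b, float(rng.uniform(8, 11)), float(rng.uniform(0.5, 1.0))),),
        target_isosbestic_nm=iso,
        spectral_extension_nm=float(c_b + 35),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
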