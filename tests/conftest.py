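import numpy as np
import pytest

import phicmap as pm
from phicmap.synthetic import simulate_consortium


@pytest.fixture(scope="session")
def consortium():
    """One fully analyzed synthetic consortium shared across tests."""
    bundle = simulate_consortium(seed=1, n_pairs=1_000_000, n_read_pairs=100_000, bin_size=5_000)
    matrix = pm.bin_pairs(bundle["pairs"], bundle["bin_size"])
    balanced = pm.ice_balance(matrix)
    profile = pm.insulation_profile(balanced, window=5)
    borders = pm.detect_borders(profile, min_prominence=0.2)
    coverage = pm.coverage_profile(
        bundle["pairs"].positions.ravel(), bundle["truth"].genome_length, window=10_000
    )
    bundle.update(
        matrix=matrix, balanced=balanced, insulation=profile, borders=borders, coverage=coverage
    )
    return bundle


@pytest.fixture()
def constant_matrix():
    n = 40
    return pm.ContactMatrix("const", 1_000, np.full((n, n), 7.0), float(7 * n * n),
                            replicon_length=n * 1_000)


@pytest.fixture()
def constant_balanced(constant_matrix):
    return pm.ice_balance(constant_matrix)
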