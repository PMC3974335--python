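import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from repsel import FamilySpec, generate_family, identity_matrix, nonredundant_set


@pytest.fixture(scope="session")
def base_family():
    """Moderately diverged 12-member family, no anomalies."""
    fam, labels = generate_family(
        FamilySpec(
            n_members=12,
            ancestor_length=80,
            mutation_rate=0.2,
            indel_rate=0.02,
            rng_seed=42,
            family_id="base",
        )
    )
    return fam, labels


@pytest.fixture(scope="session")
def base_matrix(base_family):
    fam, _ = base_family
    return identity_matrix(fam)


@pytest.fixture(scope="session")
def subgroup_family():
    """Two-subgroup family whose 50% set keeps several real members."""
    fam, labels = generate_family(
        FamilySpec(
            n_members=24,
            ancestor_length=120,
            mutation_rate=0.3,
            indel_rate=0.02,
            n_subgroups=2,
            rng_seed=17,
            family_id="sub",
        )
    )
    return fam, labels


@pytest.fixture(scope="session")
def subgroup_matrix(subgroup_family):
    fam, _ = subgroup_family
    return identity_matrix(fam)


@pytest.fixture(scope="session")
def subgroup_nr50(subgroup_family, subgroup_matrix):
    fam, _ = subgroup_family
    return nonredundant_set(fam, subgroup_matrix)
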