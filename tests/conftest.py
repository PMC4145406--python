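import numpy as np
import pytest

from pedbp import Individual, PedigreeSet, Study, StudyConfig


@pytest.fixture(scope="session")
def study_default():
    """Full-scale default study (20 families, ~849 phenotyped)."""
    return Study(StudyConfig())


@pytest.fixture(scope="session")
def reps50(study_default):
    """Fifty replicates of the default study."""
    return [study_default.run_replicate(r) for r in range(1, 51)]


@pytest.fixture(scope="session")
def reps20(reps50):
    return reps50[:20]


def three_generation_pedigree():
    """Hand-built 11-person pedigree with an MZ twin pair.

    F1: gp1 x gp2 -> (p1, aunt); p1 x sp -> (c1, c2, twins t1/t2)
    F2: unrelated founder pair u1, u2.
    """
    return PedigreeSet(
        [
            Individual("gp1", "F1", sex="male"),
            Individual("gp2", "F1", sex="female"),
            Individual("p1", "F1", "gp1", "gp2", sex="male"),
            Individual("aunt", "F1", "gp1", "gp2", sex="female"),
            Individual("sp", "F1", sex="female"),
            Individual("c1", "F1", "p1", "sp", sex="female"),
            Individual("c2", "F1", "p1", "sp", sex="male"),
            Individual("t1", "F1", "p1", "sp", sex="male", mz_group="MZ1"),
            Individual("t2", "F1", "p1", "sp", sex="male", mz_group="MZ1"),
            Individual("u1", "F2", sex="male"),
            Individual("u2", "F2", sex="female"),
        ]
    )


@pytest.fixture
def ped11():
    return three_generation_pedigree()


@pytest.fixture
def founder_block():
    """10,000 unrelated founders in one nominal family (for law-of-large-
    numbers checks on founder allele frequencies)."""
    inds = [
        Individual(f"f{i}", "F1", sex="male" if i % 2 else "female") for i in range(10_000)
    ]
    return PedigreeSet(inds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
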