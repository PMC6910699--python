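import numpy as np
import pytest

from identikit import coefficient_fixture, fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20191213)


@pytest.fixture(scope="session")
def linear3_c():
    return coefficient_fixture("linear3_c")


@pytest.fixture(scope="session")
def noleak13_c():
    return coefficient_fixture("linear3_noleak13_c")


@pytest.fixture(scope="session")
def fourcomp_c():
    return coefficient_fixture("fourcomp_c")


@pytest.fixture(scope="session")
def linear3_model():
    return fixture("linear3")


@pytest.fixture(scope="session")
def hiv_model():
    return fixture("hiv")


# The worked 12-solution benchmark for the HIV-type model at truncation
# order 7 with output jets (0.5, -0.03, -0.15, -0.2, -0.2, -0.17, -0.16,
# -0.15): parameter vectors and the extending output jet y_8, one row per
# solution, grouped 4-4-4 by y_8.
def _hiv_reference_solutions():
    rows_pm = [
        # (p1, p2, p3, p4, p5, y8); +/- rows expand to two solutions
        (0.1253, -2.4825, 4.4249, -0.9210, -0.2137, 0.1706),
        (0.2602, -2.4825, 4.4249, -0.2137, -0.9210, 0.1706),
    ]
    out = []
    for p1, p2, p3, p4, p5, y8 in rows_pm:
        out.append([p1, p2, p3, p4, p5, y8])
        out.append([-p1, p2, p3, p4, p5, y8])
    conj_rows = [
        (0.3023 + 0.0779j, -3.5234 + 0.5105j, 4.2201 + 1.9168j,
         -1.3367 - 0.0298j, -0.1080 - 0.2292j, 0.1107 - 0.4040j),
        (-0.3023 + 0.0779j, -3.5234 - 0.5105j, 4.2201 - 1.9168j,
         -1.3367 + 0.0298j, -0.1080 + 0.2292j, 0.1107 + 0.4040j),
        (0.6847 + 0.2133j, -3.5234 - 0.5105j, 4.2201 - 1.9168j,
         -0.1080 + 0.2292j, -1.3367 + 0.0298j, 0.1107 + 0.4040j),
        (-0.6847 + 0.2133j, -3.5234 + 0.5105j, 4.2201 + 1.9168j,
         -0.1080 - 0.2292j, -1.3367 - 0.0298j, 0.1107 - 0.4040j),
    ]
    for row in conj_rows:
        out.append(list(row))
        out.append([v.conjugate() for v in row])
    return np.array(out, dtype=complex)


@pytest.fixture(scope="session")
def hiv_reference_table():
    return _hiv_reference_solutions()


HIV_OUTPUT_JETS = [0.5, -0.03, -0.15, -0.2, -0.2, -0.17, -0.16, -0.15]


@pytest.fixture(scope="session")
def hiv_output_jets():
    return list(HIV_OUTPUT_JETS)
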