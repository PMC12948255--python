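import pytest

import tetrafold as tf


@pytest.fixture(scope="session")
def default_weights():
    return tf.PenaltyWeights()


@pytest.fixture(scope="session")
def mj():
    return tf.MJMatrix.default()


@pytest.fixture(scope="session")
def problem_l5():
    """L=5 fragment (anti-HIV antibody loop), full 8-qubit layout."""
    return tf.build_total("YAGYS")


@pytest.fixture(scope="session")
def problem_l4_fixed():
    """L=4 fragment with the global-rotation quotient (2 free qubits)."""
    return tf.build_total("YAGY", config=tf.BuildConfig(fix_first_turns=True))


@pytest.fixture(scope="session")
def ground_l5(problem_l5):
    return tf.exhaustive_ground_state(problem_l5)
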