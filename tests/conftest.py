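import pytest

from gobudget.solver import default_solver
from gobudget.synth import GroupDesign, generate_group, truth_wide


@pytest.fixture(scope="session")
def solver():
    return default_solver()


@pytest.fixture(scope="session")
def trade3_group():
    """Full-design synthetic group (23 subjects x 108 trials, trade3)."""
    design = GroupDesign(seed=7)
    df, truth = generate_group(design)
    return df, truth_wide(truth), design


@pytest.fixture(scope="session")
def small_trade1_group():
    """Small trade1 group for fast fitting tests (6 subjects x 36 trials)."""
    design = GroupDesign(
        n_subjects=6, n_sessions=1, trials_per_session=36,
        model_id="trade1", seed=3,
    )
    df, truth = generate_group(design)
    return df, truth_wide(truth), design
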