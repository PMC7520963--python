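import pytest

from plastaudit import PlastomeSpec, make_plastome


@pytest.fixture(scope="session")
def small_plastome():
    """An 13.5 kb quadripartite plastome (1/10 scale) with planted 2 kb IR."""
    return make_plastome(PlastomeSpec(lsc_len=8_000, ssc_len=1_500, ir_len=2_000, seed=42))


@pytest.fixture(scope="session")
def full_plastome():
    """The default 135 kb fixture: LSC 80 kb, SSC 15 kb, IR 20 kb.

    Sits above both novel-mode cutoffs (130 kbp total, 17 kbp IR) so that
    boundary tests can perturb downward.
    """
    return make_plastome(PlastomeSpec(lsc_len=80_000, ssc_len=15_000, ir_len=20_000, seed=7))
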