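import numpy as np
import pytest

import testiquant as tq


@pytest.fixture(scope="session")
def reference():
    return tq.load_reference()


@pytest.fixture(scope="session")
def cursor_sft(reference):
    return tq.make_stage_table(reference["a_cursor"]["stage_frequencies_percent"])


@pytest.fixture(scope="session")
def cursor_ladder():
    return tq.GermCellLadder.for_species("a_cursor")


@pytest.fixture(scope="session")
def templates():
    return tq.StageTemplateSet.packaged()


@pytest.fixture(scope="session")
def cursor_truth():
    return tq.TruthParams.for_species("a_cursor")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
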