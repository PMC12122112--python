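import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    from lmscore.score_model import default_table

    return default_table()


@pytest.fixture(scope="session")
def marginals(table):
    from lmscore.synthetic import load_paper_marginals

    return load_paper_marginals(table)


@pytest.fixture(scope="session")
def replica_cohort():
    from lmscore.synthetic import reconstruct_paper_cohort

    return reconstruct_paper_cohort(seed=1)


@pytest.fixture(scope="session")
def paper_events():
    from lmscore.io import load_paper_events

    return load_paper_events()


@pytest.fixture(scope="session")
def history_item_ids(table):
    from lmscore.score_model import ScorePart

    return table.item_ids(ScorePart.HISTORY)


@pytest.fixture(scope="session")
def exam_item_ids(table):
    from lmscore.score_model import ScorePart

    return table.item_ids(ScorePart.EXAM)


@pytest.fixture(scope="session")
def investigation_item_ids(table):
    from lmscore.score_model import ScorePart

    return table.item_ids(ScorePart.INVESTIGATION)
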