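import pytest
from hypothesis import HealthCheck, settings

from mkmodel.core import LQParameters
from mkmodel.io import load_published_table

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def published_table():
    """The bundled published MK parameter table (9 cell line × quality rows)."""
    return load_published_table()


@pytest.fixture(scope="session")
def lq_by_row(published_table):
    """LQParameters keyed by (cell_line, quality)."""
    return {
        (row.cell_line, row.quality): LQParameters(
            alpha=row.alpha, beta=row.beta, alpha_se=row.alpha_se, beta_se=row.beta_se,
            label=f"{row.cell_line} {row.quality}",
        )
        for row in published_table.itertuples()
    }
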