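import pytest

from virhost import presets
from virhost.inference import HostAssociationModel


@pytest.fixture(scope="session")
def table2_counts():
    return presets.table2_counts()


@pytest.fixture(scope="session")
def table2_viruses():
    return presets.table2_viruses()


@pytest.fixture(scope="session")
def table2_printed():
    return presets.table2_printed_abundance()


@pytest.fixture(scope="session")
def fitted_counts(table2_counts, table2_viruses):
    """Pipeline fitted from generated counts (the canonical input path)."""
    return HostAssociationModel(table2_counts, table2_viruses).fit()


@pytest.fixture(scope="session")
def fitted_printed(table2_printed, table2_viruses):
    """Pipeline fitted directly from the printed percentage matrix."""
    return HostAssociationModel.from_abundance(table2_printed, table2_viruses).fit()
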