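import pytest

from npchar import io_curation as ic
from npchar import synthetic_library as sl


def curate_smiles(smiles_list, prefix="m"):
    entries = [ic.RawEntry(f"{prefix}{i}", s) for i, s in enumerate(smiles_list)]
    records, reports, summary = ic.curate_library(entries)
    return records


@pytest.fixture(scope="session")
def np_like_records():
    entries, _ = sl.generate(sl.GeneratorSpec("np_like", n=120, seed=11))
    records, _, _ = ic.curate_library(entries)
    return records


@pytest.fixture(scope="session")
def drug_like_records():
    entries, _ = sl.generate(sl.GeneratorSpec("drug_like", n=120, seed=12))
    records, _, _ = ic.curate_library(entries)
    return records
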