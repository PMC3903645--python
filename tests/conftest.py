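import pytest

from habitat16s.seqio import ReferenceEntry, ReferenceStore
from habitat16s.synthetic import SimParams, generate_templates, simulate_reads


@pytest.fixture(scope="session")
def sim_params() -> SimParams:
    return SimParams(seed=1)


@pytest.fixture(scope="session")
def templates(sim_params):
    return generate_templates(sim_params)


@pytest.fixture(scope="session")
def corpus(sim_params, templates):
    """Reads with planted artifacts plus their ground truth."""
    return simulate_reads(templates, sim_params)


@pytest.fixture(scope="session")
def template_store(templates) -> ReferenceStore:
    """A reference store whose entries are the noise-free templates."""
    entries = [
        ReferenceEntry(env=env, ordinal=i + 1, residues=t)
        for env, ts in templates.items()
        for i, t in enumerate(ts)
    ]
    return ReferenceStore(entries=entries)
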