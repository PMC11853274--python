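import pytest
from hypothesis import settings

from splicedisp import catalog as cat
from splicedisp import simulate as sim
from splicedisp.kmers import SubsetPartition

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


@pytest.fixture(scope="session")
def partition6():
    return SubsetPartition.build(6)


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Planted toy annotation written to disk, with parsed models and events."""
    toy = sim.generate_toy_annotation(seed=0)
    paths = toy.write(tmp_path_factory.mktemp("toy"))
    models = cat.read_transcript_exons(paths["gtf"])
    events = cat.infer_events(models)
    catalog_df = cat.classify_acceptors(events, models)
    return {
        "annotation": toy,
        "paths": paths,
        "models": models,
        "events": events,
        "catalog": catalog_df,
        "events_frame": cat.events_frame(events, catalog_df),
    }
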