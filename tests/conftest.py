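import pytest

from cohortwiring.input_accounting import TargetSet
from cohortwiring.model import Catalog, NeuronRecord, SynapseTable
from cohortwiring.synthetic import SynthConfig, generate


def record(nid, **kw):
    defaults = dict(name=nid, side="L", segment="A1", source_type="interneuron")
    defaults.update(kw)
    return NeuronRecord(neuron_id=nid, **defaults)


def lr_pair(base, **kw):
    """Two records forming a left-right homolog pair."""
    return [
        record(f"{base}_L", side="L", homolog_id=f"{base}_R", **kw),
        record(f"{base}_R", side="R", homolog_id=f"{base}_L", **kw),
    ]


@pytest.fixture
def two_target_catalog():
    """Minimal catalog: one L/R target pair plus assorted input candidates."""
    recs = lr_pair("t")
    recs += lr_pair("p")  # paired interneuron candidate
    recs.append(record("mid", side="M", homolog_id="mid", morph_class="Ladder"))
    recs.append(record("sens_L", side="L", homolog_id="sens_R",
                       source_type="sensory", sensory_class="chordotonal"))
    recs.append(record("sens_R", side="R", homolog_id="sens_L",
                       source_type="sensory", sensory_class="chordotonal"))
    recs.append(record("lone", homolog_id=None))
    return Catalog(recs)


@pytest.fixture
def two_targets():
    return TargetSet(name="pair", members=["t_L", "t_R"],
                     homolog_pairs=[("t_L", "t_R")])


def table_of(*rows):
    return SynapseTable.from_rows(rows)


@pytest.fixture(scope="session")
def sharp_system():
    """One default sharp-model synthetic nervous system, reused across tests."""
    return generate(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def null_system():
    return generate(SynthConfig(wiring_model="null"), seed=12)
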