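import logging

import pytest

from terminome.ingest import load_dialects
from terminome.knowledgebase import ProteinEntry, ProcessingFeature
from terminome.synthetic import FixtureSpec, generate_experiment

logging.getLogger("terminome").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dialects():
    return load_dialects()


@pytest.fixture(scope="session")
def pd_dialect(dialects):
    return dialects["proteome_discoverer"]


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic experiment (30 true substrates, 200 nulls,
    2 conditions x 5 replicates, log2FC effect 2, noise sd 0.3)."""
    outdir = tmp_path_factory.mktemp("fixture_default")
    return generate_experiment(
        FixtureSpec(seed=0, n_known_true_cleavages=2), outdir)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A reduced experiment for fast pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(seed=7, n_proteins=8, n_true_cleavages=10,
                       n_background_peptides=40, n_merops_substrates=15)
    return generate_experiment(spec, outdir)


@pytest.fixture()
def toy_entry():
    return ProteinEntry(accession="P00001", sequence="MKTAYIAKQRQISF",
                        gene="TOY1", description="toy protein")


@pytest.fixture()
def signal_entry():
    seq = "M" + "A" * 21 + "CDEFGHIKLMNPQRSTVWY" * 3
    return ProteinEntry(
        accession="P00002", sequence=seq, gene="TOY2",
        features=[ProcessingFeature("signal_peptide", 1, 22)])
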