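import pytest

from budmir.catalog import MiRNARef
from budmir.config import SynthConfig
from budmir import synth


@pytest.fixture(scope="session")
def small_ref():
    """Hand-written 4-entry mature miRNA reference."""
    return [
        MiRNARef("vvi-miR156a", "vvi", "156", "TGACAGAAGAGAGTGAGCACA", True),
        MiRNARef("vvi-miR166a", "vvi", "166", "TCGGACCAGGCTTCATTCCCC", True),
        MiRNARef("ath-miR156a", "ath", "156", "TGACAGAAGAGAGTGAGCACG", False),
        MiRNARef("ath-miR172a", "ath", "172", "AGAATCTTGATGATGCTGCAT", False),
    ]


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def synth_ref(synth_cfg):
    return synth.gen_mirna_reference(synth_cfg)


@pytest.fixture(scope="session")
def synth_libs(synth_cfg, synth_ref):
    return synth.gen_smallrna_libraries(synth_cfg, synth_ref)


@pytest.fixture(scope="session")
def synth_transcriptome(synth_cfg, synth_ref):
    return synth.gen_transcriptome_with_sites(synth_cfg, synth_ref)


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory, synth_cfg):
    """All synthetic artifacts written to one session directory."""
    outdir = tmp_path_factory.mktemp("synth")
    paths = synth.generate_all(synth_cfg, outdir)
    return paths
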