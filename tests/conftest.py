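import pytest

from secscan.cmcore import build_model, load_bundled_model
from secscan.cmcore.stockholm import SeedAlignment


@pytest.fixture(scope="session")
def euk_model():
    return load_bundled_model("eukaryota")


@pytest.fixture(scope="session")
def bact_model():
    return load_bundled_model("bacteria")


@pytest.fixture(scope="session")
def arch_model():
    return load_bundled_model("archaea")


@pytest.fixture(scope="session")
def all_models(euk_model, bact_model, arch_model):
    return [euk_model, bact_model, arch_model]


@pytest.fixture(scope="session")
def toy_model():
    """Tiny 2-pair stem-loop model for exhaustive-oracle comparisons."""
    rows = [("a", "GGACCC"), ("b", "GCAAGC"), ("c", "GGAACC")]
    aln = SeedAlignment(sequences=rows, consensus_structure="<<..>>")
    return build_model(aln, name="toy")


@pytest.fixture(scope="session")
def toy_model_4p():
    """4-pair model with a bifurcation (two hairpins) for oracle tests."""
    rows = [("a", "GGAACCGCAAGC"),
            ("b", "GCAAGCGGAACC"),
            ("c", "GGAACCGGAACC")]
    aln = SeedAlignment(sequences=rows, consensus_structure="<<..>><<..>>")
    return build_model(aln, name="toy4")
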