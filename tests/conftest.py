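import pytest

from abdb import chain_id, numbering
from abdb.fixtures import FixtureSpec, make_entry, make_nonantibody_entry, make_scfv_entry
from abdb.params import PipelineParams


@pytest.fixture(scope="session")
def profile():
    return chain_id.load_default_profile()


@pytest.fixture(scope="session")
def table():
    return numbering.load_scheme_table()


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


CORPUS_SPECS = [
    FixtureSpec(code="1FRE"),                                        # free complete
    FixtureSpec(code="1PRO", antigen="protein"),                     # protein complex
    FixtureSpec(code="1DVX", antigen="anti_idiotype"),               # anti-idiotype pair
    FixtureSpec(code="1DIM", form="light_only"),                     # Bence-Jones dimer
    FixtureSpec(code="1BIO", form="light_only", light_dimer_via_biomt=True),
    FixtureSpec(code="1VHH", form="heavy_only"),                     # camelid VHH
    FixtureSpec(code="1HAP", antigen="hapten_free"),                 # hapten complex
    FixtureSpec(code="1COV", antigen="hapten_covalent"),             # covalent hapten
    FixtureSpec(code="3VWX", antigen="dna"),                         # DNA antigen
    FixtureSpec(code="1DEX", antigen="framework_binder"),            # SpA-like binder
    FixtureSpec(code="1AFX", n_antibodies=2, antigen="protein"),     # 2 copies, 2 antigens
]


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """A directory of synthetic entries spanning every pipeline branch."""
    d = tmp_path_factory.mktemp("pdbs")
    for spec in CORPUS_SPECS:
        (d / f"{spec.code.lower()}.pdb").write_text(make_entry(spec))
    (d / "1fcx.pdb").write_text(make_nonantibody_entry("1FCX"))
    (d / "1scf.pdb").write_text(make_scfv_entry("1SCF"))
    return d


@pytest.fixture(scope="session")
def corpus_codes():
    return [s.code for s in CORPUS_SPECS] + ["1FCX", "1SCF"]
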