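import pytest

import valtrans as vt
from valtrans.codon_content import build_background, content_matrix


@pytest.fixture(scope="session")
def small_genes():
    """60-gene synthetic transcriptome shared by module tests."""
    spec = vt.TranscriptomeSpec(n_genes=60, cds_length_range=(100, 200), seed=2)
    return vt.generate_transcriptome(spec)


@pytest.fixture(scope="session")
def small_aa_background(small_genes):
    return build_background(content_matrix(small_genes, "aa"), "aa")


@pytest.fixture(scope="session")
def small_codon_background(small_genes):
    return build_background(content_matrix(small_genes, "codon"), "codon")
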