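import numpy as np
import pytest

from caseinevo.seqio import Alignment, read_tree


@pytest.fixture
def newick_file(tmp_path):
    def _write(text, name="tree.nwk"):
        p = tmp_path / name
        p.write_text(text + ("\n" if not text.endswith("\n") else ""))
        return p

    return _write


@pytest.fixture
def worked_tree(newick_file):
    """Three-leaf tree with hand-computable GSC weights."""
    return read_tree(newick_file("((A:20,B:20):30,C:50);"))


@pytest.fixture
def toy_alignment():
    return Alignment(
        (
            ("cow", "SAEPK-RT"),
            ("pig", "SAEPKIRT"),
            ("rat", "TAE-KIRT"),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
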