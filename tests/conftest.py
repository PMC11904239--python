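"""Shared fixtures: a synthetic structure corpus, its pentamer database
and the default alphabet, built once per session.

The corpus draws sequences from a reduced 8-letter alphabet so that
pentamer sequences recur across chains in different conformations —
the situation that gives fold-variation columns depth > 1.
"""

import pytest

from pfvmkit import PfscAlphabet, build_db, index_library, make_fixture_library

CORPUS_SEED = 20240901
CORPUS_ALPHABET = "ACDEFGHI"


@pytest.fixture(scope="session")
def alphabet():
    return PfscAlphabet()


@pytest.fixture(scope="session")
def corpus_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    return make_fixture_library(10, seed=CORPUS_SEED, out_dir=out,
                                seq_alphabet=CORPUS_ALPHABET)


@pytest.fixture(scope="session")
def corpus_db(corpus_paths, alphabet):
    return build_db(corpus_paths, alphabet)


@pytest.fixture(scope="session")
def corpus_library(corpus_paths, alphabet):
    return index_library(corpus_paths, alphabet)
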