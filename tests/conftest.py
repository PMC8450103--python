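"""Shared fixtures: everything is generated programmatically and seeded."""

import numpy as np
import pytest

from cloverscan.classifier import DecodingTable
from cloverscan.formats import SeedAlignment
from cloverscan.model import train_model
from cloverscan.simulate import make_fixture_set


@pytest.fixture(scope="session")
def fixture_set():
    """The full offline fixture set at the canonical seed."""
    return make_fixture_set(rng_seed=1, genome_length=100_000)


@pytest.fixture(scope="session")
def euk_table():
    return DecodingTable.load("eukaryote")


@pytest.fixture(scope="session")
def hairpin_model():
    """A tiny oracle-checkable hairpin model (2 pairs, 3 loop singles)."""
    aln = SeedAlignment(
        rows=[("a", "GGACACC"), ("b", "GGTCACC"), ("c", "GGACTCC"),
              ("d", "GGACACC")],
        ss_cons="<<...>>", name="hairpin", isotype="Test",
    )
    return train_model(aln)


@pytest.fixture(scope="session")
def mito_registry(fixture_set):
    from cloverscan.mito import build_mito_registry
    return build_mito_registry(list(fixture_set.mito_alignments.values()))


def random_tiny_model(rng, max_cols: int = 6):
    """A random small trained model for oracle-equivalence checks."""
    structures = ["<<..>>", "......", "<...>.", "<><..>", ".<<>>.",
                  "<.>.<>", "<<<>>>", "..<.>.", "<....>", ".<..>."]
    ss = structures[int(rng.integers(len(structures)))][:max_cols]
    nrows = int(rng.integers(1, 4))
    while True:
        rows = [
            (f"r{k}", "".join(
                rng.choice(list("ACGT-"), p=[.22, .22, .22, .22, .12])
                for _ in ss))
            for k in range(nrows)
        ]
        try:
            return train_model(SeedAlignment(rows=rows, ss_cons=ss,
                                             name="tiny"))
        except Exception:
            continue


def random_seq(rng, max_len: int = 8) -> str:
    L = int(rng.integers(0, max_len + 1))
    return "".join(
        rng.choice(list("ACGTN"), p=[.24, .24, .24, .24, .04])
        for _ in range(L))
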