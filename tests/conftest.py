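from __future__ import annotations

import numpy as np
import pytest

from siftsforge.config import SiftsConfig
from siftsforge.fixtures import FixtureSpec, generate_archive
from siftsforge.pipeline import run_mapping
from siftsforge.seq import STANDARD_AA, AlignmentParams, SequenceRecord


@pytest.fixture(scope="session")
def params_semiglobal() -> AlignmentParams:
    return AlignmentParams(mode="semiglobal")


@pytest.fixture(scope="session")
def params_global() -> AlignmentParams:
    return AlignmentParams(mode="global")


@pytest.fixture(scope="session")
def small_archive(tmp_path_factory):
    """A 12-protein synthetic archive shared across tests (seed-pinned)."""
    out = tmp_path_factory.mktemp("archive")
    spec = FixtureSpec(seed=11, n_proteins=12)
    truth = generate_archive(spec, out)
    return out, truth, spec


@pytest.fixture(scope="session")
def small_run(small_archive):
    out, truth, _spec = small_archive
    config = SiftsConfig(date_pin="2020-01-01")
    run = run_mapping(
        out / "structures", out / "sequences.fasta",
        out / "sequences_meta.tsv", out / "xrefs.tsv", config,
    )
    return run, truth


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))


def mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Substitute exactly n_sub distinct positions with different residues."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        alt = [c for c in STANDARD_AA if c != out[pos]]
        out[pos] = alt[int(rng.integers(len(alt)))]
    return "".join(out)


def record(acc: str, seq: str, **kw) -> SequenceRecord:
    return SequenceRecord(accession=acc, sequence=seq, **kw)
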