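"""Shared fixtures: synthetic scoring problems and tiny MSA builders."""
from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pytest

from zeppi import (
    FixtureSpec,
    PairedMSA,
    make_paired_fixture_msas,
    read_msa,
    pair_msas,
    write_toy_dimer,
)


def msa_from_fasta(text: str, **kwargs):
    """Read a SpeciesMSA straight from FASTA text (word species labels)."""
    kwargs.setdefault("species_regex", r"OX=(\w+)")
    return read_msa(io.StringIO(text), format=kwargs.pop("format", "fasta"), **kwargs)


def fasta(*seqs: str, species: list[str] | None = None) -> str:
    """FASTA text with OX= species labels (default: one species per row)."""
    species = species or [str(i + 1) for i in range(len(seqs))]
    return "".join(
        f">row{i} OX={sp}\n{s}\n" for i, (sp, s) in enumerate(zip(species, seqs))
    )


def paired_from_columns(cols1: list[str], cols2: list[str]) -> PairedMSA:
    """Build a PairedMSA whose protein-1/2 columns are the given strings.

    ``cols1[c][r]`` is the residue of row r at protein-1 column c; no
    filtering is applied (all rows share a species with themselves).
    """
    n_rows = len(cols1[0])
    rows1 = ["".join(col[r] for col in cols1) for r in range(n_rows)]
    rows2 = ["".join(col[r] for col in cols2) for r in range(n_rows)]
    return PairedMSA(
        rows=[(str(r + 1), s1, s2) for r, (s1, s2) in enumerate(zip(rows1, rows2))],
        len1=len(cols1),
        len2=len(cols2),
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("fixtures")


def build_problem(spec: FixtureSpec, out_dir: Path):
    """Toy dimer PDB + matching MSA files for one FixtureSpec."""
    sub = out_dir / f"spec_{spec.seed}_{spec.fidelity}_{len(spec.planted_pairs)}"
    sub.mkdir(parents=True, exist_ok=True)
    pdb = write_toy_dimer(spec, sub / "dimer.pdb")
    p1, p2 = make_paired_fixture_msas(spec, sub)
    return pdb, p1, p2


@pytest.fixture(scope="session")
def signal_problem(fixture_dir):
    """Planted covariation at the true contacts (fidelity 1, depth 500)."""
    spec = FixtureSpec(seed=11, fidelity=1.0)
    return spec, *build_problem(spec, fixture_dir)


@pytest.fixture(scope="session")
def null_problem(fixture_dir):
    """Interface columns drawn from the surface-column distribution."""
    spec = FixtureSpec(seed=11, covarying_pairs=())
    return spec, *build_problem(spec, fixture_dir)


def random_small_msa(rng: np.random.Generator, max_rows=6, max_cols=4):
    """A tiny random paired MSA for brute-force oracle comparisons."""
    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols1 = int(rng.integers(1, max_cols // 2 + 1))
    n_cols2 = int(rng.integers(1, max_cols - n_cols1 + 1))
    letters = list("ARND-")
    rows1 = [
        "".join(rng.choice(letters, size=n_cols1)) for _ in range(n_rows)
    ]
    rows2 = [
        "".join(rng.choice(letters, size=n_cols2)) for _ in range(n_rows)
    ]
    # the query (row 0) must be gapless in this package's convention
    rows1[0] = rows1[0].replace("-", "A")
    rows2[0] = rows2[0].replace("-", "A")
    m1 = msa_from_fasta(fasta(*rows1))
    m2 = msa_from_fasta(fasta(*rows2))
    return pair_msas(m1, m2)
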