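"""Seeded synthetic fixtures: toy dimers and species-labeled MSAs.

Every stage of the scorer is testable offline with these generators.
They emulate the two signal classes an interface can carry — per-column
conservation and planted covariation between designated column pairs —
plus gaps and controllable depth. They are not a biophysically realistic
sequence simulator: no phylogenetic correlation between rows, i.i.d.
gaps, single working alphabet per column.

Sequence model, per column: a working alphabet of ``alphabet_size``
letters is drawn once; each row repeats the query letter with probability
``conservation`` and otherwise draws uniformly from the working alphabet.
A covarying pair (one column in each protein) shares a fixed bijection
between its two working alphabets: the partner column copies the mapped
letter with probability ``fidelity`` and otherwise draws from its own
background. ``fidelity = 0`` therefore makes planted columns
statistically identical to ordinary surface columns (an exchangeable
null), while ``fidelity = 1`` with ``conservation = 0`` gives a planted
mutual information of ln(alphabet_size).

Toy dimers place one heavy atom per residue (an optional backbone mode
adds four atoms) so that the designated contacts sit at 5.0 Angstrom
across the interface and every other inter-chain distance exceeds
8 Angstrom.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from ._alphabet import AA_LETTERS

CONTACT_DISTANCE = 5.0  # Angstrom across the interface
SLOT_SPACING = 30.0     # Angstrom between interface slots
FAR_OFFSET = 60.0       # Angstrom from interface plane to spectators

DEFAULT_CONTACTS = ((2, 3), (5, 7), (8, 11), (11, 15))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic scoring problem.

    ``contacts`` are 0-based residue-index pairs (chain 1, chain 2) that
    form the true interface of the toy dimer; by default the same pairs
    (as query-column pairs) carry the planted covariation.
    """

    n_residues1: int = 30
    n_residues2: int = 30
    contacts: tuple[tuple[int, int], ...] = DEFAULT_CONTACTS
    msa_depth: int = 500
    conservation: float = 0.5
    fidelity: float = 1.0
    covarying_pairs: tuple[tuple[int, int], ...] | None = None
    gap_fraction: float = 0.05
    alphabet_size: int = 8
    seed: int = 0
    backbone: bool = False
    homodimer: bool = False  # both chains carry the same protein

    def __post_init__(self) -> None:
        if self.homodimer and self.n_residues1 != self.n_residues2:
            raise ValueError("homodimer chains must have equal length")
        for i, j in self.contacts:
            if not (0 <= i < self.n_residues1 and 0 <= j < self.n_residues2):
                raise ValueError(f"contact ({i},{j}) outside chain bounds")
        if not 2 <= self.alphabet_size <= 20:
            raise ValueError("alphabet_size must be in 2..20")
        for name in ("conservation", "fidelity", "gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def planted_pairs(self) -> tuple[tuple[int, int], ...]:
        return (
            self.covarying_pairs
            if self.covarying_pairs is not None
            else self.contacts
        )


@dataclass
class _ColumnModel:
    alphabet: np.ndarray  # letter codes, query letter first
    query_letter: str


def _column_models(spec: FixtureSpec) -> tuple[list[_ColumnModel], list[_ColumnModel]]:
    """Per-column working alphabets and query letters, seeded once."""
    rng = np.random.default_rng([spec.seed, 0])
    letters = np.array(list(AA_LETTERS))
    out: list[list[_ColumnModel]] = []
    for n_res in (spec.n_residues1, spec.n_residues2):
        cols = []
        for _ in range(n_res):
            alpha = rng.choice(20, size=spec.alphabet_size, replace=False)
            cols.append(
                _ColumnModel(alphabet=alpha, query_letter=letters[alpha[0]])
            )
        out.append(cols)
    if spec.homodimer:
        return out[0], out[0]
    return out[0], out[1]


def query_sequences(spec: FixtureSpec) -> tuple[str, str]:
    """The two proteins' query sequences implied by the spec's seed."""
    cols1, cols2 = _column_models(spec)
    return (
        "".join(c.query_letter for c in cols1),
        "".join(c.query_letter for c in cols2),
    )


def _sample_protein(
    rng: np.random.Generator,
    cols: list[_ColumnModel],
    depth: int,
    conservation: float,
) -> np.ndarray:
    """Letter-code matrix (depth, n_cols) from the background model."""
    n = len(cols)
    out = np.empty((depth, n), dtype=np.intp)
    for c, model in enumerate(cols):
        conserve = rng.random(depth) < conservation
        draws = model.alphabet[rng.integers(len(model.alphabet), size=depth)]
        draws[conserve] = model.alphabet[0]
        out[:, c] = draws
    return out


def make_fixture_msa_texts(spec: FixtureSpec) -> tuple[str, str]:
    """FASTA texts of the two per-protein MSAs (first record = query).

    Species labels are ``OX=<taxid>`` with taxid 1..depth; the query is
    species 1 and carries no gaps. Byte-identical for a given spec.
    """
    cols1, cols2 = _column_models(spec)
    rng = np.random.default_rng([spec.seed, 1])
    depth = spec.msa_depth
    m1 = _sample_protein(rng, cols1, depth, spec.conservation)
    # a homodimer has one protein: its planted pairs couple two columns
    # of the same MSA, and the second "protein" is the same matrix
    m2 = (
        m1
        if spec.homodimer
        else _sample_protein(rng, cols2, depth, spec.conservation)
    )

    # planted covariation: partner column copies through the bijection
    for i, j in spec.planted_pairs:
        a1 = cols1[i].alphabet
        a2 = cols2[j].alphabet
        sigma = {int(x): int(y) for x, y in zip(a1, a2)}
        copy = rng.random(depth) < spec.fidelity
        m2[copy, j] = np.array(
            [sigma[int(x)] for x in m1[copy, i]], dtype=np.intp
        )

    # query row: species 1, exactly the query sequence, never gapped
    m1[0] = [c.alphabet[0] for c in cols1]
    m2[0] = [c.alphabet[0] for c in cols2]

    letters = np.array(list(AA_LETTERS))
    texts = []
    proteins = ((1, m1),) if spec.homodimer else ((1, m1), (2, m2))
    for p, m in proteins:
        gaps = rng.random(m.shape) < spec.gap_fraction
        gaps[0] = False
        chars = letters[m]
        chars[gaps] = "-"
        records = []
        for t in range(depth):
            records.append(
                f">p{p}_tax{t + 1} OX={t + 1}\n" + "".join(chars[t])
            )
        texts.append("\n".join(records) + "\n")
    if spec.homodimer:
        return texts[0], texts[0]
    return texts[0], texts[1]


def make_paired_fixture_msas(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the two fixture MSAs as FASTA files and return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t1, t2 = make_fixture_msa_texts(spec)
    p1 = out_dir / f"fixture_seed{spec.seed}_p1.fasta"
    p2 = out_dir / f"fixture_seed{spec.seed}_p2.fasta"
    p1.write_text(t1)
    p2.write_text(t2)
    return p1, p2


_BACKBONE_OFFSETS = np.array(
    [
        (0.0, 0.0, 0.0),     # CA
        (-1.2, 0.4, 0.0),    # N
        (1.2, 0.4, 0.0),     # C
        (1.6, 1.2, 0.8),     # O
    ]
)
_BACKBONE_NAMES = ("CA", "N", "C", "O")
_BACKBONE_ELEMENTS = ("C", "N", "C", "O")


def _residue_centers(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Residue center coordinates realising the designated contacts."""
    iface1 = sorted({i for i, _ in spec.contacts})
    slot = {r: k for k, r in enumerate(iface1)}
    partners: dict[int, list[int]] = {r: [] for r in iface1}
    owner: dict[int, int] = {}
    for i, j in spec.contacts:
        if j in owner and owner[j] != i:
            raise ValueError(
                "infeasible geometry: a chain-2 residue contacts two "
                "different chain-1 residues"
            )
        owner[j] = i
        partners[i].append(j)
    offsets = [(0.0, 3.0, 4.0), (0.0, -3.0, 4.0)]  # both 5.0 A away
    for i, js in partners.items():
        if len(js) > len(offsets):
            raise ValueError(
                f"infeasible geometry: residue {i} has {len(js)} partners"
            )

    c1 = np.zeros((spec.n_residues1, 3))
    for r in range(spec.n_residues1):
        if r in slot:
            c1[r] = (SLOT_SPACING * slot[r], 0.0, 0.0)
        else:
            c1[r] = (SLOT_SPACING * r, -FAR_OFFSET, 0.0)
    c2 = np.zeros((spec.n_residues2, 3))
    placed = set()
    for i, js in partners.items():
        for t, j in enumerate(sorted(js)):
            dx, dy, dz = offsets[t]
            c2[j] = (SLOT_SPACING * slot[i] + dx, dy, dz)
            placed.add(j)
    for r in range(spec.n_residues2):
        if r not in placed:
            c2[r] = (SLOT_SPACING * r, FAR_OFFSET, 0.0)
    return c1, c2


def make_toy_dimer(spec: FixtureSpec) -> str:
    """PDB text of a two-chain toy dimer realising the spec's contacts.

    Chains A and B; residue sequences equal the fixture MSA queries, so
    structure-to-MSA mapping is the identity. Contact residue pairs sit
    at 5.0 Angstrom, all other inter-chain residue distances exceed
    8 Angstrom; deterministic for a given spec.
    """
    seq1, seq2 = query_sequences(spec)
    c1, c2 = _residue_centers(spec)
    if spec.backbone:
        offs, names, elements = (
            _BACKBONE_OFFSETS,
            _BACKBONE_NAMES,
            _BACKBONE_ELEMENTS,
        )
    else:
        offs = _BACKBONE_OFFSETS[:1]
        names = _BACKBONE_NAMES[:1]
        elements = _BACKBONE_ELEMENTS[:1]
    n_per = len(offs)
    total = (len(seq1) + len(seq2)) * n_per
    atoms = struc.AtomArray(total)
    k = 0
    for chain_id, seq, centers in (("A", seq1, c1), ("B", seq2, c2)):
        for r, (aa, center) in enumerate(zip(seq, centers)):
            res3 = ProteinSequence.convert_letter_1to3(aa)
            for o in range(n_per):
                atoms.coord[k] = center + offs[o]
                atoms.chain_id[k] = chain_id
                atoms.res_id[k] = r + 1
                atoms.res_name[k] = res3
                atoms.atom_name[k] = names[o]
                atoms.element[k] = elements[o]
                atoms.hetero[k] = False
                k += 1
    pdb = PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def write_toy_dimer(spec: FixtureSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(make_toy_dimer(spec))
    return path


def sample_potts_pair(
    depth: int,
    beta: float,
    n_independent: int = 8,
    q: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Sequences from a two-site Potts model plus independent columns.

    Columns 0 and 1 are coupled: x is uniform over q states and y copies
    a fixed random bijection of x with probability
    exp(beta) / (exp(beta) + q - 1), otherwise it is uniform over the
    remaining states — the exact conditional of a Potts pair with
    coupling matrix J(x, y) = beta * [sigma(x) = y]. The other
    ``n_independent`` columns are i.i.d. uniform. Returned as a
    (depth, 2 + n_independent) uint8 state matrix (no gaps).
    """
    rng = np.random.default_rng(seed)
    sigma = rng.permutation(q)
    x = rng.integers(q, size=depth)
    p_copy = np.exp(beta) / (np.exp(beta) + q - 1)
    copy = rng.random(depth) < p_copy
    y = rng.integers(q - 1, size=depth)
    mapped = sigma[x]
    # uniform over the q-1 non-mapped states
    y = np.where(y >= mapped, y + 1, y)
    y[copy] = mapped[copy]
    rest = rng.integers(q, size=(depth, n_independent))
    return np.column_stack([x, y, rest]).astype(np.uint8)
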