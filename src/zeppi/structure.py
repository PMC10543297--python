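"""Dimer structure handling: parsing, solvent accessibility, contacts.

A structural model of a two-chain complex is reduced to heavy-atom
coordinates of its protein residues. Three quantities are derived:

* per-residue accessible surface area (ASA) of each chain in isolation
  and in the complex (Shrake-Rupley spheres);
* a surface/buried classification by relative ASA against theoretical
  per-residue maxima (Tien et al. 2013);
* the inter-chain interface: residue pairs whose minimal heavy-atom
  distance is strictly below a cutoff (default 6.0 Angstrom).

Residue identity is (author residue number, insertion code); all reports
use author numbering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io import pdbx
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .errors import (
    ChainNotFoundError,
    EmptyChainError,
    EmptyInterfaceError,
    SequenceStructureMismatchError,
    StructureFormatError,
)

ResKey = tuple[int, str]  # (author residue number, insertion code)

#: Theoretical maximum ASA per residue (Angstrom^2), Tien et al. 2013.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}

DEFAULT_CONTACT_CUTOFF = 6.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_REL_ASA = 0.05
SASA_POINTS = 960


@dataclass
class ChainStructure:
    """Heavy-atom representation of one protein chain."""

    chain_id: str
    atoms: struc.AtomArray
    res_keys: list[ResKey]
    sequence: str
    res_starts: np.ndarray  # len n_res + 1, segment bounds into `atoms`

    @property
    def n_residues(self) -> int:
        return len(self.res_keys)

    def residue_coords(self, i: int) -> np.ndarray:
        return self.atoms.coord[self.res_starts[i]:self.res_starts[i + 1]]

    def key_index(self) -> dict[ResKey, int]:
        return {k: i for i, k in enumerate(self.res_keys)}


@dataclass
class SurfaceMap:
    """Per-residue ASA and surface/interface-by-ASA classification."""

    res_keys: list[ResKey]
    asa_isolated: np.ndarray
    asa_complexed: np.ndarray
    buried_asa: np.ndarray
    is_surface: np.ndarray
    is_interface: np.ndarray  # buried ASA > 0 in the complex

    def surface_residues(self) -> set[ResKey]:
        return {k for k, s in zip(self.res_keys, self.is_surface) if s}

    def to_dataframe(self, chain: ChainStructure) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": chain.chain_id,
                "resnum": [f"{n}{i}" for n, i in self.res_keys],
                "aa": list(chain.sequence),
                "asa_isolated": self.asa_isolated,
                "buried_asa": self.buried_asa,
                "is_surface": self.is_surface,
                "is_interface": self.is_interface,
            }
        )


@dataclass
class InterfaceContacts:
    """Inter-chain residue contacts under the heavy-atom distance cutoff."""

    contacts: list[tuple[ResKey, ResKey]]
    iface1: list[ResKey] = field(default_factory=list)
    iface2: list[ResKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.iface1:
            self.iface1 = sorted({a for a, _ in self.contacts})
        if not self.iface2:
            self.iface2 = sorted({b for _, b in self.contacts})

    @property
    def is_empty(self) -> bool:
        return len(self.contacts) == 0

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def transpose(self) -> "InterfaceContacts":
        return InterfaceContacts(
            contacts=sorted((b, a) for a, b in self.contacts)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res1": [f"{n}{i}" for (n, i), _ in self.contacts],
                "res2": [f"{n}{i}" for _, (n, i) in self.contacts],
            }
        )


def _three_to_one(res_name: str) -> str:
    if res_name == "MSE":
        return "M"
    try:
        one = ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"
    return one if one in MAX_ASA else "X"


def _load_atom_array(structure_file: str | Path) -> struc.AtomArray:
    path = Path(structure_file)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            cif = pdbx.CIFFile.read(str(path))
            return pdbx.get_structure(cif, model=1, altloc="occupancy")
        pdb = PDBFile.read(str(path))
        return pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise StructureFormatError(
            f"could not parse {path} as PDB/mmCIF: {exc}"
        ) from exc


def _extract_chain(arr: struc.AtomArray, chain_id: str) -> ChainStructure:
    if chain_id not in set(arr.chain_id):
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    sub = arr[arr.chain_id == chain_id]
    # heavy protein atoms only; MSE kept as selenomethionine -> MET
    keep = (sub.element != "H") & (sub.element != "D")
    keep &= struc.filter_amino_acids(sub) | (sub.res_name == "MSE")
    sub = sub[keep]
    if sub.array_length() == 0:
        raise EmptyChainError(f"empty chain: {chain_id!r} has no protein residues")
    starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
    res_keys: list[ResKey] = []
    seq_chars: list[str] = []
    for s in starts[:-1]:
        ins = sub.ins_code[s] if hasattr(sub, "ins_code") else ""
        res_keys.append((int(sub.res_id[s]), str(ins)))
        seq_chars.append(_three_to_one(str(sub.res_name[s])))
    return ChainStructure(
        chain_id=chain_id,
        atoms=sub,
        res_keys=res_keys,
        sequence="".join(seq_chars),
        res_starts=starts,
    )


def parse_dimer(
    structure_file: str | Path, chain1: str, chain2: str
) -> tuple[ChainStructure, ChainStructure]:
    """Parse a two-chain model into heavy-atom chain structures.

    Hydrogens, solvent and hetero ligands are removed; alternate
    locations are resolved to the highest-occupancy atom; only the first
    model of a multi-model file is read.
    """
    arr = _load_atom_array(structure_file)
    return _extract_chain(arr, chain1), _extract_chain(arr, chain2)


def _residue_asa(chain: ChainStructure, atom_sasa: np.ndarray) -> np.ndarray:
    vals = np.nan_to_num(atom_sasa, nan=0.0)
    out = np.empty(chain.n_residues)
    for i in range(chain.n_residues):
        out[i] = vals[chain.res_starts[i]:chain.res_starts[i + 1]].sum()
    return out


def compute_surface(
    chain1: ChainStructure,
    chain2: ChainStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    rel_asa_threshold: float = DEFAULT_REL_ASA,
    point_number: int = SASA_POINTS,
) -> tuple[SurfaceMap, SurfaceMap]:
    """Shrake-Rupley ASA of each chain alone and within the complex.

    A residue is *surface* when its isolated-chain ASA reaches
    ``rel_asa_threshold`` of the residue-type maximum; it is
    *interface-by-ASA* when complex formation buries any of its area.
    Element (single-atom) van der Waals radii are used so that
    reduced-representation models remain computable.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")

    def chain_sasa(atoms: struc.AtomArray) -> np.ndarray:
        return struc.sasa(
            atoms,
            probe_radius=probe_radius,
            point_number=point_number,
            vdw_radii="Single",
        )

    complex_atoms = chain1.atoms + chain2.atoms
    sasa_complex = chain_sasa(complex_atoms)
    n1 = chain1.atoms.array_length()
    maps = []
    for chain, cplx in (
        (chain1, sasa_complex[:n1]),
        (chain2, sasa_complex[n1:]),
    ):
        iso = _residue_asa(chain, chain_sasa(chain.atoms))
        com = _residue_asa(
            chain,
            cplx,
        )
        buried = np.maximum(iso - com, 0.0)
        max_asa = np.array([MAX_ASA[a] for a in chain.sequence])
        is_surface = (iso / max_asa) >= rel_asa_threshold
        is_iface = buried > 1e-6
        maps.append(
            SurfaceMap(
                res_keys=list(chain.res_keys),
                asa_isolated=iso,
                asa_complexed=com,
                buried_asa=buried,
                is_surface=is_surface,
                is_interface=is_iface,
            )
        )
    return maps[0], maps[1]


def extract_contacts(
    chain1: ChainStructure,
    chain2: ChainStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InterfaceContacts:
    """Residue pairs with minimal heavy-atom distance strictly < cutoff.

    Returns an empty :class:`InterfaceContacts` (``is_empty``) when no
    pair qualifies — the empty-interface signal for unscoreable models.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree1 = cKDTree(chain1.atoms.coord)
    tree2 = cKDTree(chain2.atoms.coord)
    # atom index -> residue index lookup per chain
    res_of_atom1 = np.repeat(
        np.arange(chain1.n_residues), np.diff(chain1.res_starts)
    )
    res_of_atom2 = np.repeat(
        np.arange(chain2.n_residues), np.diff(chain2.res_starts)
    )
    pairs = tree1.query_ball_tree(tree2, r=cutoff)
    seen: set[tuple[int, int]] = set()
    for i, js in enumerate(pairs):
        if not js:
            continue
        d = np.linalg.norm(
            chain2.atoms.coord[js] - chain1.atoms.coord[i], axis=1
        )
        for j, dij in zip(js, d):
            if dij < cutoff:  # strict: the closed KD-tree ball is refined
                seen.add((int(res_of_atom1[i]), int(res_of_atom2[j])))
    contacts = sorted(
        (chain1.res_keys[a], chain2.res_keys[b]) for a, b in seen
    )
    return InterfaceContacts(contacts=contacts)


def require_contacts(contacts: InterfaceContacts) -> InterfaceContacts:
    """Raise the empty-interface error for models without any contact."""
    if contacts.is_empty:
        raise EmptyInterfaceError("empty interface: no heavy-atom contact under cutoff")
    return contacts


def map_structure_to_msa(
    chain: ChainStructure,
    msa_query_sequence: str,
    min_identity: float = 0.30,
) -> dict[ResKey, int]:
    """Map author-numbered residues onto MSA query positions.

    Global alignment (BLOSUM62, gap open 10 / extend 0.5, free terminal
    gaps) of the chain's one-letter sequence against the ungapped MSA
    query; each residue maps to at most one query position, unaligned
    residues stay unmapped.
    """
    if not chain.sequence or not msa_query_sequence:
        raise SequenceStructureMismatchError("empty sequence for mapping")
    s1 = ProteinSequence(chain.sequence)
    s2 = ProteinSequence(msa_query_sequence.upper())
    matrix = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62
    ali = align_optimal(
        s1, s2, matrix, gap_penalty=(-10, -0.5), terminal_penalty=False
    )[0]
    trace = ali.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    mapped = trace[both]
    if len(mapped) == 0:
        raise SequenceStructureMismatchError("no aligned positions")
    matches = sum(
        chain.sequence[i] == msa_query_sequence[j].upper() for i, j in mapped
    )
    identity = matches / len(mapped)
    if identity < min_identity:
        raise SequenceStructureMismatchError(
            f"sequence/structure mismatch: identity {identity:.2f} < {min_identity:.2f}"
        )
    return {chain.res_keys[i]: int(j) for i, j in mapped}
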