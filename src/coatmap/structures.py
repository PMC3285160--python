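"""Structure data model, PDB I/O and near-neighbor subcomplex decomposition.

The in-memory model is a thin chains -> residues -> atoms hierarchy carrying
exactly what the downstream surface-area and interface machinery needs:
author residue numbering (with insertion codes), per-atom van der Waals
radii, and a per-chain flag marking chains that provide alpha-carbon
coordinates only (the situation typical of low-resolution cryo-EM fits of
large assemblies such as clathrin coats).

Large assemblies are decomposed into per-chain "subcomplexes": each chain
together with its near neighbors, where two chains are near neighbors if
any inter-chain C-alpha/C-alpha distance is <= 5 A. Each subcomplex can
then be treated as an independent structure by the interface detector,
which keeps the solvent-accessibility computation tractable for coats of
eighteen or more polypeptide chains.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Subcomplex",
    "DEFAULT_RADII",
    "CA_UNITED_RADIUS",
    "read_structure",
    "write_structure",
    "near_neighbors",
    "build_subcomplexes",
]

# Protein heavy-atom van der Waals radii (A), Chothia-style united-atom set.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}

# United-residue radius for CA atoms of calpha-only chains. The coarse
# model treats each residue as a single sphere centred on its C-alpha.
CA_UNITED_RADIUS = 1.87

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = tuple(sorted(THREE_TO_ONE))

_WATERS = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) A
    radius: float      # vdW radius, A

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.radius > 0:
            raise ValueError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    chain_id: str
    seq_id: int          # author numbering
    icode: str           # insertion code, "" if none
    res_type: str        # three-letter code or UNK
    atoms: list[Atom]

    @property
    def res_id(self) -> tuple[int, str]:
        """Author residue identity used everywhere downstream."""
        return (self.seq_id, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_type, "X")

    @property
    def label(self) -> str:
        """Compact label in the style interface tables use, e.g. ``L845``."""
        return f"{self.one_letter}{self.seq_id}{self.icode}"

    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def calpha_only(self) -> bool:
        return all(len(r.atoms) == 1 and r.atoms[0].name == "CA" for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        coords = [r.ca().coord for r in self.residues if r.ca() is not None]
        if not coords:
            raise ValueError(f"chain {self.chain_id} has no CA atoms")
        return np.asarray(coords)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            if r.res_id in seen:
                raise ValueError(f"chain {self.chain_id}: duplicate residue id {r.res_id}")
            seen.add(r.res_id)


@dataclass
class Structure:
    chains: list[Chain]
    source_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def subset(self, chain_ids) -> "Structure":
        """New Structure restricted to *chain_ids*, coordinates unchanged."""
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chain_ids]
        if missing:
            raise KeyError(f"chains {missing} not in structure")
        chains = [copy.deepcopy(self.chain(c)) for c in wanted]
        return Structure(chains=chains, source_id=self.source_id)

    def atoms(self):
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    def to_calpha(self, ca_radius: float = CA_UNITED_RADIUS) -> "Structure":
        """C-alpha-only rendition: all non-CA atoms removed, coordinates kept."""
        chains = []
        for chain in self.chains:
            residues = []
            for res in chain.residues:
                ca = res.ca()
                if ca is None:
                    raise ValueError(
                        f"residue {res.label} in chain {chain.chain_id} has no CA atom"
                    )
                residues.append(
                    Residue(
                        chain_id=chain.chain_id,
                        seq_id=res.seq_id,
                        icode=res.icode,
                        res_type=res.res_type,
                        atoms=[Atom("CA", "C", ca.coord.copy(), ca_radius)],
                    )
                )
            chains.append(Chain(chain_id=chain.chain_id, residues=residues))
        return Structure(chains=chains, source_id=self.source_id)


@dataclass
class Subcomplex:
    focal_chain: str
    members: list[str]  # focal first, then file order

    def __post_init__(self) -> None:
        if self.focal_chain not in self.members:
            raise ValueError("focal chain must be a member of its subcomplex")

    @property
    def member_string(self) -> str:
        """Table-style member string, e.g. ``AEFJB``."""
        return "".join(self.members)


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        name = bio_atom.get_name().strip()
        elem = "".join(ch for ch in name if ch.isalpha())[:1].upper()
    return elem


def read_structure(
    path,
    model_index: int = 0,
    radii: dict[str, float] | None = None,
    ca_united_radius: float = CA_UNITED_RADIUS,
    unk_radius: float = 1.87,
    source_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    HETATM records other than MSE (read as MET) and waters are excluded,
    hydrogens are dropped, and alternate locations are resolved to the
    highest-occupancy conformer (first in file on a tie). Radii are
    assigned from *radii* (element-keyed); CA atoms of chains that turn
    out to be calpha-only are re-assigned the united-residue radius.
    """
    from Bio.PDB import PDBParser

    radii = dict(DEFAULT_RADII if radii is None else radii)
    parser = PDBParser(QUIET=True)
    model_struct = parser.get_structure("s", str(path))
    models = list(model_struct)
    if not models:
        raise ValueError(f"{path}: empty model")
    try:
        model = models[model_index]
    except IndexError:
        raise ValueError(f"{path}: model index {model_index} out of range") from None

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            het, seq_id, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            if resname in _WATERS:
                continue
            if het.strip() and resname != "MSE":
                continue  # non-MSE heteroatom group
            res_type = "MET" if resname == "MSE" else resname
            if res_type not in THREE_TO_ONE:
                res_type = "UNK"
            atoms: list[Atom] = []
            # resolve altlocs: group unpacked atoms by name, keep best
            by_name: dict[str, list] = {}
            for bio_atom in bio_res.get_unpacked_list():
                by_name.setdefault(bio_atom.get_name(), []).append(bio_atom)
            for name, cands in by_name.items():
                best = max(cands, key=lambda a: (a.get_occupancy() or 0.0))
                # max() keeps the first on ties, matching file order
                elem = _element_of(best)
                if elem in ("H", "D"):
                    continue
                name_fixed = "SE" if elem == "SE" else name
                radius = radii.get(elem)
                if radius is None:
                    if res_type == "UNK":
                        radius = unk_radius
                    else:
                        raise ValueError(
                            f"{path}: no radius for element {elem!r} "
                            f"(atom {name} in {resname} {seq_id}{icode.strip()})"
                        )
                atoms.append(Atom(name=name_fixed, element=elem,
                                  coord=np.array(best.get_coord(), dtype=float),
                                  radius=radius))
            if atoms:
                residues.append(Residue(
                    chain_id=bio_chain.id, seq_id=seq_id,
                    icode=icode.strip(), res_type=res_type, atoms=atoms,
                ))
        if residues:
            chains.append(Chain(chain_id=bio_chain.id, residues=residues))
    if not chains:
        raise ValueError(f"{path}: empty model")

    structure = Structure(
        chains=chains,
        source_id=source_id if source_id is not None else str(path),
    )
    for chain in structure.chains:
        if chain.calpha_only:
            for res in chain.residues:
                res.atoms[0].radius = ca_united_radius
    return structure


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as a minimal fixed-format PDB file.

    Output is byte-deterministic for a given structure: fixed field
    widths, %8.3f coordinates, occupancy 1.00, B-factor 0.00.
    """
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name column convention: start in col 14 for
                # one/two-letter carbon-style names
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{res.res_type:>3s} "
                    f"{chain.chain_id}{res.seq_id:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].res_type:>3s} "
                     f"{chain.chain_id}{chain.residues[-1].seq_id:4d}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def near_neighbors(structure: Structure, cutoff: float = 5.0) -> dict[str, set[str]]:
    """Symmetric chain adjacency: chains are near neighbors iff their
    closest inter-chain C-alpha pair is within *cutoff* (inclusive)."""
    coords = {}
    for chain in structure.chains:
        coords[chain.chain_id] = chain.ca_coords()  # raises if no CA
    ids = structure.chain_ids
    adj: dict[str, set[str]] = {cid: set() for cid in ids}
    trees = {cid: cKDTree(xyz) for cid, xyz in coords.items()}
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            dmin = trees[ci].query(coords[cj], k=1)[0].min()
            if dmin <= cutoff:
                adj[ci].add(cj)
                adj[cj].add(ci)
    return adj


def build_subcomplexes(structure: Structure, cutoff: float = 5.0) -> list[Subcomplex]:
    """One subcomplex per chain: the chain plus all its near neighbors,
    members ordered focal-first then by position in the file."""
    adj = near_neighbors(structure, cutoff=cutoff)
    out = []
    for cid in structure.chain_ids:
        members = [cid] + [c for c in structure.chain_ids if c in adj[cid] and c != cid]
        out.append(Subcomplex(focal_chain=cid, members=members))
    return out
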