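"""Shrake–Rupley solvent-accessible surface area with a deterministic quadrature.

Each atom is inflated by the probe radius and sampled with a fixed
golden-spiral point set; a sample point is occluded if it falls inside any
other atom's inflated sphere. The accessible area of the atom is the
exposed fraction of its inflated-sphere area, and residue ASA is the sum
over the residue's atoms. Two probe regimes are used downstream: 1.4 A
(water-sized, all-atom structures) and 3.5 A (coarse probe for
C-alpha-only models, where each residue is a single united sphere).

Relative accessibility is the residue ASA as a percentage of a
residue-type-specific reference maximum. The default all-atom reference is
the theoretical Gly-X-Gly maximum-ASA set of Tien et al. (2013); for the
C-alpha regime a reference is derived once from an extended C-alpha-trace
tripeptide (informational only — the coarse-regime interface criterion
works in absolute A^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import CA_UNITED_RADIUS, Structure

__all__ = [
    "SasaProfile",
    "MAX_ASA_ALLATOM",
    "calpha_reference_max",
    "sphere_points",
    "compute_sasa",
    "isolated_chain_sasa",
]

MIN_POINTS = 92
DEFAULT_POINTS = 960

# Theoretical maximum ASA (A^2) per residue type, probe 1.4 A, from the
# Gly-X-Gly tripeptide scale of Tien et al. 2013.
MAX_ASA_ALLATOM: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere point set, fixed orientation."""
    if n < MIN_POINTS:
        raise ValueError(f"n_points must be >= {MIN_POINTS}, got {n}")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


@dataclass
class SasaProfile:
    """Per-residue absolute ASA and relative accessibility for one structure.

    Keys are ``(chain_id, (seq_id, icode))``. ``rel_acc`` is NaN where the
    residue type has no reference maximum (e.g. UNK).
    """

    probe_radius: float
    n_points: int
    abs_asa: dict[tuple[str, tuple[int, str]], float]
    rel_acc: dict[tuple[str, tuple[int, str]], float]
    res_types: dict[tuple[str, tuple[int, str]], str]

    def residues_of(self, chain_id: str):
        return [k for k in self.abs_asa if k[0] == chain_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": cid, "seq_id": rid[0], "icode": rid[1],
                "res_type": self.res_types[(cid, rid)],
                "abs_asa": self.abs_asa[(cid, rid)],
                "rel_acc": self.rel_acc[(cid, rid)],
            }
            for (cid, rid) in self.abs_asa
        ]
        return pd.DataFrame(rows)


def _atom_table(structure: Structure):
    coords, radii, owner = [], [], []
    for chain, res, atom in structure.atoms():
        coords.append(atom.coord)
        radii.append(atom.radius)
        owner.append((chain.chain_id, res.res_id))
    if not coords:
        raise ValueError("structure has no atoms")
    return np.asarray(coords), np.asarray(radii), owner


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (A^2) by Shrake–Rupley quadrature."""
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if np.any(radii <= 0):
        raise ValueError("all atom radii must be positive")
    pts = sphere_points(n_points)
    n_atoms = len(coords)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    out = np.empty(n_atoms)
    r_max = inflated.max()
    for i in range(n_atoms):
        Ri = inflated[i]
        cand = tree.query_ball_point(coords[i], Ri + r_max)
        cand = [j for j in cand if j != i]
        if cand:
            cand = np.asarray(cand)
            keep = np.linalg.norm(coords[cand] - coords[i], axis=1) < Ri + inflated[cand]
            cand = cand[keep]
        if len(cand) == 0:
            out[i] = 4.0 * np.pi * Ri * Ri
            continue
        sample = coords[i] + Ri * pts  # (n_points, 3)
        d2 = ((sample[:, None, :] - coords[cand][None, :, :]) ** 2).sum(axis=2)
        occluded = (d2 < (inflated[cand] ** 2)[None, :]).any(axis=1)
        exposed_frac = 1.0 - occluded.mean()
        out[i] = exposed_frac * 4.0 * np.pi * Ri * Ri
    return out


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = DEFAULT_POINTS,
    reference: dict[str, float] | None = None,
) -> SasaProfile:
    """Residue-level SASA profile of *structure* under *probe_radius*.

    *reference* maps residue type to maximal ASA for the relative
    accessibility column; it defaults to the all-atom table for probe
    1.4 A and to the C-alpha-trace reference otherwise.
    """
    if reference is None:
        reference = (
            MAX_ASA_ALLATOM
            if abs(probe_radius - 1.4) < 1e-9
            else calpha_reference_max(probe_radius)
        )
    coords, radii, owner = _atom_table(structure)
    per_atom = atom_sasa(coords, radii, probe_radius, n_points)

    abs_asa: dict = {}
    res_types: dict = {}
    for (key, asa) in zip(owner, per_atom):
        abs_asa[key] = abs_asa.get(key, 0.0) + float(asa)
    for chain, res, _atom in structure.atoms():
        res_types[(chain.chain_id, res.res_id)] = res.res_type
    rel_acc = {
        key: (100.0 * v / reference[res_types[key]] if res_types[key] in reference else float("nan"))
        for key, v in abs_asa.items()
    }
    return SasaProfile(
        probe_radius=probe_radius,
        n_points=n_points,
        abs_asa=abs_asa,
        rel_acc=rel_acc,
        res_types=res_types,
    )


def isolated_chain_sasa(
    structure: Structure,
    chain_id: str,
    probe_radius: float = 1.4,
    n_points: int = DEFAULT_POINTS,
    reference: dict[str, float] | None = None,
) -> SasaProfile:
    """SASA of one chain extracted from the complex, coordinates unchanged."""
    return compute_sasa(
        structure.subset([chain_id]),
        probe_radius=probe_radius,
        n_points=n_points,
        reference=reference,
    )


@lru_cache(maxsize=4)
def calpha_reference_max(
    probe_radius: float = 3.5,
    ca_radius: float = CA_UNITED_RADIUS,
    n_points: int = DEFAULT_POINTS,
) -> dict[str, float]:
    """Reference maximum C-alpha ASA per residue type under the coarse probe.

    Computed from an extended (3.8 A spaced, collinear) three-residue
    C-alpha trace: the central sphere's ASA is the most a residue's
    C-alpha can expose inside a chain. In the united-sphere model the
    geometry is residue-type independent, so all twenty types share one
    value; the table is keyed per type for interface uniformity.
    """
    spacing = 3.8
    coords = np.array([[-spacing, 0, 0], [0, 0, 0], [spacing, 0, 0]], dtype=float)
    radii = np.full(3, ca_radius)
    central = float(atom_sasa(coords, radii, probe_radius, n_points)[1])
    return {res_type: central for res_type in MAX_ASA_ALLATOM}
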