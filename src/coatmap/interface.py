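"""Interface-residue detection in all-atom and C-alpha-only regimes.

A residue belongs to a protein-protein interface when it is buried in the
complex yet exposed once its chain is taken out of the complex. In the
all-atom regime (probe 1.4 A) the criterion is relative accessibility
< 7% in the complex AND > 10% in isolation, both strict. For
C-alpha-only models (probe 3.5 A) the same dual criterion is expressed as
residue-type-dependent absolute cutoffs on the C-alpha ASA; the cutoff
table is calibrated from all-atom training structures by a monotone
(isotonic) regression of C-alpha ASA on all-atom relative accessibility,
evaluated at 7% and 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sasa import SasaProfile, compute_sasa, isolated_chain_sasa
from .structures import STANDARD_RESIDUES, Structure, build_subcomplexes

__all__ = [
    "BURIED_PCT",
    "EXPOSED_PCT",
    "CutoffTable",
    "InterfaceSet",
    "detect_interface_allatom",
    "detect_interface_calpha",
    "fit_cutoff_table",
    "calibrate_calpha_cutoffs",
    "compare_interfaces",
    "detect_assembly_interfaces",
]

# Dual accessibility criterion (%): buried in complex, exposed in isolation.
BURIED_PCT = 7.0
EXPOSED_PCT = 10.0

POOLED_KEY = "__pooled__"


@dataclass
class CutoffTable:
    """Per-residue-type C-alpha ASA thresholds (A^2) for the coarse regime.

    ``buried_cutoff`` corresponds to 7% relative accessibility and
    ``exposed_cutoff`` to 10%; ``fallback`` marks types whose entry came
    from the pooled all-type fit for lack of per-type training data.
    """

    buried: dict[str, float]
    exposed: dict[str, float]
    n_train: dict[str, int] = field(default_factory=dict)
    fallback: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rt in self.buried:
            b, e = self.buried[rt], self.exposed[rt]
            if not (0 < b < e):
                raise ValueError(
                    f"cutoff table invalid for {rt}: buried {b} must be < exposed {e}, both > 0"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "res_type": rt,
                "buried_cutoff": self.buried[rt],
                "exposed_cutoff": self.exposed[rt],
                "n_train": self.n_train.get(rt, 0),
                "fallback": rt in self.fallback,
            }
            for rt in sorted(self.buried)
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CutoffTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            buried=dict(zip(df.res_type, df.buried_cutoff)),
            exposed=dict(zip(df.res_type, df.exposed_cutoff)),
            n_train=dict(zip(df.res_type, df.n_train.astype(int))),
            fallback=set(df.res_type[df.fallback.astype(bool)]),
        )


@dataclass
class InterfaceSet:
    """Interface residues per chain, with the detection context recorded."""

    structure_id: str
    regime: str  # "all-atom" | "calpha"
    residues: dict[str, set[tuple[int, str]]]
    excluded: dict[str, set[tuple[int, str]]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> set[tuple[int, str]]:
        return self.residues.get(chain_id, set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain": cid, "seq_id": rid[0], "icode": rid[1]}
            for cid, rids in sorted(self.residues.items())
            for rid in sorted(rids)
        ]
        return pd.DataFrame(rows, columns=["chain", "seq_id", "icode"])


def _classify_dual(
    complex_vals, isolated_vals, buried_threshold, exposed_threshold
) -> bool:
    return complex_vals < buried_threshold and isolated_vals > exposed_threshold


def detect_interface_allatom(
    complex_profile: SasaProfile,
    isolated_profiles: dict[str, SasaProfile],
    structure_id: str = "",
) -> InterfaceSet:
    """All-atom interface detection: relative accessibility < 7% in the
    complex and > 10% in the isolated chain (both strict).

    Residues whose type has no reference maximum (NaN relative
    accessibility) cannot be classified; they are excluded with a warning
    and reported in ``InterfaceSet.excluded``.
    """
    residues: dict[str, set] = {cid: set() for cid in isolated_profiles}
    excluded: dict[str, set] = {}
    for (cid, rid), rel_complex in complex_profile.rel_acc.items():
        if cid not in isolated_profiles:
            continue
        iso = isolated_profiles[cid]
        if (cid, rid) not in iso.rel_acc:
            raise KeyError(f"residue {rid} of chain {cid} missing from isolated profile")
        rel_iso = iso.rel_acc[(cid, rid)]
        if np.isnan(rel_complex) or np.isnan(rel_iso):
            excluded.setdefault(cid, set()).add(rid)
            continue
        if _classify_dual(rel_complex, rel_iso, BURIED_PCT, EXPOSED_PCT):
            residues[cid].add(rid)
    if excluded:
        n = sum(len(v) for v in excluded.values())
        warnings.warn(f"{n} residue(s) without reference area excluded from classification")
    return InterfaceSet(structure_id=structure_id, regime="all-atom",
                        residues=residues, excluded=excluded)


def detect_interface_calpha(
    complex_profile: SasaProfile,
    isolated_profiles: dict[str, SasaProfile],
    cutoffs: CutoffTable,
    structure_id: str = "",
) -> InterfaceSet:
    """Coarse-regime detection on C-alpha ASA (probe 3.5 A) with
    residue-type-dependent absolute cutoffs."""
    residues: dict[str, set] = {cid: set() for cid in isolated_profiles}
    excluded: dict[str, set] = {}
    for (cid, rid), asa_complex in complex_profile.abs_asa.items():
        if cid not in isolated_profiles:
            continue
        iso = isolated_profiles[cid]
        if (cid, rid) not in iso.abs_asa:
            raise KeyError(f"residue {rid} of chain {cid} missing from isolated profile")
        res_type = complex_profile.res_types[(cid, rid)]
        if res_type not in cutoffs.buried:
            excluded.setdefault(cid, set()).add(rid)
            continue
        if _classify_dual(
            asa_complex, iso.abs_asa[(cid, rid)],
            cutoffs.buried[res_type], cutoffs.exposed[res_type],
        ):
            residues[cid].add(rid)
    if excluded:
        n = sum(len(v) for v in excluded.values())
        warnings.warn(f"{n} residue(s) without cutoff entry excluded from classification")
    return InterfaceSet(structure_id=structure_id, regime="calpha",
                        residues=residues, excluded=excluded)


def fit_cutoff_table(
    pairs: dict[str, np.ndarray],
    min_train: int = 50,
) -> CutoffTable:
    """Fit the C-alpha cutoff table from (relative accessibility, C-alpha ASA)
    training pairs pooled per residue type.

    A monotone non-decreasing (isotonic) regression maps all-atom relative
    accessibility to expected C-alpha ASA; the cutoffs are its values at
    7% and 10%. Types with fewer than *min_train* pairs fall back to the
    pooled all-type fit and are flagged.
    """
    from sklearn.isotonic import IsotonicRegression

    clean = {rt: np.asarray(p, dtype=float).reshape(-1, 2) for rt, p in pairs.items()}
    if not clean or all(len(p) == 0 for p in clean.values()):
        raise ValueError("empty training set")

    def _fit_eval(arr: np.ndarray) -> tuple[float, float]:
        iso = IsotonicRegression(out_of_bounds="clip")
        iso.fit(arr[:, 0], arr[:, 1])
        b, e = iso.predict([BURIED_PCT, EXPOSED_PCT])
        return float(b), float(e)

    pooled_arr = np.vstack([p for p in clean.values() if len(p)])
    pooled_b, pooled_e = _fit_eval(pooled_arr)

    buried, exposed, n_train, fallback = {}, {}, {}, set()
    for rt in STANDARD_RESIDUES:
        arr = clean.get(rt, np.empty((0, 2)))
        n_train[rt] = len(arr)
        if len(arr) >= min_train:
            buried[rt], exposed[rt] = _fit_eval(arr)
        else:
            buried[rt], exposed[rt] = pooled_b, pooled_e
            fallback.add(rt)
        if not buried[rt] < exposed[rt]:  # flat fit: widen minimally
            mid = max(buried[rt], 1e-6)
            buried[rt], exposed[rt] = mid - 5e-7, mid + 5e-7
            fallback.add(rt)
    return CutoffTable(buried=buried, exposed=exposed, n_train=n_train, fallback=fallback)


def calibrate_calpha_cutoffs(
    training: list[Structure],
    probe_lowres: float = 3.5,
    probe_hires: float = 1.4,
    n_points: int = 960,
    min_train: int = 50,
) -> CutoffTable:
    """Calibrate C-alpha ASA cutoffs from all-atom training structures.

    For every residue of every training complex the pair (all-atom
    relative accessibility at *probe_hires*, C-alpha ASA at *probe_lowres*
    with the whole complex reduced to C-alpha traces) is collected; the
    pooled pairs per residue type are fed to :func:`fit_cutoff_table`.
    """
    if not training:
        raise ValueError("empty training set")
    pairs: dict[str, list] = {}
    for structure in training:
        if any(c.calpha_only for c in structure.chains):
            raise ValueError("training structures must be all-atom")
        hires = compute_sasa(structure, probe_radius=probe_hires, n_points=n_points)
        lowres = compute_sasa(structure.to_calpha(), probe_radius=probe_lowres,
                              n_points=n_points)
        for key, rel in hires.rel_acc.items():
            if np.isnan(rel):
                continue
            pairs.setdefault(hires.res_types[key], []).append(
                (rel, lowres.abs_asa[key])
            )
    return fit_cutoff_table(
        {rt: np.asarray(v) for rt, v in pairs.items()}, min_train=min_train
    )


def compare_interfaces(a: InterfaceSet, b: InterfaceSet) -> pd.DataFrame:
    """Per-chain overlap report between two interface sets: shared,
    only-a, only-b counts and Jaccard index over the common chains."""
    common = sorted(set(a.residues) & set(b.residues))
    if not common:
        raise ValueError("interface sets share no chain ids")
    rows = []
    for cid in common:
        sa, sb = a.chain(cid), b.chain(cid)
        union = sa | sb
        shared = sa & sb
        rows.append({
            "chain": cid,
            "shared": len(shared),
            "only_a": len(sa - sb),
            "only_b": len(sb - sa),
            "jaccard": (len(shared) / len(union)) if union else 1.0,
            "shared_residues": ",".join(f"{r[0]}{r[1]}" for r in sorted(shared)),
        })
    return pd.DataFrame(rows)


def detect_assembly_interfaces(
    structure: Structure,
    regime: str = "all-atom",
    cutoffs: CutoffTable | None = None,
    neighbor_cutoff: float = 5.0,
    probe_radius: float | None = None,
    n_points: int = 960,
) -> InterfaceSet:
    """Detect interfaces of a (possibly large) assembly chain by chain.

    The assembly is decomposed into per-chain subcomplexes (a chain plus
    its <=5 A near neighbors); each chain's interface is computed inside
    its own subcomplex, treated as an independent structure. This mirrors
    how coat-sized assemblies (18+ chains) are made tractable.
    """
    if regime not in ("all-atom", "calpha"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "calpha" and cutoffs is None:
        raise ValueError("calpha regime requires a cutoff table")
    probe = probe_radius if probe_radius is not None else (1.4 if regime == "all-atom" else 3.5)
    residues: dict[str, set] = {}
    excluded: dict[str, set] = {}
    for sub in build_subcomplexes(structure, cutoff=neighbor_cutoff):
        sub_struct = structure.subset(sub.members)
        complex_profile = compute_sasa(sub_struct, probe_radius=probe, n_points=n_points)
        iso = {
            sub.focal_chain: isolated_chain_sasa(
                sub_struct, sub.focal_chain, probe_radius=probe, n_points=n_points
            )
        }
        if regime == "all-atom":
            found = detect_interface_allatom(complex_profile, iso, structure.source_id)
        else:
            found = detect_interface_calpha(complex_profile, iso, cutoffs, structure.source_id)
        residues[sub.focal_chain] = found.chain(sub.focal_chain)
        if found.excluded.get(sub.focal_chain):
            excluded[sub.focal_chain] = found.excluded[sub.focal_chain]
    return InterfaceSet(structure_id=structure.source_id, regime=regime,
                        residues=residues, excluded=excluded)
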