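"""Genetic distance matrices, neighbor-joining trees and mirror-tree correlation.

Pairwise amino-acid distances are maximum-likelihood corrections of the
observed proportion of differing sites: Poisson (d = -ln(1-p)) or
Gamma-corrected (d = a((1-p)^(-1/a) - 1)) for rate heterogeneity with
shape a. Distances near saturation (p >= 0.95 by default) are capped at a
finite sentinel so downstream correlations stay defined. Correlated
evolution between two protein families is quantified as the Pearson
correlation between their species-by-species distance matrices over the
common species (upper triangles), with a label-permutation (Mantel-style)
significance test and support for designated unrelated-pair baselines.
Externally computed distance matrices (PHYLIP square format) and trees
(Newick) can be imported for real-data parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conservation import GAP_CHARS, Msa

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "MirrorResult",
    "pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "matrix_correlation",
    "correlation_significance",
    "mirror_batch",
]

P_MAX = 0.95
D_MAX = 10.0
MIN_COMMON_SPECIES = 4


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species genetic distances (substitutions/site)."""

    species: list[str]
    values: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match species count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def restrict(self, species: list[str]) -> "DistanceMatrix":
        idx = [self.species.index(s) for s in species]
        return DistanceMatrix(species=list(species),
                              values=self.values[np.ix_(idx, idx)])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.species), k=1)
        return self.values[iu]

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.species)}\n")
            for sp, row in zip(self.species, self.values):
                fh.write(sp + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        species, rows = [], []
        k = 1
        for _ in range(n):
            species.append(tokens[k])
            rows.append([float(t) for t in tokens[k + 1:k + 1 + n]])
            k += 1 + n
        return cls(species=species, values=np.asarray(rows))


@dataclass
class PhyloTree:
    """Unrooted tree over species labels with non-negative branch lengths."""

    newick: str
    clamped_negative: int = 0  # NJ branches clamped to zero
    tied_joins: int = 0        # joins decided by the deterministic tie-break

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 preserve_underscores=True)

    @property
    def leaf_labels(self) -> list[str]:
        tree = self.to_dendropy()
        return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    def path_distance_matrix(self) -> DistanceMatrix:
        tree = self.to_dendropy()
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in tree.taxon_namespace)
        taxa = {t.label: t for t in tree.taxon_namespace}
        n = len(labels)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                values[i, j] = values[j, i] = d
        return DistanceMatrix(species=labels, values=values)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick.rstrip() + "\n")

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls(newick=fh.read().strip())


def _comparable_columns(seq_a: str, seq_b: str) -> tuple[int, int]:
    comparable = differing = 0
    for a, b in zip(seq_a, seq_b):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a != b:
            differing += 1
    return comparable, differing


def pairwise_distance(
    seq_a: str,
    seq_b: str,
    model: str = "poisson",
    alpha: float | None = None,
    p_max: float = P_MAX,
    d_max: float = D_MAX,
) -> tuple[float, bool]:
    """ML-corrected distance between two aligned sequences.

    Returns ``(distance, saturated)``; *saturated* is true when the
    observed difference proportion reached *p_max* and the distance was
    capped at *d_max*.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    comparable, differing = _comparable_columns(seq_a, seq_b)
    if comparable == 0:
        raise ValueError("no comparable (non-gap in both) columns")
    p = differing / comparable
    if p >= p_max:
        return d_max, True
    if model == "poisson":
        return float(-np.log(1.0 - p)), False
    if model == "gamma":
        if alpha is None or alpha <= 0:
            raise ValueError("gamma model requires a positive shape alpha")
        return float(alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)), False
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(msa: Msa, model: str = "poisson", alpha: float | None = None) -> DistanceMatrix:
    """All pairwise corrected distances of an alignment."""
    n = msa.n_sequences
    values = np.zeros((n, n))
    saturated = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, sat = pairwise_distance(msa.sequences[i], msa.sequences[j],
                                           model=model, alpha=alpha)
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair ({msa.species[i]}, {msa.species[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
            if sat:
                saturated.add((msa.species[i], msa.species[j]))
    return DistanceMatrix(species=list(msa.species), values=values, saturated=saturated)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; exact
    ties go to the lexicographically lowest index pair. Negative branch
    lengths are clamped to zero and counted in ``clamped_negative``.
    """
    n = len(matrix.species)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes = [f"{sp}" for sp in matrix.species]  # newick fragments
    active = list(range(n))
    clamped = 0
    ties = 0

    def fmt(bl: float) -> str:
        nonlocal clamped
        if bl < 0:
            clamped += 1
            bl = 0.0
        return f"{bl:.6f}"

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        if len(cand) > 1:
            ties += 1
        ai, aj = min(cand)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (totals[ai] - totals[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        newick = f"({nodes[i]}:{fmt(bi)},{nodes[j]}:{fmt(bj)})"
        # distances from the new node to every other active node
        new_row = np.zeros(len(D) + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(newick)
        active = [a for a in active if a not in (i, j)] + [len(D) - 1]

    i, j = active
    newick = f"({nodes[i]}:0.000000,{nodes[j]}:{fmt(D[i, j])});"
    return PhyloTree(newick=newick, clamped_negative=clamped, tied_joins=ties)


@dataclass
class MirrorResult:
    family_a: str
    family_b: str
    common_species: int
    r: float
    p_value: float | None = None
    n_permutations: int | None = None

    def to_dict(self) -> dict:
        return {
            "family_a": self.family_a, "family_b": self.family_b,
            "common_species": self.common_species, "r": self.r,
            "p_value": self.p_value, "n_permutations": self.n_permutations,
        }


def _common_pair(a: DistanceMatrix, b: DistanceMatrix, min_species: int):
    common = [s for s in a.species if s in set(b.species)]
    if len(common) < min_species:
        raise ValueError(
            f"only {len(common)} common species; at least {min_species} required"
        )
    return a.restrict(common), b.restrict(common), common


def matrix_correlation(
    a: DistanceMatrix,
    b: DistanceMatrix,
    name_a: str = "a",
    name_b: str = "b",
    min_species: int = MIN_COMMON_SPECIES,
) -> MirrorResult:
    """Pearson correlation of the two matrices' upper triangles over
    their common species (species-order aligned)."""
    ra, rb, common = _common_pair(a, b, min_species)
    r = float(stats.pearsonr(ra.upper_triangle(), rb.upper_triangle()).statistic)
    return MirrorResult(family_a=name_a, family_b=name_b,
                        common_species=len(common), r=r)


def correlation_significance(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int = 0,
    min_species: int = MIN_COMMON_SPECIES,
) -> MirrorResult:
    """One-sided label-permutation test of the mirror correlation.

    Species labels of *b* are permuted (rows and columns together),
    the correlation recomputed, and p = (1 + #{r_perm >= r_obs}) /
    (1 + n_perm). One-sided because positive co-evolution is the
    hypothesis of interest.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    ra, rb, common = _common_pair(a, b, min_species)
    iu = np.triu_indices(len(common), k=1)
    va = ra.values[iu]
    r_obs = float(stats.pearsonr(va, rb.values[iu]).statistic)
    rng = np.random.default_rng(seed)
    n = len(common)
    count = 0
    va_c = va - va.mean()
    va_norm = np.sqrt((va_c ** 2).sum())
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb = rb.values[np.ix_(perm, perm)][iu]
        vb_c = vb - vb.mean()
        denom = va_norm * np.sqrt((vb_c ** 2).sum())
        r_perm = float(va_c @ vb_c / denom) if denom > 0 else 0.0
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MirrorResult(family_a="a", family_b="b", common_species=n,
                        r=r_obs, p_value=p, n_permutations=n_perm)


def mirror_batch(
    matrices: dict[str, DistanceMatrix],
    pairs: list[tuple[str, str]],
    baseline_pairs: list[tuple[str, str]] | None = None,
    n_perm: int | None = None,
    seed: int = 0,
    min_species: int = MIN_COMMON_SPECIES,
):
    """Mirror correlations for a list of family pairs plus designated
    unrelated baseline pairs; returns a tidy DataFrame."""
    import pandas as pd

    rows = []
    for kind, plist in (("pair", pairs), ("baseline", baseline_pairs or [])):
        for fa, fb in plist:
            res = matrix_correlation(matrices[fa], matrices[fb], fa, fb,
                                     min_species=min_species)
            p_value = None
            if n_perm:
                p_value = correlation_significance(
                    matrices[fa], matrices[fb], n_perm=n_perm, seed=seed,
                    min_species=min_species,
                ).p_value
            rows.append({"family_a": fa, "family_b": fb, "kind": kind,
                         "common_species": res.common_species,
                         "r": res.r, "p_value": p_value})
    return pd.DataFrame(rows)
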