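"""Orthologue filtering and interface-vs-surface conservation comparison.

Homologue hits are kept when they show more than 30% sequence identity to
the query and cover more than 70% of its length (both strict), the usual
PSI-BLAST-style selection for building orthologue alignments. Per-column
conservation is scored by sequence-weighted Shannon entropy, z-normalized
across positions, with the convention that the lowest score marks the
most conserved position (externally produced conservation grades with the
same convention can be imported instead). Surface residues of a chain are
partitioned into interface / non-interface surface-exposed / buried, and
the mean conservation of interface vs non-interface surface residues is
compared with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = "-."

IDENTITY_MIN_PCT = 30.0
COVERAGE_MIN_PCT = 70.0

__all__ = [
    "Msa",
    "ConservationProfile",
    "ConservationComparison",
    "PairwiseHit",
    "filter_homologs",
    "conservation_scores",
    "read_conservation_scores",
    "classify_surface",
    "compare_interface_conservation",
]


@dataclass
class Msa:
    """Gapped alignment over the 20 amino acids with unique species labels."""

    species: list[str]
    sequences: list[str]
    target: str | None = None  # species label of the structure-mapped sequence

    def __post_init__(self) -> None:
        if len(self.species) != len(self.sequences):
            raise ValueError("species and sequences must align")
        if len(self.species) < 3:
            raise ValueError("an alignment needs at least 3 sequences")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if self.target is not None and self.target not in self.species:
            raise ValueError(f"target {self.target!r} not among species")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def sequence(self, species: str) -> str:
        return self.sequences[self.species.index(species)]

    def target_sequence(self) -> str:
        if self.target is None:
            raise ValueError("no target designated")
        return self.sequence(self.target)

    @classmethod
    def from_fasta(cls, path, target: str | None = None) -> "Msa":
        from Bio import SeqIO

        species, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            species.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(species=species, sequences=seqs, target=target)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, seq in zip(self.species, self.sequences):
                fh.write(f">{sp}\n{seq}\n")


@dataclass
class PairwiseHit:
    """A candidate homologue with its pairwise alignment to the query.

    ``aligned_query`` and ``aligned_hit`` are equal-length gapped strings
    covering the aligned span (global or local alignment rows).
    """

    name: str
    aligned_query: str
    aligned_hit: str

    def identity_pct(self) -> float:
        """Identical pairs / aligned columns, gap-gap columns excluded."""
        pairs = [
            (q, h)
            for q, h in zip(self.aligned_query, self.aligned_hit)
            if not (q in GAP_CHARS and h in GAP_CHARS)
        ]
        if not pairs:
            return 0.0
        ident = sum(q == h and q not in GAP_CHARS for q, h in pairs)
        return 100.0 * ident / len(pairs)

    def coverage_pct(self, query_length: int) -> float:
        """Query positions inside the aligned span / full query length."""
        qpos = 0
        first = last = None
        for q, h in zip(self.aligned_query, self.aligned_hit):
            if q not in GAP_CHARS:
                qpos += 1
                if h not in GAP_CHARS:
                    if first is None:
                        first = qpos
                    last = qpos
        if first is None:
            return 0.0
        return 100.0 * (last - first + 1) / query_length


def _align_global(query: str, hit: str) -> PairwiseHit:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(query, hit)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseHit(name="", aligned_query=a, aligned_hit=b)


def filter_homologs(
    query: str,
    candidates: list[PairwiseHit | tuple[str, str]],
    identity_min: float = IDENTITY_MIN_PCT,
    coverage_min: float = COVERAGE_MIN_PCT,
    align_missing: bool = True,
) -> list[PairwiseHit]:
    """Keep hits with identity > *identity_min* % and coverage >
    *coverage_min* % of the query (strict inequalities).

    Candidates may be :class:`PairwiseHit` objects or ``(name, sequence)``
    tuples; the latter are globally aligned to the query internally when
    *align_missing* is true (error otherwise).
    """
    kept = []
    for cand in candidates:
        if isinstance(cand, PairwiseHit):
            hit = cand
        else:
            name, seq = cand
            if not align_missing:
                raise ValueError(f"candidate {name!r} has no alignment and internal alignment is disabled")
            hit = _align_global(query, seq)
            hit.name = name
        if hit.identity_pct() > identity_min and hit.coverage_pct(len(query)) > coverage_min:
            kept.append(hit)
    return kept


@dataclass
class ConservationProfile:
    """Per-target-position conservation scores, lowest = most conserved.

    ``score`` is the z-normalized weighted column entropy (mean 0, sd 1
    across scored positions; all-zero if every column is identical);
    ``raw_score`` is the entropy before normalization, comparable across
    alignments of the same depth. Positions are 1-based indices into the
    ungapped target sequence.
    """

    positions: np.ndarray        # 1-based target positions
    score: np.ndarray            # z-normalized, NaN where unscorable
    raw_score: np.ndarray
    n_effective: np.ndarray      # non-gap sequences per column
    gap_flagged: np.ndarray      # bool: column >50% gaps
    target: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "score": self.score,
            "raw_score": self.raw_score,
            "n_effective": self.n_effective,
            "gap_flagged": self.gap_flagged,
        })

    def score_of(self, position: int) -> float:
        idx = np.flatnonzero(self.positions == position)
        if idx.size == 0:
            raise KeyError(f"position {position} not scored")
        return float(self.score[idx[0]])


def _position_weights(columns: np.ndarray) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights.

    Each column contributes 1/(r*s) to the sequences showing one of its r
    distinct symbols s times; gaps count as a symbol for weighting.
    Weights are normalized to sum to 1.
    """
    n_seq, n_col = columns.shape
    weights = np.zeros(n_seq)
    for c in range(n_col):
        col = columns[:, c]
        symbols, counts = np.unique(col, return_counts=True)
        r = len(symbols)
        count_of = dict(zip(symbols.tolist(), counts.tolist()))
        for i in range(n_seq):
            weights[i] += 1.0 / (r * count_of[col[i]])
    total = weights.sum()
    if total <= 0:
        return np.full(n_seq, 1.0 / n_seq)
    return weights / total


def conservation_scores(msa: Msa, gap_flag_fraction: float = 0.5) -> ConservationProfile:
    """Sequence-weighted Shannon entropy per column covering the target,
    z-normalized across positions (lowest score = most conserved)."""
    target_seq = msa.target_sequence()
    cols = np.array([list(s) for s in msa.sequences])
    weights = _position_weights(cols)

    positions, raws, neffs, flags = [], [], [], []
    tpos = 0
    for c in range(msa.n_columns):
        t_char = target_seq[c]
        if t_char in GAP_CHARS:
            continue
        tpos += 1
        col = cols[:, c]
        non_gap = ~np.isin(col, list(GAP_CHARS))
        gap_fraction = 1.0 - non_gap.mean()
        if not non_gap.any():
            # cannot happen for a target-covered column (target is non-gap)
            continue
        freqs = np.zeros(20)
        for aa, w in zip(col[non_gap], weights[non_gap]):
            if aa in AA_INDEX:
                freqs[AA_INDEX[aa]] += w
        total = freqs.sum()
        if total <= 0:
            raw = np.nan
        else:
            p = freqs / total
            nz = p[p > 0]
            raw = float(-(nz * np.log(nz)).sum())
        positions.append(tpos)
        raws.append(raw)
        neffs.append(int(non_gap.sum()))
        flags.append(gap_fraction > gap_flag_fraction)

    raws_arr = np.asarray(raws, dtype=float)
    ok = np.isfinite(raws_arr)
    scores = np.full_like(raws_arr, np.nan)
    if ok.any():
        sd = raws_arr[ok].std()
        if sd < 1e-12:
            scores[ok] = 0.0  # constant profile convention
        else:
            scores[ok] = (raws_arr[ok] - raws_arr[ok].mean()) / sd
    return ConservationProfile(
        positions=np.asarray(positions, dtype=int),
        score=scores,
        raw_score=raws_arr,
        n_effective=np.asarray(neffs, dtype=int),
        gap_flagged=np.asarray(flags, dtype=bool),
        target=msa.target,
    )


def read_conservation_scores(path, target: str | None = None) -> ConservationProfile:
    """Import externally computed conservation grades (TSV with columns
    ``position`` and ``score``; same convention: lowest = most conserved)."""
    df = pd.read_csv(path, sep="\t")
    if not {"position", "score"} <= set(df.columns):
        raise ValueError("expected columns 'position' and 'score'")
    score = df["score"].to_numpy(dtype=float)
    raw = df["raw_score"].to_numpy(dtype=float) if "raw_score" in df else score.copy()
    n = len(df)
    return ConservationProfile(
        positions=df["position"].to_numpy(dtype=int),
        score=score,
        raw_score=raw,
        n_effective=df.get("n_effective", pd.Series(np.zeros(n))).to_numpy(dtype=int),
        gap_flagged=df.get("gap_flagged", pd.Series([False] * n)).to_numpy(dtype=bool),
        target=target,
    )


def classify_surface(profile, interface_set, chain_id: str) -> dict:
    """Partition one chain's residues into interface / non-interface
    surface-exposed / buried classes.

    *profile* is the isolated-chain SASA profile; a residue is surface
    exposed when its isolated relative accessibility exceeds 10%.
    Interface membership (from *interface_set*) takes precedence.
    """
    iface = interface_set.chain(chain_id)
    keys = profile.residues_of(chain_id)
    if not keys:
        raise ValueError(f"profile has no residues for chain {chain_id!r}")
    partition = {}
    for cid, rid in keys:
        if rid in iface:
            partition[rid] = "interface"
        else:
            rel = profile.rel_acc[(cid, rid)]
            if np.isfinite(rel) and rel > 10.0:
                partition[rid] = "surface"
            else:
                partition[rid] = "buried"
    return partition


@dataclass
class ConservationComparison:
    mean_interface: float
    mean_surface: float
    difference: float           # interface - surface; negative = interface more conserved
    ci_low: float
    ci_high: float
    n_interface: int
    n_surface: int

    def to_dict(self) -> dict:
        return {
            "mean_interface": self.mean_interface,
            "mean_surface": self.mean_surface,
            "difference": self.difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_interface": self.n_interface,
            "n_surface": self.n_surface,
        }


def compare_interface_conservation(
    profile: ConservationProfile,
    partition: dict,
    residue_positions: dict,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 95.0,
) -> ConservationComparison:
    """Mean conservation of interface vs non-interface surface residues.

    *residue_positions* maps residue ids to 1-based target positions.
    Gap-flagged positions are excluded from the group means. The
    difference (interface - surface) carries a bootstrap percentile CI;
    a negative difference means the interface is more conserved.
    """
    pos_index = {int(p): i for i, p in enumerate(profile.positions)}
    groups: dict[str, list[float]] = {"interface": [], "surface": []}
    for rid, cls in partition.items():
        if cls not in groups:
            continue
        pos = residue_positions.get(rid)
        if pos is None or pos not in pos_index:
            continue
        i = pos_index[pos]
        if profile.gap_flagged[i] or not np.isfinite(profile.score[i]):
            continue
        groups[cls].append(float(profile.score[i]))
    iface = np.asarray(groups["interface"])
    surf = np.asarray(groups["surface"])
    if iface.size == 0 or surf.size == 0:
        raise ValueError("both groups must be non-empty for the comparison")
    if iface.size == 1 or surf.size == 1:
        warnings.warn("a comparison group has a single residue; CI is degenerate-wide")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        diffs[b] = (
            rng.choice(iface, size=iface.size, replace=True).mean()
            - rng.choice(surf, size=surf.size, replace=True).mean()
        )
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(diffs, [alpha, 100.0 - alpha])
    return ConservationComparison(
        mean_interface=float(iface.mean()),
        mean_surface=float(surf.mean()),
        difference=float(iface.mean() - surf.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_interface=int(iface.size),
        n_surface=int(surf.size),
    )
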