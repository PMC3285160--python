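"""Homolog filtering, entropy conservation scores and group comparison."""

import numpy as np
import pytest

from coatmap.conservation import (
    ConservationProfile,
    Msa,
    PairwiseHit,
    compare_interface_conservation,
    classify_surface,
    conservation_scores,
    filter_homologs,
)
from coatmap.interface import InterfaceSet
from coatmap.sasa import SasaProfile
from coatmap.synthetic import EvolutionScenario, simulate_family


def hit_with(identity_pct, coverage_pct, query_len=100):
    """Construct a pairwise alignment with exact identity and coverage.

    Identity denominator is every aligned column that is not gap-gap
    (here: all query_len columns); coverage is the aligned span over the
    full query length.
    """
    span = int(round(coverage_pct / 100 * query_len))
    ident = int(round(identity_pct / 100 * query_len))
    assert ident <= span
    q = "A" * query_len
    h = "A" * ident + "G" * (span - ident) + "-" * (query_len - span)
    return PairwiseHit(name=f"hit{identity_pct}_{coverage_pct}",
                       aligned_query=q, aligned_hit=h)


class TestFilterHomologs:
    @pytest.mark.parametrize(
        "identity, coverage, kept",
        [
            (35.0, 80.0, True),
            (30.0, 90.0, False),  # strict >30%
            (50.0, 65.0, False),  # fails coverage
            (31.0, 70.0, False),  # strict >70%
        ],
    )
    def test_strict_identity_and_coverage_thresholds(self, identity, coverage, kept):
        query = "A" * 100
        result = filter_homologs(query, [hit_with(identity, coverage)])
        assert (len(result) == 1) is kept

    def test_idempotent_and_monotone_in_thresholds(self):
        query = "A" * 100
        hits = [hit_with(i, c) for i in (25, 35, 45, 60) for c in (60, 75, 90)]
        kept = filter_homologs(query, hits)
        assert filter_homologs(query, kept) == kept
        stricter = filter_homologs(query, hits, identity_min=40, coverage_min=80)
        assert set(h.name for h in stricter) <= set(h.name for h in kept)

    def test_unaligned_candidate_without_internal_alignment_errors(self):
        with pytest.raises(ValueError, match="alignment"):
            filter_homologs("AAAA", [("x", "AAAA")], align_missing=False)

    def test_internal_global_alignment_path(self):
        query = "MKVLITGAGSGIGL"
        kept = filter_homologs(query, [("close", "MKVLITGAGSGIGL"),
                                       ("far", "WWWWYYYYFFFFHH")])
        assert [h.name for h in kept] == ["close"]


class TestConservationScores:
    def msa(self, seqs, target="s1"):
        return Msa(species=[f"s{i+1}" for i in range(len(seqs))],
                   sequences=seqs, target=target)

    def test_identical_column_scores_below_diverse_column(self):
        seqs = ["AC", "AD", "AE", "AF", "AG", "AH"]
        profile = conservation_scores(self.msa(seqs))
        assert profile.score[0] < profile.score[1]

    def test_all_identical_alignment_gives_zero_scores(self):
        profile = conservation_scores(self.msa(["ACDE"] * 5))
        np.testing.assert_array_equal(profile.score, 0.0)
        np.testing.assert_array_equal(profile.raw_score, 0.0)

    def test_invariant_to_sequence_order_and_duplication(self):
        seqs = ["ACDEF", "ACDEG", "AWDEF", "ACKEF"]
        base = conservation_scores(self.msa(seqs))
        shuffled = Msa(species=["s4", "s2", "s3", "s1"],
                       sequences=[seqs[3], seqs[1], seqs[2], seqs[0]], target="s1")
        np.testing.assert_allclose(conservation_scores(shuffled).score, base.score,
                                   atol=1e-9)
        doubled = Msa(
            species=[f"s{i}" for i in range(8)],
            sequences=seqs + seqs, target="s0",
        )
        np.testing.assert_allclose(conservation_scores(doubled).score, base.score,
                                   atol=1e-9)

    def test_majority_gap_columns_flagged(self):
        seqs = ["AC", "A-", "A-", "A-"]
        profile = conservation_scores(self.msa(seqs))
        assert not profile.gap_flagged[0] and profile.gap_flagged[1]

    def test_simulated_slow_sites_score_lower(self):
        hits = 0
        for seed in range(20):
            scn = EvolutionScenario(
                n_taxa=16, n_sites=300,
                site_classes=[("slow", 0.2, 0.3), ("fast", 1.0, 0.7)], seed=seed,
            )
            fam = simulate_family(scn)
            profile = conservation_scores(fam.msa)
            slow = profile.score[fam.site_labels == "slow"]
            fast = profile.score[fam.site_labels == "fast"]
            hits += np.nanmean(slow) < np.nanmean(fast)
        assert hits >= 19

    def test_score_gap_monotone_in_rate_multiplier(self):
        gaps = []
        for mult in (0.2, 0.5, 0.8):
            per_seed = []
            for seed in range(10):
                scn = EvolutionScenario(
                    n_taxa=16, n_sites=300,
                    site_classes=[("slow", mult, 0.3), ("fast", 1.0, 0.7)], seed=seed,
                )
                fam = simulate_family(scn)
                profile = conservation_scores(fam.msa)
                per_seed.append(
                    np.nanmean(profile.score[fam.site_labels == "slow"])
                    - np.nanmean(profile.score[fam.site_labels == "fast"])
                )
            gaps.append(np.mean(per_seed))
        assert gaps[0] < gaps[1] < gaps[2] < 0


class TestClassifySurface:
    def profile(self, rel_by_seq):
        keys = {("A", (seq, "")): rel for seq, rel in rel_by_seq.items()}
        return SasaProfile(
            probe_radius=1.4, n_points=960,
            abs_asa={k: 50.0 for k in keys},
            rel_acc=dict(keys),
            res_types={k: "LEU" for k in keys},
        )

    def test_three_way_partition(self):
        profile = self.profile({1: 25.0, 2: 4.0, 3: 2.0})
        iface = InterfaceSet("x", "all-atom", {"A": {(3, "")}})
        partition = classify_surface(profile, iface, "A")
        assert partition == {(1, ""): "surface", (2, ""): "buried", (3, ""): "interface"}

    def test_interface_takes_precedence_over_accessibility(self):
        profile = self.profile({1: 45.0})
        iface = InterfaceSet("x", "all-atom", {"A": {(1, "")}})
        assert classify_surface(profile, iface, "A")[(1, "")] == "interface"


class TestCompareConservation:
    def build(self, iface_scores, surf_scores):
        n = len(iface_scores) + len(surf_scores)
        profile = ConservationProfile(
            positions=np.arange(1, n + 1),
            score=np.array(iface_scores + surf_scores, dtype=float),
            raw_score=np.zeros(n),
            n_effective=np.full(n, 10),
            gap_flagged=np.zeros(n, dtype=bool),
        )
        partition = {}
        positions = {}
        for i in range(n):
            rid = (i + 1, "")
            partition[rid] = "interface" if i < len(iface_scores) else "surface"
            positions[rid] = i + 1
        return profile, partition, positions

    def test_separated_groups_negative_difference_ci_excludes_zero(self):
        profile, partition, positions = self.build(
            [-1.4, -1.1, -1.2, -0.9], [0.4, 0.6, 0.8, 0.5, 0.7]
        )
        cmp = compare_interface_conservation(profile, partition, positions,
                                             n_boot=2000, seed=0)
        assert cmp.difference < 0
        assert cmp.ci_high < 0

    def test_null_groups_ci_contains_zero(self):
        rng = np.random.default_rng(5)
        pool = rng.normal(size=30)
        cmp = compare_interface_conservation(
            *self.build(pool[:12].tolist(), pool[12:].tolist()),
            n_boot=2000, seed=1,
        )
        assert cmp.ci_low < 0 < cmp.ci_high

    def test_single_member_group_warns_but_runs(self):
        profile, partition, positions = self.build([-1.0], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="single"):
            cmp = compare_interface_conservation(profile, partition, positions,
                                                 n_boot=500, seed=2)
        assert cmp.n_interface == 1

    def test_empty_group_is_an_error(self):
        profile, partition, positions = self.build([-1.0, -0.5], [0.1])
        partition = {k: "surface" for k in partition}
        with pytest.raises(ValueError, match="non-empty"):
            compare_interface_conservation(profile, partition, positions)
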