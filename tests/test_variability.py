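"""Consensus sequences, variability tables, ANOVA-Tukey, sliding windows."""

import math

import numpy as np
import pytest

from mtbarcode.distances import count_site_patterns, k2p_distance, p_distance
from mtbarcode.profiles import GeneProfile
from mtbarcode.variability import (
    anova_tukey,
    consensus_iupac,
    mean_interspecific,
    mean_intraspecific,
    n_windows,
    sliding_window,
    variability_table,
)


def _profile(entries):
    """entries: acc -> (seq, species, genus)."""
    return GeneProfile(
        "x",
        {a: seq for a, (seq, _, _) in entries.items()},
        {a: (sp, gen, "S") for a, (_, sp, gen) in entries.items()},
    )


class TestConsensus:
    def test_iupac_columns(self):
        prof = _profile({
            "a": ("AAGA", "sp1", "g"),
            "b": ("AGCA", "sp1", "g"),
            "c": ("AGTC", "sp1", "g"),
        })
        cons = consensus_iupac(prof, "sp1")
        # columns: {A}, {A,G}=R, {G,C,T}=B, {A,C}=M
        assert cons.sequence == "ARBM"
        assert cons.n_sources == 3

    def test_four_bases_give_n_and_gaps_stay(self):
        prof = _profile({
            "a": ("A-", "sp1", "g"),
            "b": ("C-", "sp1", "g"),
            "c": ("G-", "sp1", "g"),
            "d": ("T-", "sp1", "g"),
        })
        assert consensus_iupac(prof, "sp1").sequence == "N-"

    def test_singleton_species_rejected(self):
        prof = _profile({"a": ("ACGT", "sp1", "g"), "b": ("ACGT", "sp2", "g")})
        with pytest.raises(ValueError):
            consensus_iupac(prof, "sp1")


class TestMeans:
    def test_identical_pair_zero(self):
        prof = _profile({
            "a": ("ACGTACGT", "sp1", "g"),
            "b": ("ACGTACGT", "sp1", "g"),
        })
        assert mean_intraspecific(prof)["sp1"] == 0.0

    def test_three_sequence_mean_matches_recount(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=300)
        seqs = {}
        for i in range(3):
            s = base.copy()
            mask = rng.random(300) < 0.05
            s[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
            seqs[f"a{i}"] = "".join(s)
        prof = _profile({a: (s, "sp1", "g") for a, s in seqs.items()})
        got = mean_intraspecific(prof)["sp1"]
        vals = []
        accs = list(seqs)
        for i in range(3):
            for j in range(i + 1, 3):
                vals.append(
                    k2p_distance(count_site_patterns(seqs[accs[i]], seqs[accs[j]]))
                )
        assert got == pytest.approx(np.mean(vals))

    def test_interspecific_single_pair(self):
        rng = np.random.default_rng(1)
        base = rng.choice(list("ACGT"), size=500)
        other = base.copy()
        mask = rng.random(500) < 0.08
        other[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
        prof = _profile({
            "a": ("".join(base), "sp1", "g"),
            "b": ("".join(other), "sp2", "g"),
        })
        expected = k2p_distance(
            count_site_patterns("".join(base), "".join(other))
        )
        assert mean_interspecific(prof)["g"] == pytest.approx(expected)

    def test_zero_divergence_genus(self):
        prof = _profile({
            "a": ("ACGTACGT", "sp1", "g"),
            "b": ("ACGTACGT", "sp2", "g"),
        })
        assert mean_interspecific(prof)["g"] == 0.0

    def test_consensus_equals_plain_when_species_invariant(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), size=400))
        other = list(base)
        for i in range(0, 400, 25):
            other[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[other[i]]
        other = "".join(other)
        # sp1 has two identical members: consensus == member sequence.
        prof = _profile({
            "a1": (base, "sp1", "g"),
            "a2": (base, "sp1", "g"),
            "b": (other, "sp2", "g"),
        })
        direct = k2p_distance(count_site_patterns(base, other))
        assert mean_interspecific(prof)["g"] == pytest.approx(direct)

    def test_simulated_depth_recovery(self):
        """Table means recover realized tree depths within Monte-Carlo error.

        Uses a rate-homogeneous, transition-biased generating model: the K2P
        estimator is consistent for it, so the only slack needed covers
        substitution sampling noise and the mild unequal-frequency bias.
        (Under gamma + invariable-sites heterogeneity K2P systematically
        underestimates deep distances; that bias is a property of the
        estimator, not a defect of the table machinery.)
        """
        from mtbarcode.simulate import (
            SubstitutionModel, SyntheticConfig, simulate_dataset,
        )

        cfg = SyntheticConfig(
            n_genera=8, species_per_genus=2, seqs_per_species=2,
            gene_lengths={"ND5": 3000},
            model=SubstitutionModel(kappa=8.0, alpha=None, prop_invariable=0.0),
            seed=42,
        )
        ds = simulate_dataset(cfg)
        ingroup = [
            a for a in ds.profiles["ND5"].alignment
            if a not in ds.profiles.outgroup_accessions
        ]
        table = variability_table(ds.profiles["ND5"].subset(ingroup))
        intra_expected = np.mean(list(ds.truth["species_intra_depth"].values()))
        inter_expected = np.mean(list(ds.truth["genus_inter_depth"].values()))
        assert table.mean_intra == pytest.approx(intra_expected, rel=0.12)
        # A union-IUPAC consensus acts like the species' ancestral sequence,
        # so consensus-based interspecific distances estimate the
        # ancestor-to-ancestor path: the leaf path minus the two
        # within-species depths.
        assert table.mean_inter == pytest.approx(
            inter_expected - intra_expected, rel=0.12
        )
        assert table.mean_intra < table.mean_inter


class TestAnovaTukey:
    def test_three_group_hand_worked(self):
        groups = {"p1": [1.0, 2.0, 3.0], "p2": [2.0, 3.0, 4.0], "p3": [4.0, 5.0, 6.0]}
        f, p, tukey = anova_tukey(groups)
        # Hand-worked sums of squares: means 2, 3, 5; grand 10/3.
        means = [2.0, 3.0, 5.0]
        grand = np.mean([v for g in groups.values() for v in g])
        ss_between = 3 * sum((m - grand) ** 2 for m in means)
        ss_within = sum(
            (v - m) ** 2 for g, m in zip(groups.values(), means) for v in g
        )
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert f == pytest.approx(f_hand)
        assert not tukey.empty

    def test_identical_groups(self):
        groups = {"p1": [1.0, 2.0, 3.0], "p2": [1.0, 2.0, 3.0]}
        f, p, _ = anova_tukey(groups)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_equals_t_test(self):
        from scipy import stats

        g1 = [0.01, 0.02, 0.015, 0.03]
        g2 = [0.02, 0.025, 0.04]
        f, p, _ = anova_tukey({"a": g1, "b": g2})
        t, p_t = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t ** 2)
        assert p == pytest.approx(p_t)

    def test_degenerate_constant_everywhere(self):
        f, p, frame = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert math.isnan(f) and math.isnan(p)


class TestSlidingWindow:
    def _two_seq_profile(self, length=1200, n_diff=6):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), size=length)
        other = base.copy()
        idx = rng.choice(length, size=n_diff, replace=False)
        for i in idx:
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[i]]
        return _profile({
            "a": ("".join(base), "sp1", "g"),
            "b": ("".join(other), "sp1", "g"),
        })

    def test_pi_equals_p_distance_per_window(self):
        prof = self._two_seq_profile()
        wp = sliding_window(prof, "sp1", window=600, step=50)
        seq_a, seq_b = prof.alignment["a"], prof.alignment["b"]
        for mid, val in zip(wp.midpoints, wp.values):
            start = int(mid - 300)
            c = count_site_patterns(seq_a[start:start + 600], seq_b[start:start + 600])
            assert val == pytest.approx(p_distance(c))

    def test_window_count_formula(self):
        prof = self._two_seq_profile(length=11127 // 9)  # arbitrary odd size
        wp = sliding_window(prof, "sp1", window=600, step=5)
        assert len(wp.values) == n_windows(prof.length, 600, 5)
        assert n_windows(11127, 600, 5) == 2106

    def test_single_full_window_equals_whole_alignment(self):
        prof = self._two_seq_profile(length=900, n_diff=9)
        wp = sliding_window(prof, "sp1", window=900, step=10)
        whole = p_distance(
            count_site_patterns(prof.alignment["a"], prof.alignment["b"])
        )
        assert len(wp.values) == 1
        assert wp.values[0] == pytest.approx(whole)

    def test_window_mean_near_whole_alignment_for_constant_rate(self):
        prof = self._two_seq_profile(length=6000, n_diff=60)
        wp = sliding_window(prof, "sp1", window=600, step=5)
        whole = p_distance(
            count_site_patterns(prof.alignment["a"], prof.alignment["b"])
        )
        assert np.nanmean(wp.values) == pytest.approx(whole, rel=0.25)

    def test_dxy_between_species(self):
        rng = np.random.default_rng(4)
        base = rng.choice(list("ACGT"), size=800)
        o1, o2 = base.copy(), base.copy()
        o2[::40] = "A"
        prof = _profile({
            "a": ("".join(base), "sp1", "g"),
            "b": ("".join(o1), "sp1", "g"),
            "c": ("".join(o2), "sp2", "g"),
        })
        wp = sliding_window(prof, ("sp1", "sp2"), window=400, step=100)
        assert wp.statistic == "dxy"
        assert (wp.values >= 0).all()

    def test_window_larger_than_alignment_rejected(self):
        prof = self._two_seq_profile(length=500)
        with pytest.raises(ValueError):
            sliding_window(prof, "sp1", window=600, step=5)

    def test_gappy_windows_missing_not_zero(self):
        gap_block = "-" * 500 + "ACGT" * 100
        prof = _profile({
            "a": (gap_block, "sp1", "g"),
            "b": ("ACGT" * 225, "sp1", "g"),
        })
        wp = sliding_window(prof, "sp1", window=400, step=50)
        assert np.isnan(wp.values[0])  # first window mostly gap in 'a'
        assert not np.isnan(wp.values[-1])
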