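"""Likelihoods, model selection, GC content, saturation profiling."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from mtbarcode.distances import count_site_patterns, percent_ti
from mtbarcode.model_fit import (
    ModelFit,
    _build_q,
    discrete_gamma_rates,
    fit_model,
    gc_content,
    saturation_profile,
    tree_likelihood,
)
from mtbarcode.profiles import GeneProfile
from mtbarcode.trees import PhyloTree

TAX = ("sp", "gen", "so")


def _profile(seqs):
    return GeneProfile("x", dict(seqs), {a: TAX for a in seqs})


def brute_force_lnl(tree_spec, seqs, freqs, rates, rate_multiplier=1.0):
    """Enumeration oracle: sums over all internal-node states explicitly.

    ``tree_spec`` is a nested tuple ``(children...)`` with leaves as
    (name, branch_length) and internal nodes as ((spec...), branch_length).
    """
    Q = _build_q(np.asarray(freqs), np.asarray(rates))

    def node_partial(spec):
        children, _ = spec
        if isinstance(children, str):  # leaf
            from mtbarcode._seqcodes import encode

            return [encode(seqs[children])]
        return None

    from mtbarcode._seqcodes import encode

    enc = {name: encode(s) for name, s in seqs.items()}
    length = len(next(iter(seqs.values())))

    def site_lik(spec, site, state):
        children, _ = spec
        if isinstance(children, str):
            return 1.0 if enc[children][site] == state else 0.0
        total = 1.0
        for child_spec in children:
            _, t = child_spec
            P = expm(Q * t * rate_multiplier)
            total *= sum(
                P[state, x] * site_lik(child_spec, site, x) for x in range(4)
            )
        return total

    lnl = 0.0
    for site in range(length):
        lik = sum(
            freqs[r] * site_lik(tree_spec, site, r) for r in range(4)
        )
        lnl += math.log(lik)
    return lnl


class TestTreeLikelihood:
    def test_jc_two_leaf_closed_form(self):
        t = 0.25
        tree = PhyloTree.from_newick(f"(a:{t},b:0.0);")
        prof = _profile({"a": "A", "b": "A"})
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
        assert tree_likelihood(prof, tree) == pytest.approx(expected, abs=1e-12)
        prof2 = _profile({"a": "A", "b": "G"})
        expected2 = math.log(0.25 * 0.25 * (1 - math.exp(-4 * t / 3)))
        assert tree_likelihood(prof2, tree) == pytest.approx(expected2, abs=1e-12)

    def test_zero_length_identical_limit(self):
        tree = PhyloTree.from_newick("(a:0.0,b:0.0);")
        seq = "ACGTACGTAC"
        prof = _profile({"a": seq, "b": seq})
        assert tree_likelihood(prof, tree) == pytest.approx(
            len(seq) * math.log(0.25)
        )

    def test_five_taxon_gtr_matches_enumeration(self):
        rng = np.random.default_rng(0)
        seqs = {l: "".join(rng.choice(list("ACGT"), size=20)) for l in "abcde"}
        tree = PhyloTree.from_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.08):0.12,e:0.3);"
        )
        freqs = np.array([0.3, 0.25, 0.15, 0.3])
        rates = np.array([1.2, 4.0, 0.8, 1.1, 5.0, 1.0])
        spec = (
            (
                ((("a", 0.1), ("b", 0.2)), 0.05),
                ((("c", 0.15), ("d", 0.08)), 0.12),
                ("e", 0.3),
            ),
            None,
        )
        oracle = brute_force_lnl(spec, seqs, freqs, rates)
        got = tree_likelihood(_profile(seqs), tree, freqs=freqs, rates=rates)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_gamma_mixture_matches_enumeration(self):
        rng = np.random.default_rng(1)
        seqs = {l: "".join(rng.choice(list("ACGT"), size=12)) for l in "abc"}
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.15);")
        freqs = np.full(4, 0.25)
        rates = np.ones(6)
        spec = ((("a", 0.1), ("b", 0.2), ("c", 0.15)), None)
        cat = discrete_gamma_rates(0.5, 4)
        # Mixture oracle: average the per-category enumeration likelihoods
        # site by site.
        from mtbarcode._seqcodes import encode

        per_cat = []
        for r in cat:
            lnl_sites = []
            Q = _build_q(freqs, rates)
            for site in range(12):
                P = {t: expm(Q * t * r) for t in (0.1, 0.2, 0.15)}
                lik = sum(
                    freqs[x]
                    * P[0.1][x, encode(seqs["a"])[site]]
                    * P[0.2][x, encode(seqs["b"])[site]]
                    * P[0.15][x, encode(seqs["c"])[site]]
                    for x in range(4)
                )
                lnl_sites.append(lik)
            per_cat.append(lnl_sites)
        mix = np.mean(np.array(per_cat), axis=0)
        oracle = float(np.log(mix).sum())
        got = tree_likelihood(_profile(seqs), tree, alpha=0.5)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_invariable_zero_equals_base_model(self):
        rng = np.random.default_rng(2)
        seqs = {l: "".join(rng.choice(list("ACGT"), size=50)) for l in "abcd"}
        tree = PhyloTree.from_newick("((a:0.1,b:0.2):0.1,c:0.15,d:0.3);")
        prof = _profile(seqs)
        base = tree_likelihood(prof, tree, kappa=3.0)
        with_i0 = tree_likelihood(prof, tree, kappa=3.0, prop_invariable=0.0)
        assert with_i0 == pytest.approx(base, abs=1e-12)

    def test_large_alpha_approaches_homogeneous(self):
        rng = np.random.default_rng(3)
        seqs = {l: "".join(rng.choice(list("ACGT"), size=60)) for l in "abc"}
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.15);")
        prof = _profile(seqs)
        base = tree_likelihood(prof, tree)
        near = tree_likelihood(prof, tree, alpha=500.0)
        assert near == pytest.approx(base, abs=1e-3)

    def test_negative_branch_lengths_clamped(self):
        tree = PhyloTree.from_newick("(a:-0.05,b:0.1,c:0.1);")
        prof = _profile({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        zero = PhyloTree.from_newick("(a:0.0,b:0.1,c:0.1);")
        assert tree_likelihood(prof, tree) == pytest.approx(
            tree_likelihood(prof, zero)
        )


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0, 50.0])
    def test_category_rates_mean_one(self, alpha):
        rates = discrete_gamma_rates(alpha)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(rates) > 0).all()


class TestGC:
    def test_trivial_compositions(self):
        assert gc_content(_profile({"a": "GGCC"})) == 1.0
        assert gc_content(_profile({"a": "AATT"})) == 0.0
        assert gc_content(_profile({"a": "ACGT", "b": "A-GN"})) == pytest.approx(3 / 6)

    def test_simulation_recovery(self, tiny_locus_dataset):
        prof = tiny_locus_dataset.profiles["locus"]
        freqs = tiny_locus_dataset.config.model.freqs
        expected = freqs[1] + freqs[2]
        assert gc_content(prof) == pytest.approx(expected, abs=0.02)


class TestFitAndSelect:
    def test_kappa_recovery_k80(self):
        from mtbarcode.distances import build_distance_matrix
        from mtbarcode.simulate import (
            SubstitutionModel, SyntheticConfig, simulate_dataset,
        )
        from mtbarcode.trees import neighbor_joining, root_with_outgroup

        cfg = SyntheticConfig(
            n_genera=5, species_per_genus=1, seqs_per_species=2,
            gene_lengths={"locus": 3000},
            model=SubstitutionModel(
                freqs=(0.25, 0.25, 0.25, 0.25), kappa=4.0,
                alpha=None, prop_invariable=0.0,
            ),
            seed=9,
        )
        ds = simulate_dataset(cfg)
        prof = ds.profiles["locus"]
        dm = build_distance_matrix(prof, "k2p")
        tree = root_with_outgroup(
            neighbor_joining(dm), ds.profiles.outgroup_accessions
        )
        fit = fit_model(prof, tree, "K80", n_starts=1)
        assert fit.kappa == pytest.approx(4.0, abs=0.8)

    def test_all_variable_sites_give_near_zero_i(self):
        from mtbarcode.distances import build_distance_matrix
        from mtbarcode.simulate import (
            SubstitutionModel, SyntheticConfig, simulate_dataset,
        )
        from mtbarcode.trees import neighbor_joining, root_with_outgroup

        cfg = SyntheticConfig(
            n_genera=5, species_per_genus=1, seqs_per_species=2,
            gene_lengths={"locus": 2000},
            model=SubstitutionModel(
                freqs=(0.25, 0.25, 0.25, 0.25), kappa=4.0,
                alpha=None, prop_invariable=0.0,
            ),
            seed=10,
        )
        ds = simulate_dataset(cfg)
        prof = ds.profiles["locus"]
        dm = build_distance_matrix(prof, "k2p")
        tree = root_with_outgroup(
            neighbor_joining(dm), ds.profiles.outgroup_accessions
        )
        fit = fit_model(prof, tree, "K80+I", n_starts=1)
        assert fit.prop_invariable < 0.12

    def test_bic_tie_prefers_fewer_parameters(self):
        a = ModelFit("JC69", -100.0, np.full(4, 0.25), np.ones(6),
                     k_free=1, n_sites=100)
        b = ModelFit("GTR", -100.0, np.full(4, 0.25), np.ones(6),
                     k_free=9, n_sites=100)
        assert a.bic < b.bic
        assert a.bic == pytest.approx(200.0 + 1 * math.log(100))


class TestSaturation:
    def test_single_pair_point(self):
        seqs = {"a": "A" * 100, "b": "G" * 2 + "A" * 98}
        series = saturation_profile(_profile(seqs))
        assert len(series.pairs) == 1
        d, ti = series.pairs[0]
        c = count_site_patterns(seqs["a"], seqs["b"])
        assert ti == 1.0
        assert d == pytest.approx(-0.5 * math.log(1 - 2 * 0.02) - 0.0)

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(4)
        seqs = {"a": "ACGT" * 25}
        seqs["b"] = seqs["a"]  # zero-distance pair
        seqs["c"] = "".join(rng.choice(list("ACGT"), size=100))
        seqs["d"] = "".join(rng.choice(list("ACGT"), size=100))
        series = saturation_profile(_profile(seqs))
        n = 4
        assert (
            len(series.pairs)
            + series.excluded_zero_pairs
            + series.excluded_undefined_pairs
            == n * (n - 1) // 2
        )
        assert series.excluded_zero_pairs >= 1

    def test_transition_bias_decays_with_distance(self, small_dataset):
        """Ti-biased evolution saturates: mean %Ti falls from shallow to deep
        distance bins (the hallmark saturation pattern)."""
        genome = None
        from mtbarcode.profiles import build_genome_profile

        genome = build_genome_profile(small_dataset.profiles)
        series = saturation_profile(genome)
        df = series.to_frame()
        shallow = df[df.k2p < 0.05]["percent_ti"]
        deep = df[df.k2p > 0.2]["percent_ti"]
        assert len(shallow) and len(deep)
        assert shallow.mean() > deep.mean() + 0.05
        # At low divergence %Ti matches the instantaneous transition flux
        # fraction of the generating model.
        model = small_dataset.config.model
        Q = _build_q(np.asarray(model.freqs), model.exchangeabilities())
        pi = np.asarray(model.freqs)
        flux = pi[:, None] * Q
        ti_flux = flux[0, 2] + flux[2, 0] + flux[1, 3] + flux[3, 1]
        total = flux.sum() - np.trace(flux)
        assert shallow.mean() == pytest.approx(ti_flux / total, abs=0.05)
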