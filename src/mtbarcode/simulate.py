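"""Synthetic multi-gene, taxonomy-structured datasets with known ground truth.

The generator emulates the statistical structure of a multi-genome
mitochondrial dataset: ~35 genera in four super-orders, species sampled with
multiple conspecific sequences, intraspecific divergence around 1.5% and
congeneric interspecific divergence around 8%, transition-biased
substitution with gamma rate heterogeneity and invariable sites, and
optional introgression events that break species monophyly.

Depths are expressed as expected *pairwise* divergence in substitutions per
site, so configured values are directly comparable to pipeline distance
output (coalescence node heights are depth/2 on the ultrametric scaffold).
All 12 simulated genes share one genealogy, mirroring maternally inherited,
non-recombining mtDNA: lineage-sorting failures hit every gene identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seqcodes import BASES, MITO_STOPS, encode
from .profiles import PCG_GENES, GeneProfile, ProfileSet
from .trees import Node, PhyloTree, is_monophyletic

__all__ = [
    "SubstitutionModel",
    "IntrogressionEvent",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_species_system",
    "evolve_sequences",
    "apply_introgression",
    "simulate_dataset",
    "DEFAULT_GENE_LENGTHS",
]

#: Per-gene alignment lengths (bp) of the 14-profile study design; the 12
#: genes sum to the 11,127 bp concatenated genome profile.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ATP6": 705, "ATP8": 216, "CO1": 1554, "CO2": 693, "CO3": 834,
    "CytB": 1143, "ND1": 966, "ND2": 1062, "ND3": 363, "ND4": 1431,
    "ND4L": 294, "ND5": 1866,
}


@dataclass
class SubstitutionModel:
    """Time-reversible substitution model parameters for simulation.

    ``rates`` are the six GTR exchangeabilities in (AC, AG, AT, CG, CT, GT)
    order; ``kappa`` (when not None) overrides them with the HKY pattern
    (AG = CT = kappa, others 1).  ``alpha`` is the gamma shape for among-site
    rate variation (None disables it) and ``prop_invariable`` the invariable
    fraction.  ``gamma_categories`` draws site rates from the discrete
    (mean-of-quartile) gamma representation with that many categories — the
    same representation the likelihood machinery fits — or from the
    continuous gamma when None.  Defaults give a transition-biased,
    mammal-mtDNA-flavoured model (GC ~ 0.39).
    """

    freqs: tuple[float, float, float, float] = (0.33, 0.26, 0.13, 0.28)
    kappa: float | None = 8.0
    rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: float | None = 0.5
    prop_invariable: float = 0.2
    gamma_categories: int | None = 4

    def exchangeabilities(self) -> np.ndarray:
        if self.kappa is not None:
            return np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        return np.asarray(self.rates, dtype=float)

    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalised to one expected substitution per unit time."""
        pi = np.asarray(self.freqs, dtype=float)
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        s = self.exchangeabilities()
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(s, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu


@dataclass
class IntrogressionEvent:
    """Transfer of mitochondrial lineages between (usually congeneric) species.

    ``fraction`` of the recipient's sequences are re-simulated from inside
    the donor's clade; with fraction 1.0 the recipient nests entirely within
    the donor, leaving the donor paraphyletic and the recipient monophyletic.
    """

    donor: str
    recipient: str
    fraction: float = 1.0


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic dataset generator.

    ``species_per_genus`` and ``seqs_per_species`` accept an int or an
    inclusive (low, high) range sampled uniformly.  Depths are expected
    pairwise divergences (substitutions/site): within species
    (``intra_depth``), between congeneric species (``inter_depth``), and
    between genera/super-orders (``deep_depth``).
    """

    n_genera: int = 35
    species_per_genus: int | tuple[int, int] = (1, 3)
    seqs_per_species: int | tuple[int, int] = (1, 4)
    intra_depth: float = 0.015
    inter_depth: float = 0.08
    deep_depth: float = 0.30
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    model: SubstitutionModel = field(default_factory=SubstitutionModel)
    introgression_events: list[IntrogressionEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (self.intra_depth < self.inter_depth < self.deep_depth):
            raise ValueError("depths must satisfy intra < inter < deep")


@dataclass
class SyntheticDataset:
    """Simulated profiles plus the ground truth they were generated from."""

    profiles: ProfileSet
    true_tree: PhyloTree
    taxonomy: dict[str, tuple[str, str, str]]
    truth: dict
    config: SyntheticConfig


def _count(spec, rng) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _jitter(rng) -> float:
    # Mean-1 shifted-exponential multiplier; keeps heights positive with
    # moderate spread so the intra < inter < deep hierarchy survives.
    return 0.7 + rng.exponential(0.3)


def generate_species_system(config: SyntheticConfig, rng=None):
    """Rooted ultrametric-with-jitter genealogy plus taxonomy labels.

    Super-orders split deepest, genera within them, congeneric species at
    ``inter_depth``/2, and conspecific lineages coalesce at
    ``intra_depth``/2 (heights multiplied by exponential jitter, clamped to
    preserve the hierarchy).  Two outgroup lineages attach basally.

    Returns ``(tree, taxonomy)`` with node heights annotated on the tree.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    h_deep = config.deep_depth / 2.0

    taxonomy: dict[str, tuple[str, str, str]] = {}
    acc_counter = [0]

    def new_leaf(species, genus, superorder):
        acc_counter[0] += 1
        acc = f"SYN{acc_counter[0]:04d}"
        taxonomy[acc] = (species, genus, superorder)
        leaf = Node(acc)
        leaf.height = 0.0
        return leaf

    def join_at(nodes, heights):
        """Successive random coalescence of subtrees at sorted heights."""
        nodes = list(nodes)
        heights = sorted(heights)
        for h in heights:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            h = max(h, nodes[i].height, nodes[j].height)
            parent = Node(children=[nodes[i], nodes[j]])
            parent.height = h
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        return nodes[0]

    superorder_roots = []
    genus_id = 0
    for so_index in range(4):
        superorder = (
            "Laurasiatheria", "Euarchontoglires", "Xenarthra", "Afrotheria"
        )[so_index]
        n_gen = config.n_genera // 4 + (1 if so_index < config.n_genera % 4 else 0)
        genus_nodes = []
        for _ in range(n_gen):
            genus_id += 1
            genus = f"Genus{genus_id:02d}"
            n_sp = _count(config.species_per_genus, rng)
            species_nodes = []
            h_gen = min(config.inter_depth / 2.0 * _jitter(rng), 0.5 * h_deep)
            for s in range(n_sp):
                species = f"{genus} sp{s + 1}"
                n_seq = _count(config.seqs_per_species, rng)
                h_sp = min(config.intra_depth / 2.0 * _jitter(rng), 0.8 * h_gen)
                leaves = [
                    new_leaf(species, genus, superorder) for _ in range(n_seq)
                ]
                if len(leaves) == 1:
                    node = leaves[0]
                else:
                    node = Node(children=leaves)
                    node.height = h_sp
                species_nodes.append(node)
            if len(species_nodes) == 1:
                genus_nodes.append(species_nodes[0])
            else:
                heights = [h_gen] + [
                    min(config.inter_depth / 2.0 * _jitter(rng), 0.5 * h_deep)
                    for _ in range(len(species_nodes) - 2)
                ]
                genus_nodes.append(join_at(species_nodes, heights))
        if not genus_nodes:
            continue
        if len(genus_nodes) == 1:
            superorder_roots.append(genus_nodes[0])
        else:
            heights = h_deep * rng.uniform(0.55, 0.9, size=len(genus_nodes) - 1)
            superorder_roots.append(join_at(genus_nodes, heights))

    if len(superorder_roots) == 1:
        ingroup = superorder_roots[0]
    else:
        ingroup = join_at(
            superorder_roots,
            h_deep * rng.uniform(0.95, 1.15, size=len(superorder_roots) - 1),
        )
    og1 = new_leaf("Outgroup sp1", "OutgroupGenus1", "Outgroup")
    og2 = new_leaf("Outgroup sp2", "OutgroupGenus2", "Outgroup")
    og = Node(children=[og1, og2])
    og.height = h_deep * 0.9
    root = Node(children=[ingroup, og])
    root.height = max(1.4 * h_deep, ingroup.height * 1.1)

    tree = PhyloTree(root, rooted=True)
    _heights_to_lengths(tree)
    return tree, taxonomy


def _heights_to_lengths(tree: PhyloTree) -> None:
    for node in tree.root.preorder():
        if node.parent is None:
            node.length = None
        else:
            node.length = max(node.parent.height - node.height, 1e-9)


def _sample_states(probs: np.ndarray, rng) -> np.ndarray:
    """Vectorised categorical draw; ``probs`` is (L, 4) row-stochastic."""
    u = rng.random(probs.shape[0])
    cum = probs.cumsum(axis=1)
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


def _find_stops(states: np.ndarray) -> np.ndarray:
    """Indices of codon starts whose codon is a mito stop."""
    stops = {tuple(encode(c)) for c in MITO_STOPS}
    codons = states.reshape(-1, 3)
    mask = np.zeros(codons.shape[0], dtype=bool)
    for s in stops:
        mask |= (codons == np.array(s)).all(axis=1)
    return np.nonzero(mask)[0]


def evolve_sequences(true_tree: PhyloTree, gene_lengths: dict[str, int],
                     model: SubstitutionModel, rng=None,
                     seed: int = 0) -> ProfileSet:
    """Simulate aligned sequences for each gene along the genealogy.

    Per gene, the root sequence is drawn from the model's base frequencies
    and each branch evolves sites under the continuous-time model with
    per-site gamma rate multipliers and an invariable fraction.  Genes named
    after the 12 protein-coding genes are kept stop-free (vertebrate
    mitochondrial stops rejected at the root and resampled during
    evolution), so alignment-finalisation checks stay meaningful.  There are
    no indels: alignment is by construction.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    pi = np.asarray(model.freqs)
    Q = model.q_matrix()
    # Reversible Q: symmetrise for a real eigendecomposition.
    sq = np.sqrt(pi)
    S = (Q * sq[:, None]) / sq[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    U = V / sq[:, None]        # rows scale
    Uinv = V.T * sq[None, :]

    def transition_probs(parent_states, t_times_r):
        """Row of P(t*r) for each site's parent state; (L, 4)."""
        E = np.exp(np.outer(t_times_r, lam))        # (L, 4)
        probs = (U[parent_states] * E) @ Uinv       # (L, 4)
        probs = np.clip(probs, 0.0, None)
        return probs / probs.sum(axis=1, keepdims=True)

    profiles: dict[str, GeneProfile] = {}
    taxonomy = getattr(true_tree, "_taxonomy", None)

    for gene, L in gene_lengths.items():
        coding = gene in PCG_GENES
        if coding and L % 3:
            raise ValueError(f"{gene}: coding length {L} not divisible by 3")
        # Site rates: invariable fraction at rate 0, the rest gamma.
        rates = np.ones(L)
        if model.prop_invariable > 0:
            rates[rng.random(L) < model.prop_invariable] = 0.0
        if model.alpha is not None:
            variable = rates > 0
            nv = int(variable.sum())
            if model.gamma_categories:
                from .model_fit import discrete_gamma_rates

                cat = discrete_gamma_rates(model.alpha, model.gamma_categories)
                rates[variable] = cat[rng.integers(len(cat), size=nv)]
            else:
                rates[variable] = rng.gamma(model.alpha, 1.0 / model.alpha, size=nv)

        root_states = _sample_states(np.tile(pi, (L, 1)), rng)
        if coding:
            for _ in range(100):
                bad = _find_stops(root_states)
                if not len(bad):
                    break
                for b in bad:
                    sl = slice(3 * b, 3 * b + 3)
                    root_states[sl] = _sample_states(np.tile(pi, (3, 1)), rng)

        states: dict[Node, np.ndarray] = {true_tree.root: root_states}
        for node in true_tree.root.preorder():
            if node.parent is None:
                continue
            parent_states = states[node.parent]
            t = max(node.length or 0.0, 0.0)
            child = _sample_states(
                transition_probs(parent_states, t * rates), rng
            ) if t > 0 else parent_states.copy()
            if coding and t > 0:
                # Resample codons that evolved into a stop; give up after a
                # few rounds and revert those codons to the parent state.
                for _ in range(50):
                    bad = _find_stops(child)
                    if not len(bad):
                        break
                    for b in bad:
                        sl = slice(3 * b, 3 * b + 3)
                        child[sl] = _sample_states(
                            transition_probs(parent_states[sl], t * rates[sl]),
                            rng,
                        )
                else:
                    for b in _find_stops(child):
                        sl = slice(3 * b, 3 * b + 3)
                        child[sl] = parent_states[sl]
            states[node] = child

        base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
        alignment = {
            leaf.label: base_arr[states[leaf]].tobytes().decode()
            for leaf in true_tree.leaves()
        }
        profiles[gene] = GeneProfile(
            gene,
            alignment,
            {a: taxonomy[a] for a in alignment} if taxonomy else {},
        )

    outgroup = set()
    if taxonomy:
        outgroup = {a for a, t in taxonomy.items() if t[2] == "Outgroup"}
    return ProfileSet(profiles, outgroup)


def _species_node(tree: PhyloTree, taxonomy, species: str):
    """Smallest node covering all leaves of a species (a leaf for singletons)."""
    accs = frozenset(a for a, t in taxonomy.items() if t[0] == species)
    if not accs:
        raise ValueError(f"species {species!r} not in taxonomy")
    leafsets = tree.clade_leafsets()
    return min(
        (n for n, ls in leafsets.items() if accs <= ls), key=lambda n: len(leafsets[n])
    ), accs


def _graft_introgression(tree: PhyloTree, taxonomy, event: IntrogressionEvent,
                         rng) -> None:
    """Re-graft a fraction of the recipient's lineages into the donor clade.

    Operates on node heights in place; call :func:`_heights_to_lengths`
    afterwards.
    """
    donor_node, donor_accs = _species_node(tree, taxonomy, event.donor)
    _, recip_accs = _species_node(tree, taxonomy, event.recipient)
    n_move = int(round(event.fraction * len(recip_accs)))
    if n_move == 0:
        import warnings

        warnings.warn(
            f"introgression {event.donor}->{event.recipient}: fraction "
            f"{event.fraction} resolves to 0 sequences; no-op"
        )
        return
    moved = sorted(recip_accs)[:n_move]

    leaves = {l.label: l for l in tree.leaves()}
    for label in moved:
        node = leaves[label]
        parent = node.parent
        parent.remove_child(node)
        # Splice out degenerate ancestors left behind.
        while parent is not None and parent.parent is not None and len(parent.children) == 1:
            gp = parent.parent
            (only,) = parent.children
            parent.remove_child(only)
            gp.remove_child(parent)
            gp.add_child(only)
            parent = gp

    # Attachment: split the pendant edge of one donor leaf, placing the
    # transferred lineages inside the donor clade (donor paraphyletic; with
    # fraction 1.0 the recipient is a nested monophyletic clade).  The
    # donor's coalescence is first deepened toward its parent so the nested
    # structure stays resolvable - echoing the unusually deep intraspecific
    # divergence that introgressed species show in real data.  A
    # single-sequence donor has no own clade to break and stays unevaluated.
    if not donor_node.is_leaf:
        h_parent = donor_node.parent.height
        donor_node.height = max(
            donor_node.height, donor_node.height + 0.6 * (h_parent - donor_node.height)
        )
    donor_leaf = leaves[sorted(donor_accs)[int(rng.integers(len(donor_accs)))]]
    h_top = donor_node.height if not donor_node.is_leaf else donor_node.parent.height
    h_att = 0.55 * h_top
    if len(moved) == 1:
        transferred = leaves[moved[0]]
    else:
        transferred = Node(children=[leaves[m] for m in moved])
        transferred.height = 0.5 * h_att
    dl_parent = donor_leaf.parent
    dl_parent.remove_child(donor_leaf)
    junction = Node(children=[donor_leaf, transferred])
    junction.height = h_att
    dl_parent.add_child(junction)


def apply_introgression(dataset: SyntheticDataset,
                        events: list[IntrogressionEvent]) -> SyntheticDataset:
    """Dataset re-simulated with additional introgression events.

    Re-simulation (same seed, modified genealogy) keeps the result fully
    deterministic; an empty event list returns an identical dataset.
    """
    if not events:
        return dataset
    config = replace(
        dataset.config,
        introgression_events=list(dataset.config.introgression_events) + list(events),
    )
    return simulate_dataset(config)


def _compute_truth(tree: PhyloTree, taxonomy, config: SyntheticConfig) -> dict:
    """Ground-truth monophyly flags and expected depths from the genealogy."""
    patristic = tree.leaf_distance_matrix()
    by_species: dict[str, list[str]] = {}
    by_genus: dict[str, set[str]] = {}
    for acc, (sp, gen, so) in taxonomy.items():
        if so == "Outgroup":
            continue
        by_species.setdefault(sp, []).append(acc)
        by_genus.setdefault(gen, set()).add(sp)

    species_monophyletic = {}
    species_depth = {}
    for sp, accs in by_species.items():
        if len(accs) >= 2:
            species_monophyletic[sp] = (
                is_monophyletic(tree, accs) == "monophyletic"
            )
            d = [
                patristic.get(a, b)
                for i, a in enumerate(accs)
                for b in accs[i + 1 :]
            ]
            species_depth[sp] = float(np.mean(d))
    genus_depth = {}
    for gen, spp in by_genus.items():
        if len(spp) < 2:
            continue
        reps = [by_species[sp][0] for sp in sorted(spp)]
        d = [
            patristic.get(a, b)
            for i, a in enumerate(reps)
            for b in reps[i + 1 :]
        ]
        genus_depth[gen] = float(np.mean(d))
    return {
        "species_monophyletic": species_monophyletic,
        "species_intra_depth": species_depth,
        "genus_inter_depth": genus_depth,
        "expected_intra": config.intra_depth,
        "expected_inter": config.inter_depth,
    }


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """End-to-end simulation: genealogy, introgression, sequence evolution.

    Deterministic in ``config.seed``; the same configuration yields
    byte-identical profiles.
    """
    rng = np.random.default_rng(config.seed)
    tree, taxonomy = generate_species_system(config, rng)
    for event in config.introgression_events:
        _graft_introgression(tree, taxonomy, event, rng)
    _heights_to_lengths(tree)
    tree._taxonomy = taxonomy
    evo_rng = np.random.default_rng((config.seed, 1))
    profiles = evolve_sequences(
        tree, config.gene_lengths, config.model, rng=evo_rng
    )
    truth = _compute_truth(tree, taxonomy, config)
    return SyntheticDataset(profiles, tree, taxonomy, truth, config)
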