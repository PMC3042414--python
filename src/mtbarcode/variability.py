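"""Intra/interspecific variability tables and sliding-window diversity.

Variability tables use K2P distances (ambiguities resolved by proportional
redistribution), summarised as the unweighted mean over conspecific pairs
(per species) or congeneric species pairs (per genus, species with multiple
sequences first collapsed to an IUPAC consensus).  Sliding-window statistics
deliberately use the uncorrected p-distance instead: nucleotide diversity
(pi) within a species and divergence (Dxy) between two species, in 600 bp
windows advanced 5 bp at a time across the concatenated genome profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seqcodes import IUPAC_OF_SET, encode, encode_matrix
from .distances import count_site_patterns, k2p_distance
from .profiles import GeneProfile

__all__ = [
    "ConsensusSequence",
    "VariabilityTable",
    "WindowProfile",
    "consensus_iupac",
    "mean_intraspecific",
    "mean_interspecific",
    "variability_table",
    "anova_tukey",
    "sliding_window",
]


@dataclass
class ConsensusSequence:
    """Species consensus with conspecific variability summarised by IUPAC codes."""

    species: str
    sequence: str
    n_sources: int


@dataclass
class VariabilityTable:
    """Mean intraspecific (per species) and interspecific (per genus) K2P."""

    profile: str
    intra: dict[str, float]
    inter: dict[str, float]
    flagged: list[str] = field(default_factory=list)

    @property
    def mean_intra(self) -> float:
        vals = [v for v in self.intra.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def mean_inter(self) -> float:
        vals = [v for v in self.inter.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [("intra", k, v) for k, v in self.intra.items()]
        rows += [("inter", k, v) for k, v in self.inter.items()]
        return pd.DataFrame(rows, columns=["level", "taxon", "mean_k2p"])


def consensus_iupac(profile: GeneProfile, species: str) -> ConsensusSequence:
    """Strict union-to-IUPAC consensus over a species' sequences.

    Per column, the minimal IUPAC code covering the observed unambiguous
    bases; columns that are gap in all members stay gap.
    """
    members = [
        s for a, s in profile.alignment.items() if profile.species_of(a) == species
    ]
    if len(members) < 2:
        raise ValueError(f"species {species!r} has fewer than 2 sequences")
    E = encode_matrix(members)
    out = []
    for col in E.T:
        bases = frozenset(int(c) for c in col if 0 <= c <= 3)
        out.append(IUPAC_OF_SET[bases] if bases else "-")
    return ConsensusSequence(species, "".join(out), len(members))


def _mean_pairwise_k2p(seqs: list, ambiguity_mode: str = "infer") -> float:
    vals = []
    enc = [encode(s) if isinstance(s, str) else s for s in seqs]
    for i in range(len(enc)):
        for j in range(i + 1, len(enc)):
            d = k2p_distance(
                count_site_patterns(enc[i], enc[j], ambiguity_mode)
            )
            vals.append(d)
    defined = [v for v in vals if not math.isnan(v)]
    return float(np.mean(defined)) if defined else math.nan


def mean_intraspecific(profile: GeneProfile,
                       ambiguity_mode: str = "infer") -> dict[str, float]:
    """Mean conspecific pairwise K2P per species (>=2 sequences).

    Species whose pairs are all undefined (saturated) map to ``nan``.
    """
    by_species: dict[str, list[str]] = {}
    for acc, seq in profile.alignment.items():
        by_species.setdefault(profile.species_of(acc), []).append(seq)
    return {
        sp: _mean_pairwise_k2p(seqs, ambiguity_mode)
        for sp, seqs in sorted(by_species.items())
        if len(seqs) >= 2
    }


def mean_interspecific(profile: GeneProfile,
                       ambiguity_mode: str = "infer") -> dict[str, float]:
    """Mean congeneric interspecific K2P per genus (>=2 species).

    Species with multiple sequences are first replaced by their IUPAC
    consensus; ambiguity-bearing columns are handled by proportional
    redistribution (mode ``'infer'``) by default.
    """
    by_genus: dict[str, dict[str, list[str]]] = {}
    for acc, seq in profile.alignment.items():
        sp, gen = profile.taxonomy[acc][0], profile.taxonomy[acc][1]
        by_genus.setdefault(gen, {}).setdefault(sp, []).append(seq)
    out = {}
    for gen, species in sorted(by_genus.items()):
        if len(species) < 2:
            continue
        reps = []
        for sp, seqs in sorted(species.items()):
            if len(seqs) >= 2:
                reps.append(consensus_iupac(profile, sp).sequence)
            else:
                reps.append(seqs[0])
        out[gen] = _mean_pairwise_k2p(reps, ambiguity_mode)
    return out


def variability_table(profile: GeneProfile,
                      ambiguity_mode: str = "infer") -> VariabilityTable:
    intra = mean_intraspecific(profile, ambiguity_mode)
    inter = mean_interspecific(profile, ambiguity_mode)
    flagged = [k for k, v in {**intra, **inter}.items() if math.isnan(v)]
    return VariabilityTable(profile.gene, intra, inter, flagged)


def anova_tukey(groups: dict[str, list[float]]):
    """One-way ANOVA plus Tukey(-Kramer) HSD pairwise comparisons.

    ``groups`` maps profile name -> per-taxon mean distances.  Returns
    ``(f_stat, p_value, tukey_frame)``; with zero within-group variance
    everywhere the F statistic is undefined and ``(nan, nan, empty)`` is
    returned.
    """
    names = [k for k, v in groups.items() if len(v) >= 2]
    if len(names) < 2:
        raise ValueError("need at least two groups with >=2 values each")
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if all(np.allclose(d, d[0]) for d in data):
        grand = np.concatenate(data)
        if np.allclose(grand, grand[0]):
            return math.nan, math.nan, pd.DataFrame()
    f_stat, p_value = stats.f_oneway(*data)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(data)
    labels = np.concatenate([[n] * len(d) for n, d in zip(names, data)])
    tk = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return float(f_stat), float(p_value), frame


@dataclass
class WindowProfile:
    """Sliding-window diversity (pi) or divergence (Dxy) track."""

    statistic: str
    taxon_or_pair: str
    midpoints: np.ndarray
    values: np.ndarray
    window: int
    step: int
    gene_boundaries: dict[str, tuple[int, int]] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"midpoint": self.midpoints, self.statistic: self.values}
        )


def n_windows(length: int, window: int, step: int) -> int:
    """Count of fully contained windows: floor((L - window)/step) + 1."""
    if window > length:
        raise ValueError("window exceeds alignment length")
    return (length - window) // step + 1


def _window_pair_stats(profile: GeneProfile, pairs, window: int, step: int,
                       min_comparable_frac: float = 0.5):
    """Mean pairwise p-distance per window over the given accession pairs.

    Per pair and window, sites are compared under pairwise deletion; a pair
    contributes a missing value in windows where fewer than
    ``min_comparable_frac`` of the columns are comparable.  The window value
    is the mean over contributing pairs (nan when none contributes).
    """
    L = profile.length
    nw = n_windows(L, window, step)
    starts = np.arange(nw) * step
    enc = {a: encode(profile.alignment[a]) for a in
           {x for p in pairs for x in p}}
    acc_vals = np.full((len(pairs), nw), np.nan)
    for k, (a, b) in enumerate(pairs):
        ca, cb = enc[a], enc[b]
        comp = ((ca >= 0) & (ca <= 3) & (cb >= 0) & (cb <= 3)).astype(int)
        diff = ((ca != cb) & (comp == 1)).astype(int)
        ccomp = np.concatenate([[0], np.cumsum(comp)])
        cdiff = np.concatenate([[0], np.cumsum(diff)])
        win_comp = ccomp[starts + window] - ccomp[starts]
        win_diff = cdiff[starts + window] - cdiff[starts]
        ok = win_comp >= min_comparable_frac * window
        with np.errstate(invalid="ignore", divide="ignore"):
            acc_vals[k] = np.where(ok, win_diff / np.maximum(win_comp, 1), np.nan)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan windows
        values = np.nanmean(acc_vals, axis=0)
    midpoints = starts + window / 2.0
    return midpoints, values


def sliding_window(profile: GeneProfile, selection, window: int = 600,
                   step: int = 5) -> WindowProfile:
    """Sliding-window pi (one species) or Dxy (a species pair).

    ``selection`` is a species name (nucleotide diversity over all
    conspecific pairs) or a tuple of two species names (divergence over all
    between-species sequence pairs).  Distances are uncorrected p-distances;
    windows must fit inside the alignment.  Gene boundaries are carried over
    from concatenated profiles for plot annotation; genes shorter than the
    window contain no wholly-contained window.
    """
    members: dict[str, list[str]] = {}
    for acc in profile.alignment:
        members.setdefault(profile.species_of(acc), []).append(acc)

    if isinstance(selection, str):
        accs = members.get(selection, [])
        if len(accs) < 2:
            raise ValueError(f"pi needs >=2 sequences for {selection!r}")
        pairs = [
            (a, b) for i, a in enumerate(accs) for b in accs[i + 1 :]
        ]
        statistic, name = "pi", selection
    else:
        sp_a, sp_b = selection
        accs_a, accs_b = members.get(sp_a, []), members.get(sp_b, [])
        if not accs_a or not accs_b:
            raise ValueError(f"Dxy needs >=1 sequence per species of {selection}")
        pairs = [(a, b) for a in accs_a for b in accs_b]
        statistic, name = "dxy", f"{sp_a} vs {sp_b}"

    midpoints, values = _window_pair_stats(profile, pairs, window, step)
    return WindowProfile(
        statistic, name, midpoints, values, window, step,
        gene_boundaries=profile.gene_boundaries,
    )
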