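"""Pairwise genetic distances: p-distance, Kimura two-parameter (K2P),
amino-acid Kimura distance, and transition/transversion summaries.

The K2P model corrects separately for transitions (proportion P) and
transversions (proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Saturated pairs, where an argument of a logarithm is non-positive, are
reported as undefined rather than clamped; downstream consumers decide how
to handle them (the NJ stage substitutes a configurable cap).

Gap handling is pairwise deletion throughout: each pair is scored over the
columns where both sequences carry an unambiguous base.  Ambiguity codes can
either be excluded or resolved by proportional redistribution
(``ambiguity_mode='infer'``): each ambiguous column is distributed over its
consistent resolutions with weights proportional to the identity /
transition / transversion proportions observed at the pair's unambiguous
columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqcodes import IS_PURINE, RESOLUTIONS, encode, encode_matrix

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "count_site_patterns",
    "p_distance",
    "k2p_distance",
    "aa_kimura_distance",
    "percent_ti",
    "build_distance_matrix",
    "pairwise_counts",
    "write_phylip",
    "read_phylip",
]


@dataclass
class SitePairCounts:
    """Site-pattern counts for one aligned sequence pair.

    ``transitions``/``transversions`` may be fractional under
    ``ambiguity_mode='infer'``; ``sites_compared`` counts the columns that
    entered the comparison.
    """

    sites_compared: float
    transitions: float
    transversions: float
    ambiguous_sites: int = 0

    @property
    def P(self) -> float:
        return self.transitions / self.sites_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.sites_compared


def count_site_patterns(a, b, ambiguity_mode: str = "exclude") -> SitePairCounts:
    """Count identity/transition/transversion site patterns for a pair.

    Parameters
    ----------
    a, b:
        Aligned nucleotide strings (or pre-encoded int arrays) of equal length.
    ambiguity_mode:
        ``'exclude'`` skips any column with a gap or IUPAC ambiguity code in
        either sequence.  ``'infer'`` keeps ambiguity-bearing (non-gap)
        columns and distributes each over its consistent resolutions,
        weighted by the unambiguous pattern proportions of the same pair.
    """
    ca = encode(a) if isinstance(a, str) else np.asarray(a)
    cb = encode(b) if isinstance(b, str) else np.asarray(b)
    if ca.shape != cb.shape:
        raise ValueError("sequences must be aligned to equal length")
    if ambiguity_mode not in ("exclude", "infer"):
        raise ValueError(f"unknown ambiguity_mode: {ambiguity_mode!r}")

    plain_a = (ca >= 0) & (ca <= 3)
    plain_b = (cb >= 0) & (cb <= 3)
    both_plain = plain_a & plain_b
    xa, xb = ca[both_plain], cb[both_plain]
    diff = xa != xb
    ti_mask = diff & (IS_PURINE[xa] == IS_PURINE[xb])
    n_plain = int(both_plain.sum())
    ti = float(ti_mask.sum())
    tv = float(diff.sum() - ti_mask.sum())

    ambig = (plain_a | (ca > 3)) & (plain_b | (cb > 3)) & ~both_plain
    n_ambig = int(ambig.sum())

    if ambiguity_mode == "exclude" or n_ambig == 0:
        counts = SitePairCounts(n_plain, ti, tv, ambiguous_sites=n_ambig)
        if counts.sites_compared == 0:
            raise ValueError("no comparable sites between the pair")
        return counts

    # Unambiguous category proportions for this pair (identity, ti, tv).
    if n_plain > 0:
        props = {
            "id": (n_plain - ti - tv) / n_plain,
            "ti": ti / n_plain,
            "tv": tv / n_plain,
        }
    else:
        props = {"id": 1.0, "ti": 1.0, "tv": 1.0}  # degenerate: uniform

    sites = float(n_plain)
    for i in np.nonzero(ambig)[0]:
        cats = []
        for x, y in itertools.product(RESOLUTIONS[ca[i]], RESOLUTIONS[cb[i]]):
            if x == y:
                cats.append("id")
            elif IS_PURINE[x] == IS_PURINE[y]:
                cats.append("ti")
            else:
                cats.append("tv")
        weights = np.array([props[c] for c in cats])
        total = weights.sum()
        if total <= 0:
            weights = np.ones(len(cats))
            total = float(len(cats))
        weights /= total
        ti += float(sum(w for w, c in zip(weights, cats) if c == "ti"))
        tv += float(sum(w for w, c in zip(weights, cats) if c == "tv"))
        sites += 1.0

    counts = SitePairCounts(sites, ti, tv, ambiguous_sites=n_ambig)
    if counts.sites_compared == 0:
        raise ValueError("no comparable sites between the pair")
    return counts


def p_distance(counts: SitePairCounts) -> float:
    """Uncorrected proportion of differing sites."""
    if counts.sites_compared <= 0:
        raise ValueError("sites_compared must be positive")
    return (counts.transitions + counts.transversions) / counts.sites_compared


def k2p_distance(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance; ``nan`` when the correction is undefined.

    Requires 1 - 2P - Q > 0 and 1 - 2Q > 0; pairs violating either bound are
    saturated under the model and reported as ``nan`` (never clamped here).
    """
    if counts.sites_compared <= 0:
        raise ValueError("sites_compared must be positive")
    P, Q = counts.P, counts.Q
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def aa_kimura_distance(a: str, b: str) -> float:
    """Kimura's distance for aligned amino-acid sequences.

    With p the differing fraction over columns where both sequences carry a
    residue, d = -ln(1 - p - 0.2 p^2); ``nan`` when the argument is <= 0.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x not in "-?.X*" and y not in "-?.X*"
    ]
    if not pairs:
        raise ValueError("no comparable sites between the pair")
    p = sum(x != y for x, y in pairs) / len(pairs)
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return math.nan
    return -math.log(arg)


def percent_ti(counts: SitePairCounts) -> float:
    """Transitions as a fraction of all substitutions, Ti/(Ti+Tv).

    Values <= 0.5 (Ti/Tv <= 1) flag saturation.  Raises when the pair shows
    no substitutions (such pairs are excluded from saturation plots).
    """
    total = counts.transitions + counts.transversions
    if total <= 0:
        raise ValueError("no substitutions observed; %Ti undefined")
    return counts.transitions / total


def is_low_ti(fraction: float) -> bool:
    """Low-%Ti flag: at or below 50% (Ti/Tv <= 1)."""
    return fraction <= 0.5


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with a method tag.

    Undefined (saturated) entries are stored as ``nan`` and enumerated by
    :attr:`undefined_pairs`.
    """

    labels: list[str]
    values: np.ndarray
    method: str
    undefined_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not self.undefined_pairs:
            ii, jj = np.nonzero(np.isnan(np.triu(self.values, 1)))
            self.undefined_pairs = {
                (self.labels[i], self.labels[j]) for i, j in zip(ii, jj)
            }

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def capped(self, cap: float = 5.0) -> np.ndarray:
        """Matrix with undefined entries replaced by ``cap`` (for NJ input)."""
        out = self.values.copy()
        out[np.isnan(out)] = cap
        return out

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.method
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    (self.labels[i], self.labels[j], self.values[i, j])
                )
        return pd.DataFrame(rows, columns=["label_a", "label_b", "distance"])


def pairwise_counts(profile, ambiguity_mode: str = "exclude"):
    """Vectorised site-pattern counts for every unordered pair of a profile.

    Returns ``(labels, sites, ti, tv)`` where the last three are (n, n)
    arrays.  ``ambiguity_mode='infer'`` falls back to the per-pair scalar
    routine (used on the small consensus-sequence sets).
    """
    labels = list(profile.alignment)
    seqs = [profile.alignment[l] for l in labels]
    n = len(labels)
    if ambiguity_mode == "infer":
        sites = np.zeros((n, n))
        ti = np.zeros((n, n))
        tv = np.zeros((n, n))
        enc = [encode(s) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                c = count_site_patterns(enc[i], enc[j], "infer")
                sites[i, j] = sites[j, i] = c.sites_compared
                ti[i, j] = ti[j, i] = c.transitions
                tv[i, j] = tv[j, i] = c.transversions
        return labels, sites, ti, tv

    E = encode_matrix(seqs)
    ok = (E >= 0) & (E <= 3)
    pur = np.zeros_like(ok)
    pur[ok] = IS_PURINE[E[ok]]
    sites = np.zeros((n, n))
    ti = np.zeros((n, n))
    tv = np.zeros((n, n))
    for i in range(n - 1):
        comp = ok[i] & ok[i + 1 :]
        diff = (E[i + 1 :] != E[i]) & comp
        same_class = pur[i + 1 :] == pur[i]
        ti_row = (diff & same_class).sum(axis=1).astype(float)
        d_row = diff.sum(axis=1).astype(float)
        s_row = comp.sum(axis=1).astype(float)
        sites[i, i + 1 :] = sites[i + 1 :, i] = s_row
        ti[i, i + 1 :] = ti[i + 1 :, i] = ti_row
        tv[i, i + 1 :] = tv[i + 1 :, i] = d_row - ti_row
    return labels, sites, ti, tv


def build_distance_matrix(
    profile, method: str = "k2p", ambiguity_mode: str = "exclude"
) -> DistanceMatrix:
    """Distance matrix over all unordered pairs of a profile.

    ``method`` is one of ``'p'``, ``'k2p'`` (nucleotide profiles) or
    ``'aa_kimura'`` (amino-acid profiles).  Saturated pairs are flagged, not
    clamped.
    """
    labels = list(profile.alignment)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two sequences")

    if method == "aa_kimura":
        vals = np.zeros((n, n))
        seqs = [profile.alignment[l] for l in labels]
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = aa_kimura_distance(seqs[i], seqs[j])
        return DistanceMatrix(labels, vals, "aa_kimura")

    labels, sites, ti, tv = pairwise_counts(profile, ambiguity_mode)
    if (sites[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("a pair shares zero comparable sites")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ti / sites
        Q = tv / sites
        if method == "p":
            vals = P + Q
        elif method == "k2p":
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            vals = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        else:
            raise ValueError(f"unknown method: {method!r}")
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels, vals, method)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a square PHYLIP (dnadist/protdist-style) distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, label in enumerate(dm.labels):
            name = label[:10].ljust(10)
            row = "  ".join(f"{v:.6f}" for v in dm.values[i])
            fh.write(f"{name}{row}\n")


def read_phylip(path, method: str = "k2p") -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (one sequence per line)."""
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    labels, vals = [], np.zeros((n, n))
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        pos += 1
        vals[i] = [float(t) for t in tokens[pos : pos + n]]
        pos += n
    return DistanceMatrix(labels, vals, method)
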