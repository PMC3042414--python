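"""Maximum-likelihood substitution-model fitting and saturation profiling.

Likelihoods are computed by Felsenstein pruning on a fixed tree (the NJ-K2P
tree, per the classic model-selection protocol), with a single global
branch-length scale optimised alongside the model parameters.  Rate
heterogeneity uses a 4-category discrete gamma (category rate = mean of its
quartile); invariable sites enter as the standard rate-zero mixture
component.  Models are ranked by BIC = -2 lnL + k ln(n_sites) over a
16-model grid: {JC69, K80, HKY85, GTR} x {-, +I, +G, +I+G}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammainc, gammaincinv

from ._seqcodes import RESOLUTIONS, encode_matrix
from .distances import (
    SitePairCounts,
    k2p_distance,
    pairwise_counts,
    percent_ti,
)
from .profiles import GeneProfile
from .trees import PhyloTree

__all__ = [
    "ModelFit",
    "SaturationSeries",
    "MODEL_GRID",
    "gc_content",
    "discrete_gamma_rates",
    "tree_likelihood",
    "fit_model",
    "select_model_bic",
    "saturation_profile",
]

BASE_MODELS = ("JC69", "K80", "HKY85", "GTR")
MODEL_GRID = tuple(
    f"{b}{s}" for b in BASE_MODELS for s in ("", "+I", "+G", "+I+G")
)

_RATE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


@dataclass
class ModelFit:
    """A fitted substitution model with its BIC score."""

    model: str
    lnL: float
    freqs: np.ndarray
    rates: np.ndarray                      # six exchangeabilities, GT = 1
    prop_invariable: float | None = None
    gamma_shape: float | None = None
    kappa: float | None = None
    branch_scale: float = 1.0
    k_free: int = 0
    n_sites: int = 0
    converged: bool = True

    @property
    def bic(self) -> float:
        return -2.0 * self.lnL + self.k_free * math.log(self.n_sites)


def gc_content(profile: GeneProfile) -> float:
    """Pooled G+C fraction over unambiguous bases of all sequences."""
    E = encode_matrix(list(profile.alignment.values()))
    plain = (E >= 0) & (E <= 3)
    total = int(plain.sum())
    if total == 0:
        raise ValueError("no unambiguous bases in profile")
    gc = int(((E == 1) | (E == 2)).sum())
    return gc / total


def empirical_freqs(profile: GeneProfile) -> np.ndarray:
    E = encode_matrix(list(profile.alignment.values()))
    counts = np.array([(E == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in profile")
    return counts / counts.sum()


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean-of-quantile category rates for the discrete gamma (mean 1)."""
    quantiles = gammaincinv(alpha, np.arange(1, ncat) / ncat) / alpha
    bounds = np.concatenate([[0.0], quantiles, [np.inf]])
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    return ncat * (upper - lower)


def _build_q(freqs: np.ndarray, rates: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(rates, _RATE_PAIRS):
        Q[i, j] = r * freqs[j]
        Q[j, i] = r * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def _eigen(freqs: np.ndarray, rates: np.ndarray):
    Q = _build_q(freqs, rates)
    sq = np.sqrt(freqs)
    S = (Q * sq[:, None]) / sq[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    U = V / sq[:, None]
    Uinv = V.T * sq[None, :]
    return lam, U, Uinv


class _Pruner:
    """Pattern-compressed pruning likelihood over a fixed tree."""

    def __init__(self, profile: GeneProfile, tree: PhyloTree, ncat: int = 4):
        self.tree = tree
        labels = tree.leaf_labels()
        missing = [l for l in labels if l not in profile.alignment]
        if missing:
            raise ValueError(f"profile lacks tree leaves: {missing[:5]}")
        E = encode_matrix([profile.alignment[l] for l in labels])
        # Pattern compression over columns.
        patterns, inverse, counts = np.unique(
            E.T, axis=0, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self.n_sites = E.shape[1]
        self.n_patterns = patterns.shape[0]
        self.ncat = ncat
        # Leaf partials: indicator over resolutions (ambiguity/gap -> all 1).
        self.leaf_partials = {}
        for row, label in enumerate(labels):
            codes = patterns[:, row]
            part = np.zeros((self.n_patterns, 4))
            for p in range(self.n_patterns):
                c = codes[p]
                if c < 0:
                    part[p] = 1.0
                else:
                    part[p, list(RESOLUTIONS[c])] = 1.0
            self.leaf_partials[label] = part
        self.postorder = [n for n in tree.postorder()]
        self.branch_lengths = {
            id(n): max(n.length or 0.0, 0.0) for n in self.postorder
        }

    def site_likelihoods(self, freqs, rates_vec, category_rates, branch_scale):
        """Per-pattern likelihood for each rate category; (ncat, n_patterns)."""
        lam, U, Uinv = _eigen(freqs, rates_vec)
        out = np.zeros((len(category_rates), self.n_patterns))
        for c, r in enumerate(category_rates):
            if r == 0.0:
                out[c] = self._invariant_likelihood(freqs)
                continue
            log_scale = np.zeros(self.n_patterns)
            partial = {}
            for node in self.postorder:
                if node.is_leaf:
                    partial[id(node)] = self.leaf_partials[node.label]
                    continue
                prod = np.ones((self.n_patterns, 4))
                for child in node.children:
                    t = self.branch_lengths[id(child)] * branch_scale * r
                    P = U @ (np.exp(lam * t)[:, None] * Uinv)
                    P = np.clip(P, 0.0, None)
                    prod *= partial[id(child)] @ P.T
                m = prod.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                prod /= m[:, None]
                log_scale += np.log(m)
                partial[id(node)] = prod
            root = partial[id(self.postorder[-1])]
            out[c] = (root @ freqs) * np.exp(log_scale)
        return out

    def _invariant_likelihood(self, freqs):
        prod = np.ones((self.n_patterns, 4))
        for label, part in self.leaf_partials.items():
            prod *= part
        return prod @ freqs

    def lnL(self, freqs, rates_vec, alpha, prop_invariable, branch_scale):
        if alpha is not None:
            cat = discrete_gamma_rates(alpha, self.ncat)
        else:
            cat = np.array([1.0])
        L_var = self.site_likelihoods(
            freqs, rates_vec, cat, branch_scale
        ).mean(axis=0)
        if prop_invariable is not None and prop_invariable > 0:
            L0 = self._invariant_likelihood(freqs)
            mix = prop_invariable * L0 + (1.0 - prop_invariable) * L_var
        else:
            mix = L_var
        mix = np.maximum(mix, 1e-300)
        return float((self.weights * np.log(mix)).sum())


def tree_likelihood(profile: GeneProfile, tree: PhyloTree, *,
                    freqs=None, rates=None, kappa: float | None = None,
                    alpha: float | None = None,
                    prop_invariable: float | None = None,
                    branch_scale: float = 1.0, ncat: int = 4) -> float:
    """Log-likelihood of an alignment on a fixed tree under a GTR-family model.

    ``rates`` are six exchangeabilities (AC, AG, AT, CG, CT, GT); ``kappa``
    overrides them with the transition/transversion pattern.  Negative
    branch lengths are clamped to zero.  ``alpha`` enables 4-category
    discrete gamma rates, ``prop_invariable`` the invariable-sites mixture.
    """
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    if kappa is not None:
        rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    elif rates is None:
        rates = np.ones(6)
    pruner = _Pruner(profile, tree, ncat)
    return pruner.lnL(freqs, np.asarray(rates, float), alpha,
                      prop_invariable, branch_scale)


def _parse_model(name: str):
    base = name.split("+")[0]
    if base not in BASE_MODELS:
        raise ValueError(f"unknown model {name!r}")
    return base, "+I" in name.replace("+I+G", "+I +G"), "+G" in name


def _model_k_free(base: str, with_i: bool, with_g: bool) -> int:
    k = {"JC69": 0, "K80": 1, "HKY85": 4, "GTR": 8}[base]
    return k + int(with_i) + int(with_g) + 1  # +1 global branch scale


def fit_model(profile: GeneProfile, tree: PhyloTree, model: str = "GTR+I+G",
              ncat: int = 4, n_starts: int = 3,
              tol: float = 1e-6) -> ModelFit:
    """Maximise the likelihood of one model on a fixed tree.

    Base frequencies are empirical; exchangeabilities (or kappa), the
    invariable proportion, the gamma shape, and a global branch-length
    scale are optimised (L-BFGS-B on transformed parameters, multi-start on
    alpha and I).  Bounds: alpha in [0.02, 100], I in [0, 0.99].
    """
    base, with_i, with_g = _parse_model(model)
    freqs = (
        np.full(4, 0.25) if base in ("JC69", "K80") else empirical_freqs(profile)
    )
    pruner = _Pruner(profile, tree, ncat)

    n_rate = {"JC69": 0, "K80": 1, "GTR": 5}.get(base, 1)

    def unpack(x):
        i = 0
        if base == "JC69":
            rates = np.ones(6)
        elif base in ("K80", "HKY85"):
            kappa = math.exp(x[i]); i += 1
            rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        else:
            rates = np.concatenate([np.exp(x[i : i + 5]), [1.0]])
            i += 5
        scale = math.exp(x[i]); i += 1
        alpha = math.exp(x[i]) if with_g else None
        if with_g:
            i += 1
        prop_inv = 1.0 / (1.0 + math.exp(-x[i])) * 0.99 if with_i else None
        return rates, scale, alpha, prop_inv

    def neg_lnL(x):
        rates, scale, alpha, prop_inv = unpack(x)
        if alpha is not None:
            alpha = min(max(alpha, 0.02), 100.0)
        try:
            return -pruner.lnL(freqs, rates, alpha, prop_inv, scale)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    starts = [(0.5, 0.1), (1.0, 0.3), (5.0, 0.02)][: max(n_starts, 1)]
    if not (with_g or with_i):
        starts = starts[:1]

    best = None
    for a0, i0 in starts:
        x0 = []
        if base in ("K80", "HKY85"):
            x0.append(math.log(4.0))
        elif base == "GTR":
            x0.extend([0.0, math.log(4.0), 0.0, 0.0, math.log(4.0)])
        x0.append(0.0)  # log branch scale
        if with_g:
            x0.append(math.log(a0))
        if with_i:
            x0.append(math.log(i0 / (0.99 - i0)))
        res = optimize.minimize(
            neg_lnL, np.array(x0), method="L-BFGS-B",
            options={"ftol": tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    rates, scale, alpha, prop_inv = unpack(best.x)
    if alpha is not None:
        alpha = min(max(alpha, 0.02), 100.0)
    kappa = rates[1] if base in ("K80", "HKY85") else None
    return ModelFit(
        model=model,
        lnL=-float(best.fun),
        freqs=freqs,
        rates=rates,
        prop_invariable=prop_inv,
        gamma_shape=alpha,
        kappa=kappa,
        branch_scale=scale,
        k_free=_model_k_free(base, with_i, with_g),
        n_sites=pruner.n_sites,
        converged=bool(best.success),
    )


def select_model_bic(profile: GeneProfile, tree: PhyloTree,
                     models=MODEL_GRID, ncat: int = 4) -> list[ModelFit]:
    """Fit the model grid and rank by BIC (ascending; n = column count).

    Per-model failures are propagated as log entries and the remaining
    models still ranked.  Ties in BIC resolve to the smaller ``k_free``.
    """
    fits = []
    for name in models:
        try:
            fits.append(fit_model(profile, tree, name, ncat))
        except Exception as exc:  # noqa: BLE001 - isolate per-model failure
            import logging

            logging.getLogger(__name__).warning("model %s failed: %s", name, exc)
    fits.sort(key=lambda f: (round(f.bic, 9), f.k_free))
    return fits


def model_table(fits: list[ModelFit], gc: float | None = None) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "model": f.model, "lnL": f.lnL, "k": f.k_free, "BIC": f.bic,
            "alpha": f.gamma_shape, "I": f.prop_invariable,
            "kappa": f.kappa, "GC": gc,
        })
    return pd.DataFrame(rows)


@dataclass
class SaturationSeries:
    """(K2P distance, %Ti) points for all informative sequence pairs."""

    profile: str
    pairs: list[tuple[float, float]]
    excluded_zero_pairs: int = 0
    excluded_undefined_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["k2p", "percent_ti"])

    def low_ti_fraction_by_decile(self, n_bins: int = 10) -> pd.DataFrame:
        """Fraction of low-%Ti (<=0.5) pairs per K2P-distance bin."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(columns=["bin", "mean_k2p", "low_ti_fraction"])
        df["bin"] = pd.cut(df["k2p"], bins=n_bins)
        grouped = df.groupby("bin", observed=True)
        return pd.DataFrame({
            "mean_k2p": grouped["k2p"].mean(),
            "mean_percent_ti": grouped["percent_ti"].mean(),
            "low_ti_fraction": grouped["percent_ti"].apply(
                lambda s: float((s <= 0.5).mean())
            ),
            "n": grouped.size(),
        }).reset_index()


def saturation_profile(profile: GeneProfile) -> SaturationSeries:
    """%Ti against pairwise K2P distance for every informative pair.

    Pairs with zero distance (no substitutions) and saturated pairs with an
    undefined K2P correction are excluded and counted separately; the total
    of points plus exclusions is n(n-1)/2.
    """
    if profile.n_sequences < 2:
        raise ValueError("need at least two sequences")
    labels, sites, ti, tv = pairwise_counts(profile, "exclude")
    n = len(labels)
    points = []
    zero = undef = 0
    for i, j in itertools.combinations(range(n), 2):
        subs = ti[i, j] + tv[i, j]
        if subs == 0:
            zero += 1
            continue
        counts = SitePairCounts(sites[i, j], ti[i, j], tv[i, j])
        d = k2p_distance(counts)
        if math.isnan(d):
            undef += 1
            continue
        points.append((d, percent_ti(counts)))
    return SaturationSeries(profile.gene, points, zero, undef)
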