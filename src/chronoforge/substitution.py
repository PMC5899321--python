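"""Amino-acid substitution models and pruning likelihoods.

Implements empirical (LG, WAG), general time-reversible (GTR) and
Poisson/F81 exchangeability schemes over the 20 amino acids, discrete-gamma
(default four category) among-site rate variation, and Felsenstein pruning
with per-node rescaling.  Site-heterogeneous CAT mixtures build on the same
kernels (see :mod:`chronoforge.catmixture`).

Rate matrices are normalised to one expected substitution per unit branch
length at stationarity, so branch lengths are in substitutions/site.
"""

from __future__ import annotations

import heapq
import importlib.resources
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammainc, gammaincinv

from .trees import Phylogram

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: characters treated as missing in a leaf column (all-ones partial vector)
MISSING_CHARS = set("-?X*.")
#: ambiguous residues normalised to unknown
AMBIGUOUS_CHARS = set("BZJUO")

__all__ = [
    "AMINO_ACIDS",
    "N_STATES",
    "encode_sequence",
    "decode_sequence",
    "load_empirical_model",
    "discrete_gamma_rates",
    "build_rate_matrix",
    "stationary_sampler",
    "SubstModel",
    "make_model",
    "TransitionKernel",
    "site_log_likelihoods",
    "log_likelihood",
    "FixedTopologyLikelihood",
]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string to int8 codes; missing/unknown -> -1."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in _AA_INDEX:
            out[i] = _AA_INDEX[ch]
        elif ch in MISSING_CHARS or ch in AMBIGUOUS_CHARS:
            out[i] = -1
        else:
            raise ValueError(f"unknown residue {ch!r} at column {i}")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("?" if c < 0 else AMINO_ACIDS[c] for c in codes)


def _read_matrix_file(name: str) -> Tuple[np.ndarray, np.ndarray]:
    text = (
        importlib.resources.files("chronoforge.data").joinpath(name).read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    order = lines[0].split()
    assert order == list(AMINO_ACIDS), "unexpected residue order in data file"
    exch = np.zeros((N_STATES, N_STATES))
    for i in range(1, N_STATES):
        row = [float(x) for x in lines[i].split()]
        for j, v in enumerate(row):
            exch[i, j] = exch[j, i] = v
    freqs = np.array([float(x) for x in lines[N_STATES].split()])
    freqs = freqs / freqs.sum()
    return exch, freqs


_EMPIRICAL_CACHE: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}


def load_empirical_model(name: str) -> Tuple[np.ndarray, np.ndarray]:
    """Return (exchangeabilities, frequencies) for 'lg' or 'wag'."""
    key = name.lower()
    if key not in ("lg", "wag"):
        raise ValueError(f"unknown empirical model {name!r}")
    if key not in _EMPIRICAL_CACHE:
        _EMPIRICAL_CACHE[key] = _read_matrix_file(f"{key}.txt")
    exch, freqs = _EMPIRICAL_CACHE[key]
    return exch.copy(), freqs.copy()


def discrete_gamma_rates(
    alpha: float, ncat: int = 4, *, method: str = "mean"
) -> Tuple[np.ndarray, np.ndarray]:
    """Discrete-gamma rate categories (equal-probability bins).

    Category rates are the conditional means of a Gamma(alpha, alpha)
    distribution within each bin (``method='median'`` uses bin medians
    instead); rates are renormalised so the weighted mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    weights = np.full(ncat, 1.0 / ncat)
    edges = gammaincinv(alpha, np.linspace(0.0, 1.0, ncat + 1)) / alpha
    if method == "mean":
        # E[X; a<X<b] for X~Gamma(alpha, rate alpha): uses the shape+1 identity
        upper = gammainc(alpha + 1.0, alpha * edges[1:])
        lower = gammainc(alpha + 1.0, alpha * edges[:-1])
        rates = ncat * (upper - lower)
    elif method == "median":
        mids = (np.arange(ncat) + 0.5) / ncat
        rates = gammaincinv(alpha, mids) / alpha
    else:
        raise ValueError("method must be 'mean' or 'median'")
    rates = rates / float(rates @ weights)
    return rates, weights


def build_rate_matrix(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """GTR generator Q with q_ij = rho_ij * pi_j, normalised to rate 1.

    Zero frequencies are tolerated: the corresponding rows and columns of Q
    are zero, so those states are absorbing-and-unreachable and drop out of
    the stationary process.
    """
    exch = np.asarray(exch, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if exch.shape != (N_STATES, N_STATES):
        raise ValueError("exchangeability matrix must be 20x20")
    if not np.allclose(exch, exch.T):
        raise ValueError("exchangeability matrix must be symmetric")
    if (exch < 0).any() or not exch.any():
        raise ValueError("exchangeabilities must be non-negative and not all zero")
    q = exch * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(freqs @ np.diag(q))
    if mean_rate > 0:
        q = q / mean_rate
    return q


@dataclass(frozen=True)
class SubstModel:
    """A (possibly gamma-mixed) site-homogeneous substitution model."""

    name: str
    exch: np.ndarray
    freqs: np.ndarray
    alpha: Optional[float] = None  # None -> single rate class at rate 1
    ncat: int = 4

    def gamma(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.alpha is None:
            return np.array([1.0]), np.array([1.0])
        return discrete_gamma_rates(self.alpha, self.ncat)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exch, self.freqs)

    def with_params(self, **kw) -> "SubstModel":
        return replace(self, **kw)

    @property
    def equal_exchangeabilities(self) -> bool:
        off = self.exch[~np.eye(N_STATES, dtype=bool)]
        return bool(np.allclose(off, off[0]) and off[0] > 0)


def make_model(
    name: str,
    *,
    alpha: Optional[float] = None,
    ncat: int = 4,
    freqs: Optional[np.ndarray] = None,
    exch: Optional[np.ndarray] = None,
) -> SubstModel:
    """Construct a named model: poisson, f81, lg, wag, or gtr.

    ``poisson`` is uniform frequencies + equal exchangeabilities; ``f81``
    equal exchangeabilities with supplied frequencies; ``gtr`` requires both
    ``exch`` and ``freqs``.
    """
    key = name.lower()
    ones = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    if key == "poisson":
        return SubstModel(key, ones, np.full(N_STATES, 1.0 / N_STATES), alpha, ncat)
    if key == "f81":
        if freqs is None:
            raise ValueError("f81 needs frequencies")
        return SubstModel(key, ones, np.asarray(freqs, float), alpha, ncat)
    if key in ("lg", "wag"):
        e, f = load_empirical_model(key)
        if freqs is not None:  # +F variant
            f = np.asarray(freqs, float)
        return SubstModel(key, e, f, alpha, ncat)
    if key == "gtr":
        if exch is None or freqs is None:
            raise ValueError("gtr needs exchangeabilities and frequencies")
        return SubstModel(key, np.asarray(exch, float), np.asarray(freqs, float), alpha, ncat)
    raise ValueError(f"unknown model {name!r}")


def stationary_sampler(freqs: np.ndarray, rng: np.random.Generator):
    cum = np.cumsum(freqs / freqs.sum())

    def draw(n: int) -> np.ndarray:
        return np.searchsorted(cum, rng.random(n)).astype(np.int8)

    return draw


class TransitionKernel:
    """Computes P(t) = exp(Qt) and propagates partial likelihoods.

    Equal-exchangeability models use the closed-form F81 transition
    probabilities (O(20) per site); general models use the symmetric
    eigendecomposition of the reversible generator.
    """

    def __init__(self, exch: np.ndarray, freqs: np.ndarray):
        self.freqs = np.asarray(freqs, dtype=float)
        off = exch[~np.eye(N_STATES, dtype=bool)]
        self._f81 = bool(np.allclose(off, off[0]) and off[0] > 0)
        q = build_rate_matrix(exch, freqs)
        if self._f81:
            # normalised F81: q_ij = beta * pi_j with beta = 1/(1 - sum pi^2)
            denom = 1.0 - float(self.freqs @ self.freqs)
            self._beta = 1.0 / denom if denom > 0 else 0.0
        else:
            pi = np.clip(self.freqs, 1e-300, None)
            d = np.sqrt(pi)
            b = (q * d[:, None]) / d[None, :]
            b = 0.5 * (b + b.T)
            w, u = np.linalg.eigh(b)
            self._w = w
            self._left = u / d[:, None]       # D^{-1/2} U
            self._right = (u * d[:, None]).T  # U^T D^{1/2}

    def probability_matrix(self, t: float) -> np.ndarray:
        t = max(float(t), 0.0)
        if t == 0.0:
            return np.eye(N_STATES)
        if self._f81:
            e = np.exp(-self._beta * t)
            p = (1.0 - e) * np.tile(self.freqs, (N_STATES, 1))
            p[np.diag_indices(N_STATES)] += e
            return p
        p = (self._left * np.exp(self._w * t)[None, :]) @ self._right
        return np.clip(p, 0.0, None)  # rows: from-state i -> P[i, j]

    def propagate(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Return M with M_a = sum_b P_ab(t) L_b for each site row of L."""
        t = max(float(t), 0.0)
        if self._f81:
            e = np.exp(-self._beta * t)
            w = partial @ self.freqs
            return e * partial + (1.0 - e) * w[..., None]
        return partial @ self.probability_matrix(t).T

    def propagate_cats(
        self, partial: np.ndarray, t: float, rates: np.ndarray
    ) -> np.ndarray:
        """Batched :meth:`propagate` over gamma categories.

        ``partial`` has shape (ncat, nsites, 20); category k is propagated
        along a branch of length ``t * rates[k]``.
        """
        t = max(float(t), 0.0)
        if self._f81:
            e = np.exp(-self._beta * t * np.asarray(rates))[:, None, None]
            w = partial @ self.freqs
            return e * partial + (1.0 - e) * w[..., None]
        mats = np.stack([self.probability_matrix(t * r).T for r in rates])
        return np.matmul(partial, mats)


def _leaf_partial(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    partial = np.zeros((n, N_STATES))
    missing = codes < 0
    partial[np.arange(n)[~missing], codes[~missing]] = 1.0
    partial[missing] = 1.0
    return partial


def site_log_likelihoods(
    tree: Phylogram,
    codes_by_taxon: Dict[str, np.ndarray],
    model: SubstModel,
    *,
    site_freqs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning.

    ``site_freqs`` (n_sites x 20), when given, replaces the model
    frequencies at the root — used by CAT mixtures where each site carries
    its own stationary profile but shares exchangeabilities (the kernel is
    then built per profile by the caller; this entry point serves the
    homogeneous case and the per-component case alike).
    """
    for leaf in tree.leaves():
        if leaf.name not in codes_by_taxon:
            raise KeyError(f"taxon {leaf.name!r} missing from the alignment")
    rates, weights = model.gamma()
    kernel = TransitionKernel(model.exch, model.freqs)
    n_sites = len(next(iter(codes_by_taxon.values())))
    ncat = len(rates)

    partials: Dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            lp = _leaf_partial(codes_by_taxon[node.name])
            partials[id(node)] = np.broadcast_to(lp, (ncat, n_sites, N_STATES))
            continue
        prod = np.ones((ncat, n_sites, N_STATES))
        for child in node.children:
            cp = partials.pop(id(child))
            prod *= kernel.propagate_cats(cp, child.length or 0.0, rates)
        scale = prod.max(axis=(0, 2))
        safe = np.where(scale > 0, scale, 1.0)
        prod /= safe[None, :, None]
        logscale += np.where(scale > 0, np.log(safe), -np.inf)
        partials[id(node)] = prod

    root_partial = partials[id(tree.root)]
    if site_freqs is not None:
        site_l = (root_partial * site_freqs[None, :, :]).sum(axis=2).T @ weights
    else:
        site_l = (root_partial @ kernel.freqs).T @ weights
    with np.errstate(divide="ignore"):
        return np.log(site_l) + logscale


def log_likelihood(
    tree: Phylogram, codes_by_taxon: Dict[str, np.ndarray], model: SubstModel
) -> float:
    return float(site_log_likelihoods(tree, codes_by_taxon, model).sum())


class FixedTopologyLikelihood:
    """Incremental pruning likelihood on a fixed topology.

    Branch lengths are set or updated per node; only the path from a changed
    branch to the root is recomputed, with full revert support — this is the
    inner loop of the dating sampler, where a node-age move touches at most
    three branches.

    Nodes are indexed in postorder; the caller addresses branches by the
    postorder index of the node below the branch.
    """

    def __init__(
        self,
        postorder_nodes: Sequence,
        parent_index: Sequence[int],
        leaf_codes: Dict[int, np.ndarray],
        model: SubstModel,
    ):
        self.n_nodes = len(postorder_nodes)
        self.parent = np.asarray(parent_index, dtype=int)  # -1 for root
        self.children: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        self.model = model
        self.rates, self.weights = model.gamma()
        self.kernel = TransitionKernel(model.exch, model.freqs)
        ncat = len(self.rates)
        # collapse identical site patterns (exact: pattern weights restore
        # the per-site totals)
        leaf_idx = sorted(leaf_codes)
        matrix = np.vstack([leaf_codes[i] for i in leaf_idx])
        self.total_sites = matrix.shape[1]
        patterns, counts = np.unique(matrix, axis=1, return_counts=True)
        self.pattern_weights = counts.astype(float)
        leaf_codes = {i: patterns[k] for k, i in enumerate(leaf_idx)}
        n_sites = patterns.shape[1]
        self.n_sites = n_sites

        self._partial: List[Optional[np.ndarray]] = [None] * self.n_nodes
        self._logscale: List[float] = [0.0] * self.n_nodes
        self._msg: List[Optional[np.ndarray]] = [None] * self.n_nodes
        self.blen = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            if self.is_leaf[i]:
                lp = _leaf_partial(leaf_codes[i])
                self._partial[i] = np.ascontiguousarray(
                    np.broadcast_to(lp, (ncat, n_sites, N_STATES))
                )
                self._logscale[i] = 0.0
        self._trail: List[Tuple[str, int, object]] = []
        self._loglik = -np.inf

    # -- internals ---------------------------------------------------------
    def _compute_msg(self, i: int) -> np.ndarray:
        return self.kernel.propagate_cats(self._partial[i], self.blen[i], self.rates)

    def _compute_partial(self, i: int) -> Tuple[np.ndarray, float]:
        # a single scalar rescale per node keeps every site in float64 range
        # at these tree depths and is far cheaper than per-site scaling
        prod = None
        ls = 0.0
        for c in self.children[i]:
            prod = self._msg[c].copy() if prod is None else prod * self._msg[c]
            ls += self._logscale[c]
        scale = float(prod.max())
        if scale > 0:
            prod *= 1.0 / scale
            ls += math.log(scale)
        else:
            ls = -np.inf
        return prod, ls

    def _root_loglik(self) -> float:
        root = self.n_nodes - 1
        ls = self._logscale[root]
        if not np.isfinite(ls):
            return -np.inf
        site_l = (self._partial[root] @ self.kernel.freqs).T @ self.weights
        if (site_l <= 0).any():
            return -np.inf
        return float(
            np.log(site_l) @ self.pattern_weights + self.total_sites * ls
        )

    # -- public API --------------------------------------------------------
    def set_lengths(self, blen: np.ndarray) -> float:
        """Full recompute with the given branch lengths (root entry ignored)."""
        self.blen = np.asarray(blen, dtype=float).copy()
        for i in range(self.n_nodes):
            # postorder: children's messages exist before the parent's partial
            if not self.is_leaf[i]:
                self._partial[i], self._logscale[i] = self._compute_partial(i)
            if self.parent[i] >= 0:
                self._msg[i] = self._compute_msg(i)
        self._trail = []
        self._loglik = self._root_loglik()
        return self._loglik

    def update(self, changed: Dict[int, float]) -> float:
        """Change a few branch lengths; recompute only the affected path."""
        if not changed:
            self._trail = []
            return self._loglik
        self._trail = []
        dirty_partials: set = set()
        for i, b in changed.items():
            if self.parent[i] < 0:
                continue
            self._trail.append(("blen", i, self.blen[i]))
            self.blen[i] = b
            self._trail.append(("msg", i, self._msg[i]))
            self._msg[i] = self._compute_msg(i)
            dirty_partials.add(int(self.parent[i]))
        heap = sorted(dirty_partials)  # postorder index: children before parents
        done: set = set()
        while heap:
            i = heapq.heappop(heap)
            if i in done:
                continue
            done.add(i)
            self._trail.append(("partial", i, (self._partial[i], self._logscale[i])))
            self._partial[i], self._logscale[i] = self._compute_partial(i)
            if self.parent[i] >= 0:
                self._trail.append(("msg", i, self._msg[i]))
                self._msg[i] = self._compute_msg(i)
                heapq.heappush(heap, int(self.parent[i]))
        self._trail.append(("loglik", -1, self._loglik))
        self._loglik = self._root_loglik()
        return self._loglik

    def revert(self) -> None:
        for kind, i, old in reversed(self._trail):
            if kind == "blen":
                self.blen[i] = old
            elif kind == "msg":
                self._msg[i] = old
            elif kind == "partial":
                self._partial[i], self._logscale[i] = old
            else:
                self._loglik = old
        self._trail = []

    def accept(self) -> None:
        self._trail = []

    @property
    def loglik(self) -> float:
        return self._loglik
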