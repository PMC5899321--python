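"""Metropolis-within-Gibbs samplers for tree inference and divergence dating.

Two chain modes share the trace machinery:

* ``phylogram`` — topology + branch lengths + substitution parameters
  (NNI/SPR topology moves, branch multipliers, gamma-shape and GTR/CAT
  parameter updates);
* ``chronogram`` — fixed topology, node ages + branch rates under a relaxed
  clock, with a birth-death node-age prior, soft calibrations and a root-age
  prior.  Only the branches touched by a move are re-peeled (see
  :class:`chronoforge.substitution.FixedTopologyLikelihood`).

One *cycle* is a full sweep of the move schedule; samples are recorded every
``thin`` cycles.  Chains are reproducible: a single seeded generator drives
each chain, the chain id offsetting the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from . import catmixture as catmod
from . import clocks as clk
from . import substitution as subst
from .trees import (
    Chronogram,
    Node,
    Phylogram,
    max_clade_support_diff,
    parse_newick,
    write_newick,
)

__all__ = [
    "ChainConfig",
    "PosteriorTrace",
    "PhyloInferenceSpec",
    "DatingSpec",
    "run_chain",
    "run_phylogram_chain",
    "run_dating_chain",
    "propose_nni",
    "propose_spr",
    "random_phylogram",
    "convergence_report",
]


@dataclass
class ChainConfig:
    cycles: int
    thin: int = 1
    burnin: int = 0  # in retained samples
    seed: int = 0
    chain_id: int = 0

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        retained = self.cycles // self.thin
        if self.burnin >= retained:
            raise ValueError("burn-in must be smaller than the retained sample count")

    @property
    def rng_seed(self) -> int:
        return (self.seed + 1000003 * self.chain_id) % (2**31 - 1)


@dataclass
class PosteriorTrace:
    """Ordered posterior samples plus the metadata needed to interpret them."""

    mode: str
    config: ChainConfig
    model_name: str
    scalars: Dict[str, np.ndarray]
    trees: Optional[List[str]] = None               # phylogram mode
    param_samples: Optional[List[dict]] = None      # per-sample model params
    topology: Optional[str] = None                  # chronogram mode, fixed
    clades: Optional[List[FrozenSet[str]]] = None   # per node index
    leaf_names: Optional[List[str]] = None          # node index -> taxon (leaves)
    ages: Optional[np.ndarray] = None               # (S, n_nodes)
    branch_rates: Optional[np.ndarray] = None       # (S, n_nodes) effective
    branch_lengths: Optional[np.ndarray] = None     # (S, n_nodes) subs/site

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.scalars.values())))

    def retained(self, burnin: Optional[int] = None) -> slice:
        b = self.config.burnin if burnin is None else burnin
        if b >= self.n_samples:
            raise ValueError("trace shorter than the requested burn-in")
        return slice(b, self.n_samples)

    def scalar_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scalars)

    def save(self, prefix: str) -> None:
        self.scalar_frame().to_csv(f"{prefix}.trace.tsv", sep="\t", index_label="sample")
        if self.trees is not None:
            with open(f"{prefix}.trees", "w") as fh:
                fh.write("\n".join(self.trees) + "\n")


# ---------------------------------------------------------------------------
# Topology proposals
# ---------------------------------------------------------------------------


def random_phylogram(
    taxa: Sequence[str], rng: np.random.Generator, bl_mean: float = 0.1
) -> Phylogram:
    """Random rooted binary topology (sequential joins) with exp lengths."""
    nodes = [Node(t, float(rng.exponential(bl_mean))) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(None, float(rng.exponential(bl_mean)))
        merged.add_child(nodes[i])
        merged.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = None
    tree = Phylogram(root)
    tree.validate()
    return tree


def _copy_phylogram(tree: Phylogram) -> Phylogram:
    def rec(node: Node) -> Node:
        new = Node(node.name, node.length)
        new.support = node.support
        for c in node.children:
            new.add_child(rec(c))
        return new

    return Phylogram(rec(tree.root))


def propose_nni(
    tree: Phylogram, rng: np.random.Generator
) -> Optional[Tuple[Phylogram, float]]:
    """Nearest-neighbour interchange: swap a child of an internal node with
    one of that node's siblings.  Symmetric proposal (log Hastings = 0)."""
    new = _copy_phylogram(tree)
    eligible = [
        n for n in new.postorder() if not n.is_leaf and n.parent is not None
    ]
    if not eligible:
        return None
    v = eligible[rng.integers(len(eligible))]
    u = v.parent
    a = v.children[rng.integers(len(v.children))]
    siblings = [c for c in u.children if c is not v]
    s = siblings[rng.integers(len(siblings))]
    v.children[v.children.index(a)] = s
    u.children[u.children.index(s)] = a
    s.parent, a.parent = v, u
    return new, 0.0


def propose_reroot(
    tree: Phylogram, rng: np.random.Generator
) -> Optional[Tuple[Phylogram, float]]:
    """Move the root onto a uniformly chosen edge, at a uniform position.

    Under a reversible substitution model the likelihood is invariant, so
    this move lets the chain mix over root placements that the data cannot
    distinguish.  A degree-two old root is suppressed (its incident edges
    merged); the Hastings term is the ratio of the split and merged edge
    lengths.
    """
    if len(tree.root.children) != 2:
        return None  # the move operates within binary-rooted tree space
    new = _copy_phylogram(tree)
    edges = [
        n
        for n in new.postorder()
        if n.parent is not None and (n.length or 0.0) > 0
    ]
    if not edges:
        return None
    e = edges[rng.integers(len(edges))]
    if e.parent is new.root:
        # splitting a root-adjacent edge re-creates the same rooting
        return None
    le = float(e.length)
    u = float(rng.random())
    merged_len = sum(float(c.length or 0.0) for c in new.root.children)
    if merged_len <= 0:
        return None

    # reverse the parent path from e's parent up to the old root
    path = []
    node = e.parent
    while node is not None:
        path.append(node)
        node = node.parent
    orig_len = {id(n): float(n.length or 0.0) for n in path}
    for a in path[:-1]:
        a.parent.children.remove(a)
    p = path[0]
    p.children.remove(e)

    root = Node()
    root.add_child(e)
    e.length = u * le
    root.add_child(p)
    p.length = (1.0 - u) * le
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        if i + 1 == len(path) - 1 and len(b.children) == 1:
            # suppress the degree-two old root: merge its remaining edge
            c = b.children[0]
            a.add_child(c)
            c.length = float(c.length or 0.0) + orig_len[id(a)]
        else:
            a.add_child(b)
            b.length = orig_len[id(a)]
    out = Phylogram(root)
    out.validate()
    return out, math.log(le / merged_len)


def propose_spr(
    tree: Phylogram, rng: np.random.Generator
) -> Optional[Tuple[Phylogram, float]]:
    """Subtree prune-and-regraft with uniform edge choice and uniform
    position on the target edge; the Hastings term accounts for the edge
    lengths at the detach and attach sites."""
    new = _copy_phylogram(tree)
    candidates = [
        n
        for n in new.postorder()
        if n.parent is not None and n.parent.parent is not None
        and len(n.parent.children) == 2
    ]
    if not candidates:
        return None
    s = candidates[rng.integers(len(candidates))]
    p = s.parent
    g = p.parent
    t = next(c for c in p.children if c is not s)
    merged_len = (t.length or 0.0) + (p.length or 0.0)
    # detach p, splice t into g
    g.children[g.children.index(p)] = t
    t.parent = g
    t.length = merged_len

    forbidden = set(id(n) for n in s.postorder())
    edges = [
        n
        for n in new.postorder()
        if n.parent is not None and id(n) not in forbidden and (n.length or 0.0) > 0
    ]
    if not edges or merged_len <= 0:
        return None
    e = edges[rng.integers(len(edges))]
    le = e.length
    u = float(rng.random())
    holder = e.parent
    p.children = []
    holder.children[holder.children.index(e)] = p
    p.parent = holder
    p.length = (1.0 - u) * le
    e.length = u * le
    p.add_child(e)
    p.add_child(s)
    log_hastings = math.log(le / merged_len)
    return new, log_hastings


# ---------------------------------------------------------------------------
# Phylogram-mode sampler
# ---------------------------------------------------------------------------


@dataclass
class PhyloInferenceSpec:
    """Model/move configuration for topology + branch-length inference."""

    model: str = "poisson"            # poisson, f81, lg, wag, gtr, cat-f81, cat-gtr
    alpha: Optional[float] = 1.0      # initial gamma shape; None -> no gamma
    estimate_alpha: bool = True
    ncat: int = 4
    bl_prior_mean: float = 0.1
    n_branch_moves: int = 10
    n_topology_moves: int = 2
    likelihood: bool = True
    mode: str = field(default="phylogram", init=False)

    def is_cat(self) -> bool:
        return self.model.startswith("cat")


def _empirical_freqs(codes_by_taxon: Dict[str, np.ndarray]) -> np.ndarray:
    counts = np.zeros(subst.N_STATES)
    for codes in codes_by_taxon.values():
        obs = codes[codes >= 0]
        counts += np.bincount(obs, minlength=subst.N_STATES)
    return (counts + 1.0) / (counts.sum() + subst.N_STATES)


class _PhylogramState:
    def __init__(self, spec, codes, rng):
        self.spec = spec
        self.codes = codes
        taxa = sorted(codes)
        self.tree = random_phylogram(taxa, rng, spec.bl_prior_mean)
        self.alpha = spec.alpha
        self.cat: Optional[catmod.CATMixtureState] = None
        freqs = _empirical_freqs(codes)
        uniform_exch = np.ones((subst.N_STATES, subst.N_STATES)) - np.eye(subst.N_STATES)
        if spec.model == "gtr":
            self.exch = uniform_exch.copy()
            self.freqs = freqs
        elif spec.model in ("lg", "wag"):
            self.exch, self.freqs = subst.load_empirical_model(spec.model)
        elif spec.model == "f81":
            self.exch, self.freqs = uniform_exch, freqs
        elif spec.model == "poisson":
            self.exch = uniform_exch
            self.freqs = np.full(subst.N_STATES, 1.0 / subst.N_STATES)
        elif spec.is_cat():
            exch = uniform_exch
            if spec.model == "cat-gtr":
                exch, _ = subst.load_empirical_model("lg")  # informative start
            self.cat = catmod.initial_cat_state(
                codes, exch=exch, alpha=self.alpha, ncat=spec.ncat
            )
            self.exch, self.freqs = exch, freqs
        else:
            raise ValueError(f"unknown model {spec.model!r}")

    def model_obj(self) -> subst.SubstModel:
        return subst.SubstModel("m", self.exch, self.freqs, self.alpha, self.spec.ncat)

    def loglik(self, tree=None) -> float:
        if not self.spec.likelihood:
            return 0.0
        tree = tree or self.tree
        if self.cat is not None:
            self.cat.alpha = self.alpha
            return catmod.cat_log_likelihood(tree, self.codes, self.cat)
        return subst.log_likelihood(tree, self.codes, self.model_obj())

    def logprior(self, tree=None, alpha=None) -> float:
        tree = tree or self.tree
        alpha = self.alpha if alpha is None else alpha
        mean = self.spec.bl_prior_mean
        total = 0.0
        for n in tree.postorder():
            if n.parent is None:
                continue
            b = n.length or 0.0
            if b < 0:
                return -math.inf
            total += -b / mean - math.log(mean)
        if alpha is not None:
            if not (0.01 <= alpha <= 100.0):
                return -math.inf
            total += -math.log(alpha)  # log-uniform on [0.01, 100]
        return total


def run_phylogram_chain(
    codes_by_taxon: Dict[str, np.ndarray],
    spec: PhyloInferenceSpec,
    config: ChainConfig,
) -> PosteriorTrace:
    """Sample topology, branch lengths and substitution parameters."""
    rng = np.random.default_rng(config.rng_seed)
    for _attempt in range(20):
        state = _PhylogramState(spec, codes_by_taxon, rng)
        cur_ll = state.loglik()
        cur_lp = state.logprior()
        if math.isfinite(cur_ll + cur_lp):
            break
    else:
        raise RuntimeError("could not find a finite-posterior initial state")

    scalars: Dict[str, List[float]] = {
        "lnL": [], "lnPrior": [], "alpha": [], "tree_length": [], "n_components": [],
    }
    trees: List[str] = []
    params: List[dict] = []

    def mh_tree(new_tree, log_hastings):
        nonlocal cur_ll, cur_lp
        new_lp = state.logprior(tree=new_tree)
        if not math.isfinite(new_lp):
            return
        new_ll = state.loglik(tree=new_tree)
        if math.log(rng.random() + 1e-300) < (new_ll + new_lp - cur_ll - cur_lp + log_hastings):
            state.tree = new_tree
            cur_ll, cur_lp = new_ll, new_lp

    branch_nodes = lambda: [n for n in state.tree.postorder() if n.parent is not None]

    for cycle in range(1, config.cycles + 1):
        # branch-length multipliers
        for _ in range(spec.n_branch_moves):
            nodes = branch_nodes()
            node = nodes[rng.integers(len(nodes))]
            old = node.length or 1e-9
            factor = math.exp(0.8 * (rng.random() - 0.5))
            node.length = old * factor
            new_lp = state.logprior()
            new_ll = state.loglik()
            if math.log(rng.random() + 1e-300) < (
                new_ll + new_lp - cur_ll - cur_lp + math.log(factor)
            ):
                cur_ll, cur_lp = new_ll, new_lp
            else:
                node.length = old
        # topology moves
        if state.tree.n_leaves() >= 3:
            for _ in range(spec.n_topology_moves):
                prop = propose_nni(state.tree, rng)
                if prop:
                    mh_tree(*prop)
            prop = propose_spr(state.tree, rng)
            if prop:
                mh_tree(*prop)
            prop = propose_reroot(state.tree, rng)
            if prop:
                mh_tree(*prop)
        # gamma shape
        if spec.estimate_alpha and state.alpha is not None:
            old_a = state.alpha
            factor = math.exp(0.5 * (rng.random() - 0.5))
            new_a = old_a * factor
            new_lp = state.logprior(alpha=new_a)
            if math.isfinite(new_lp):
                state.alpha = new_a
                if state.cat is not None:
                    state.cat.alpha = new_a
                new_ll = state.loglik()
                if math.log(rng.random() + 1e-300) < (
                    new_ll + new_lp - cur_ll - cur_lp + math.log(factor)
                ):
                    cur_ll, cur_lp = new_ll, new_lp
                else:
                    state.alpha = old_a
                    if state.cat is not None:
                        state.cat.alpha = old_a
        # GTR parameter moves
        if spec.model == "gtr":
            iu = np.triu_indices(subst.N_STATES, k=1)
            for _ in range(3):
                k = rng.integers(len(iu[0]))
                i, j = int(iu[0][k]), int(iu[1][k])
                old = state.exch[i, j]
                factor = math.exp(1.0 * (rng.random() - 0.5))
                newv = old * factor
                state.exch[i, j] = state.exch[j, i] = newv
                # exp(1) prior on each exchangeability
                new_ll = state.loglik()
                dprior = -(newv - old)
                if math.log(rng.random() + 1e-300) < (
                    new_ll - cur_ll + dprior + math.log(factor)
                ):
                    cur_ll = new_ll
                    cur_lp += dprior
                else:
                    state.exch[i, j] = state.exch[j, i] = old
            # frequency move: Dirichlet proposal centred on current
            conc = 1000.0
            old_f = state.freqs
            prop_f = rng.dirichlet(conc * old_f + 1e-6)
            prop_f = np.clip(prop_f, 1e-8, None)
            prop_f /= prop_f.sum()
            from scipy.stats import dirichlet as _dir

            state.freqs = prop_f
            new_ll = state.loglik()
            lh = _dir.logpdf(old_f, conc * prop_f + 1e-6) - _dir.logpdf(
                prop_f, conc * old_f + 1e-6
            )
            if math.log(rng.random() + 1e-300) < (new_ll - cur_ll + lh):
                cur_ll = new_ll
            else:
                state.freqs = old_f
        # CAT sweeps
        if state.cat is not None:
            state.cat = catmod.cat_gibbs_sweep(state.cat, state.tree, codes_by_taxon, rng)
            state.cat, _ = catmod.sample_component_profiles(
                state.cat, state.tree, codes_by_taxon, rng
            )
            state.cat = catmod.sample_concentration(state.cat, rng)
            cur_ll = state.loglik()

        if cycle % config.thin == 0:
            scalars["lnL"].append(cur_ll)
            scalars["lnPrior"].append(cur_lp)
            scalars["alpha"].append(state.alpha if state.alpha is not None else np.nan)
            scalars["tree_length"].append(state.tree.total_length())
            scalars["n_components"].append(
                state.cat.n_components() if state.cat else 1
            )
            trees.append(write_newick(state.tree, supports=False))
            entry = {"alpha": state.alpha, "freqs": state.freqs.copy(), "exch": state.exch.copy()}
            if state.cat is not None:
                counts = np.bincount(
                    state.cat.allocations, minlength=state.cat.n_components()
                ).astype(float)
                entry["profiles"] = np.vstack(state.cat.profiles)
                entry["weights"] = counts / counts.sum()
            params.append(entry)

    return PosteriorTrace(
        mode="phylogram",
        config=config,
        model_name=spec.model,
        scalars={k: np.array(v) for k, v in scalars.items()},
        trees=trees,
        param_samples=params,
    )


# ---------------------------------------------------------------------------
# Chronogram-mode (dating) sampler
# ---------------------------------------------------------------------------


@dataclass
class DatingSpec:
    """Configuration for fixed-topology relaxed-clock dating."""

    clock: clk.ClockModel
    bd: clk.BirthDeathPrior
    root_prior: clk.RootPrior
    calibrations: Sequence[clk.CalibrationConstraint] = ()
    subst_model: Optional[subst.SubstModel] = None
    likelihood: bool = True
    estimate_hyper: bool = True
    estimate_mu_rate: bool = True
    sample_bd: bool = False
    branch_rate_mode: str = "arithmetic"
    mu_prior_logmean: float = math.log(0.005)
    mu_prior_logsd: float = 3.0
    hyper_prior_mean: float = 1.0      # exp prior mean for sigma2 / nu
    bd_birth_prior_mean: float = 0.1
    bd_death_prior_mean: float = 0.05
    mode: str = field(default="chronogram", init=False)


class _DatingState:
    """Indexed arrays over the fixed topology (postorder; root last)."""

    def __init__(self, chrono: Chronogram, spec: DatingSpec, codes, rng):
        self.spec = spec
        self.nodes = list(chrono.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent else -1 for n in self.nodes]
        )
        self.is_leaf = np.array([n.is_leaf for n in self.nodes])
        self.n = len(self.nodes)
        self.root = self.n - 1
        self.children = [[] for _ in range(self.n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.leaf_name = {
            i: n.name for i, n in enumerate(self.nodes) if n.is_leaf
        }
        clade_sets: List[FrozenSet[str]] = [None] * self.n
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                clade_sets[i] = frozenset([node.name])
            else:
                acc = set()
                for c in self.children[i]:
                    acc |= clade_sets[c]
                clade_sets[i] = frozenset(acc)
        self.clades = clade_sets
        self.ages = np.array([float(n.age) for n in self.nodes])
        kind = spec.clock.kind
        self.mu_rate = spec.clock.mu_rate
        self.sigma2 = spec.clock.sigma2
        self.nu = spec.clock.nu
        self.lam = spec.bd.birth
        self.mu_death = spec.bd.death
        if kind == "ln":
            self.rates = np.full(self.n, self.mu_rate)
        elif kind == "ugam":
            self.rates = np.full(self.n, self.mu_rate)  # per-branch (node below)
        else:
            self.rates = None
        # map calibrations to MRCA node index
        self.descendants: List[List[int]] = [[] for _ in range(self.n)]
        for i in range(self.n):  # postorder: children first
            acc = [i]
            for c in self.children[i]:
                acc.extend(self.descendants[c])
            self.descendants[i] = acc
        self.cal_nodes: List[Tuple[int, clk.CalibrationConstraint]] = []
        for cal in spec.calibrations:
            hits = [
                i
                for i in range(self.n)
                if not self.is_leaf[i] and cal.taxa <= self.clades[i]
            ]
            if not hits:
                raise ValueError(f"calibration {cal.name}: taxa not in the tree")
            mrca = min(hits, key=lambda i: len(self.clades[i]))
            self.cal_nodes.append((mrca, cal))

        self.engine: Optional[subst.FixedTopologyLikelihood] = None
        if spec.likelihood:
            if spec.subst_model is None or codes is None:
                raise ValueError("likelihood on: need data and a substitution model")
            leaf_codes = {i: codes[self.leaf_name[i]] for i in self.leaf_name}
            self.engine = subst.FixedTopologyLikelihood(
                self.nodes, self.parent, leaf_codes, spec.subst_model
            )

    # -- derived quantities -------------------------------------------------
    def durations(self) -> np.ndarray:
        out = np.zeros(self.n)
        nz = self.parent >= 0
        out[nz] = self.ages[self.parent[nz]] - self.ages[nz]
        return out

    def effective_rates(self) -> np.ndarray:
        kind = self.spec.clock.kind
        if kind == "cl":
            out = np.full(self.n, self.mu_rate)
            out[self.root] = 0.0
            return out
        if kind == "ln":
            return clk.ln_branch_rates(
                self.rates, self.parent, self.spec.branch_rate_mode
            )
        out = self.rates.copy()
        out[self.root] = 0.0
        return out

    def branch_lengths(self) -> np.ndarray:
        return self.durations() * self.effective_rates()

    def log_prior(self) -> float:
        s = self.spec
        total = clk.birthdeath_ages_logdensity_arrays(
            self.ages, self.parent, self.is_leaf, self.lam, self.mu_death
        )
        if not math.isfinite(total):
            return -math.inf
        total += clk.root_prior_logdensity(self.ages[self.root], s.root_prior)
        for idx, cal in self.cal_nodes:
            total += clk.calibration_logfactor(float(self.ages[idx]), cal)
        kind = s.clock.kind
        if kind == "ln":
            total += clk.ln_clock_logdensity(
                self.ages, self.rates, self.parent, self.sigma2,
                self.mu_rate, s.clock.root_spread,
            )
            total += -self.sigma2 / s.hyper_prior_mean
        elif kind == "ugam":
            branch = self.rates[np.arange(self.n) != self.root]
            total += clk.ugam_clock_logdensity(branch, self.nu, self.mu_rate)
            total += -self.nu / s.hyper_prior_mean
        z = (math.log(self.mu_rate) - s.mu_prior_logmean) / s.mu_prior_logsd
        total += -0.5 * z * z - math.log(self.mu_rate)
        if s.sample_bd:
            total += -self.lam / s.bd_birth_prior_mean
            total += -self.mu_death / s.bd_death_prior_mean
        return total


def run_dating_chain(
    codes_by_taxon: Optional[Dict[str, np.ndarray]],
    chrono_init: Chronogram,
    spec: DatingSpec,
    config: ChainConfig,
) -> PosteriorTrace:
    """Fixed-topology dating: sample node ages, rates and hyperparameters."""
    rng = np.random.default_rng(config.rng_seed)
    state = None
    for attempt in range(25):
        candidate = _DatingState(chrono_init, spec, codes_by_taxon, rng)
        if attempt > 0:
            _redraw_ages(candidate, rng)
        if math.isfinite(candidate.log_prior()):
            state = candidate
            break
    if state is None:
        raise RuntimeError("no finite-prior initial state after retries")

    cur_lp = state.log_prior()
    cur_ll = 0.0
    if state.engine is not None:
        cur_ll = state.engine.set_lengths(state.branch_lengths())

    internal = [
        i for i in range(state.n) if not state.is_leaf[i] and i != state.root
    ]
    kind = spec.clock.kind

    def lik_update(changed: Dict[int, float]) -> float:
        if state.engine is None:
            return 0.0
        return state.engine.update(changed)

    def lik_revert():
        if state.engine is not None:
            state.engine.revert()

    def lik_accept():
        if state.engine is not None:
            state.engine.accept()

    def affected_branches(node_idx: int) -> List[int]:
        out = [c for c in state.children[node_idx]]
        if node_idx != state.root:
            out.append(node_idx)
        return out

    def try_move(log_hastings: float, changed_nodes: List[int], undo: Callable):
        nonlocal cur_lp, cur_ll
        new_lp = state.log_prior()
        if not math.isfinite(new_lp):
            undo()
            return False
        blens = state.branch_lengths()
        changed = {i: blens[i] for i in changed_nodes if state.parent[i] >= 0}
        new_ll = lik_update(changed)
        if math.log(rng.random() + 1e-300) < (
            new_ll + new_lp - cur_ll - cur_lp + log_hastings
        ):
            cur_lp, cur_ll = new_lp, new_ll
            lik_accept()
            return True
        lik_revert()
        undo()
        return False

    scalars: Dict[str, List[float]] = {
        "lnL": [], "lnPrior": [], "root_age": [], "mu_rate": [],
        "sigma2": [], "nu": [], "birth": [],
    }
    age_rows, rate_rows, blen_rows = [], [], []

    for cycle in range(1, config.cycles + 1):
        # node-age slides
        for i in internal:
            lo = max(state.ages[c] for c in state.children[i])
            hi = state.ages[state.parent[i]]
            if hi <= lo:
                continue
            old = state.ages[i]
            state.ages[i] = lo + (hi - lo) * rng.random()
            affected = affected_branches(i)

            def undo(i=i, old=old):
                state.ages[i] = old

            try_move(0.0, affected, undo)
        # root-age gap move
        i = state.root
        lo = max(state.ages[c] for c in state.children[i])
        gap = state.ages[i] - lo
        if gap > 0:
            delta = 0.6 * (rng.random() - 0.5)
            old = state.ages[i]
            state.ages[i] = lo + gap * math.exp(delta)

            def undo_root(old=old):
                state.ages[i] = old

            try_move(delta, affected_branches(i), undo_root)
        # independence root proposal from the truncated exponential prior
        # (proposal density cancels the root-prior factor in the ratio)
        lo = max(state.ages[c] for c in state.children[i])
        old = state.ages[i]
        state.ages[i] = lo + rng.exponential(spec.root_prior.mean)

        def undo_root2(old=old):
            state.ages[i] = old

        try_move(
            (state.ages[i] - old) / spec.root_prior.mean,
            affected_branches(i),
            undo_root2,
        )
        # joint scaling of all internal ages: with the likelihood on this
        # changes every branch length (full re-peel, almost always
        # rejected), so it is used only in prior-only runs — the joint
        # rate-time rescale below covers the scale direction otherwise
        if state.engine is None:
            delta = 0.3 * (rng.random() - 0.5)
            c = math.exp(delta)
            old_ages = state.ages.copy()
            mask = ~state.is_leaf
            state.ages[mask] = state.ages[mask] * c

            def undo_scale(old_ages=old_ages):
                state.ages[:] = old_ages

            try_move(int(mask.sum()) * delta, list(range(state.n)), undo_scale)

        # joint rate-time rescale: ages x c, rates / c leaves every branch
        # length (and hence the likelihood) unchanged, letting the chain
        # travel along the rate/time ridge that single-parameter moves
        # cannot cross
        if kind in ("ln", "ugam") or spec.estimate_mu_rate:
            # likelihood-free, so several repeats per cycle are nearly free
            for _ in range(5):
                delta = 0.4 * (rng.random() - 0.5)
                c = math.exp(delta)
                old_ages = state.ages.copy()
                mask = ~state.is_leaf
                state.ages[mask] = state.ages[mask] * c
                if kind == "cl":
                    old_rates, n_rates = state.mu_rate, 1
                    state.mu_rate = state.mu_rate / c
                else:
                    old_rates = state.rates.copy()
                    state.rates = state.rates / c
                    n_rates = state.n if kind == "ln" else state.n - 1

                def undo_rescale(old_ages=old_ages, old_rates=old_rates):
                    state.ages[:] = old_ages
                    if kind == "cl":
                        state.mu_rate = old_rates
                    else:
                        state.rates = old_rates

                try_move((int(mask.sum()) - n_rates) * delta, [], undo_rescale)

        # local rate-time rescale per subtree: ages of the subtree's internal
        # nodes x c, its rates / c — every branch length inside the subtree
        # is invariant, so only the stem branch needs re-peeling; this is
        # what lets a mis-scaled subtree slide along its own rate/time ridge
        if kind in ("ln", "ugam"):
            for v in internal:
                sub = state.descendants[v]
                sub_internal = [i for i in sub if not state.is_leaf[i]]
                delta = 0.5 * (rng.random() - 0.5)
                c = math.exp(delta)
                if state.ages[v] * c >= state.ages[state.parent[v]]:
                    continue
                old_ages = state.ages[sub_internal].copy()
                state.ages[sub_internal] = state.ages[sub_internal] * c
                if kind == "ln":
                    rate_set = sub
                else:
                    rate_set = [i for i in sub if i != v]
                old_rates = state.rates[rate_set].copy()
                state.rates[rate_set] = state.rates[rate_set] / c

                def undo_sub(si=sub_internal, rs=rate_set, oa=old_ages, orr=old_rates):
                    state.ages[si] = oa
                    state.rates[rs] = orr

                jac = (len(sub_internal) - len(rate_set)) * delta
                try_move(jac, [v], undo_sub)

        # rate moves
        if kind in ("ln", "ugam"):
            order = rng.permutation(state.n)
            for i in order:
                if kind == "ugam" and i == state.root:
                    continue
                old = state.rates[i]
                delta = 0.7 * (rng.random() - 0.5)
                state.rates[i] = old * math.exp(delta)
                affected = affected_branches(i) if kind == "ln" else [i]

                def undo_rate(i=i, old=old):
                    state.rates[i] = old

                try_move(delta, affected, undo_rate)
        # mean-rate move
        if spec.estimate_mu_rate:
            old = state.mu_rate
            delta = 0.5 * (rng.random() - 0.5)
            state.mu_rate = old * math.exp(delta)
            changed_nodes = list(range(state.n)) if kind == "cl" else []

            def undo_mu(old=old):
                state.mu_rate = old

            try_move(delta, changed_nodes, undo_mu)
        # clock-variance hyperparameter
        if spec.estimate_hyper and kind in ("ln", "ugam"):
            attr = "sigma2" if kind == "ln" else "nu"
            old = getattr(state, attr)
            if old > 0:
                delta = 0.5 * (rng.random() - 0.5)
                setattr(state, attr, old * math.exp(delta))

                def undo_h(attr=attr, old=old):
                    setattr(state, attr, old)

                try_move(delta, [], undo_h)
        # birth-death hyperparameters
        if spec.sample_bd:
            for attr in ("lam", "mu_death"):
                old = getattr(state, attr)
                if old <= 0:
                    continue
                delta = 0.5 * (rng.random() - 0.5)
                setattr(state, attr, old * math.exp(delta))

                def undo_bd(attr=attr, old=old):
                    setattr(state, attr, old)

                try_move(delta, [], undo_bd)

        # periodic from-scratch likelihood guard against incremental drift
        if state.engine is not None and cycle % 1000 == 0:
            fresh = state.engine.set_lengths(state.branch_lengths())
            if math.isfinite(cur_ll) and abs(fresh - cur_ll) > 1e-6 * max(1.0, abs(fresh)):
                raise RuntimeError(
                    f"incremental likelihood drifted: {cur_ll} vs {fresh}"
                )
            cur_ll = fresh

        if cycle % config.thin == 0:
            scalars["lnL"].append(cur_ll)
            scalars["lnPrior"].append(cur_lp)
            scalars["root_age"].append(float(state.ages[state.root]))
            scalars["mu_rate"].append(state.mu_rate)
            scalars["sigma2"].append(state.sigma2)
            scalars["nu"].append(state.nu)
            scalars["birth"].append(state.lam)
            age_rows.append(state.ages.copy())
            rate_rows.append(state.effective_rates())
            blen_rows.append(state.branch_lengths())

    return PosteriorTrace(
        mode="chronogram",
        config=config,
        model_name=f"{spec.clock.kind}",
        scalars={k: np.array(v) for k, v in scalars.items()},
        topology=write_newick(Phylogram(chrono_init.root), lengths=False),
        clades=state.clades,
        leaf_names=[
            state.leaf_name.get(i) for i in range(state.n)
        ],
        ages=np.vstack(age_rows),
        branch_rates=np.vstack(rate_rows),
        branch_lengths=np.vstack(blen_rows),
    )


def _redraw_ages(state: "_DatingState", rng: np.random.Generator) -> None:
    """Hierarchical age redraw consistent with the calibration plateaus."""
    cal_by_node = {i: c for i, c in state.cal_nodes}
    floor = np.zeros(state.n)
    for i in range(state.n):  # postorder: children first
        if state.is_leaf[i]:
            continue
        lo = max((floor[c] for c in state.children[i]), default=0.0) + 1.0
        cal = cal_by_node.get(i)
        if cal is not None and cal.min_age is not None:
            lo = max(lo, cal.min_age)
        floor[i] = lo
    order = sorted(
        [i for i in range(state.n) if not state.is_leaf[i]],
        key=lambda i: -len(state.clades[i]),
    )
    for i in order:
        p = state.parent[i]
        hi = state.ages[p] - 1.0 if p >= 0 else max(
            floor[i] * 1.2, state.spec.root_prior.mean
        )
        cal = cal_by_node.get(i)
        if cal is not None and cal.max_age is not None:
            hi = min(hi, cal.max_age)
        lo = floor[i]
        state.ages[i] = lo if hi <= lo else lo + (hi - lo) * rng.random()


def run_chain(data, spec, config: ChainConfig, **kw) -> PosteriorTrace:
    """Dispatch on spec.mode: phylogram inference or chronogram dating."""
    if spec.mode == "phylogram":
        return run_phylogram_chain(data, spec, config)
    if spec.mode == "chronogram":
        return run_dating_chain(data, kw["chrono_init"], spec, config)
    raise ValueError(f"unknown mode {spec.mode!r}")


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


def convergence_report(
    trace_a: PosteriorTrace,
    trace_b: PosteriorTrace,
    burnin: Optional[int] = None,
    *,
    clade_threshold: float = 0.3,
    scalar_threshold: float = 0.3,
) -> dict:
    """Two-chain convergence check: clade max_diff plus scalar discrepancies.

    Scalar parameters are compared by the relative difference of their
    post-burn-in means; tree samples by the maximum clade-frequency
    difference (the bpcomp-style criterion).
    """
    sl_a = trace_a.retained(burnin)
    sl_b = trace_b.retained(burnin)
    report: dict = {"max_diff": 0.0, "scalars": {}, "passed": True}
    if trace_a.trees is not None and trace_b.trees is not None:
        ta = [parse_newick(t) for t in trace_a.trees[sl_a]]
        tb = [parse_newick(t) for t in trace_b.trees[sl_b]]
        report["max_diff"] = max_clade_support_diff(ta, tb)
        if report["max_diff"] >= clade_threshold:
            report["passed"] = False
    for key in trace_a.scalars:
        if key not in trace_b.scalars:
            continue
        a = trace_a.scalars[key][sl_a]
        b = trace_b.scalars[key][sl_b]
        if np.isnan(a).all() or np.isnan(b).all():
            continue
        ma, mb = float(np.nanmean(a)), float(np.nanmean(b))
        denom = max(abs(ma), abs(mb), 1e-12)
        rel = abs(ma - mb) / denom
        report["scalars"][key] = rel
        if rel >= scalar_threshold and key in ("lnL",):
            report["passed"] = False
    return report
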