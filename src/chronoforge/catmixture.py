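"""Dirichlet-process CAT profile mixtures over alignment sites.

Each site is allocated to a mixture component carrying its own 20-state
equilibrium profile; exchangeabilities are shared across components (uniform
for CAT-F81, free for CAT-GTR).  Allocations are resampled by Gibbs sweeps
with auxiliary components (Neal's Algorithm-8 style, m = 3, with the
auxiliary profile pool drawn once per sweep); component profiles move by
Metropolis-Hastings with Dirichlet proposals; the concentration parameter
gets an exponential hyperprior (mean 10) and a log-scale random walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import substitution as subst
from .trees import Phylogram

__all__ = [
    "CATMixtureState",
    "initial_cat_state",
    "component_site_loglikelihoods",
    "cat_site_log_likelihoods",
    "cat_log_likelihood",
    "cat_gibbs_sweep",
    "sample_component_profiles",
    "sample_concentration",
]

#: auxiliary components per Gibbs sweep
M_AUX = 3
#: mean of the exponential hyperprior on the DP concentration
CONCENTRATION_PRIOR_MEAN = 10.0


@dataclass
class CATMixtureState:
    """Profiles, per-site allocations and hyperparameters of a CAT mixture."""

    profiles: List[np.ndarray]           # each a point on the 20-simplex
    allocations: np.ndarray              # site -> component index
    concentration: float
    exch: np.ndarray                     # shared exchangeabilities
    alpha: Optional[float] = None        # gamma shape (None: single rate)
    ncat: int = 4

    def validate(self) -> None:
        k = len(self.profiles)
        if k == 0:
            raise ValueError("need at least one component")
        if self.allocations.min() < 0 or self.allocations.max() >= k:
            raise ValueError("allocation outside component range")
        counts = np.bincount(self.allocations, minlength=k)
        if (counts == 0).any():
            raise ValueError("empty component present")
        if k > len(self.allocations):
            raise ValueError("more components than sites")
        for p in self.profiles:
            if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("profile off the simplex")

    def n_components(self) -> int:
        return len(self.profiles)

    def component_model(self, c: int) -> subst.SubstModel:
        return subst.SubstModel("cat-comp", self.exch, self.profiles[c], self.alpha, self.ncat)

    def site_freqs(self) -> np.ndarray:
        return np.vstack([self.profiles[c] for c in self.allocations])


def initial_cat_state(
    codes_by_taxon: Dict[str, np.ndarray],
    *,
    exch: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
    ncat: int = 4,
    concentration: float = 1.0,
    start: str = "per-site",
) -> CATMixtureState:
    """Initial mixture state.

    ``start='per-site'`` (default) gives every site its own component with a
    profile from the site's residue counts — Gibbs merges components far
    more readily than it splits them, so an over-dispersed start mixes
    better.  ``start='single'`` pools everything into one component at the
    global residue frequency.
    """
    n_sites = len(next(iter(codes_by_taxon.values())))
    if exch is None:
        exch = np.ones((subst.N_STATES, subst.N_STATES)) - np.eye(subst.N_STATES)
    if start == "single":
        counts = np.zeros(subst.N_STATES)
        for codes in codes_by_taxon.values():
            obs = codes[codes >= 0]
            counts += np.bincount(obs, minlength=subst.N_STATES)
        profile = (counts + 1.0) / (counts.sum() + subst.N_STATES)
        return CATMixtureState(
            [profile], np.zeros(n_sites, dtype=int), concentration, exch, alpha, ncat
        )
    if start != "per-site":
        raise ValueError("start must be 'per-site' or 'single'")
    profiles = []
    for i in range(n_sites):
        counts = np.zeros(subst.N_STATES)
        for codes in codes_by_taxon.values():
            c = codes[i]
            if c >= 0:
                counts[c] += 1.0
        profiles.append((counts + 0.5) / (counts.sum() + 0.5 * subst.N_STATES))
    return CATMixtureState(
        profiles, np.arange(n_sites, dtype=int), concentration, exch, alpha, ncat
    )


def component_site_loglikelihoods(
    tree: Phylogram,
    codes_by_taxon: Dict[str, np.ndarray],
    state: CATMixtureState,
    profiles: List[np.ndarray],
) -> np.ndarray:
    """Per-site log-likelihood of every site under each candidate profile.

    Returns an array (n_profiles, n_sites): one pruning pass per profile.
    """
    rows = []
    for p in profiles:
        model = subst.SubstModel("cat-comp", state.exch, p, state.alpha, state.ncat)
        rows.append(subst.site_log_likelihoods(tree, codes_by_taxon, model))
    return np.vstack(rows)


def cat_site_log_likelihoods(
    tree: Phylogram, codes_by_taxon: Dict[str, np.ndarray], state: CATMixtureState
) -> np.ndarray:
    """Per-site log-likelihoods under the current allocations."""
    n_sites = len(state.allocations)
    out = np.empty(n_sites)
    for c in range(state.n_components()):
        sites = np.where(state.allocations == c)[0]
        if len(sites) == 0:
            continue
        sub = {t: codes[sites] for t, codes in codes_by_taxon.items()}
        out[sites] = subst.site_log_likelihoods(tree, sub, state.component_model(c))
    return out


def cat_log_likelihood(tree, codes_by_taxon, state) -> float:
    return float(cat_site_log_likelihoods(tree, codes_by_taxon, state).sum())


def _single_site_loglik(
    tree: Phylogram,
    codes_by_taxon: Dict[str, np.ndarray],
    state: CATMixtureState,
    profile: np.ndarray,
    site: int,
) -> float:
    sub = {t: codes[site : site + 1] for t, codes in codes_by_taxon.items()}
    model = subst.SubstModel("cat-comp", state.exch, profile, state.alpha, state.ncat)
    return float(subst.site_log_likelihoods(tree, sub, model)[0])


def cat_gibbs_sweep(
    state: CATMixtureState,
    tree: Phylogram,
    codes_by_taxon: Dict[str, np.ndarray],
    rng: np.random.Generator,
    *,
    m_aux: int = M_AUX,
) -> CATMixtureState:
    """Resample every site's allocation from its full conditional.

    Existing components weigh size x site likelihood; new components weigh
    (concentration / m) x likelihood under m auxiliary profiles drawn fresh
    for each site from the symmetric Dirichlet(1) base measure (when a site
    is currently a singleton, its own profile fills the first auxiliary
    slot).  Empty components are removed afterwards.
    """
    n_sites = len(state.allocations)
    profiles = [p.copy() for p in state.profiles]
    alloc = state.allocations.copy()

    # likelihood of every site under every existing profile (one pruning
    # pass per profile); rows are extended as components are created
    logl = component_site_loglikelihoods(tree, codes_by_taxon, state, profiles)
    counts = np.bincount(alloc, minlength=len(profiles)).astype(float)

    for i in range(n_sites):
        c_old = int(alloc[i])
        counts[c_old] -= 1.0
        singleton = counts[c_old] == 0

        aux_profiles = [rng.dirichlet(np.ones(subst.N_STATES)) for _ in range(m_aux)]
        if singleton:
            aux_profiles[0] = profiles[c_old]
        aux_logl = [
            logl[c_old, i]
            if (singleton and j == 0)
            else _single_site_loglik(tree, codes_by_taxon, state, p, i)
            for j, p in enumerate(aux_profiles)
        ]

        cand_logw: List[float] = []
        cand_kind: List[Tuple[str, int]] = []
        for c in range(len(profiles)):
            if counts[c] > 0:
                cand_logw.append(math.log(counts[c]) + logl[c, i])
                cand_kind.append(("existing", c))
        for j in range(m_aux):
            cand_logw.append(math.log(state.concentration / m_aux) + aux_logl[j])
            cand_kind.append(("aux", j))

        logw = np.array(cand_logw)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        kind, ref = cand_kind[rng.choice(len(w), p=w)]
        if kind == "existing":
            alloc[i] = ref
            counts[ref] += 1.0
        elif singleton:
            # stay in (or repurpose) the singleton's own slot
            profiles[c_old] = np.asarray(aux_profiles[ref])
            new_row = (
                logl[c_old]
                if ref == 0
                else component_site_loglikelihoods(
                    tree, codes_by_taxon, state, [profiles[c_old]]
                )[0]
            )
            logl[c_old] = new_row
            alloc[i] = c_old
            counts[c_old] += 1.0
        else:
            profiles.append(np.asarray(aux_profiles[ref]))
            row = component_site_loglikelihoods(
                tree, codes_by_taxon, state, [profiles[-1]]
            )
            logl = np.vstack([logl, row])
            counts = np.append(counts, 1.0)
            alloc[i] = len(profiles) - 1

    keep = [c for c in range(len(profiles)) if counts[c] > 0]
    remap = {c: j for j, c in enumerate(keep)}
    new_state = CATMixtureState(
        [profiles[c] for c in keep],
        np.array([remap[c] for c in alloc], dtype=int),
        state.concentration,
        state.exch,
        state.alpha,
        state.ncat,
    )
    new_state.validate()
    return new_state


def sample_component_profiles(
    state: CATMixtureState,
    tree: Phylogram,
    codes_by_taxon: Dict[str, np.ndarray],
    rng: np.random.Generator,
    *,
    proposal_concentration: float = 300.0,
) -> Tuple[CATMixtureState, float]:
    """Metropolis-Hastings update of every component profile.

    Two proposal flavours alternate at random: a Dirichlet random walk
    centred on the current profile, and an independence draw from a
    Dirichlet fitted to the component's observed residue counts (a
    near-conjugate guess that mixes fast when the data are informative).
    Target: Dirichlet(1) base measure times the component-site likelihood.
    Returns the new state and the acceptance fraction.
    """
    from scipy.stats import dirichlet as _dirichlet

    profiles = [p.copy() for p in state.profiles]
    accepted = 0
    floor = 1e-8
    for c in range(len(profiles)):
        sites = np.where(state.allocations == c)[0]
        sub = {t: codes[sites] for t, codes in codes_by_taxon.items()}
        cur = profiles[c]
        cur_ll = float(
            subst.site_log_likelihoods(
                tree, sub, subst.SubstModel("c", state.exch, cur, state.alpha, state.ncat)
            ).sum()
        )
        if rng.random() < 0.5:
            a_fwd = proposal_concentration * cur + floor
            prop = rng.dirichlet(a_fwd)
            prop = np.clip(prop, floor, None)
            prop /= prop.sum()
            a_rev = proposal_concentration * prop + floor
            log_hastings = _dirichlet.logpdf(cur, a_rev) - _dirichlet.logpdf(
                prop, a_fwd
            )
        else:
            counts = np.zeros(subst.N_STATES)
            for codes in sub.values():
                obs = codes[codes >= 0]
                counts += np.bincount(obs, minlength=subst.N_STATES)
            a_ind = counts + 1.0
            prop = rng.dirichlet(a_ind)
            prop = np.clip(prop, floor, None)
            prop /= prop.sum()
            log_hastings = _dirichlet.logpdf(cur, a_ind) - _dirichlet.logpdf(
                prop, a_ind
            )
        prop_ll = float(
            subst.site_log_likelihoods(
                tree, sub, subst.SubstModel("c", state.exch, prop, state.alpha, state.ncat)
            ).sum()
        )
        # base measure Dirichlet(1) is flat on the simplex: no prior term
        if math.log(rng.random()) < (prop_ll - cur_ll) + log_hastings:
            profiles[c] = prop
            accepted += 1
    new_state = CATMixtureState(
        profiles,
        state.allocations.copy(),
        state.concentration,
        state.exch,
        state.alpha,
        state.ncat,
    )
    return new_state, accepted / max(len(profiles), 1)


def sample_concentration(
    state: CATMixtureState,
    rng: np.random.Generator,
    *,
    prior_mean: float = CONCENTRATION_PRIOR_MEAN,
    step: float = 0.5,
) -> CATMixtureState:
    """Log-scale random walk on the DP concentration.

    Target: exponential(prior_mean) prior times the Chinese-restaurant
    marginal  conc^K * Gamma(conc) / Gamma(conc + n).
    """
    n = len(state.allocations)
    k = state.n_components()

    def log_target(c: float) -> float:
        return (
            -c / prior_mean
            + k * math.log(c)
            + math.lgamma(c)
            - math.lgamma(c + n)
        )

    cur = state.concentration
    prop = cur * math.exp(step * (rng.random() - 0.5))
    log_acc = log_target(prop) - log_target(cur) + math.log(prop / cur)
    new = prop if math.log(rng.random()) < log_acc else cur
    return CATMixtureState(
        [p.copy() for p in state.profiles],
        state.allocations.copy(),
        new,
        state.exch,
        state.alpha,
        state.ncat,
    )
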