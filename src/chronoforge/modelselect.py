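"""Bayesian cross-validation for substitution- and clock-model comparison.

The data are split into learning and test sites (fixed counts, e.g.
10,000/2,000, or fractions, e.g. 90/10).  A posterior is sampled on the
learning sites; the cross-validation score of a model is the log of the
posterior-sample average of the test-site likelihood,

    score = ln[(1/S) * sum_s L(test | theta_s)],

computed with a running log-sum-exp.  Models are compared by paired
per-replicate score differences summarised as mean +/- sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from . import substitution as subst
from .mcmc import PosteriorTrace
from .trees import parse_newick

__all__ = [
    "CVSplit",
    "CVResult",
    "make_cv_splits",
    "predictive_logscore",
    "cv_predictive_score",
    "phylogram_sample_loglik",
    "dating_sample_loglik",
    "compare_models",
]


@dataclass
class CVSplit:
    replicate: int
    learning: np.ndarray
    test: np.ndarray
    seed: int

    def validate(self, n_sites: int) -> None:
        if len(self.learning) == 0 or len(self.test) == 0:
            raise ValueError("both site sets must be non-empty")
        if np.intersect1d(self.learning, self.test).size:
            raise ValueError("learning and test sites overlap")
        top = max(self.learning.max(), self.test.max())
        if top >= n_sites or min(self.learning.min(), self.test.min()) < 0:
            raise ValueError("site index out of bounds")


@dataclass
class CVResult:
    """Per-replicate score differences (model A minus model B)."""

    deltas: np.ndarray
    model_a: str = "A"
    model_b: str = "B"

    @property
    def mean(self) -> float:
        return float(self.deltas.mean())

    @property
    def sd(self) -> float:
        return float(self.deltas.std(ddof=1)) if len(self.deltas) > 1 else 0.0

    def __str__(self) -> str:
        return (
            f"dlnL({self.model_a} - {self.model_b}) = "
            f"{self.mean:.1f} +/- {self.sd:.1f} over {len(self.deltas)} replicates"
        )


def make_cv_splits(
    n_sites: int,
    scheme: Tuple,
    replicates: int = 10,
    seed: int = 0,
) -> List[CVSplit]:
    """Random learning/test site splits.

    ``scheme`` is ``('counts', n_learn, n_test)`` or
    ``('fractions', f_learn, f_test)``; fractions are rounded to the nearest
    site for the learning set, the test share taking the remainder of the
    requested coverage.  Sampling is uniform without replacement and
    reproducible by seed.
    """
    kind = scheme[0]
    if kind == "counts":
        n_learn, n_test = int(scheme[1]), int(scheme[2])
    elif kind == "fractions":
        f_learn, f_test = float(scheme[1]), float(scheme[2])
        if f_learn + f_test > 1.0 + 1e-9:
            raise ValueError("fractions exceed 1")
        n_learn = int(round(f_learn * n_sites))
        n_test = int(round((f_learn + f_test) * n_sites)) - n_learn
    else:
        raise ValueError("scheme must be 'counts' or 'fractions'")
    if n_learn + n_test > n_sites:
        raise ValueError("learning + test exceeds the available sites")
    if n_learn == 0 or n_test == 0:
        raise ValueError("both site sets must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        chosen = rng.choice(n_sites, size=n_learn + n_test, replace=False)
        split = CVSplit(rep, np.sort(chosen[:n_learn]), np.sort(chosen[n_learn:]), seed)
        split.validate(n_sites)
        out.append(split)
    return out


def predictive_logscore(sample_logliks: Iterable[float]) -> float:
    """log of the average likelihood over posterior samples (log-sum-exp)."""
    vals = np.asarray(list(sample_logliks), dtype=float)
    if vals.size == 0:
        raise ValueError("empty posterior sample")
    return float(logsumexp(vals) - math.log(vals.size))


def phylogram_sample_loglik(
    trace: PosteriorTrace,
    test_codes: Dict[str, np.ndarray],
    *,
    burnin: Optional[int] = None,
) -> np.ndarray:
    """Test-site log-likelihood at every retained phylogram sample.

    For CAT samples the test-site likelihood mixes the sampled components
    with their occupancy weights (a new-component term is omitted; with the
    concentrations involved its weight is negligible and the simplification
    is conservative across models compared on the same trace length).
    """
    sl = trace.retained(burnin)
    out = []
    for tree_str, params in zip(trace.trees[sl], trace.param_samples[sl]):
        tree = parse_newick(tree_str)
        if "profiles" in params:
            comp_logl = []
            for p, w in zip(params["profiles"], params["weights"]):
                model = subst.SubstModel(
                    "cat-comp", params["exch"], p, params["alpha"]
                )
                comp_logl.append(
                    math.log(max(w, 1e-300))
                    + subst.site_log_likelihoods(tree, test_codes, model)
                )
            site_log = logsumexp(np.vstack(comp_logl), axis=0)
            out.append(float(site_log.sum()))
        else:
            model = subst.SubstModel(
                "m", params["exch"], params["freqs"], params["alpha"]
            )
            out.append(
                float(subst.site_log_likelihoods(tree, test_codes, model).sum())
            )
    return np.array(out)


def dating_sample_loglik(
    trace: PosteriorTrace,
    test_codes: Dict[str, np.ndarray],
    model: subst.SubstModel,
    *,
    burnin: Optional[int] = None,
) -> np.ndarray:
    """Test-site log-likelihood at every retained dating sample.

    Each sample supplies branch lengths (rate x duration per branch) on the
    fixed topology.
    """
    sl = trace.retained(burnin)
    topo = parse_newick(trace.topology)
    post = list(topo.postorder())
    out = []
    for blens in trace.branch_lengths[sl]:
        for node, b in zip(post, blens):
            node.length = float(b) if node.parent is not None else None
        out.append(float(subst.site_log_likelihoods(topo, test_codes, model).sum()))
    return np.array(out)


def cv_predictive_score(
    trace: PosteriorTrace,
    test_codes: Dict[str, np.ndarray],
    *,
    model: Optional[subst.SubstModel] = None,
    burnin: Optional[int] = None,
    estimator: str = "log-mean",
) -> float:
    """Cross-validation score of one learning-set posterior on test sites.

    ``estimator='log-mean'`` (default) is the log of the posterior-averaged
    likelihood; ``'mean-log'`` averages the log-likelihoods instead.
    """
    if trace.mode == "phylogram":
        vals = phylogram_sample_loglik(trace, test_codes, burnin=burnin)
    else:
        if model is None:
            raise ValueError("dating traces need the substitution model")
        vals = dating_sample_loglik(trace, test_codes, model, burnin=burnin)
    if estimator == "log-mean":
        return predictive_logscore(vals)
    if estimator == "mean-log":
        return float(vals.mean())
    raise ValueError("estimator must be 'log-mean' or 'mean-log'")


def compare_models(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    model_a: str = "A",
    model_b: str = "B",
) -> CVResult:
    """Paired per-replicate comparison (A minus B), mean +/- sample SD."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate score lists must pair up")
    return CVResult(a - b, model_a, model_b)
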