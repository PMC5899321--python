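"""Relaxed molecular clocks and node-age priors for divergence dating.

Three clock models: strict (CL), autocorrelated log-normal (LN) and
uncorrelated gamma (UGAM).  Node ages carry a birth-death prior conditional
on the root age; the root age gets an exponential prior; fossil information
enters through *soft* calibration bounds — flat on the allowed interval with
exponential tails holding a small mass fraction outside each bound.

Conventions: time in Mya before present, tips at age 0; rates in
substitutions/site/Mya.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .trees import Chronogram

__all__ = [
    "ClockModel",
    "BirthDeathPrior",
    "CalibrationConstraint",
    "RootPrior",
    "ln_clock_logdensity",
    "ln_branch_rates",
    "ugam_clock_logdensity",
    "bd_kernel_logpdf",
    "bd_kernel_cdf",
    "bd_kernel_ppf",
    "birthdeath_ages_logdensity",
    "calibration_logfactor",
    "root_prior_logdensity",
    "load_calibrations",
    "save_calibrations",
    "paper_calibrations",
]


@dataclass
class ClockModel:
    """Clock-relaxation model: 'cl', 'ln' (sigma2 per Mya) or 'ugam' (nu)."""

    kind: str
    mu_rate: float
    sigma2: float = 0.0
    nu: float = 0.0
    root_spread: float = 1.0  # sd of ln(root rate) around ln(mu_rate), LN model

    def __post_init__(self):
        if self.kind not in ("cl", "ln", "ugam"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.mu_rate <= 0 or self.sigma2 < 0 or self.nu < 0:
            raise ValueError("invalid clock parameters")


@dataclass
class BirthDeathPrior:
    """Birth-death node-age prior (rates per lineage per Mya)."""

    birth: float
    death: float = 0.0

    def __post_init__(self):
        if self.birth < 0 or self.death < 0 or self.death > self.birth:
            raise ValueError("need birth >= death >= 0")


@dataclass
class RootPrior:
    mean: float  # Mya

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("root prior mean must be positive")


@dataclass
class CalibrationConstraint:
    """Soft fossil bounds on the age of the MRCA of ``taxa``."""

    name: str
    taxa: FrozenSet[str]
    min_age: Optional[float] = None
    max_age: Optional[float] = None
    tail_prob: float = 0.025

    def __post_init__(self):
        self.taxa = frozenset(self.taxa)
        if not self.taxa:
            raise ValueError(f"calibration {self.name}: empty taxon set")
        if self.min_age is None and self.max_age is None:
            raise ValueError(f"calibration {self.name}: needs at least one bound")
        if (
            self.min_age is not None
            and self.max_age is not None
            and not self.min_age < self.max_age
        ):
            raise ValueError(f"calibration {self.name}: min must be below max")
        if not 0.0 < self.tail_prob < 0.5:
            raise ValueError("tail probability must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# Clock densities (array form: nodes in postorder, parent[-1] root)
# ---------------------------------------------------------------------------


def _lognormal_logpdf(x: float, mu: float, sd: float) -> float:
    if x <= 0 or sd <= 0:
        return -math.inf
    z = (math.log(x) - mu) / sd
    return -math.log(x * sd * math.sqrt(2 * math.pi)) - 0.5 * z * z


def ln_clock_logdensity(
    ages: np.ndarray,
    rates: np.ndarray,
    parent: np.ndarray,
    sigma2: float,
    mu_rate: float,
    root_spread: float = 1.0,
) -> float:
    """Autocorrelated log-normal clock: per-node instantaneous rates.

    ln r_child ~ Normal(ln r_parent - sigma2*dt/2, sigma2*dt) with dt the
    parent-child time gap; the -sigma2*dt/2 mean correction keeps
    E[r_child | r_parent] = r_parent.  The root rate is
    LogNormal(ln mu_rate, root_spread).
    """
    if (rates <= 0).any():
        return -math.inf
    root = int(np.where(parent < 0)[0][0])
    total = _lognormal_logpdf(float(rates[root]), math.log(mu_rate), root_spread)
    nz = parent >= 0
    dt = ages[parent[nz]] - ages[nz]
    if (dt < 0).any():
        return -math.inf
    r_child = rates[nz]
    r_parent = rates[parent[nz]]
    degen = (dt == 0) | (sigma2 == 0)
    if degen.any():
        if not np.allclose(r_child[degen], r_parent[degen], rtol=1e-12):
            return -math.inf
    live = ~degen
    if live.any():
        var = sigma2 * dt[live]
        log_rc = np.log(r_child[live])
        z = (log_rc - np.log(r_parent[live]) + var / 2.0) / np.sqrt(var)
        total += float(
            (-log_rc - 0.5 * np.log(2.0 * math.pi * var) - 0.5 * z * z).sum()
        )
    return total


def ln_branch_rates(
    rates: np.ndarray, parent: np.ndarray, mode: str = "arithmetic"
) -> np.ndarray:
    """Effective per-branch rate from the endpoint node rates (LN model)."""
    out = np.zeros_like(rates)
    for i in range(len(parent)):
        p = parent[i]
        if p < 0:
            continue
        if mode == "arithmetic":
            out[i] = 0.5 * (rates[i] + rates[p])
        elif mode == "geometric":
            out[i] = math.sqrt(rates[i] * rates[p])
        else:
            raise ValueError("mode must be 'arithmetic' or 'geometric'")
    return out


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    # written out from the series definition so it stands apart from any
    # library pdf used as an oracle in the tests
    if x <= 0:
        return -math.inf
    return (
        (shape - 1.0) * math.log(x)
        - x / scale
        - math.lgamma(shape)
        - shape * math.log(scale)
    )


def ugam_clock_logdensity(
    branch_rates: np.ndarray, nu: float, mu_rate: float
) -> float:
    """Uncorrelated gamma clock: i.i.d. branch rates with mean mu_rate,
    variance nu * mu_rate**2 (shape 1/nu, scale nu*mu_rate)."""
    if nu == 0:
        return 0.0 if np.allclose(branch_rates, mu_rate) else -math.inf
    shape = 1.0 / nu
    scale = nu * mu_rate
    return float(sum(_gamma_logpdf(float(r), shape, scale) for r in branch_rates))


# ---------------------------------------------------------------------------
# Birth-death node-age prior (conditional on root age and n)
# ---------------------------------------------------------------------------


def _bd_normaliser(t1: float, lam: float, mu: float) -> float:
    """Integral of lam*p1(t) over (0, t1)."""
    if lam <= 0:
        return t1  # uniform kernel limit
    if mu <= 0:
        return 1.0 - math.exp(-lam * t1)
    r = lam - mu
    if abs(r) < 1e-12:
        return lam * t1 / (1.0 + lam * t1)
    return (lam * r / mu) * (1.0 / (lam - mu) - 1.0 / (lam - mu * math.exp(-r * t1)))


def bd_kernel_logpdf(t: float, t1: float, lam: float, mu: float) -> float:
    """Log density of one non-root internal node age, conditional on root age.

    Internal node ages (other than the root) of a birth-death tree
    conditioned on root age ``t1`` and taxon count are i.i.d. draws from this
    kernel; the Yule (mu=0) case reduces to a truncated exponential and
    lam -> 0 to a uniform on (0, t1).
    """
    if not 0.0 <= t <= t1:
        return -math.inf
    v = _bd_normaliser(t1, lam, mu)
    if lam <= 0:
        return -math.log(t1)
    if mu <= 0:
        return math.log(lam) - lam * t - math.log(v)
    r = lam - mu
    if abs(r) < 1e-12:
        return math.log(lam) - 2.0 * math.log1p(lam * t) - math.log(v)
    p1 = (r * r * math.exp(-r * t)) / (lam - mu * math.exp(-r * t)) ** 2
    return math.log(lam * p1) - math.log(v)


def bd_kernel_cdf(t: float, t1: float, lam: float, mu: float) -> float:
    if t <= 0:
        return 0.0
    if t >= t1:
        return 1.0
    return _bd_normaliser(t, lam, mu) / _bd_normaliser(t1, lam, mu)


def bd_kernel_ppf(u: float, t1: float, lam: float, mu: float) -> float:
    """Inverse CDF of the node-age kernel (closed form in every regime)."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    if lam <= 0:
        return u * t1
    if mu <= 0:
        return -math.log(1.0 - u * (1.0 - math.exp(-lam * t1))) / lam
    r = lam - mu
    target = u * _bd_normaliser(t1, lam, mu)
    if abs(r) < 1e-12:
        # target = lam*t/(1+lam*t)
        return target / (lam * (1.0 - target))
    inv = 1.0 / (lam - mu) - target * mu / (lam * r)
    return -math.log((lam - 1.0 / inv) / mu) / r


def birthdeath_ages_logdensity(
    chrono: Chronogram, lam: float, mu: float
) -> float:
    """Joint log density of the internal node ages given the root age.

    Invariant to node labelling (an overall ordering constant is dropped).
    Any violation of the age ordering or of tip-age-zero returns -inf.
    """
    try:
        chrono.validate()
    except Exception:
        return -math.inf
    t1 = chrono.root_age
    total = 0.0
    for node in chrono.internal_nodes():
        if node is chrono.root:
            continue
        total += bd_kernel_logpdf(float(node.age), t1, lam, mu)
    return total


def birthdeath_ages_logdensity_arrays(
    ages: np.ndarray, parent: np.ndarray, is_leaf: np.ndarray, lam: float, mu: float
) -> float:
    root = int(np.where(parent < 0)[0][0])
    t1 = float(ages[root])
    if t1 <= 0:
        return -math.inf
    if (ages[is_leaf] != 0.0).any():
        return -math.inf
    nz = parent >= 0
    if not (ages[parent[nz]] > ages[nz]).all():
        return -math.inf
    mask = (~is_leaf) & nz
    t = ages[mask]
    if ((t < 0) | (t > t1)).any():
        return -math.inf
    n_int = int(mask.sum())
    if n_int == 0:
        return 0.0
    if lam <= 0:
        return -n_int * math.log(t1)
    v = _bd_normaliser(t1, lam, mu)
    if mu <= 0:
        return float(
            n_int * (math.log(lam) - math.log(v)) - lam * t.sum()
        )
    r = lam - mu
    if abs(r) < 1e-12:
        return float(
            n_int * (math.log(lam) - math.log(v))
            - 2.0 * np.log1p(lam * t).sum()
        )
    e = np.exp(-r * t)
    p1 = (r * r * e) / (lam - mu * e) ** 2
    return float(np.log(lam * p1).sum() - n_int * math.log(v))


# ---------------------------------------------------------------------------
# Calibrations and root prior
# ---------------------------------------------------------------------------


def _tail_scale(c: CalibrationConstraint) -> Tuple[float, float]:
    eps = c.tail_prob
    if c.min_age is not None and c.max_age is not None:
        width = c.max_age - c.min_age
        s = eps * width / (1.0 - 2.0 * eps)
        return s, s
    if c.max_age is not None:  # plateau [0, max]
        return 0.0, eps * c.max_age / (1.0 - eps)
    # min only: reference width is the bound itself
    return eps * c.min_age / (1.0 - eps), 0.0


def calibration_logfactor(age: float, c: CalibrationConstraint) -> float:
    """Log multiplicative soft-bound factor: 0 on the plateau, exponential
    decay outside, scaled so each used tail holds mass fraction tail_prob of
    the normalised factor (reference width for a minimum-only bound is the
    bound itself)."""
    if age < 0:
        return -math.inf
    s_lo, s_hi = _tail_scale(c)
    if c.min_age is not None and age < c.min_age:
        return -(c.min_age - age) / s_lo
    if c.max_age is not None and age > c.max_age:
        return -(age - c.max_age) / s_hi
    return 0.0


def root_prior_logdensity(age: float, prior: RootPrior) -> float:
    if age < 0:
        return -math.inf
    return -math.log(prior.mean) - age / prior.mean


# ---------------------------------------------------------------------------
# Calibration file I/O
# ---------------------------------------------------------------------------

_HEADER = "clade_name\ttaxa\tmin_age\tmax_age\ttail_prob"


def save_calibrations(cals: Sequence[CalibrationConstraint], path) -> None:
    lines = [_HEADER]
    for c in cals:
        lines.append(
            "\t".join(
                [
                    c.name,
                    ",".join(sorted(c.taxa)),
                    "" if c.min_age is None else f"{c.min_age:g}",
                    "" if c.max_age is None else f"{c.max_age:g}",
                    f"{c.tail_prob:g}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_calibration_text(text: str) -> List[CalibrationConstraint]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = []
    for ln in lines[1:]:
        name, taxa, lo, hi, eps = ln.split("\t")
        out.append(
            CalibrationConstraint(
                name,
                frozenset(taxa.split(",")),
                float(lo) if lo else None,
                float(hi) if hi else None,
                float(eps) if eps else 0.025,
            )
        )
    return out


def load_calibrations(path) -> List[CalibrationConstraint]:
    with open(path) as fh:
        return _parse_calibration_text(fh.read())


def paper_calibrations() -> List[CalibrationConstraint]:
    """The packaged 13-constraint fossil calibration set (12 vertebrate
    intervals plus one echinoderm minimum), ages in Mya."""
    text = (
        importlib.resources.files("chronoforge.data")
        .joinpath("calibrations_paper13.tsv")
        .read_text()
    )
    return _parse_calibration_text(text)
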