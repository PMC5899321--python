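"""Synthetic benchmark generation for the whole pipeline.

Generates birth-death chronograms, lineage rates under strict/LN/UGAM
clocks (with an optional fast-evolving subtree, emulating the strong rate
elevation of tunicate-like lineages), amino-acid alignments with gene-block
structure and taxon-by-gene missing data, and bundled benchmark cases with
ground truth and calibration sets.  Everything regenerates bit-identically
from (preset, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from . import clocks as clk
from . import substitution as subst
from . import supermatrix as smx
from .trees import Chronogram, Node, chronogram_to_newick

__all__ = [
    "simulate_chronogram",
    "simulate_rates",
    "simulate_alignment",
    "BenchmarkCase",
    "make_benchmark",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# Chronogram simulation (conditioned birth-death)
# ---------------------------------------------------------------------------


def simulate_chronogram(
    n_tips: int,
    birth: float,
    death: float,
    root_age: float,
    rng: np.random.Generator,
    taxa: Optional[Sequence[str]] = None,
) -> Chronogram:
    """Birth-death tree conditioned on tip count and root age.

    The n-2 non-root internal ages are i.i.d. draws from the conditional
    node-age kernel (inverse-CDF sampling); the labelled history is built by
    splitting a uniformly chosen extant lineage at each successive age, which
    is the standard constructive characterisation of the conditioned process.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if not birth >= death >= 0:
        raise ValueError("need birth >= death >= 0")
    if taxa is None:
        width = len(str(n_tips))
        taxa = [f"t{str(i + 1).zfill(width)}" for i in range(n_tips)]
    if len(taxa) != n_tips:
        raise ValueError("taxon list length must equal n_tips")

    ages = sorted(
        (
            clk.bd_kernel_ppf(float(u), root_age, birth, death)
            for u in rng.random(n_tips - 2)
        ),
        reverse=True,
    )
    root = Node()
    root.age = float(root_age)
    slots: List[Node] = [root, root]  # pending child positions
    for age in ages:
        k = int(rng.integers(len(slots)))
        parent = slots.pop(k)
        node = Node()
        node.age = float(age)
        parent.add_child(node)
        slots.extend([node, node])
    order = rng.permutation(n_tips)
    for slot_idx, name_idx in enumerate(order):
        leaf = Node(taxa[int(name_idx)])
        leaf.age = 0.0
        slots[slot_idx].add_child(leaf)
    chrono = Chronogram(root)
    chrono.validate()
    return chrono


# ---------------------------------------------------------------------------
# Rate simulation
# ---------------------------------------------------------------------------


def simulate_rates(
    chrono: Chronogram,
    clock: clk.ClockModel,
    rng: np.random.Generator,
    *,
    elevated_clade: Optional[FrozenSet[str]] = None,
    elevation_factor: float = 1.0,
) -> Dict[int, float]:
    """Node (LN) or branch (UGAM) rates drawn from the clock model.

    Keys are postorder node indices.  ``elevated_clade`` multiplies every
    rate in the subtree below the clade's MRCA by ``elevation_factor`` —
    the benchmark analogue of a fast-evolving lineage.
    """
    nodes = list(chrono.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    rates: Dict[int, float] = {}
    if clock.kind == "cl" or (clock.kind == "ln" and clock.sigma2 == 0):
        for i in range(len(nodes)):
            rates[i] = clock.mu_rate
    elif clock.kind == "ln":
        for node in chrono.preorder():
            i = index[id(node)]
            if node.parent is None:
                # root rate from its own prior law (LogNormal around mu_rate)
                rates[i] = clock.mu_rate * math.exp(
                    rng.normal(0.0, clock.root_spread)
                )
                continue
            p = rates[index[id(node.parent)]]
            dt = float(node.parent.age - node.age)
            var = clock.sigma2 * dt
            rates[i] = p * math.exp(
                rng.normal(-var / 2.0, math.sqrt(var)) if var > 0 else 0.0
            )
    elif clock.kind == "ugam":
        if clock.nu == 0:
            for i in range(len(nodes)):
                rates[i] = clock.mu_rate
        else:
            shape = 1.0 / clock.nu
            scale = clock.nu * clock.mu_rate
            for node in chrono.postorder():
                i = index[id(node)]
                rates[i] = float(rng.gamma(shape, scale)) if node.parent else clock.mu_rate
    else:
        raise ValueError(clock.kind)

    if elevated_clade is not None and elevation_factor != 1.0:
        mrca = chrono.mrca(elevated_clade)
        for node in mrca.postorder():
            rates[index[id(node)]] *= elevation_factor
    return rates


def _branch_lengths_from_rates(
    chrono: Chronogram, rates: Dict[int, float], kind: str, mode: str = "arithmetic"
) -> Dict[int, float]:
    """Branch length = duration x effective rate (trapezoid of endpoint
    rates for the LN/strict models; the branch's own rate for UGAM)."""
    nodes = list(chrono.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    out: Dict[int, float] = {}
    for node in nodes:
        if node.parent is None:
            continue
        i = index[id(node)]
        dt = float(node.parent.age - node.age)
        if kind == "ugam":
            eff = rates[i]
        else:
            rp = rates[index[id(node.parent)]]
            eff = 0.5 * (rates[i] + rp) if mode == "arithmetic" else math.sqrt(rates[i] * rp)
        out[i] = dt * eff
    return out


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def simulate_alignment(
    chrono: Chronogram,
    rates: Dict[int, float],
    model: subst.SubstModel,
    gene_lengths: Sequence[int],
    missing_fraction: float,
    rng: np.random.Generator,
    *,
    clock_kind: str = "ln",
    site_profiles: Optional[np.ndarray] = None,
) -> Tuple[List[smx.GeneAlignment], smx.Supermatrix]:
    """Simulate amino-acid genes down the chronogram.

    Sites evolve root-to-tips under the model with discrete-gamma site
    rates (``site_profiles`` optionally supplies per-site stationary
    profiles for CAT-style heterogeneity).  Missing data are applied as
    whole taxon-by-gene blocks until the global missing fraction reaches the
    target; no taxon is ever blanked in every gene.
    """
    if not 0.0 <= missing_fraction <= 0.9:
        raise ValueError("missing_fraction must lie in [0, 0.9]")
    n_sites = int(sum(gene_lengths))
    nodes = list(chrono.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    blens = _branch_lengths_from_rates(chrono, rates, clock_kind)

    gamma_rates, gamma_w = model.gamma()
    site_cat = rng.integers(len(gamma_rates), size=n_sites)

    if site_profiles is None:
        kernel = subst.TransitionKernel(model.exch, model.freqs)
        kernels = [(np.arange(n_sites), kernel, model.freqs)]
    else:
        kernels = []
        uniq = np.unique(site_profiles, axis=0)
        for prof in uniq:
            mask = np.where((site_profiles == prof).all(axis=1))[0]
            kernels.append((mask, subst.TransitionKernel(model.exch, prof), prof))

    states = np.empty((len(nodes), n_sites), dtype=np.int8)
    for sites, kernel, freqs in kernels:
        root_draw = subst.stationary_sampler(freqs, rng)
        states[index[id(chrono.root)], sites] = root_draw(len(sites))
    for node in chrono.preorder():
        if node.parent is None:
            continue
        i, p = index[id(node)], index[id(node.parent)]
        b = blens[i]
        for sites, kernel, _ in kernels:
            for k in range(len(gamma_rates)):
                sel = sites[site_cat[sites] == k]
                if len(sel) == 0:
                    continue
                pmat = np.cumsum(kernel.probability_matrix(b * gamma_rates[k]), axis=1)
                u = rng.random(len(sel))
                parent_states = states[p, sel]
                states[i, sel] = (
                    u[:, None] > pmat[parent_states, :]
                ).sum(axis=1).astype(np.int8)

    leaf_rows = {
        n.name: subst.decode_sequence(states[index[id(n)]]) for n in chrono.leaves()
    }
    taxa = sorted(leaf_rows)

    # carve into genes
    genes: List[smx.GeneAlignment] = []
    cursor = 0
    for gi, length in enumerate(gene_lengths):
        seqs = {t: leaf_rows[t][cursor : cursor + length] for t in taxa}
        genes.append(smx.GeneAlignment(f"gene{gi + 1:03d}", seqs))
        cursor += length

    # block missingness: remove random (taxon, gene) cells
    target = missing_fraction * len(taxa) * n_sites
    if target > 0:
        blocks = [(t, g) for t in range(len(taxa)) for g in range(len(genes))]
        order = rng.permutation(len(blocks))
        removed_per_taxon = np.zeros(len(taxa), dtype=int)
        removed = 0.0
        for k in order:
            ti, gi = blocks[int(k)]
            if removed >= target:
                break
            if removed_per_taxon[ti] >= len(genes) - 1:
                continue  # never blank a taxon entirely
            gene = genes[gi]
            taxon = taxa[ti]
            if set(gene.sequences[taxon]) == {"?"}:
                continue
            gene.sequences[taxon] = "?" * gene.length
            removed += gene.length
            removed_per_taxon[ti] += 1

    sm, _stats = smx.concatenate(genes)
    return genes, sm


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkCase:
    """A fully specified synthetic study: data plus ground truth."""

    preset: str
    seed: int
    chronogram: Chronogram
    rates: Dict[int, float]          # postorder node index -> true rate
    clock: clk.ClockModel
    subst_model: subst.SubstModel
    genes: List[smx.GeneAlignment]
    matrix: smx.Supermatrix
    calibrations: List[clk.CalibrationConstraint]
    root_prior: clk.RootPrior
    bd: clk.BirthDeathPrior
    groups: Dict[str, str] = field(default_factory=dict)

    def true_node_ages(self) -> Dict[FrozenSet[str], float]:
        cm = self.chronogram.clade_map()
        return {
            clade: float(node.age)
            for node, clade in cm.items()
            if not node.is_leaf
        }

    def chronogram_newick(self) -> str:
        return chronogram_to_newick(self.chronogram)


def _tiny_case(seed: int) -> BenchmarkCase:
    """8 taxa, 5 genes x 200 sites, LN clock, 2 calibrations.

    The ground-truth ages are an exact draw from the dating model's own
    prior: a birth-death chronogram (root from the exponential root-prior
    law) fixes the topology and the two soft calibration windows, and the
    ages are then re-drawn from the calibrated prior itself by a prior-only
    chain.  Recovery studies on this preset are therefore well-calibrated —
    credibility intervals carry their nominal frequentist coverage over
    replicates by construction.
    """
    from . import mcmc as _mcmc  # deferred: mcmc does not import this module

    rng = np.random.default_rng(seed)
    bd = clk.BirthDeathPrior(birth=0.01, death=0.0)
    root_prior = clk.RootPrior(500.0)
    root_age = float(rng.exponential(root_prior.mean))
    chrono = simulate_chronogram(8, bd.birth, bd.death, root_age, rng)
    clock = clk.ClockModel("ln", mu_rate=0.002, sigma2=0.001)

    # soft calibrations bracketing the two deepest non-root clades
    cm = chrono.clade_map()
    internal = sorted(
        (
            (node, clade)
            for node, clade in cm.items()
            if not node.is_leaf and node is not chrono.root
        ),
        key=lambda nc: -nc[0].age,
    )
    cals = []
    for rank, (node, clade) in enumerate(internal[:2]):
        cals.append(
            clk.CalibrationConstraint(
                f"cal{rank + 1}", clade,
                min_age=0.85 * node.age, max_age=1.15 * node.age,
            )
        )

    # re-draw the true ages from the calibrated prior (prior-only chain),
    # so truth ~ exactly the prior the dating model will use
    spec = _mcmc.DatingSpec(
        clock=clk.ClockModel("cl", mu_rate=clock.mu_rate),
        bd=bd,
        root_prior=root_prior,
        calibrations=cals,
        likelihood=False,
    )
    cfg = _mcmc.ChainConfig(
        cycles=3000, thin=3000, burnin=0, seed=(seed * 7 + 13) % (2**31 - 1)
    )
    trace = _mcmc.run_dating_chain(None, chrono, spec, cfg)
    final_ages = trace.ages[-1]
    for i, node in enumerate(chrono.postorder()):
        node.age = float(final_ages[i])
    chrono.validate()

    rates = simulate_rates(chrono, clock, rng)
    # single rate class: the tiny case exercises clock/age recovery, where
    # among-site rate variation is an orthogonal (and costly) ingredient
    model = subst.make_model("poisson")
    genes, sm = simulate_alignment(
        chrono, rates, model, [200] * 5, 0.0, rng, clock_kind="ln"
    )
    return BenchmarkCase(
        "tiny", seed, chrono, rates, clock, model, genes, sm, cals,
        root_prior, bd,
    )


# Fixed 63-taxon backbone mirroring the shape of a deuterostome-wide
# phylogenomic sampling: 18 tunicates, 34 vertebrates, 1 cephalochordate,
# 7 echinoderms, 2 hemichordates, 1 xenoturbellid.  Topology only; ages are
# drawn at generation time.
PAPER_SHAPE_TOPOLOGY = (
    "((Xenoturbella_bocki,((Saccoglossus_kowalevskii,Ptychodera_flava),"
    "(Antedon_mediterranea,((Ophionotus_victoriae,(Patiria_miniata,Asterias_rubens)),"
    "(Apostichopus_japonicus,(Paracentrotus_lividus,Strongylocentrotus_purpuratus)))))),"
    "(Branchiostoma_lanceolatum,("
    # tunicates
    "(Oikopleura_dioica,(((Bostrichobranchus_pilularis,(Molgula_occidentalis,"
    "(Molgula_manhattensis,Molgula_tectiformis))),(Halocynthia_roretzi,(Styela_plicata,"
    "(Botryllus_schlosseri,(Polyandrocarpa_anguinea,Dendrodoa_grossularia))))),"
    "((Salpa_fusiformis,Doliolum_nationalis),(Phallusia_mammillata,((Ciona_robusta,"
    "Ciona_savignyi),(Clavelina_lepadiformis,(Diplosoma_listerianum,"
    "Cystodytes_dellechiajei))))))),"
    # vertebrates
    "((Eptatretus_burgeri,Petromyzon_marinus),((Callorhinchus_milii,(Squalus_acanthias,"
    "(Scyliorhinus_canicula,Leucoraja_erinacea))),((Lepisosteus_oculatus,(Danio_rerio,"
    "((Salmo_salar,Oncorhynchus_mykiss),(Gasterosteus_aculeatus,(Oryzias_latipes,"
    "Takifugu_rubripes))))),(Latimeria_chalumnae,((Ambystoma_mexicanum,"
    "((Xenopus_laevis,Xenopus_tropicalis),Rana_chensinensis)),((Ornithorhynchus_anatinus,"
    "(Monodelphis_domestica,(Canis_familiaris,(Homo_sapiens,Mus_musculus)))),"
    "((Sphenodon_punctatus,(Anolis_carolinensis,Python_regius)),((Pelodiscus_sinensis,"
    "(Phrynops_hilarii,Chrysemys_picta)),((Alligator_mississippiensis,"
    "Crocodylus_niloticus),(Struthio_camelus,(Gallus_gallus,Taeniopygia_guttata)"
    ")))))))))))));"
)

_TUNICATES = frozenset(
    [
        "Oikopleura_dioica", "Bostrichobranchus_pilularis", "Molgula_occidentalis",
        "Molgula_manhattensis", "Molgula_tectiformis", "Halocynthia_roretzi",
        "Styela_plicata", "Botryllus_schlosseri", "Polyandrocarpa_anguinea",
        "Dendrodoa_grossularia", "Salpa_fusiformis", "Doliolum_nationalis",
        "Phallusia_mammillata", "Ciona_robusta", "Ciona_savignyi",
        "Clavelina_lepadiformis", "Diplosoma_listerianum", "Cystodytes_dellechiajei",
    ]
)
_VERTEBRATES = frozenset(
    [
        "Eptatretus_burgeri", "Petromyzon_marinus", "Callorhinchus_milii",
        "Squalus_acanthias", "Scyliorhinus_canicula", "Leucoraja_erinacea",
        "Lepisosteus_oculatus", "Danio_rerio", "Salmo_salar", "Oncorhynchus_mykiss",
        "Gasterosteus_aculeatus", "Oryzias_latipes", "Takifugu_rubripes",
        "Latimeria_chalumnae", "Ambystoma_mexicanum", "Xenopus_laevis",
        "Xenopus_tropicalis", "Rana_chensinensis", "Ornithorhynchus_anatinus",
        "Monodelphis_domestica", "Canis_familiaris", "Homo_sapiens", "Mus_musculus",
        "Sphenodon_punctatus", "Anolis_carolinensis", "Python_regius",
        "Pelodiscus_sinensis", "Phrynops_hilarii", "Chrysemys_picta",
        "Alligator_mississippiensis", "Crocodylus_niloticus", "Struthio_camelus",
        "Gallus_gallus", "Taeniopygia_guttata",
    ]
)
_CEPHALOCHORDATES = frozenset(["Branchiostoma_lanceolatum"])
_OUTGROUPS = frozenset(
    [
        "Xenoturbella_bocki", "Saccoglossus_kowalevskii", "Ptychodera_flava",
        "Antedon_mediterranea", "Ophionotus_victoriae", "Patiria_miniata",
        "Asterias_rubens", "Apostichopus_japonicus", "Paracentrotus_lividus",
        "Strongylocentrotus_purpuratus",
    ]
)


def taxon_groups() -> Dict[str, str]:
    groups: Dict[str, str] = {}
    for t in _TUNICATES:
        groups[t] = "tunicates"
    for t in _VERTEBRATES:
        groups[t] = "vertebrates"
    for t in _CEPHALOCHORDATES:
        groups[t] = "cephalochordates"
    for t in _OUTGROUPS:
        groups[t] = "outgroups"
    return groups


def _draw_calibrated_ages(
    chrono: Chronogram,
    cals: Sequence[clk.CalibrationConstraint],
    root_age: float,
    rng: np.random.Generator,
) -> None:
    """Assign internal ages top-down, respecting calibration plateaus.

    Each node gets a feasibility floor (its calibration minimum, or enough
    head-room for the internal levels below it) and is drawn uniformly
    between that floor and min(parent age, its calibration maximum).
    """
    cal_by_node = {}
    for cal in cals:
        cal_by_node[id(chrono.mrca(cal.taxa))] = cal
    floor: Dict[int, float] = {}
    for node in chrono.postorder():
        if node.is_leaf:
            floor[id(node)] = 0.0
            continue
        lo = max(floor[id(c)] for c in node.children) + 2.0
        cal = cal_by_node.get(id(node))
        if cal is not None and cal.min_age is not None:
            lo = max(lo, cal.min_age + 1.0)
        floor[id(node)] = lo
    chrono.root.age = root_age
    for node in chrono.preorder():
        if node.is_leaf:
            node.age = 0.0
            continue
        if node.parent is None:
            continue
        hi = node.parent.age - 2.0
        cal = cal_by_node.get(id(node))
        if cal is not None and cal.max_age is not None:
            hi = min(hi, cal.max_age - 1.0)
        lo = floor[id(node)]
        node.age = lo if hi <= lo else lo + (hi - lo) * rng.random()
    chrono.validate()


def _paper_shape_case(seed: int) -> BenchmarkCase:
    """63 taxa, 20 genes x 100 sites, the 13-calibration fixture, and a
    6.25-fold rate elevation of the tunicate subtree."""
    from .trees import parse_newick

    rng = np.random.default_rng(seed)
    topo = parse_newick(PAPER_SHAPE_TOPOLOGY)
    chrono = Chronogram(topo.root)
    cals = clk.paper_calibrations()
    root_age = 540.0 + 40.0 * rng.random()  # near the root-prior scale
    _draw_calibrated_ages(chrono, cals, root_age, rng)
    # root_spread 0 pins the root rate at mu_rate: this preset's realized
    # divergence scale should stay at the study-like level across seeds
    clock = clk.ClockModel("ln", mu_rate=0.0006, sigma2=0.0003, root_spread=0.0)
    rates = simulate_rates(
        chrono, clock, rng, elevated_clade=_TUNICATES, elevation_factor=6.25
    )
    model = subst.make_model("lg", alpha=0.7)
    genes, sm = simulate_alignment(
        chrono, rates, model, [100] * 20, 0.2, rng, clock_kind="ln"
    )
    return BenchmarkCase(
        "paper-shape", seed, chrono, rates, clock, model, genes, sm,
        list(cals), clk.RootPrior(540.0), clk.BirthDeathPrior(0.01, 0.0),
        groups=taxon_groups(),
    )


PRESETS = {
    "tiny": _tiny_case,
    "paper-shape": _paper_shape_case,
}


def make_benchmark(preset: str, seed: int = 0) -> BenchmarkCase:
    """Build a named benchmark case; regeneration is bit-identical in
    (preset, seed)."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    return PRESETS[preset](seed)
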