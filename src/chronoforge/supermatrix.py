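"""Phylogenomic supermatrix assembly.

Per-gene amino-acid alignments are merged into operational taxonomic units
(OTUs, possibly chimeric across closely related source species), filtered by
per-gene missing-OTU counts, and concatenated into one character matrix with
gene partitions.  Gene-jackknife resampling and pairwise identity statistics
live here too.

Coordinates are 0-based half-open internally; user-facing partition reports
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from . import substitution as subst
from .trees import RootedTree

MISSING_SET = set("-?X")

__all__ = [
    "GeneAlignment",
    "OTUDefinition",
    "Supermatrix",
    "JackknifeScheme",
    "AlignmentError",
    "read_gene_alignments",
    "read_alignment_file",
    "pairwise_ml_distance",
    "choose_representative",
    "make_chimera",
    "filter_by_missing",
    "concatenate",
    "gene_jackknife",
    "jackknife_support",
    "pairwise_identity",
]


class AlignmentError(ValueError):
    pass


def normalize_sequence(seq: str) -> str:
    """Uppercase; ambiguity codes B/Z/J/U/O and '*'/'.' become 'X'; keep '-', '?'."""
    out = []
    for ch in seq.upper():
        if ch in subst._AA_INDEX:
            out.append(ch)
        elif ch in "-?":
            out.append(ch)
        elif ch in "BZJUOX*.":
            out.append("X")
        else:
            raise AlignmentError(f"unexpected residue {ch!r}")
    return "".join(out)


@dataclass
class GeneAlignment:
    """One gene's aligned amino-acid sequences (taxon -> row)."""

    gene_id: str
    sequences: Dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if not self.sequences:
            raise AlignmentError(f"gene {self.gene_id}: no sequences")
        if len(lengths) != 1:
            raise AlignmentError(f"gene {self.gene_id}: ragged alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(self.sequences)

    def non_missing_fraction(self, taxon: str) -> float:
        row = self.sequences[taxon]
        return sum(c not in MISSING_SET for c in row) / len(row)


@dataclass
class OTUDefinition:
    """An OTU and the ordered source taxa eligible to represent it."""

    name: str
    sources: List[str]

    def __post_init__(self):
        if not self.sources:
            raise AlignmentError(f"OTU {self.name}: empty source list")


@dataclass
class Supermatrix:
    otus: List[str]
    rows: Dict[str, str]
    partitions: Dict[str, Tuple[int, int]]  # gene -> [start, end)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values())))

    def validate(self) -> None:
        n = self.n_sites
        for otu, row in self.rows.items():
            if len(row) != n:
                raise AlignmentError(f"OTU {otu}: row length {len(row)} != {n}")
        spans = sorted(self.partitions.values())
        cursor = 0
        for start, end in spans:
            if start != cursor or end <= start:
                raise AlignmentError("partitions must tile the matrix without overlap")
            cursor = end
        if cursor != n:
            raise AlignmentError("partitions do not cover all sites")

    def pct_missing(self) -> float:
        total = len(self.otus) * self.n_sites
        missing = sum(
            sum(c in MISSING_SET for c in row) for row in self.rows.values()
        )
        return 100.0 * missing / total

    def extract_gene(self, gene_id: str) -> GeneAlignment:
        start, end = self.partitions[gene_id]
        return GeneAlignment(
            gene_id, {otu: self.rows[otu][start:end] for otu in self.otus}
        )

    def partition_report(self) -> List[Tuple[str, int, int]]:
        """Gene spans, 1-based inclusive, in matrix order."""
        return [
            (g, s + 1, e)
            for g, (s, e) in sorted(self.partitions.items(), key=lambda kv: kv[1])
        ]

    def encoded(self) -> Dict[str, np.ndarray]:
        return {otu: subst.encode_sequence(row) for otu, row in self.rows.items()}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_fasta(text: str, label: str) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name: Optional[str] = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0].strip()
            if name in seqs:
                raise AlignmentError(f"{label}: duplicate taxon {name}")
            seqs[name] = []
        else:
            if name is None:
                raise AlignmentError(f"{label}: sequence data before first header")
            seqs[name].append(line)
    if not seqs:
        raise AlignmentError(f"{label}: empty file")
    return {t: "".join(parts) for t, parts in seqs.items()}


def _parse_relaxed_phylip(text: str, label: str) -> Dict[str, str]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AlignmentError(f"{label}: empty file")
    header = lines[0].split()
    try:
        n_seq, n_cols = int(header[0]), int(header[1])
    except (IndexError, ValueError):
        raise AlignmentError(f"{label}: bad PHYLIP header {lines[0]!r}")
    seqs: Dict[str, str] = {}
    for ln in lines[1 : n_seq + 1]:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise AlignmentError(f"{label}: bad PHYLIP row {ln!r}")
        name, seq = parts[0].strip(), parts[1].replace(" ", "")
        if len(seq) != n_cols:
            raise AlignmentError(
                f"{label}: taxon {name} has {len(seq)} columns, expected {n_cols}"
            )
        seqs[name] = seq
    if len(seqs) != n_seq:
        raise AlignmentError(f"{label}: expected {n_seq} sequences, found {len(seqs)}")
    return seqs


def read_alignment_file(path, gene_id: Optional[str] = None) -> GeneAlignment:
    """Read one FASTA or relaxed (sequential) PHYLIP alignment."""
    import pathlib

    p = pathlib.Path(path)
    text = p.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise AlignmentError(f"{p.name}: empty file")
    raw = (
        _parse_fasta(text, p.name)
        if stripped.startswith(">")
        else _parse_relaxed_phylip(text, p.name)
    )
    seqs = {}
    for taxon, seq in raw.items():
        try:
            seqs[taxon.strip()] = normalize_sequence(seq)
        except AlignmentError as exc:
            raise AlignmentError(f"{p.name}, taxon {taxon}: {exc}") from exc
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        offender = max(seqs, key=lambda t: len(seqs[t]))
        raise AlignmentError(f"{p.name}: ragged alignment (see taxon {offender})")
    return GeneAlignment(gene_id or p.stem, seqs)


def read_gene_alignments(paths: Iterable) -> List[GeneAlignment]:
    return [read_alignment_file(p) for p in paths]


# ---------------------------------------------------------------------------
# ML distances and representative choice
# ---------------------------------------------------------------------------


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mask = (a >= 0) & (b >= 0)
    if not mask.any():
        raise AlignmentError("no shared non-missing columns")
    counts = np.zeros((subst.N_STATES, subst.N_STATES))
    np.add.at(counts, (a[mask], b[mask]), 1.0)
    return counts


def pairwise_ml_distance(
    seq_a: str,
    seq_b: str,
    *,
    model: str = "wag",
    alpha: Optional[float] = None,
    max_distance: float = 20.0,
) -> float:
    """Two-sequence maximum-likelihood distance (substitutions/site).

    Uses the requested empirical exchangeabilities with frequencies estimated
    from the sequence pair ('+F').  The two-sequence likelihood reduces to a
    20x20 pair-count sufficient statistic, so evaluation is cheap and the
    optimum is found by bounded scalar optimisation.  ``alpha`` optionally
    adds discrete-gamma rate averaging.
    """
    a = subst.encode_sequence(normalize_sequence(seq_a))
    b = subst.encode_sequence(normalize_sequence(seq_b))
    if len(a) != len(b):
        raise AlignmentError("sequences must be aligned to equal length")
    counts = _pair_counts(a, b)
    state_counts = counts.sum(axis=1) + counts.sum(axis=0)
    freqs = state_counts + 1e-8
    freqs = freqs / freqs.sum()
    exch, _ = subst.load_empirical_model(model)
    kernel = subst.TransitionKernel(exch, freqs)
    if alpha is not None:
        rates, weights = subst.discrete_gamma_rates(alpha)
    else:
        rates, weights = np.array([1.0]), np.array([1.0])
    log_pi = np.log(freqs)

    def neg_loglik(d: float) -> float:
        p = np.zeros((subst.N_STATES, subst.N_STATES))
        for r, w in zip(rates, weights):
            p += w * kernel.probability_matrix(d * r)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(np.clip(p, 1e-300, None)))
        return -float(ll.sum())

    res = minimize_scalar(
        neg_loglik, bounds=(0.0, max_distance), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def choose_representative(
    gene: GeneAlignment,
    candidates: Sequence[str],
    background: Sequence[str],
    *,
    aggregate: str = "mean",
    alpha: Optional[float] = None,
) -> Optional[str]:
    """Pick the slowest-evolving candidate for an OTU within one gene.

    'Slowest' is the candidate with minimal mean (or max, with
    ``aggregate='max'``) ML distance to the background taxa present in the
    gene; ties break lexicographically.  Returns None when no candidate has
    data in the gene.
    """
    present = [c for c in candidates if c in gene.sequences]
    if not present:
        return None
    if len(present) == 1:
        return present[0]
    bg = [t for t in background if t in gene.sequences and t not in present]
    if not bg:
        return sorted(present)[0]
    agg = np.mean if aggregate == "mean" else np.max
    scored = []
    for cand in sorted(present):
        dists = []
        for t in bg:
            try:
                dists.append(
                    pairwise_ml_distance(
                        gene.sequences[cand], gene.sequences[t], alpha=alpha
                    )
                )
            except AlignmentError:
                continue
        score = float(agg(dists)) if dists else np.inf
        scored.append((score, cand))
    scored.sort()
    return scored[0][1]


def make_chimera(
    genes: Sequence[GeneAlignment],
    otu: OTUDefinition,
    *,
    slowest: bool = True,
) -> Dict[str, Optional[str]]:
    """Per-gene source assignment for one OTU.

    Each gene independently contributes the representative source taxon (the
    slowest-evolving present source by default, or simply the first available
    one when ``slowest=False``); genes with no source present map to None and
    become fully missing for the OTU.
    """
    assignment: Dict[str, Optional[str]] = {}
    for gene in genes:
        if slowest:
            background = sorted(gene.taxa - set(otu.sources))
            assignment[gene.gene_id] = choose_representative(
                gene, otu.sources, background
            )
        else:
            present = [s for s in otu.sources if s in gene.sequences]
            assignment[gene.gene_id] = present[0] if present else None
    return assignment


def filter_by_missing(
    genes: Sequence[GeneAlignment],
    otus: Sequence[OTUDefinition],
    max_missing: int = 15,
) -> List[GeneAlignment]:
    """Keep genes with at most ``max_missing`` OTUs lacking any source (inclusive)."""
    kept = []
    for gene in genes:
        n_absent = sum(
            1
            for otu in otus
            if not any(s in gene.sequences for s in otu.sources)
        )
        if n_absent <= max_missing:
            kept.append(gene)
    return kept


def concatenate(
    genes: Sequence[GeneAlignment],
    otus: Optional[Sequence[OTUDefinition]] = None,
    *,
    slowest: bool = True,
) -> Tuple[Supermatrix, Dict[str, float]]:
    """Concatenate genes into a supermatrix, in gene input order.

    With ``otus`` given, each OTU row is assembled gene-by-gene via
    :func:`make_chimera`; otherwise each distinct taxon becomes its own OTU.
    Returns the matrix plus summary stats (n_genes, n_otus, n_sites,
    pct_missing counting gaps and unknowns).
    """
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise AlignmentError("duplicate gene ids")
    if not genes:
        raise AlignmentError("need at least one gene")
    if otus is None:
        names = sorted({t for g in genes for t in g.taxa})
        otus = [OTUDefinition(n, [n]) for n in names]
    names = [o.name for o in otus]
    if len(names) != len(set(names)):
        raise AlignmentError("duplicate OTU names")

    assignments = {o.name: make_chimera(genes, o, slowest=slowest) for o in otus}
    rows = {o.name: [] for o in otus}
    partitions: Dict[str, Tuple[int, int]] = {}
    cursor = 0
    for gene in genes:
        partitions[gene.gene_id] = (cursor, cursor + gene.length)
        cursor += gene.length
        for o in otus:
            src = assignments[o.name][gene.gene_id]
            rows[o.name].append(
                gene.sequences[src] if src is not None else "?" * gene.length
            )
    sm = Supermatrix(names, {n: "".join(parts) for n, parts in rows.items()}, partitions)
    sm.validate()
    stats = {
        "n_genes": float(len(genes)),
        "n_otus": float(len(names)),
        "n_sites": float(sm.n_sites),
        "pct_missing": sm.pct_missing(),
    }
    return sm, stats


# ---------------------------------------------------------------------------
# Jackknife and identity
# ---------------------------------------------------------------------------


@dataclass
class JackknifeScheme:
    gene_ids: List[str]
    k: int
    seed: int
    replicates: List[List[str]] = field(default_factory=list)

    def validate(self) -> None:
        pool = set(self.gene_ids)
        for rep in self.replicates:
            if len(rep) != self.k or len(set(rep)) != self.k:
                raise AlignmentError("replicate does not hold k distinct genes")
            if not set(rep) <= pool:
                raise AlignmentError("replicate references unknown genes")


def gene_jackknife(
    gene_ids: Sequence[str], k: int = 130, replicates: int = 100, seed: int = 0
) -> JackknifeScheme:
    """Draw gene-jackknife replicates: k distinct genes each, without
    replacement within a replicate, independently across replicates."""
    ids = list(gene_ids)
    if k > len(ids):
        raise AlignmentError(f"k={k} exceeds the {len(ids)} available genes")
    rng = np.random.default_rng(seed)
    reps = [
        [ids[j] for j in rng.choice(len(ids), size=k, replace=False)]
        for _ in range(replicates)
    ]
    scheme = JackknifeScheme(ids, k, seed, reps)
    scheme.validate()
    return scheme


def jackknife_support(consensus_trees: Sequence[RootedTree]) -> Dict[FrozenSet[str], float]:
    """Jackknife support (JS) percentages from replicate consensus trees."""
    from .trees import _check_common_leafset, _clade_frequencies

    _check_common_leafset(consensus_trees)
    return {c: 100.0 * f for c, f in _clade_frequencies(consensus_trees).items()}


def pairwise_identity(sm: Supermatrix, otu_a: str, otu_b: str) -> float:
    """Percent identity over columns where both OTUs carry a residue."""
    row_a, row_b = sm.rows[otu_a], sm.rows[otu_b]
    comparable = matches = 0
    for ca, cb in zip(row_a, row_b):
        if ca in MISSING_SET or cb in MISSING_SET:
            continue
        comparable += 1
        matches += ca == cb
    if comparable == 0:
        raise AlignmentError(f"no comparable columns between {otu_a} and {otu_b}")
    return 100.0 * matches / comparable
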