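"""Supermatrix assembly: readers, ML distances, chimeras, concatenation."""

import numpy as np
import pytest

from chronoforge import substitution as subst
from chronoforge import supermatrix as smx
from chronoforge import trees as trx


@pytest.fixture()
def fasta_file(tmp_path):
    p = tmp_path / "gene1.fasta"
    p.write_text(">tax1\nARNDARNDAR\n>tax2\nARNDARNDAC\n>tax3\nARND-RNDAX\n")
    return p


class TestReaders:
    def test_fasta(self, fasta_file):
        aln = smx.read_alignment_file(fasta_file)
        assert len(aln.sequences) == 3 and aln.length == 10

    def test_relaxed_phylip(self, tmp_path):
        p = tmp_path / "gene2.phy"
        p.write_text("4 12\ntaxA ARNDCQEGHILK\ntaxB ARNDCQEGHILK\ntaxC ARNDCQEGHILK\ntaxD ARNDCQEGHILK\n")
        aln = smx.read_alignment_file(p)
        assert len(aln.sequences) == 4 and aln.length == 12

    def test_ambiguity_codes_become_unknown(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">x\nABZJUO\n>y\nAAAAAA\n")
        aln = smx.read_alignment_file(p)
        assert aln.sequences["x"] == "AXXXXX"

    def test_ragged_alignment_names_file(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nAAAA\n>y\nAA\n")
        with pytest.raises(smx.AlignmentError, match="bad.fasta"):
            smx.read_alignment_file(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(smx.AlignmentError, match="empty"):
            smx.read_alignment_file(p)


class TestMLDistance:
    def test_identical_sequences_distance_zero(self):
        seq = "ARNDCQEGHILKMFPSTWYV" * 20
        assert smx.pairwise_ml_distance(seq, seq) < 1e-6

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = subst.decode_sequence(rng.integers(0, 20, 200).astype(np.int8))
            b = subst.decode_sequence(rng.integers(0, 20, 200).astype(np.int8))
            assert smx.pairwise_ml_distance(a, b) == pytest.approx(
                smx.pairwise_ml_distance(b, a), abs=1e-6
            )

    def test_recovers_simulated_distance_against_grid_oracle(self):
        # pair simulated at true distance 0.3 under WAG, 1e5 sites
        rng = np.random.default_rng(4)
        exch, freqs = subst.load_empirical_model("wag")
        kernel = subst.TransitionKernel(exch, freqs)
        n = 100_000
        a = subst.stationary_sampler(freqs, rng)(n)
        cum = np.cumsum(kernel.probability_matrix(0.3), axis=1)
        b = (rng.random(n)[:, None] > cum[a]).sum(1).astype(np.int8)
        sa, sb = subst.decode_sequence(a), subst.decode_sequence(b)
        d = smx.pairwise_ml_distance(sa, sb)

        # independent fine-grid likelihood maximisation on the pair counts
        counts = np.zeros((20, 20))
        np.add.at(counts, (a, b), 1.0)
        pair_freqs = counts.sum(0) + counts.sum(1) + 1e-8
        pair_freqs /= pair_freqs.sum()
        kern2 = subst.TransitionKernel(exch, pair_freqs)
        grid = np.linspace(0.01, 5.0, 2000)
        lls = [
            (counts * np.log(np.clip(pair_freqs[:, None] * kern2.probability_matrix(g), 1e-300, None))).sum()
            for g in grid
        ]
        d_grid = grid[int(np.argmax(lls))]
        assert d == pytest.approx(d_grid, abs=0.01)
        assert d == pytest.approx(0.3, abs=0.02)

    def test_no_shared_columns_rejected(self):
        with pytest.raises(smx.AlignmentError):
            smx.pairwise_ml_distance("AA--", "--AA")


class TestRepresentativesAndChimeras:
    def _gene(self, rows):
        return smx.GeneAlignment("g", rows)

    def test_single_candidate_returned(self):
        g = self._gene({"x": "AAAA", "bg": "AAAA"})
        assert smx.choose_representative(g, ["x", "y"], ["bg"]) == "x"

    def test_slower_mutant_not_chosen(self):
        rng = np.random.default_rng(0)
        base = subst.decode_sequence(rng.integers(0, 20, 300).astype(np.int8))
        fast = list(base)
        for i in rng.choice(300, 60, replace=False):
            fast[i] = "ARNDCQEGHILKMFPSTWYV"[(subst._AA_INDEX[fast[i]] + 1) % 20]
        g = self._gene({"slow": base, "fast": "".join(fast), "bg1": base, "bg2": base})
        assert smx.choose_representative(g, ["slow", "fast"], ["bg1", "bg2"]) == "slow"

    def test_tie_breaks_lexicographically(self):
        g = self._gene({"b": "AAAA", "a": "AAAA", "bg": "AAAA"})
        assert smx.choose_representative(g, ["b", "a"], ["bg"]) == "a"

    def test_chimera_uses_first_available_source(self):
        g1 = self._gene({"X": "AAAA", "bg": "AAAA"})
        g2 = smx.GeneAlignment("g2", {"Y": "CCCC", "bg": "CCCC"})
        otu = smx.OTUDefinition("XY", ["X", "Y"])
        assignment = smx.make_chimera([g1, g2], otu)
        assert assignment == {"g": "X", "g2": "Y"}

    def test_absent_otu_row_is_missing(self):
        g = self._gene({"other": "AAAA"})
        otu = smx.OTUDefinition("XY", ["X"])
        sm, _ = smx.concatenate([g], [otu, smx.OTUDefinition("other", ["other"])])
        assert sm.rows["XY"] == "????"


class TestFilterAndConcatenate:
    def _genes_with_missing(self, n_otus, n_absent):
        taxa = [f"o{i}" for i in range(n_otus)]
        rows = {t: "AAAA" for t in taxa[n_absent:]}
        gene = smx.GeneAlignment("g", rows)
        otus = [smx.OTUDefinition(t, [t]) for t in taxa]
        return gene, otus

    def test_boundary_at_fifteen_missing(self):
        gene16, otus = self._genes_with_missing(63, 16)
        assert smx.filter_by_missing([gene16], otus, 15) == []
        gene15, otus = self._genes_with_missing(63, 15)
        assert smx.filter_by_missing([gene15], otus, 15) == [gene15]
        complete, otus = self._genes_with_missing(63, 0)
        assert smx.filter_by_missing([complete], otus, 15) == [complete]

    def test_concatenate_partitions_and_missing(self):
        g1 = smx.GeneAlignment("g1", {"a": "ARN", "b": "ARN"})
        g2 = smx.GeneAlignment("g2", {"a": "DCQE"})
        sm, stats = smx.concatenate([g1, g2])
        assert stats["n_sites"] == 7
        assert sm.partitions == {"g1": (0, 3), "g2": (3, 7)}
        assert stats["pct_missing"] == pytest.approx(100 * 4 / 14)
        # user-facing report is 1-based inclusive
        assert sm.partition_report() == [("g1", 1, 3), ("g2", 4, 7)]

    def test_complete_matrix_has_no_missing(self):
        g1 = smx.GeneAlignment("g1", {"a": "ARN", "b": "ARN"})
        g2 = smx.GeneAlignment("g2", {"a": "DCQE", "b": "DCQE"})
        _, stats = smx.concatenate([g1, g2])
        assert stats["pct_missing"] == 0.0

    def test_duplicate_gene_ids_rejected(self):
        g = smx.GeneAlignment("g", {"a": "AA"})
        with pytest.raises(smx.AlignmentError, match="duplicate"):
            smx.concatenate([g, g])

    def test_extraction_recovers_input_genes(self, tiny_case):
        sm = tiny_case.matrix
        for gene in tiny_case.genes:
            assert sm.extract_gene(gene.gene_id).sequences == gene.sequences

    def test_pct_missing_invariant_under_gene_reorder(self, tiny_case):
        genes = list(tiny_case.genes)
        sm1, s1 = smx.concatenate(genes)
        sm2, s2 = smx.concatenate(genes[::-1])
        assert s1["pct_missing"] == pytest.approx(s2["pct_missing"])


class TestJackknife:
    def test_k_equals_n_returns_full_set(self):
        ids = [f"g{i}" for i in range(10)]
        scheme = smx.gene_jackknife(ids, k=10, replicates=5, seed=1)
        for rep in scheme.replicates:
            assert sorted(rep) == sorted(ids)

    def test_default_dimensions(self):
        ids = [f"g{i}" for i in range(258)]
        scheme = smx.gene_jackknife(ids, k=130, replicates=100, seed=3)
        assert len(scheme.replicates) == 100
        assert all(len(set(rep)) == 130 for rep in scheme.replicates)

    def test_seed_reproducibility(self):
        ids = [f"g{i}" for i in range(50)]
        a = smx.gene_jackknife(ids, 20, 10, seed=7)
        b = smx.gene_jackknife(ids, 20, 10, seed=7)
        c = smx.gene_jackknife(ids, 20, 10, seed=8)
        assert a.replicates == b.replicates
        assert a.replicates != c.replicates

    def test_k_too_large_rejected(self):
        with pytest.raises(smx.AlignmentError):
            smx.gene_jackknife(["g1"], k=2)

    def test_jackknife_support_percentages(self):
        ab = trx.parse_newick("((A,B),(C,D));")
        ac = trx.parse_newick("((A,C),(B,D));")
        js = smx.jackknife_support([ab] * 42 + [ac] * 58)
        assert js[frozenset({"A", "B"})] == pytest.approx(42.0)
        assert js[frozenset({"A", "C"})] == pytest.approx(58.0)
        js_all = smx.jackknife_support([ab] * 100)
        assert js_all[frozenset({"A", "B"})] == pytest.approx(100.0)
        assert frozenset({"A", "C"}) not in js_all


class TestPairwiseIdentity:
    def _sm(self, rows):
        parts = {"g": (0, len(next(iter(rows.values()))))}
        return smx.Supermatrix(list(rows), rows, parts)

    def test_identical_rows(self):
        sm = self._sm({"a": "ARND", "b": "ARND"})
        assert smx.pairwise_identity(sm, "a", "b") == pytest.approx(100.0)

    def test_gaps_and_unknowns_masked(self):
        sm = self._sm({"a": "AC-D", "b": "ACXD"})
        assert smx.pairwise_identity(sm, "a", "b") == pytest.approx(100.0)

    def test_matches_brute_force_scan_and_symmetry(self, rng):
        chars = "ARND-X?"
        for _ in range(20):
            a = "".join(rng.choice(list(chars), 30))
            b = "".join(rng.choice(list(chars), 30))
            sm = self._sm({"a": a, "b": b})
            comparable = [
                (x, y)
                for x, y in zip(a, b)
                if x not in "-X?" and y not in "-X?"
            ]
            if not comparable:
                with pytest.raises(smx.AlignmentError):
                    smx.pairwise_identity(sm, "a", "b")
                continue
            expect = 100 * sum(x == y for x, y in comparable) / len(comparable)
            assert smx.pairwise_identity(sm, "a", "b") == pytest.approx(expect)
            assert smx.pairwise_identity(sm, "b", "a") == pytest.approx(expect)

    def test_no_overlap_rejected(self):
        sm = self._sm({"a": "AA--", "b": "--AA"})
        with pytest.raises(smx.AlignmentError):
            smx.pairwise_identity(sm, "a", "b")
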