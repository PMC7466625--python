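"""Insertion filtering, gene-distance binning and the count reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mosste.io import GenomicFeature, InsertionCall
from mosste.mobility import (
    UNBOUNDED,
    MobilityConfig,
    bin_insertions,
    filter_insertions,
    near_gene_fraction,
    nearest_gene_bin,
    polymorphism_count_matrix,
)
from mosste.published import (
    GENE_DISTANCE_BINS,
    POLYMORPHISM_COUNTS,
    expand_bins_to_binned,
    expand_counts_to_calls,
)
from mosste.simulate import FamilySpec, GenomeSimConfig, gen_insertion_calls, gen_te_genome


def _call(zygosity=1.0, in_ref=False, pos=100, acc="A", fam="F", seq="chr1"):
    return InsertionCall(acc, seq, pos, fam, zygosity, in_ref)


class TestFilter:
    def test_threshold_is_inclusive(self):
        kept = filter_insertions([_call(zygosity=0.7)])
        assert len(kept) == 1  # "at least 0.7" keeps the boundary call

    def test_reference_insertions_dropped(self):
        assert filter_insertions([_call(in_ref=True)]) == []

    def test_truth_recount(self):
        truth = {"A": [("chr1", i, "F") for i in range(100)]}
        calls, df = gen_insertion_calls(
            truth, zygosity_dist=("uniform", 0.8, 1.0), fp_rate=0.2, seed=1
        )
        kept = filter_insertions(calls)
        assert len(kept) == 100
        assert all(c.zygosity >= 0.7 for c in kept)

    @given(
        zygs=st.lists(st.floats(0, 1), min_size=0, max_size=50),
    )
    def test_idempotent(self, zygs):
        calls = [_call(zygosity=z) for z in zygs]
        once = filter_insertions(calls)
        assert filter_insertions(once) == once


_GENES = [
    GenomicFeature("chr1", 1000, 3000, "+", "gene", copy_id="g1"),
    GenomicFeature("chr1", 10_000, 12_000, "-", "gene", copy_id="g2"),
    GenomicFeature("chr2", 500, 800, "+", "gene", copy_id="g3"),
]


class TestBinning:
    def test_inside(self):
        b = nearest_gene_bin(_call(pos=2000), _GENES)
        assert (b.distance_bp, b.bin) == (0, "inside")

    def test_downstream_500(self):
        b = nearest_gene_bin(_call(pos=3499), _GENES)
        assert (b.distance_bp, b.bin) == (500, "near")

    def test_exactly_1kb_is_far(self):
        b = nearest_gene_bin(_call(pos=3999), _GENES)
        assert (b.distance_bp, b.bin) == (1000, "far")

    def test_chromosome_without_genes(self):
        b = nearest_gene_bin(_call(pos=50, seq="chr9"), _GENES)
        assert (b.distance_bp, b.bin) == (UNBOUNDED, "far")

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(80)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 195_000))
            genes.append(
                GenomicFeature(f"chr{rng.integers(1, 3)}", s, s + 2000, "+", "gene",
                               copy_id=f"g{i}")
            )
        cfg = MobilityConfig()
        for _ in range(300):
            call = _call(pos=int(rng.integers(0, 200_000)),
                         seq=f"chr{rng.integers(1, 3)}")
            got = nearest_gene_bin(call, genes, cfg)
            # O(n*m) oracle
            best = UNBOUNDED
            for g in genes:
                if g.seq_id != call.seq_id:
                    continue
                if g.start <= call.position < g.end:
                    d = 0
                elif call.position < g.start:
                    d = g.start - call.position
                else:
                    d = call.position - g.end + 1
                if best == UNBOUNDED or d < best:
                    best = d
            if best == 0:
                expect = "inside"
            elif best != UNBOUNDED and best < 1000:
                expect = "near"
            else:
                expect = "far"
            assert (got.distance_bp, got.bin) == (best, expect)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(81)
        calls = [_call(pos=int(p)) for p in rng.integers(0, 20_000, size=30)]
        shuffled_genes = list(_GENES)
        rng.shuffle(shuffled_genes)
        a = [(b.distance_bp, b.bin) for b in bin_insertions(calls, _GENES)]
        b = [(x.distance_bp, x.bin) for x in bin_insertions(calls, shuffled_genes)]
        assert a == b


class TestCountMatrix:
    def test_empty(self):
        assert polymorphism_count_matrix([]).empty

    def test_published_accession_totals(self):
        """Call-level expansion of the published per-family counts
        reproduces the printed accession totals and grand total."""
        mat = polymorphism_count_matrix(filter_insertions(expand_counts_to_calls()))
        row_totals = mat.sum(axis=1)
        assert row_totals["Reute"] == 27
        assert row_totals["Kaskaskia"] == 179
        assert row_totals["Villersexel"] == 303
        assert mat.to_numpy().sum() == 509
        assert mat.loc["Villersexel", "RLG1"] == POLYMORPHISM_COUNTS["Villersexel"]["RLG1"]

    def test_matrix_conservation(self):
        truth = {
            acc: [("chr1", i, f"F{i % 3}") for i in range(n)]
            for acc, n in (("A", 13), ("B", 7))
        }
        calls, _ = gen_insertion_calls(truth, zygosity_dist=1.0, seed=2)
        mat = polymorphism_count_matrix(calls)
        assert mat.to_numpy().sum() == len(calls)
        assert mat.loc["A"].sum() == 13 and mat.loc["B"].sum() == 7

    def test_family_alias_merging(self):
        calls = [_call(fam="tRLC5"), _call(fam="RLC5"), _call(fam="RLG1")]
        cfg = MobilityConfig(family_aliases={"tRLC5": "tRLC5/RLC5", "RLC5": "tRLC5/RLC5"})
        mat = polymorphism_count_matrix(calls, cfg)
        assert mat.loc["A", "tRLC5/RLC5"] == 2


class TestNearGeneFraction:
    def test_all_inside(self):
        binned = bin_insertions([_call(pos=2000)], _GENES)
        assert near_gene_fraction(binned) == 100.0

    def test_published_bins_give_20_percent(self):
        """Published distance bins: (38 + 65) / 509 -> 20.2%, i.e. the
        'one in five insertions near genes' headline."""
        assert near_gene_fraction(expand_bins_to_binned()) == 20.2
        total = sum(sum(v.values()) for v in GENE_DISTANCE_BINS.values())
        assert total == 509

    def test_simulated_adjacency_recovered(self):
        """Insertions at planted TE positions in a genome with 20% TE-gene
        adjacency recover ~20% near-gene fraction."""
        g = gen_te_genome(
            GenomeSimConfig(
                families=[
                    FamilySpec("F", n_full=10, n_fragments=70, n_solo_ltr=20,
                               ltr_len=400)
                ],
                chrom_len=900_000,
                n_genes=15,
                te_gene_adjacency_fraction=0.2,
                seed=4,
            )
        )
        calls = [
            InsertionCall("A", row.seq_id, int(row.start), row.family, 1.0, False)
            for row in g.truth.itertuples()
        ]
        pct = near_gene_fraction(bin_insertions(calls, g.gene_features))
        n = len(calls)
        assert abs(pct / 100 - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n) + 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no calls"):
            near_gene_fraction([])
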