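"""K2P dating, expressed-copy identification and the age-shift summary."""

import math

import numpy as np
import pytest
from Bio import Align
from hypothesis import given
from hypothesis import strategies as st

from mosste.align import LTRAlignment, global_align_ltrs
from mosste.dating import (
    ExpressedCopyRule,
    date_all_copies,
    estimate_age,
    find_expressed_copies,
    kimura2p,
    summarize_age_shift,
)
from mosste.io import SeqRecord, revcomp
from mosste.simulate import (
    FamilySpec,
    GenomeSimConfig,
    LTRSimConfig,
    gen_ltr_element,
    gen_te_genome,
)


def _aln(n_same, n_ts, n_tv):
    a = "A" * (n_same + n_ts + n_tv)
    b = "A" * n_same + "G" * n_ts + "C" * n_tv
    return LTRAlignment(a, b)


class TestKimura2p:
    def test_identity_gives_zero(self):
        P, Q, K = kimura2p(_aln(100, 0, 0))
        assert (P, Q, K) == (0.0, 0.0, 0.0)

    def test_closed_form_transitions_only(self):
        """P=0.1, Q=0 -> K = -0.5 ln 0.8, evaluated independently."""
        P, Q, K = kimura2p(_aln(90, 10, 0))
        assert (P, Q) == (0.1, 0.0)
        assert K == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)

    @given(
        n_ts=st.integers(0, 25),
        n_tv=st.integers(0, 20),
    )
    def test_correction_dominates_raw_divergence(self, n_ts, n_tv):
        P, Q, K = kimura2p(_aln(100, n_ts, n_tv))
        assert K >= P + Q - 1e-12
        if n_ts + n_tv == 0:
            assert K == 0.0
        else:
            assert K > P + Q

    def test_saturation_boundary(self):
        # P = 0.4, Q = 0.2 puts 1 - 2P - Q exactly at 0
        with pytest.raises(ValueError, match="saturated divergence"):
            kimura2p(_aln(40, 40, 20))

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            kimura2p(_aln(30, 5, 5))

    def test_gap_and_n_columns_excluded(self):
        a = "A" * 60 + "--" + "N" + "G" * 10
        b = "A" * 60 + "CC" + "A" + "A" * 10
        P, Q, K = kimura2p(LTRAlignment(a, b))
        assert P == pytest.approx(10 / 70)
        assert Q == 0.0


class TestEstimateAge:
    def test_arithmetic(self):
        assert estimate_age(0.0) == 0.0
        assert estimate_age(0.0018, 9e-9) == pytest.approx(100_000)
        assert estimate_age(0.018, 9e-9) == pytest.approx(1_000_000)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            estimate_age(0.1, 0.0)


class TestParameterRecovery:
    def test_mean_age_within_15pct_and_monotone(self):
        """Simulated LTR pairs at 0.25/0.5/1/2 Myr (r=9e-9, 1 kb LTRs, 100
        replicates each): mean estimate within 15% of truth, monotone."""
        rng = np.random.default_rng(60)
        means = []
        for age in (0.25e6, 0.5e6, 1e6, 2e6):
            cfg = LTRSimConfig(age_T=age, rate_r=9e-9, ltr_len=1000, internal_len=200)
            estimates = []
            for _ in range(100):
                elem = gen_ltr_element(cfg, rng)
                aln = global_align_ltrs(
                    SeqRecord("l5", elem.element.sequence[:1000]),
                    SeqRecord("l3", elem.element.sequence[-1000:]),
                )
                _, _, K = kimura2p(aln)
                estimates.append(estimate_age(K))
            mean = float(np.mean(estimates))
            assert mean == pytest.approx(age, rel=0.15)
            means.append(mean)
        assert means == sorted(means)


from functools import lru_cache


@lru_cache(maxsize=2)
def _young_old_genome(seed=70):
    return gen_te_genome(
        GenomeSimConfig(
            families=[
                FamilySpec(
                    "RLG_A",
                    n_full=20,
                    n_fragments=4,
                    n_solo_ltr=1,
                    ages=[5e5] * 8 + [5e6] * 12,
                    extra_divergence=[0.0] * 8 + [0.3] * 12,
                )
            ],
            chrom_len=400_000,
            seed=seed,
        )
    )


# Full-DP oracle for the 80/80 rule: best local alignment on either strand,
# identity over columns, aligned-query fraction.
_oracle = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-2,
    open_gap_score=-2, extend_gap_score=-2,
)


def _oracle_80_80(assembly: str, copy_seq: str) -> bool:
    best = None
    for q in (assembly, revcomp(assembly)):
        score = _oracle.score(q, copy_seq)
        if best is None or score > best[0]:
            best = (score, q)
    aln = _oracle.align(best[1], copy_seq)[0]
    idx = aln.indices
    matches = sum(
        1
        for i, j in zip(idx[0], idx[1])
        if i >= 0 and j >= 0 and best[1][i] == copy_seq[j]
    )
    identity = matches / idx.shape[1]
    q_idx = [i for i in idx[0] if i >= 0]
    cov = (max(q_idx) + 1 - min(q_idx)) / len(assembly)
    return identity >= 0.8 and cov >= 0.8


class TestFindExpressedCopies:
    def test_exact_copy_found_in_both_modes(self, bundle):
        row = bundle.truth[bundle.truth.category == "full"].iloc[0]
        asm = SeqRecord("asm", bundle.chrom(row.seq_id)[row.start : row.end])
        for mode in ("best_hit", "similarity_80_80"):
            found = find_expressed_copies(
                asm, bundle.genome, bundle.te_features, ExpressedCopyRule(mode=mode)
            )
            assert row.copy_id in found

    def test_seventy_percent_identity_excluded(self):
        rng = np.random.default_rng(71)
        from conftest import random_dna
        from mosste.io import GenomicFeature

        base = random_dna(rng, 3000)
        diverged = list(base)
        for i in rng.choice(3000, 900, replace=False):
            diverged[i] = rng.choice([b for b in "ACGT" if b != diverged[i]])
        genome = [SeqRecord("chr1", "".join(diverged))]
        feats = [GenomicFeature("chr1", 0, 3000, "+", "te_copy", "F", "c1")]
        found = find_expressed_copies(
            SeqRecord("asm", base), genome, feats, ExpressedCopyRule()
        )
        assert found == []

    def test_young_subset_matches_full_alignment_oracle(self):
        """Consensus assembly vs 20 planted copies (8 young, 12 degenerate):
        the 80/80 set equals the brute-force full-alignment oracle's set and
        is exactly the young subset."""
        g = _young_old_genome()
        fam = g.families[0]
        asm = SeqRecord("asm", fam.exemplar.sequence)
        found = set(
            find_expressed_copies(asm, g.genome, g.te_features, ExpressedCopyRule())
        )
        chroms = {r.id: r.sequence for r in g.genome}
        oracle = set()
        for f in g.te_features:
            if f.kind != "te_copy":
                continue
            if _oracle_80_80(asm.sequence, chroms[f.seq_id][f.start : f.end]):
                oracle.add(f.copy_id)
        assert found == oracle
        young = set(
            g.truth[(g.truth.category == "full") & (g.truth.age_years == 5e5)].copy_id
        )
        assert found == young


class TestAgeShift:
    def test_dating_recovers_planted_age_structure(self):
        g = _young_old_genome()
        ages = date_all_copies(g.genome, g.te_features)
        assert len(ages) == 20
        merged = ages.merge(g.truth[["copy_id", "age_years"]], on="copy_id")
        young = merged[merged.age_years == 5e5]
        old = merged[merged.age_years == 5e6]
        assert young.T_years.median() < old.T_years.median()

    def test_expressed_group_detected_younger(self):
        g = _young_old_genome()
        ages = date_all_copies(g.genome, g.te_features)
        fam = g.families[0]
        expressed_ids = find_expressed_copies(
            SeqRecord("asm", fam.exemplar.sequence),
            g.genome,
            g.te_features,
            ExpressedCopyRule(),
        )
        expressed = ages[ages.copy_id.isin(expressed_ids)]
        summary = summarize_age_shift(expressed, ages)
        assert summary["median_K_expressed"] < summary["median_K_all"]
        assert summary["shift_pvalue"] < 0.05

    def test_null_case_no_shift(self):
        g = _young_old_genome()
        ages = date_all_copies(g.genome, g.te_features)
        summary = summarize_age_shift(ages, ages)
        assert summary["median_K_expressed"] == summary["median_K_all"]
        assert summary["shift_pvalue"] > 0.05

    def test_singleton_group_insufficient_n(self):
        g = _young_old_genome()
        ages = date_all_copies(g.genome, g.te_features)
        summary = summarize_age_shift(ages.iloc[:1], ages)
        assert summary["shift_statistic"] == "insufficient n"
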