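import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agame.assembly_eval import (
    best_hits,
    n50,
    percent_reference_assembled,
    reciprocal_best_hits,
    summarize_evaluation,
)
from agame.core_io import AlignmentRecord
from agame.endtag_assign import InsertClassification


def rec(q, s, s_start, s_end, bitscore=100.0, evalue=1e-10):
    return AlignmentRecord(
        query_id=q, subject_id=s, pct_identity=99.0,
        aln_length=abs(s_end - s_start) + 1, mismatches=0, gap_opens=0,
        q_start=1, q_end=abs(s_end - s_start) + 1,
        s_start=s_start, s_end=s_end, evalue=evalue, bitscore=bitscore,
    )


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([10], 10), ([5, 4, 3, 2, 1], 4), ([2, 2, 2], 2), ([1, 1, 1, 100], 100)],
    )
    def test_hand_worked(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=1,
                    max_size=50))
    def test_matches_brute_force_and_is_permutation_invariant(self, lengths):
        # oracle: scan all candidate values, take the largest L whose
        # descending cumulative sum first reaches half the total
        total = sum(lengths)
        acc, expected = 0, None
        for x in sorted(lengths, reverse=True):
            acc += x
            if acc >= total / 2:
                expected = x
                break
        value = n50(lengths)
        assert value == expected
        assert value in lengths
        assert n50(list(reversed(sorted(lengths)))) == value


class TestPercentAssembled:
    def test_overlapping_intervals_union(self):
        alns = [rec("c1", "r1", 1, 500), rec("c2", "r1", 251, 750)]
        assert percent_reference_assembled(alns, {"r1": 1000}) == 75.0

    def test_no_alignments_is_zero(self):
        assert percent_reference_assembled([], {"r1": 1000}) == 0.0

    def test_full_single_interval(self):
        assert percent_reference_assembled(
            [rec("c1", "r1", 1, 1000)], {"r1": 1000}
        ) == 100.0

    def test_minus_strand_interval_normalized(self):
        alns = [rec("c1", "r1", 500, 1)]
        assert percent_reference_assembled(alns, {"r1": 1000}) == 50.0

    def test_eligible_contigs_filter(self):
        alns = [rec("tagged", "r1", 1, 500), rec("untagged", "r1", 501, 1000)]
        assert percent_reference_assembled(
            alns, {"r1": 1000}, eligible_contigs={"tagged"}
        ) == 50.0

    def test_interval_beyond_reference_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            percent_reference_assembled([rec("c", "r1", 1, 1001)], {"r1": 1000})

    def test_monotone_and_duplicate_stable(self, rng):
        refs = {"r1": 2000, "r2": 1500}
        alns = []
        prev = 0.0
        for _ in range(40):
            r = "r1" if rng.random() < 0.5 else "r2"
            lo = int(rng.integers(1, refs[r] - 10))
            hi = int(rng.integers(lo, refs[r]))
            alns.append(rec("c", r, lo, hi))
            cur = percent_reference_assembled(alns, refs)
            assert cur >= prev - 1e-12
            prev = cur
            # duplicating the last interval changes nothing
            assert percent_reference_assembled(alns + [alns[-1]], refs) == cur

    def test_matches_boolean_mask_oracle(self, rng):
        for _ in range(200):
            refs = {f"r{j}": int(rng.integers(50, 400)) for j in range(3)}
            masks = {r: np.zeros(L, dtype=bool) for r, L in refs.items()}
            alns = []
            for _ in range(int(rng.integers(0, 15))):
                r = f"r{rng.integers(0, 3)}"
                lo = int(rng.integers(1, refs[r]))
                hi = int(rng.integers(lo, refs[r] + 1))
                if rng.random() < 0.5:
                    alns.append(rec("c", r, lo, hi))
                else:
                    alns.append(rec("c", r, hi, lo))  # minus strand
                masks[r][lo - 1 : hi] = True
            expected = 100.0 * sum(m.sum() for m in masks.values()) / sum(refs.values())
            assert percent_reference_assembled(alns, refs) == pytest.approx(expected)


class TestRBH:
    def test_mutual_best_pair(self):
        fwd = [rec("r1", "p1", 1, 100, bitscore=200)]
        back = [rec("p1", "r1", 1, 100, bitscore=200)]
        assert reciprocal_best_hits(fwd, back) == {("r1", "p1")}

    def test_non_mutual_excluded(self):
        # r2's best is p1, but p1's best is r1
        fwd = [
            rec("r1", "p1", 1, 100, bitscore=300),
            rec("r2", "p1", 1, 100, bitscore=250),
            rec("r2", "p2", 1, 100, bitscore=100),
        ]
        back = [
            rec("p1", "r1", 1, 100, bitscore=300),
            rec("p1", "r2", 1, 100, bitscore=250),
            rec("p2", "r2", 1, 100, bitscore=100),
        ]
        # r2's best hit (p1) does not reciprocate, so r2 pairs with nothing
        assert reciprocal_best_hits(fwd, back) == {("r1", "p1")}

    def test_self_search_pairs_everything_with_itself(self):
        ids = ["a", "b", "c"]
        table = [
            rec(q, s, 1, 100, bitscore=500 if q == s else 50)
            for q in ids for s in ids
        ]
        assert reciprocal_best_hits(table, table) == {(i, i) for i in ids}

    def test_tiebreak_bitscore_then_evalue_then_subject(self):
        alns = [
            rec("q", "s2", 1, 100, bitscore=100, evalue=1e-5),
            rec("q", "s1", 1, 100, bitscore=100, evalue=1e-5),
            rec("q", "s0", 1, 100, bitscore=100, evalue=1e-4),
        ]
        assert best_hits(alns) == {"q": "s1"}

    def test_fuzzed_against_brute_force(self, rng):
        for _ in range(1000):
            n_r, n_p = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            refs = [f"r{i}" for i in range(n_r)]
            pools = [f"p{i}" for i in range(n_p)]
            score = {
                (r, p): float(rng.integers(10, 500))
                for r in refs for p in pools if rng.random() < 0.7
            }
            fwd = [rec(r, p, 1, 100, bitscore=s) for (r, p), s in score.items()]
            back = [rec(p, r, 1, 100, bitscore=s) for (r, p), s in score.items()]
            # brute force over the score table
            expected = set()
            for r in refs:
                row = {p: s for (rr, p), s in score.items() if rr == r}
                if not row:
                    continue
                p_best = min(row, key=lambda p: (-row[p], p))
                col = {rr: s for (rr, pp), s in score.items() if pp == p_best}
                r_best = min(col, key=lambda rr: (-col[rr], rr))
                if r_best == r:
                    expected.add((r, p_best))
            got = reciprocal_best_hits(fwd, back)
            assert got == expected
            assert len(got) <= min(n_r, n_p)
            # symmetry: swapping the tables transposes the pairs
            assert reciprocal_best_hits(back, fwd) == {(p, r) for r, p in got}


def _cls(insert, category, contigs):
    return InsertClassification(
        insert_id=insert, n_tags_available=2, category=category,
        contigs=set(contigs),
    )


class TestSummarize:
    def test_perfect_assembly_row(self):
        classifications = [_cls(f"i{j}", "complete", {f"c{j}"}) for j in range(3)]
        lengths = {f"c{j}": 30000 for j in range(3)}
        alns = [rec(f"c{j}", f"r{j}", 1, 30000) for j in range(3)]
        refs = {f"r{j}": 30000 for j in range(3)}
        prots = [rec(f"rp{j}", f"pp{j}", 1, 100, bitscore=500) for j in range(4)]
        back = [rec(f"pp{j}", f"rp{j}", 1, 100, bitscore=500) for j in range(4)]
        row = summarize_evaluation(
            classifications, lengths, alns, refs, prots, back, 4, "toy"
        )
        assert row.complete == 3 and row.two_of_two == 0 and row.partial == 0
        assert row.pct_assembled == 100.0
        assert row.pct_ref_proteins == 100.0
        assert row.n50 == 30000 and row.total_length == 90000

    def test_empty_assembly_row(self):
        classifications = [_cls("i0", "unassigned", set())]
        row = summarize_evaluation(
            classifications, {}, [], {"r0": 1000}, [], [], 5, "empty"
        )
        assert row.complete == 0 and row.pct_assembled == 0.0
        assert row.n50 is None and "NA" in row.to_tsv()

    def test_split_reference_halves(self):
        # each insert split into two tagged contigs covering the reference
        classifications = [_cls(f"i{j}", "two_of_two", {f"c{j}a", f"c{j}b"})
                           for j in range(2)]
        lengths = {f"c{j}{h}": 15000 for j in range(2) for h in "ab"}
        alns = [rec(f"c{j}a", f"r{j}", 1, 15000) for j in range(2)] + [
            rec(f"c{j}b", f"r{j}", 15001, 30000) for j in range(2)
        ]
        refs = {f"r{j}": 30000 for j in range(2)}
        row = summarize_evaluation(
            classifications, lengths, alns, refs, [], [], 1, "halves"
        )
        assert row.two_of_two == 2 and row.pct_assembled == 100.0

    def test_rank_correlation_between_coverage_and_protein_recovery(self, rng):
        # degrading assemblies: fewer covered bases should track fewer RBHs
        from scipy.stats import spearmanr

        refs = {"r": 50000}
        n_prot = 40
        pct_asm, pct_rbh = [], []
        for frac in np.linspace(0.2, 1.0, 9):
            covered = int(50000 * frac)
            alns = [rec("c", "r", 1, covered)]
            n_found = int(n_prot * frac)
            fwd = [rec(f"rp{j}", f"pp{j}", 1, 100) for j in range(n_found)]
            back = [rec(f"pp{j}", f"rp{j}", 1, 100) for j in range(n_found)]
            row = summarize_evaluation(
                [_cls("i", "complete", {"c"})], {"c": covered}, alns, refs,
                fwd, back, n_prot, "sweep",
            )
            pct_asm.append(row.pct_assembled)
            pct_rbh.append(row.pct_ref_proteins)
        rho, _ = spearmanr(pct_asm, pct_rbh)
        assert rho > 0.9
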