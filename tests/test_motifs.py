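"""Direct/inverted repeat finders and per-site nucleotide diversity."""

import numpy as np
import pytest

from satdyn.motifs import (
    find_direct_repeats,
    find_inverted_repeats,
    per_site_diversity,
    revcomp,
)
from tests.conftest import random_seq


def brute_direct(seq, min_len=8, max_mismatch=0):
    """Independent oracle: maximal near-equal substring pairs per diagonal,
    truncated to the offset (tandem periodicity rule)."""
    n = len(seq)

    def differs(i, j):
        return seq[i] != seq[j] or seq[i] == "N" or seq[j] == "N"

    found = set()
    for d in range(min_len, n):
        m = n - d
        for s in range(m):
            # left-maximality wrt the mismatch budget
            length = 0
            mism = 0
            while s + length < m:
                if differs(s + length, s + length + d):
                    if mism == max_mismatch:
                        break
                    mism += 1
                length += 1
            if s > 0:
                prev_mism = mism + differs(s - 1, s - 1 + d)
                if prev_mism <= max_mismatch:
                    continue  # extendable leftward: not maximal
            trunc = min(length, d)
            if trunc >= min_len:
                k = sum(1 for t in range(s, s + trunc) if differs(t, t + d))
                found.add((s, s + d, trunc, k))
    # containment dedup, mirroring the reported collapse
    kept = []
    for item in sorted(found, key=lambda r: (r[0], r[1], -r[2])):
        s1, s2, L, k = item
        if any(s1 >= p[0] and s1 + L <= p[0] + p[2] and s2 >= p[1]
               and s2 + L <= p[1] + p[2] and s2 - s1 == p[1] - p[0] for p in kept):
            continue
        kept.append(item)
    return set(kept)


class TestDirectRepeats:
    def test_constructed_repeat_found(self):
        hits = find_direct_repeats("ACGTACGTNNNNACGTACGT")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start1, h.start2, h.length) == (0, 12, 8)

    def test_no_repeats_in_short_unique_sequence(self):
        assert find_direct_repeats("ACGTTGCAACCGGTTA", min_len=8) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 200)
        got = {(h.start1, h.start2, h.length, h.mismatches)
               for h in find_direct_repeats(seq, min_len=6)}
        assert got == brute_direct(seq, min_len=6)

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_with_mismatches(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_seq(rng, 120)
        got = {(h.start1, h.start2, h.length, h.mismatches)
               for h in find_direct_repeats(seq, min_len=6, max_mismatch=1)}
        assert got == brute_direct(seq, min_len=6, max_mismatch=1)

    def test_homopolymer_collapsed(self):
        hits = find_direct_repeats("A" * 30, min_len=8)
        # one hit per admissible offset, each anchored at position 0
        assert all(h.start1 == 0 for h in hits)
        assert len({h.start2 for h in hits}) == len(hits)


def brute_inverted(seq, min_arm, max_loop, max_mismatch):
    """Independent oracle: outward extension around every loop placement,
    with inner/outer mismatch trimming."""
    comp = revcomp(seq)[::-1]  # positionwise complement
    n = len(seq)
    found = set()
    for loop in range(max_loop + 1):
        for a in range(1, n):
            b = a + loop
            if b >= n:
                break
            pairs = []
            t = 1
            while a - t >= 0 and b + t - 1 < n:
                x, y = seq[a - t], seq[b + t - 1]
                pairs.append(x == comp[b + t - 1] and x != "N" and y != "N")
                t += 1
            mismatches = 0
            arm = 0
            for t0, ok in enumerate(pairs, start=1):
                if not ok:
                    if mismatches == max_mismatch:
                        break
                    mismatches += 1
                arm = t0
            inner = 0
            while inner < arm and not pairs[inner]:
                inner += 1
            while arm > inner and not pairs[arm - 1]:
                arm -= 1
            eff = arm - inner
            if eff < min_arm:
                continue
            k = sum(1 for t0 in range(inner, arm) if not pairs[t0])
            s1 = a - arm
            s2 = b + inner
            found.add((s1, s2, eff, k))
    kept = []
    for item in sorted(found, key=lambda r: (-r[2], r[0], r[1])):
        s1, s2, L, k = item
        axis = s1 + s2 + L
        if any(p[0] + p[1] + p[2] == axis and p[0] <= s1 and p[1] + p[2] >= s2 + L
               for p in kept):
            continue
        kept.append(item)
    return set(kept)


class TestInvertedRepeats:
    def test_constructed_inverted_repeat(self):
        hits = find_inverted_repeats("AAACGCGNNNCGCGTTT", min_arm=7, max_mismatch=0)
        assert any(h.length == 7 and h.start1 == 0 and h.start2 == 10 for h in hits)

    def test_restriction_site_palindrome(self):
        hits = find_inverted_repeats("GAATTC", min_arm=3, max_loop=0, max_mismatch=0)
        assert len(hits) == 1
        assert hits[0].kind == "palindrome"
        assert hits[0].loop == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 150)
        got = {(h.start1, h.start2, h.length, h.mismatches)
               for h in find_inverted_repeats(seq, min_arm=5, max_loop=20, max_mismatch=1)}
        assert got == brute_inverted(seq, min_arm=5, max_loop=20, max_mismatch=1)

    @pytest.mark.parametrize("seed", range(4))
    def test_revcomp_mirror_symmetry(self, seed):
        """Inverted repeats map onto themselves (coordinate-mirrored) when
        the input is reverse-complemented."""
        rng = np.random.default_rng(50 + seed)
        seq = random_seq(rng, 120)
        n = len(seq)
        fwd = find_inverted_repeats(seq, min_arm=5, max_loop=20, max_mismatch=0)
        rev = find_inverted_repeats(revcomp(seq), min_arm=5, max_loop=20, max_mismatch=0)
        mirrored = {(n - (h.start2 + h.length), n - (h.start1 + h.length), h.length)
                    for h in fwd}
        assert {(h.start1, h.start2, h.length) for h in rev} == mirrored


class TestDiversity:
    def test_identical_rows_zero_everywhere(self):
        prof = per_site_diversity(["ACGTACGT"] * 5)
        assert np.allclose(prof.pi, 0.0)

    def test_single_divergent_column(self):
        prof = per_site_diversity(["ACGTACGTAC", "ACGAACGTAC"])
        assert prof.pi[3] == pytest.approx(1.0)
        assert prof.pi[[0, 1, 2, 4]].sum() == 0.0

    def test_window_means_are_column_means(self, rng):
        rows = [random_seq(rng, 40) for _ in range(4)]
        prof = per_site_diversity(rows, window=5, step=5)
        for w, start in zip(prof.window_pi, range(0, 36, 5)):
            assert w == pytest.approx(np.nanmean(prof.pi[start:start + 5]))

    def test_row_permutation_invariant(self, rng):
        rows = [random_seq(rng, 30) for _ in range(5)]
        p1 = per_site_diversity(rows).pi
        p2 = per_site_diversity(rows[::-1]).pi
        np.testing.assert_allclose(p1, p2)

    def test_sparse_column_undefined(self):
        prof = per_site_diversity(["AC-", "A--", "AG-"])
        assert not np.isnan(prof.pi[0])
        assert np.isnan(prof.pi[1]) or prof.pi[1] >= 0  # one base only at col 1
        assert np.isnan(prof.pi[2])

    def test_uniform_divergence_mean_within_ci(self):
        """Mean pi over monomers mutated at 5% per site from one ancestor
        matches the pairwise-difference expectation."""
        rng = np.random.default_rng(9)
        anc = random_seq(rng, 300)
        rows = []
        for _ in range(20):
            s = list(anc)
            for i in range(len(s)):
                if rng.random() < 0.05:
                    s[i] = "ACGT"[rng.integers(4)]
            rows.append("".join(s))
        prof = per_site_diversity(rows)
        # two rows differ at a site if at least one mutated to a different base
        p_mut = 0.05 * 3 / 4
        expect = 2 * p_mut * (1 - p_mut) + p_mut**2 * (2 / 3)
        se = np.sqrt(expect * (1 - expect) / 300)
        assert abs(np.nanmean(prof.pi) - expect) < 4 * se

    def test_conserved_run_flagged(self, rng):
        var = [random_seq(rng, 20) for _ in range(6)]
        rows = [v + "ACGTACGTACGT" for v in var]
        prof = per_site_diversity(rows, conserved_floor=0.05, conserved_min_run=8)
        assert any(start >= 20 for start, _ in prof.conserved_runs)
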