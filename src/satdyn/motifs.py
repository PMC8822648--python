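"""Internal repeats, dyad symmetries and per-position nucleotide diversity.

Short internal direct repeats within a monomer hint at functional
motifs; inverted repeats (dyad symmetries) allow stem-loop/cruciform
non-B DNA conformations.  Per-position nucleotide diversity (pi) over a
monomer alignment locates conserved motifs as runs of low-diversity
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatMotif:
    """A pair of repeated segments within one sequence (0-based starts)."""

    kind: Literal["direct", "inverted", "palindrome"]
    start1: int
    start2: int
    length: int
    mismatches: int

    @property
    def loop(self) -> int:
        """Spacer length between the two segments (inverted/palindrome)."""
        return self.start2 - (self.start1 + self.length)


def find_direct_repeats(
    seq: str,
    min_len: int = 8,
    max_mismatch: int = 0,
) -> list[RepeatMotif]:
    """All maximal non-overlapping pairs of near-equal substrings.

    A hit is ``(i, j, L)`` with ``j >= i + L`` (segments do not overlap),
    at most `max_mismatch` mismatches and ``L >= min_len``, maximal in the
    sense that it cannot be extended on either side within the mismatch
    budget.  A maximal window longer than its offset ``d = j - i`` (a
    tandem periodicity, e.g. a homopolymer) is truncated to length ``d``
    anchored at the window start, which collapses the redundant shifted
    hits deterministically.
    """
    seq = seq.upper()
    n = len(seq)
    out: list[RepeatMotif] = []
    for d in range(min_len, n):  # offset between the two segment starts
        m = n - d  # diagonal length
        if m < min_len:
            break
        mism = [
            t for t in range(m)
            if seq[t] != seq[t + d] or seq[t] == "N" or seq[t + d] == "N"
        ]
        for start, length, k in _max_windows(m, mism, max_mismatch):
            length = min(length, d)  # non-overlap cap: L <= offset
            if length < min_len:
                continue
            k_eff = sum(1 for t in mism if start <= t < start + length)
            out.append(RepeatMotif("direct", start, start + d, length, k_eff))
    # deduplicate hits that became identical after the overlap cap
    uniq = sorted(set(out), key=lambda r: (r.start1, r.start2, -r.length))
    kept: list[RepeatMotif] = []
    for r in uniq:
        if any(r.start1 >= p.start1 and r.start1 + r.length <= p.start1 + p.length
               and r.start2 >= p.start2 and r.start2 + r.length <= p.start2 + p.length
               and r.start2 - r.start1 == p.start2 - p.start1
               for p in kept):
            continue
        kept.append(r)
    return kept


def _max_windows(m: int, mismatch_pos: list[int], k: int):
    """Maximal windows of [0, m) containing at most k mismatch positions.

    Yields (start, length, n_mismatches).  Windows are delimited by the
    (k+1)-th mismatch on either side; consecutive windows overlap.
    """
    pts = [-1] + mismatch_pos + [m]
    nmis = len(mismatch_pos)
    if nmis <= k:
        yield 0, m, nmis
        return
    # window i spans (pts[i], pts[i + k + 1]) exclusive of both mismatches
    for i in range(nmis - k + 1):
        lo = pts[i] + 1
        hi = pts[i + k + 1]  # exclusive
        if hi - lo > 0:
            yield lo, hi - lo, k


def find_inverted_repeats(
    seq: str,
    min_arm: int = 6,
    max_loop: int = 50,
    max_mismatch: int = 1,
) -> list[RepeatMotif]:
    """All maximal inverted repeats (dyad symmetries) with bounded loops.

    An inverted repeat is an arm pair ``seq[s1:s1+L]`` / ``seq[s2:s2+L]``
    with ``s2 = s1 + L + loop``, ``0 <= loop <= max_loop``, where the
    second arm is the reverse complement of the first up to
    `max_mismatch` mismatched base pairs.  Arms extend outward from the
    loop; a hit is maximal when no further extension stays within the
    mismatch budget and the sequence bounds, and arms are trimmed so
    that their outermost base pair matches.  Loop 0 hits are reported
    as palindromes.
    """
    seq = seq.upper()
    n = len(seq)
    comp = seq.translate(_COMPLEMENT)
    out: set[RepeatMotif] = set()
    for loop in range(0, max_loop + 1):
        for a in range(1, n):  # a = first position of the loop (end of arm1)
            b = a + loop  # first position of arm2
            if b >= n:
                break
            # pair t: seq[a - t] vs comp of seq[b + t - 1] for t = 1..
            max_t = min(a, n - b)
            mism = []
            for t in range(1, max_t + 1):
                x, y = seq[a - t], seq[b + t - 1]
                if x != comp[b + t - 1] or x == "N" or y == "N":
                    mism.append(t)
            # maximal arm: largest t with <= max_mismatch mismatches
            if len(mism) > max_mismatch:
                arm = mism[max_mismatch] - 1
            else:
                arm = max_t
            # trim inner and outer mismatched pairs off the arm
            mism_set = set(mism)
            inner_trim = 0
            while inner_trim < arm and (inner_trim + 1) in mism_set:
                inner_trim += 1
            while arm > inner_trim and arm in mism_set:
                arm -= 1
            eff = arm - inner_trim
            if eff < min_arm:
                continue
            k = sum(1 for t in mism if inner_trim < t <= arm)
            s1 = a - arm
            s2 = b + inner_trim
            eff_loop = s2 - (s1 + eff)
            kind = "palindrome" if eff_loop == 0 else "inverted"
            out.add(RepeatMotif(kind, s1, s2, eff, k))
    # drop hits whose arm pair is contained in a larger reported hit with
    # the same dyad axis
    hits = sorted(out, key=lambda r: (-r.length, r.start1, r.start2))
    kept: list[RepeatMotif] = []
    for r in hits:
        axis = r.start1 + r.start2 + r.length  # invariant along one dyad
        if any(
            p.start1 + p.start2 + p.length == axis
            and p.start1 <= r.start1
            and p.start2 + p.length >= r.start2 + r.length
            for p in kept
        ):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.start1, r.start2))
    return kept


@dataclass
class DiversityProfile:
    """Per-column nucleotide diversity over a monomer alignment."""

    pi: np.ndarray  # per column; NaN where < 2 non-gap bases
    window_pi: np.ndarray  # sliding-window means over defined columns
    window: int
    step: int
    conserved_runs: list[tuple[int, int]]  # [start, end) runs of low-pi columns


def per_site_diversity(
    aligned_monomers: Sequence[str],
    window: int = 10,
    step: int = 1,
    conserved_floor: float = 0.05,
    conserved_min_run: int = 8,
) -> DiversityProfile:
    """Nucleotide diversity (pi) per alignment column, with sliding windows.

    Per column, pi is the mean pairwise difference frequency among the
    non-gap, non-N bases (0 when all equal, 1 when every pair differs).
    Columns with fewer than two usable bases are undefined (NaN) and
    excluded from window means.  Runs of at least `conserved_min_run`
    consecutive defined columns with pi below `conserved_floor` are
    flagged as candidate conserved motifs -- an operational criterion,
    reported as such.
    """
    if len(aligned_monomers) < 2:
        raise ValueError("need at least 2 aligned monomers")
    L = len(aligned_monomers[0])
    if any(len(r) != L for r in aligned_monomers):
        raise ValueError("aligned monomers must have equal lengths")
    rows = [r.upper() for r in aligned_monomers]
    pi = np.full(L, np.nan)
    for c in range(L):
        col = [r[c] for r in rows if r[c] in "ACGT"]
        n = len(col)
        if n < 2:
            continue
        npairs = n * (n - 1) // 2
        same = sum(col.count(b) * (col.count(b) - 1) // 2 for b in set(col))
        pi[c] = (npairs - same) / npairs
    wmeans = []
    for start in range(0, max(1, L - window + 1), step):
        chunk = pi[start : start + window]
        ok = chunk[~np.isnan(chunk)]
        wmeans.append(float(ok.mean()) if len(ok) else float("nan"))
    runs = []
    run_start = None
    for c in range(L + 1):
        low = c < L and not np.isnan(pi[c]) and pi[c] < conserved_floor
        if low and run_start is None:
            run_start = c
        elif not low and run_start is not None:
            if c - run_start >= conserved_min_run:
                runs.append((run_start, c))
            run_start = None
    return DiversityProfile(
        pi=pi, window_pi=np.array(wmeans), window=window, step=step,
        conserved_runs=runs,
    )
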