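"""Clustering, naming and network views of homologous satDNA sequences.

Homologous sequence collections are clustered by pairwise identity into
subfamilies (> 95%), families (> 80%) and superfamilies (> 40%) using
single linkage, the closest formal analog of chained all-vs-all
homology searches.  Families are named ``<Prefix>Sat<NN>-<RUL>`` with a
three-letter species prefix, a rank by decreasing genomic abundance and
the repeat-unit length of the family consensus; subfamilies are
lettered A, B, C... by decreasing abundance.  Minimum spanning trees
over subfamily consensuses visualize library sorting between species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from satdyn.distances import align_pair, k2p

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"subfamily": 95.0, "family": 80.0, "superfamily": 40.0}
#: minimum mutual length coverage for a pair to receive an identity at all
MIN_LENGTH_COVERAGE = 0.5


@dataclass(frozen=True)
class SeqRecord:
    """A labelled sequence with genomic abundance (percent of genome)."""

    label: str
    sequence: str
    abundance: float = 0.0


@dataclass
class Subfamily:
    letter: str
    consensus: str
    abundance: float
    members: list[str] = field(default_factory=list)


@dataclass
class SatFamily:
    """A named satDNA family: consensus, subfamilies and landscape context."""

    name: str
    species_prefix: str
    rank: int
    consensus: str
    abundance: float
    subfamilies: list[Subfamily] = field(default_factory=list)
    landscape_mean_divergence: float = float("nan")

    @property
    def rul(self) -> int:
        """Repeat unit length: the consensus length after gap deletion."""
        return len(self.consensus)

    @property
    def at_content(self) -> float:
        s = self.consensus
        return 100.0 * sum(1 for c in s if c in "AT") / len(s) if s else float("nan")


# ---------------------------------------------------------------------------
# identity clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str, circular: bool = True) -> float:
    """Percent identity between two sequences for homology calling.

    Returns 0 (no homology call) when the shorter sequence covers less
    than half of the longer, or when the best alignment score is not
    positive: gapped alignment of unrelated DNA still matches ~half of
    its columns, so raw column identity alone cannot separate distant
    homology from noise, while the +1/-1/-2 score of unrelated pairs is
    reliably negative.
    """
    if min(len(a), len(b)) / max(len(a), len(b)) < MIN_LENGTH_COVERAGE:
        return 0.0
    aln = align_pair(a, b, circular=circular)
    if aln.score <= 0:
        return 0.0
    return aln.identity


def _single_linkage(n: int, edges: list[tuple[int, int]]) -> list[int]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)
    return [find(i) for i in range(n)]


def cluster_sequences(
    seqs: Sequence[SeqRecord],
    thresholds: dict[str, float] | None = None,
    circular: bool = True,
) -> pd.DataFrame:
    """Nested single-linkage clustering at the three identity thresholds.

    Returns a table with one row per input sequence and columns
    ``label, subfamily, family, superfamily`` holding integer cluster ids
    at each level.  Because a higher threshold only removes edges, the
    clusterings nest: every subfamily lies inside exactly one family
    inside one superfamily.  Cluster ids are canonical (assigned by the
    sorted order of member labels), so the result is invariant to input
    order.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if not thr["subfamily"] > thr["family"] > thr["superfamily"]:
        raise ValueError("thresholds must be strictly decreasing: subfamily > family > superfamily")
    order = sorted(range(len(seqs)), key=lambda i: seqs[i].label)
    records = [seqs[i] for i in order]
    n = len(records)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(
                records[i].sequence, records[j].sequence, circular=circular
            )
    out = pd.DataFrame({"label": [r.label for r in records]})
    for level in ("subfamily", "family", "superfamily"):
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if ident[i, j] > thr[level]]
        roots = _single_linkage(n, edges)
        # canonical ids in order of first appearance over sorted labels
        seen: dict[int, int] = {}
        ids = []
        for r in roots:
            if r not in seen:
                seen[r] = len(seen)
            ids.append(seen[r])
        out[level] = ids
    return out


# ---------------------------------------------------------------------------
# consensus building
# ---------------------------------------------------------------------------

def _merge_into_master(master: list[str], anchor_gapped_master: str,
                       anchor_gapped_new: str, new_gapped: str) -> tuple[list[str], str]:
    """Merge one pairwise alignment into a center-star master alignment.

    Both gapped anchors spell the same ungapped sequence; columns are
    reconciled by inserting gap columns on either side where needed.
    """
    out_rows = [""] * len(master)
    out_new = ""
    out_anchor = ""
    i = j = 0
    la, lb = len(anchor_gapped_master), len(anchor_gapped_new)
    while i < la or j < lb:
        a_ch = anchor_gapped_master[i] if i < la else None
        b_ch = anchor_gapped_new[j] if j < lb else None
        if a_ch is not None and b_ch is not None and (a_ch != "-" and b_ch != "-"):
            for r in range(len(master)):
                out_rows[r] += master[r][i]
            out_new += new_gapped[j]
            out_anchor += a_ch
            i += 1
            j += 1
        elif a_ch == "-" or (b_ch is None):
            for r in range(len(master)):
                out_rows[r] += master[r][i]
            out_new += "-"
            out_anchor += "-"
            i += 1
        else:  # b_ch == "-" or a exhausted: column only in the new alignment
            for r in range(len(master)):
                out_rows[r] += "-"
            out_new += new_gapped[j]
            out_anchor += "-"
            j += 1
    out_rows.append(out_new)
    return out_rows, out_anchor


def build_consensus(monomers: Sequence[str], abundances: Sequence[float] | None = None) -> str:
    """Majority-rule consensus via a center-star multiple alignment.

    The star center is the most abundant monomer (ties and missing
    abundances fall back to the first longest).  Per column, the majority
    base wins; base ties break by the fixed order A < C < G < T so the
    result is deterministic and unambiguous (no IUPAC codes, which would
    poison downstream K2P).  Columns where gaps hold the strict majority
    are deleted.
    """
    monomers = [m.upper() for m in monomers]
    if not monomers:
        raise ValueError("need at least one monomer")
    if len(monomers) == 1:
        return monomers[0]
    if abundances is not None:
        center_idx = int(np.argmax(abundances))
    else:
        center_idx = max(range(len(monomers)), key=lambda i: (len(monomers[i]), -i))
    center = monomers[center_idx]
    others = [m for i, m in enumerate(monomers) if i != center_idx]
    master = [center]
    anchor_g = center
    for m in others:
        aln = align_pair(center, m)
        master, anchor_g = _merge_into_master(master, anchor_g, aln.seq_a, aln.seq_b)
    ncol = len(master[0])
    nrow = len(master)
    cons = []
    for c in range(ncol):
        col = [master[r][c] for r in range(nrow)]
        gaps = col.count("-")
        if gaps > nrow / 2:
            continue
        counts = {b: col.count(b) for b in "ACGT"}
        best = max("ACGT", key=lambda b: (counts[b], -"ACGT".index(b)))
        if counts[best] == 0:
            continue
        cons.append(best)
    return "".join(cons)


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def assign_names(
    families: Sequence[Sequence[SeqRecord]],
    species_prefix: str,
    landscape_mean_divergence: Sequence[float] | None = None,
) -> list[SatFamily]:
    """Name family clusters ``<Prefix>Sat<NN>-<RUL>`` by decreasing abundance.

    Each element of `families` is the member-sequence list of one family
    cluster; subfamily structure inside a family is recovered at the 95%
    identity level.  Abundance ties rank deterministically by the label
    of the seed (first) sequence and are logged.
    """
    if len(species_prefix) != 3:
        raise ValueError("species_prefix must be 3 letters, e.g. 'Ode'")
    keyed = []
    for fam in families:
        if not fam:
            raise ValueError("empty family cluster")
        total = sum(r.abundance for r in fam)
        seed = min(r.label for r in fam)
        keyed.append((total, seed, list(fam)))
    totals = [t for t, _, _ in keyed]
    if len(set(totals)) < len(totals):
        log.info("abundance ties present; rank falls back to seed label order")
    keyed.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for rank, (total, _seed, members) in enumerate(keyed, start=1):
        subfams = _subfamilies_of(members)
        consensus = build_consensus(
            [r.sequence for r in members], [r.abundance for r in members]
        )
        name = f"{species_prefix}Sat{rank:02d}-{len(consensus)}"
        fam = SatFamily(
            name=name, species_prefix=species_prefix, rank=rank,
            consensus=consensus, abundance=total, subfamilies=subfams,
        )
        if landscape_mean_divergence is not None:
            fam.landscape_mean_divergence = landscape_mean_divergence[rank - 1]
        out.append(fam)
    return out


def _subfamilies_of(members: Sequence[SeqRecord]) -> list[Subfamily]:
    table = cluster_sequences(members)
    subfams = []
    for sid, group in table.groupby("subfamily"):
        labels = list(group["label"])
        recs = [r for r in members if r.label in labels]
        cons = build_consensus([r.sequence for r in recs], [r.abundance for r in recs])
        subfams.append((sum(r.abundance for r in recs), min(labels), cons, labels))
    subfams.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for i, (abund, _seed, cons, labels) in enumerate(subfams):
        out.append(Subfamily(letter=chr(ord("A") + i), consensus=cons,
                             abundance=abund, members=labels))
    return out


# ---------------------------------------------------------------------------
# minimum spanning trees
# ---------------------------------------------------------------------------

@dataclass
class MSTree:
    nodes: list[str]
    edges: list[tuple[str, str, float]]

    @property
    def total_weight(self) -> float:
        return float(sum(d for _, _, d in self.edges))


def build_mst(
    consensuses: Sequence[SeqRecord],
    distance: Literal["k2p", "mismatch_count"] = "k2p",
    circular: bool = False,
) -> MSTree:
    """Kruskal minimum spanning tree over labelled consensus sequences.

    Edge ties break lexicographically by ``(u, v)`` labels, so the result
    is deterministic.  An undefined pairwise distance (K2P saturation)
    raises with the offending pair named.
    """
    if len(consensuses) < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    labels = [r.label for r in consensuses]
    n = len(labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(consensuses[i].sequence, consensuses[j].sequence, circular=circular)
            if distance == "k2p":
                res = k2p(aln)
                if not res.defined:
                    raise ValueError(
                        f"undefined K2P distance between {labels[i]!r} and {labels[j]!r}"
                    )
                d = res.percent
            elif distance == "mismatch_count":
                d = float(sum(1 for x, y in zip(aln.seq_a, aln.seq_b) if x != y))
            else:
                raise ValueError(f"unknown distance: {distance!r}")
            u, v = sorted((labels[i], labels[j]))
            edges.append((d, u, v))
    edges.sort()
    index = {lab: i for i, lab in enumerate(labels)}
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    for d, u, v in edges:
        ru, rv = find(index[u]), find(index[v])
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v, d))
        if len(chosen) == n - 1:
            break
    return MSTree(nodes=list(labels), edges=chosen)


def mst_from_matrix(labels: Sequence[str], dist: np.ndarray) -> MSTree:
    """Kruskal MST from a precomputed symmetric distance matrix."""
    n = len(labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((labels[i], labels[j]))
            edges.append((float(dist[i, j]), u, v))
    edges.sort()
    index = {lab: i for i, lab in enumerate(labels)}
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    for d, u, v in edges:
        ru, rv = find(index[u]), find(index[v])
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v, d))
    if len(chosen) != n - 1:
        raise ValueError("distance matrix does not connect all nodes")
    return MSTree(nodes=list(labels), edges=chosen)
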