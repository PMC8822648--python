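"""Tandem structure from read data: TSI, junction annotation, array length.

Short paired reads estimate how tandemly structured a satDNA family is:
a pair is *homogeneous* when both mates contain repeat units of the
family and *heterogeneous* when only one does.  The tandem structure
index (TSI) is the percent of homogeneous pairs; the external mate of a
heterogeneous pair samples whatever element flanks the array.  Long
reads yield per-family array intervals whose maximum merged length is
the MAL statistic.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, TextIO

import pandas as pd
from Bio import Align

from satdyn.distances import GAP

log = logging.getLogger(__name__)

#: a mate must be covered by its best family hit over at least this fraction
DEFAULT_MIN_COVERAGE = 0.5
#: ... at at least this percent identity (the family homology threshold)
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MAX_GAP = 3
DEFAULT_MIN_MONOMERS = 1.5


@dataclass(frozen=True)
class ReadPairClass:
    pair_id: str
    family_id: str
    kind: Literal["homogeneous", "heterogeneous"]
    external_annotation: str | None = None
    external_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "homogeneous" and self.external_annotation is not None:
            raise ValueError("homogeneous pairs carry no external annotation")


@dataclass(frozen=True)
class ArrayInterval:
    """A merged tandem array on one read, 0-based half-open coordinates."""

    read_id: str
    family_id: str
    start: int
    end: int
    rul: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.start < 0:
            raise ValueError("negative coordinates rejected")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def monomer_equivalents(self) -> float:
        return self.length / self.rul


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_LOCAL = _local_aligner()


def _tile(consensus: str, span: int) -> str:
    reps = max(2, math.ceil(span / len(consensus)) + 1)
    return consensus * reps


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def best_family_hit(
    read: str,
    library: dict[str, str],
    min_cov: float = DEFAULT_MIN_COVERAGE,
    min_id: float = DEFAULT_MIN_IDENTITY,
    both_strands: bool = True,
) -> str | None:
    """Best satDNA family whose (tiled) consensus locally aligns to the read
    covering >= min_cov of the read length at >= min_id percent identity.

    The consensus is tiled so a read spanning monomer junctions aligns in
    a single pass regardless of phase.
    """
    read = read.upper()
    best: tuple[float, str] | None = None
    strands = (read, _revcomp(read)) if both_strands else (read,)
    for fam, cons in library.items():
        target = _tile(cons.upper(), len(read))
        for oriented in strands:
            aln = _LOCAL.align(oriented, target)
            if len(aln) == 0:
                continue
            top = aln[0]
            ga, gb = str(top[0]), str(top[1])
            matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
            read_cols = sum(1 for x in ga if x != GAP)
            cols = len(ga)
            if cols == 0 or read_cols == 0:
                continue
            cov = read_cols / len(read)
            ident = 100.0 * matches / cols
            if cov >= min_cov and ident >= min_id:
                score = float(top.score)
                if best is None or score > best[0]:
                    best = (score, fam)
    return best[1] if best else None


def classify_read_pairs(
    pairs: Iterable[tuple[str, str, str]],
    library: dict[str, str],
    min_cov: float = DEFAULT_MIN_COVERAGE,
    min_id: float = DEFAULT_MIN_IDENTITY,
) -> tuple[pd.DataFrame, list[ReadPairClass]]:
    """Classify read pairs as homogeneous/heterogeneous per satDNA family.

    `pairs` yields ``(pair_id, mate1, mate2)``; a mate may be None/empty
    (orphan), in which case the pair is skipped and counted.  Returns a
    per-family count table (``family, homogeneous, heterogeneous, tsi``)
    and the list of classified pairs, heterogeneous ones carrying the
    external mate sequence for junction annotation.
    """
    counts: dict[str, list[int]] = {fam: [0, 0] for fam in library}
    classed: list[ReadPairClass] = []
    orphans = 0
    for pair_id, m1, m2 in pairs:
        if not m1 or not m2:
            orphans += 1
            continue
        f1 = best_family_hit(m1, library, min_cov, min_id)
        f2 = best_family_hit(m2, library, min_cov, min_id)
        if f1 is None and f2 is None:
            continue
        if f1 == f2:
            counts[f1][0] += 1
            classed.append(ReadPairClass(pair_id, f1, "homogeneous"))
        else:
            # exactly one positive mate for a family, or two different families:
            # either way each positive family sees one heterogeneous junction
            for fam, external in ((f1, m2), (f2, m1)):
                if fam is None:
                    continue
                counts[fam][1] += 1
                classed.append(
                    ReadPairClass(pair_id, fam, "heterogeneous",
                                  external_annotation="unknown",
                                  external_sequence=external)
                )
    if orphans:
        log.info("skipped %d orphan pairs", orphans)
    rows = []
    for fam, (hom, het) in counts.items():
        rows.append({
            "family": fam, "homogeneous": hom, "heterogeneous": het,
            "tsi": tsi(hom, het) if hom + het else float("nan"),
        })
    return pd.DataFrame(rows), classed


def tsi(homogeneous: int, heterogeneous: int) -> float:
    """Tandem structure index: percent of read pairs with satDNA in both mates."""
    total = homogeneous + heterogeneous
    if total <= 0:
        raise ValueError("TSI undefined: no classified read pairs")
    return 100.0 * homogeneous / total


def annotate_junctions(
    het_pairs: Sequence[ReadPairClass],
    repeat_db: dict[str, str],
    classes: dict[str, str] | None = None,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    min_id: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Annotate the external mate of heterogeneous pairs against a repeat
    library.

    `repeat_db` maps element label to sequence; `classes` optionally maps
    element label to a class name (e.g. ``TE/Helitron``, ``LINE``,
    ``rDNA``); unmapped labels annotate as themselves.  Mates with no hit
    above the identity floor annotate as ``unknown``.  Returns per-family
    counts per annotation class.
    """
    classes = classes or {}
    counts: dict[tuple[str, str], int] = {}
    for rp in het_pairs:
        if rp.kind != "heterogeneous":
            continue
        if not rp.external_sequence:
            hit = None
        else:
            hit = best_family_hit(rp.external_sequence, repeat_db, min_cov, min_id)
        label = classes.get(hit, hit) if hit is not None else "unknown"
        key = (rp.family_id, label)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"family": fam, "annotation": ann, "count": c}
        for (fam, ann), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["family", "annotation", "count"])


# ---------------------------------------------------------------------------
# long-read arrays
# ---------------------------------------------------------------------------

def merge_arrays(
    hits: Sequence[tuple[str, str, int, int]],
    rul: dict[str, int] | int,
    max_gap: int = DEFAULT_MAX_GAP,
    min_monomers: float = DEFAULT_MIN_MONOMERS,
) -> list[ArrayInterval]:
    """Collapse per-read alignment hits into tandem arrays.

    `hits` holds ``(read_id, family_id, start, end)`` in 0-based
    half-open read coordinates (reverse-strand hits must already be
    normalized to the forward frame).  Consecutive same-family hits on a
    read separated by at most `max_gap` nucleotides merge into one array
    (absorbing short replication-slippage indels); merged arrays shorter
    than ``min_monomers x RUL`` are discarded.  Records with negative
    coordinates are rejected.
    """
    def rul_of(fam: str) -> int:
        return rul if isinstance(rul, int) else rul[fam]

    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for read_id, fam, start, end in hits:
        if start < 0 or end < 0:
            raise ValueError(f"negative coordinates rejected: {read_id} {start}-{end}")
        if end <= start:
            raise ValueError(f"empty interval rejected: {read_id} {start}-{end}")
        groups.setdefault((read_id, fam), []).append((start, end))
    out: list[ArrayInterval] = []
    for (read_id, fam), ivs in groups.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s - merged[-1][1] <= max_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        r = rul_of(fam)
        for s, e in merged:
            if (e - s) >= min_monomers * r:
                out.append(ArrayInterval(read_id=read_id, family_id=fam, start=s, end=e, rul=r))
    out.sort(key=lambda iv: (iv.read_id, iv.family_id, iv.start))
    return out


def mal(intervals: Iterable[ArrayInterval]) -> dict[str, int | None]:
    """Maximum array length (nucleotides) per family; None when a family
    has no surviving interval."""
    best: dict[str, int] = {}
    for iv in intervals:
        if iv.family_id not in best or iv.length > best[iv.family_id]:
            best[iv.family_id] = iv.length
    return best


def mal_table(intervals: Sequence[ArrayInterval]) -> pd.DataFrame:
    """MAL summary with both nucleotide and monomer-equivalent units."""
    rows = []
    per_fam: dict[str, ArrayInterval] = {}
    for iv in intervals:
        cur = per_fam.get(iv.family_id)
        if cur is None or iv.length > cur.length:
            per_fam[iv.family_id] = iv
    for fam, iv in sorted(per_fam.items()):
        rows.append({
            "family": fam, "mal_bp": iv.length,
            "mal_monomers": iv.monomer_equivalents,
            "read": iv.read_id,
        })
    return pd.DataFrame(rows, columns=["family", "mal_bp", "mal_monomers", "read"])


# ---------------------------------------------------------------------------
# RepeatMasker ".out" hit tables
# ---------------------------------------------------------------------------

def parse_rm_out(stream: TextIO | str) -> list[tuple[str, str, int, int]]:
    """Parse a RepeatMasker ``.out`` hit table into 0-based half-open hits.

    Returns ``(query_id, repeat_name, start, end)`` tuples with
    reverse-strand hits normalized to the query's forward frame (the
    query coordinates in ``.out`` are always forward, 1-based inclusive).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits = []
    for lineno, ln in enumerate(stream, start=1):
        parts = ln.split()
        if len(parts) < 11:
            continue
        try:
            int(parts[0])  # score column marks data rows
        except ValueError:
            continue
        query = parts[4]
        try:
            qbegin = int(parts[5])
            qend = int(parts[6])
        except ValueError:
            log.warning(".out line %d: unparseable coordinates, skipped", lineno)
            continue
        strand = parts[8]
        repeat = parts[9]
        if strand not in ("+", "C"):
            log.warning(".out line %d: unknown strand %r, skipped", lineno, strand)
            continue
        hits.append((query, repeat, qbegin - 1, qend))
    return hits


def scan_read_arrays(
    read: str,
    consensus: str,
    family_id: str,
    read_id: str = "read",
    min_id: float = 70.0,
    min_fraction: float = 0.6,
    max_rounds: int = 8,
) -> list[tuple[str, str, int, int]]:
    """Locate satDNA array intervals on one (possibly noisy) long read.

    Iteratively local-aligns a tiled consensus to the read, records the
    aligned read interval when it passes the identity floor and spans at
    least `min_fraction` of a monomer, masks it, and repeats.  Intended
    for simulated or low-coverage long reads where no external annotation
    table is available; real annotations enter via :func:`parse_rm_out`.
    """
    read = read.upper()
    work = list(read)
    cons = consensus.upper()
    out = []
    for _ in range(max_rounds):
        target = _tile(cons, len(work))
        aln = _LOCAL.align("".join(work), target)
        if len(aln) == 0:
            break
        top = aln[0]
        ga, gb = str(top[0]), str(top[1])
        matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
        cols = len(ga)
        if cols == 0:
            break
        ident = 100.0 * matches / cols
        qstart = int(top.aligned[0][0][0])
        qend = int(top.aligned[0][-1][1])
        if ident < min_id or (qend - qstart) < min_fraction * len(cons):
            break
        out.append((read_id, family_id, qstart, qend))
        for i in range(qstart, qend):
            work[i] = "N"
    return out
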