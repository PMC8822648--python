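"""Pairwise distances and interspecific turnover indices for satDNA.

The module provides global (optionally cyclic) pairwise alignment of
monomer and consensus sequences, Kimura two-parameter (K2P) distances,
and the interspecific comparison layer:

* CTR, consensus turnover rate: ``K / (2 T)`` where ``K`` is the K2P
  divergence (percent) between the consensus sequences of an
  orthologous family pair and ``T`` the species divergence time in Ma.
* CEI, concerted evolution index, comparing inter- to intraspecific
  divergence.  Two variants are emitted: ``log2(inter/intra)`` and the
  plain difference ``inter - intra`` on the percent scale.  Published
  satellitome tables are numerically consistent with the difference
  form, so both are always reported side by side.
* ILibS, incomplete library sorting: ``1 - CTR / maxCTR`` with maxCTR
  the largest turnover rate in the analyzed pair set (the most fully
  sorted orthologous superfamily serves as the reference for complete
  sorting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

GAP = "-"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
#: default species divergence time (Ma) for the two oedipodine lineages
DEFAULT_SPLIT_TIME_MA = 22.81


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment, possibly after a cyclic rotation of b."""

    seq_a: str
    seq_b: str
    rotation_offset: int
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal lengths")

    @property
    def identity(self) -> float:
        """Percent identity over columns excluding terminal gaps.

        Internal gap columns count as non-matches.
        """
        a, b = self.seq_a, self.seq_b
        start = 0
        end = len(a)
        while start < end and (a[start] == GAP or b[start] == GAP):
            start += 1
        while end > start and (a[end - 1] == GAP or b[end - 1] == GAP):
            end -= 1
        # fall back to the full span when one sequence is all gaps inside
        if end <= start:
            start, end = 0, len(a)
        ncols = end - start
        matches = sum(1 for i in range(start, end) if a[i] == b[i] and a[i] != GAP)
        return 100.0 * matches / ncols


@dataclass(frozen=True)
class K2PResult:
    """Kimura two-parameter distance over the gap-free columns of an alignment.

    `defined` is False when the model saturates (log argument <= 0); the
    numeric fields then hold NaN for `k` but P/Q are still reported.
    """

    p: float
    q: float
    k: float
    compared_sites: int
    defined: bool

    @property
    def percent(self) -> float:
        """K expressed in percent (substitutions per 100 sites)."""
        return 100.0 * self.k


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _validate_seq(s: str, name: str) -> str:
    if not s:
        raise ValueError(f"sequence {name} is empty")
    s = s.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence {name} contains invalid symbols: {sorted(bad)}")
    return s


def _gapped_strings(alignment) -> tuple[str, str]:
    text = str(alignment[0]), str(alignment[1])
    return text


def align_pair(a: str, b: str, circular: bool = False) -> PairwiseAlignment:
    """Globally align two sequences (match +1, mismatch -1, gap -2).

    With ``circular=True`` every cyclic rotation of `b` is tried and the
    best-scoring one returned together with its offset; tandem-repeat
    monomers have arbitrary phase, so rotation search is the appropriate
    default when comparing monomers between families or species.
    """
    a = _validate_seq(a, "a")
    b = _validate_seq(b, "b")
    offsets = range(len(b)) if circular else (0,)
    best: PairwiseAlignment | None = None
    for off in offsets:
        rot = b[off:] + b[:off]
        aln = _ALIGNER.align(a, rot)
        top = aln[0]
        if best is None or top.score > best.score:
            ga, gb = _gapped_strings(top)
            best = PairwiseAlignment(seq_a=ga, seq_b=gb, rotation_offset=off, score=top.score)
    assert best is not None
    return best


def k2p(aln: PairwiseAlignment) -> K2PResult:
    """Kimura two-parameter distance from a pairwise alignment.

    P (transitions) and Q (transversions) are proportions over columns
    free of gaps and Ns; ``K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))``.
    Saturation (a non-positive log argument) yields a flagged-undefined
    result rather than an exception.
    """
    ts = tv = n = 0
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("alignment has no gap-free, N-free columns")
    return k2p_counts(ts, tv, n)


def k2p_counts(transitions: int, transversions: int, sites: int) -> K2PResult:
    """Closed-form K2P from raw substitution counts."""
    if sites <= 0:
        raise ValueError("sites must be > 0")
    p = transitions / sites
    q = transversions / sites
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return K2PResult(p=p, q=q, k=float("nan"), compared_sites=sites, defined=False)
    k = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(p=p, q=q, k=k, compared_sites=sites, defined=True)


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of differing gap-free, N-free columns."""
    diff = n = 0
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("alignment has no gap-free, N-free columns")
    return diff / n


def inter_divergence(
    subcons_a: Sequence[str],
    subcons_b: Sequence[str],
    circular: bool = False,
) -> float:
    """Mean K2P (percent) over all cross-species subfamily-consensus pairs.

    Undefined (saturated) cells are excluded and logged; if every cell is
    undefined a ValueError is raised.
    """
    if not subcons_a or not subcons_b:
        raise ValueError("both consensus lists must be non-empty")
    vals = []
    for (i, sa), (j, sb) in product(enumerate(subcons_a), enumerate(subcons_b)):
        res = k2p(align_pair(sa, sb, circular=circular))
        if res.defined:
            vals.append(res.percent)
        else:
            log.warning("K2P undefined (saturation) for pair (%d, %d); excluded", i, j)
    if not vals:
        raise ValueError("all cross-species K2P distances are undefined (saturation)")
    return float(np.mean(vals))


def ctr(k2p_inter: float, T: float = DEFAULT_SPLIT_TIME_MA) -> float:
    """Consensus turnover rate, percent per Ma: ``K / (2 T)``."""
    if T <= 0:
        raise ValueError("divergence time T must be > 0")
    return k2p_inter / (2.0 * T)


CEIVariant = Literal["log2_ratio", "difference"]


def cei(k2p_inter: float, k2p_intra: float, variant: CEIVariant = "difference") -> float:
    """Concerted evolution index: inter- vs intraspecific divergence.

    ``log2_ratio`` returns ``log2(inter/intra)`` (NaN when intra or inter
    is non-positive); ``difference`` returns ``inter - intra`` on the same
    (percent) scale as its inputs.  Both variants are positive exactly
    when interspecific divergence exceeds intraspecific divergence.
    """
    if variant == "difference":
        return k2p_inter - k2p_intra
    if variant == "log2_ratio":
        if k2p_intra <= 0 or k2p_inter <= 0:
            log.warning("CEI log2 variant undefined for inter=%s intra=%s", k2p_inter, k2p_intra)
            return float("nan")
        return math.log2(k2p_inter / k2p_intra)
    raise ValueError(f"unknown CEI variant: {variant!r}")


def ilibs(ctr_value: float, max_ctr: float) -> float:
    """Incomplete library sorting: ``1 - CTR / maxCTR`` in [0, 1]."""
    if max_ctr <= 0:
        raise ValueError("max_ctr must be > 0")
    if ctr_value > max_ctr:
        log.warning("CTR %.4g exceeds maxCTR %.4g; ILibS clamped to 0", ctr_value, max_ctr)
        return 0.0
    return 1.0 - ctr_value / max_ctr


# ---------------------------------------------------------------------------
# ortholog table layer
# ---------------------------------------------------------------------------

def turnover_table(
    pairs: pd.DataFrame,
    T: float = DEFAULT_SPLIT_TIME_MA,
    max_ctr: float | None = None,
) -> pd.DataFrame:
    """Derive CTR and ILibS columns for a table of orthologous pairs.

    `pairs` must carry an ``interspecific_divergence`` column (K2P,
    percent).  ``maxCTR`` defaults to the largest CTR in the analyzed set
    but can be pinned to an externally chosen reference.  A
    ``concerted`` column is derived when both per-species CEI columns
    (``cei_ode``/``cei_lmi`` or ``cei_a``/``cei_b``) are present.
    """
    if "interspecific_divergence" not in pairs.columns:
        raise ValueError("pairs table needs an 'interspecific_divergence' column")
    out = pairs.copy()
    out["ctr"] = out["interspecific_divergence"].astype(float) / (2.0 * T)
    ref = float(out["ctr"].max()) if max_ctr is None else float(max_ctr)
    out["ilibs"] = [ilibs(v, ref) for v in out["ctr"]]
    cei_cols = None
    for pair_cols in (("cei_ode", "cei_lmi"), ("cei_a", "cei_b")):
        if all(c in out.columns for c in pair_cols):
            cei_cols = pair_cols
            break
    if cei_cols:
        out["concerted"] = (out[cei_cols[0]] > 0) & (out[cei_cols[1]] > 0)
    return out


def turnover_summary(table: pd.DataFrame, T: float = DEFAULT_SPLIT_TIME_MA) -> dict[str, float]:
    """Summary statistics over a derived turnover table.

    Returns mean/SD/CV of CTR, mean ILibS, maxCTR, and the complete
    sorting rate: the completely sorted fraction ``1 - mean ILibS``
    expressed as percent of the library per Ma of separate evolution.
    """
    ctr_vals = table["ctr"].to_numpy(dtype=float)
    ilibs_vals = table["ilibs"].to_numpy(dtype=float)
    mean_ctr = float(ctr_vals.mean())
    sd_ctr = float(ctr_vals.std(ddof=1)) if len(ctr_vals) > 1 else 0.0
    summary = {
        "n_pairs": int(len(table)),
        "mean_ctr": mean_ctr,
        "sd_ctr": sd_ctr,
        "cv_ctr": sd_ctr / mean_ctr if mean_ctr else float("nan"),
        "max_ctr": float(ctr_vals.max()),
        "min_ctr": float(ctr_vals.min()),
        "mean_ilibs": float(ilibs_vals.mean()),
        "complete_sorting_rate": 100.0 * (1.0 - float(ilibs_vals.mean())) / T,
    }
    if "concerted" in table.columns:
        concerted = table["concerted"].to_numpy(dtype=bool)
        summary["n_concerted"] = int(concerted.sum())
        if concerted.any():
            summary["max_ilibs_concerted"] = float(ilibs_vals[concerted].max())
    return summary


@dataclass(frozen=True)
class OrthologComparison:
    """Full per-pair comparison between two orthologous satDNA families."""

    osf_id: str
    family_a: str
    family_b: str
    k2p_inter: float
    k2p_intra_a: float
    k2p_intra_b: float
    identity: float
    ctr: float
    cei_a: float
    cei_b: float
    cei_log2_a: float
    cei_log2_b: float
    ilibs: float


def compare_orthologs(
    pairs: Iterable[tuple[str, "object", "object"]],
    T: float = DEFAULT_SPLIT_TIME_MA,
    intra_source: Literal["landscape_mean", "subconsensus"] = "landscape_mean",
    max_ctr: float | None = None,
    min_identity: float = 40.0,
) -> list[OrthologComparison]:
    """Compare orthologous family pairs from full SatFamily objects.

    Each element of `pairs` is ``(osf_id, family_a, family_b)`` where the
    families are :class:`satdyn.classify.SatFamily` instances carrying
    subfamily consensuses and (for the default intra_source) landscape
    indices.  Intraspecific divergence comes either from the
    abundance-weighted mean copy-to-consensus divergence of the family's
    repeat landscape (``landscape_mean``) or from mean pairwise K2P among
    subfamily consensuses (``subconsensus``; 0 for single-subfamily
    families).  Pairs whose consensus identity falls below
    `min_identity` are flagged (NaN indices) and excluded from maxCTR.
    """
    rows = []
    for osf_id, fam_a, fam_b in pairs:
        cons_a = [sf.consensus for sf in fam_a.subfamilies] or [fam_a.consensus]
        cons_b = [sf.consensus for sf in fam_b.subfamilies] or [fam_b.consensus]
        ident = align_pair(fam_a.consensus, fam_b.consensus, circular=True).identity
        inter = inter_divergence(cons_a, cons_b)
        if intra_source == "landscape_mean":
            intra_a = fam_a.landscape_mean_divergence
            intra_b = fam_b.landscape_mean_divergence
        elif intra_source == "subconsensus":
            intra_a = _mean_pairwise_k2p(cons_a)
            intra_b = _mean_pairwise_k2p(cons_b)
        else:
            raise ValueError(f"unknown intra_source: {intra_source!r}")
        rows.append(
            dict(
                osf_id=osf_id, family_a=fam_a.name, family_b=fam_b.name,
                k2p_inter=inter, k2p_intra_a=intra_a, k2p_intra_b=intra_b,
                identity=ident, alignable=ident >= min_identity,
            )
        )
    defined = [r for r in rows if r["alignable"]]
    if max_ctr is None:
        if not defined:
            raise ValueError("no alignable ortholog pair; cannot set maxCTR")
        ref = max(ctr(r["k2p_inter"], T) for r in defined)
    else:
        ref = max_ctr
    out = []
    for r in rows:
        if not r["alignable"]:
            log.warning("pair %s/%s below identity threshold; flagged", r["family_a"], r["family_b"])
            c = float("nan")
            il = float("nan")
        else:
            c = ctr(r["k2p_inter"], T)
            il = ilibs(c, ref)
        out.append(
            OrthologComparison(
                osf_id=r["osf_id"], family_a=r["family_a"], family_b=r["family_b"],
                k2p_inter=r["k2p_inter"],
                k2p_intra_a=r["k2p_intra_a"], k2p_intra_b=r["k2p_intra_b"],
                identity=r["identity"], ctr=c,
                cei_a=cei(r["k2p_inter"], r["k2p_intra_a"], "difference"),
                cei_b=cei(r["k2p_inter"], r["k2p_intra_b"], "difference"),
                cei_log2_a=cei(r["k2p_inter"], r["k2p_intra_a"], "log2_ratio"),
                cei_log2_b=cei(r["k2p_inter"], r["k2p_intra_b"], "log2_ratio"),
                ilibs=il,
            )
        )
    return out


def _mean_pairwise_k2p(consensuses: Sequence[str]) -> float:
    if len(consensuses) < 2:
        return 0.0
    vals = []
    for i in range(len(consensuses)):
        for j in range(i + 1, len(consensuses)):
            res = k2p(align_pair(consensuses[i], consensuses[j]))
            if res.defined:
                vals.append(res.percent)
    return float(np.mean(vals)) if vals else float("nan")
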