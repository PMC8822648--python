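"""Repeat landscapes and the homogenization/degeneration indices.

A repeat landscape (RL) is the histogram of genomic abundance of a
satDNA family binned by the divergence of each copy from the family
consensus, in 1% classes from 0 to 40%.  Three indices summarize it:

* DIVPEAK  -- the divergence class with maximum abundance; grows with
  time since the last amplification, so it indexes *degeneration*.
* PEAK-SIZE -- summed abundance of the five classes centered on
  DIVPEAK (DIVPEAK +/- 2%), i.e. the mass of the last amplification.
* RPS      -- PEAK-SIZE / total abundance, the fraction of the family
  belonging to the amplification peak; it indexes *homogenization*.

Kurtosis of the abundance-weighted divergence distribution is a second
homogenization index: freshly amplified families are leptokurtic,
degenerated ones platykurtic.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

log = logging.getLogger(__name__)

#: divergence classes above this are outside the measured scale and dropped
MAX_DIVERGENCE_CLASS = 40


class LandscapeError(ValueError):
    """Raised for empty or malformed landscapes."""


@dataclass(frozen=True)
class CopyHit:
    """One aligned copy of a satDNA family.

    Parameters
    ----------
    family_id : str
        Family the copy was assigned to.
    copy_length : int
        Aligned length in nucleotides (> 0).
    divergence : float
        Percent divergence of the copy from the family consensus (0-100).
    """

    family_id: str
    copy_length: int
    divergence: float

    def __post_init__(self) -> None:
        if self.copy_length <= 0:
            raise ValueError(f"copy_length must be > 0, got {self.copy_length}")
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError(f"divergence must be in [0, 100], got {self.divergence}")


@dataclass
class RepeatLandscape:
    """Binned abundance-by-divergence histogram for one family.

    ``bins[k]`` is the abundance (percent of genome) of copies with
    divergence in the half-open class ``[k*bin_width, (k+1)*bin_width)``.
    """

    family_id: str
    bins: np.ndarray
    genome_size: int
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.ndim != 1:
            raise LandscapeError("bins must be one-dimensional")
        if np.any(self.bins < 0):
            raise LandscapeError("bin abundances must be >= 0")

    @property
    def total_abundance(self) -> float:
        return float(self.bins.sum())

    @property
    def n_classes(self) -> int:
        return len(self.bins)

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_classes) + 0.5) * self.bin_width

    def is_empty(self) -> bool:
        return not np.any(self.bins > 0)


@dataclass(frozen=True)
class LandscapeIndices:
    """Summary indices of one repeat landscape."""

    family_id: str
    divpeak: int
    peak_size: float
    rps: float
    kurtosis: float
    total_abundance: float
    mean_divergence: float
    max_divergence: float


def build_landscape(
    hits: Iterable[CopyHit],
    genome_size: int,
    bin_width: float = 1.0,
    family_id: str | None = None,
) -> RepeatLandscape:
    """Accumulate per-copy divergence hits into a repeat landscape.

    Each copy contributes ``copy_length / genome_size`` (as percent of the
    genome) to the class ``floor(divergence / bin_width)``.  Copies falling
    beyond the 40% divergence cap are dropped (and logged); records with
    negative divergence are rejected by :class:`CopyHit` itself.

    Raises
    ------
    LandscapeError
        If `hits` is empty or `genome_size` is not positive.
    """
    if genome_size <= 0:
        raise LandscapeError(f"genome_size must be > 0, got {genome_size}")
    hits = list(hits)
    if not hits:
        raise LandscapeError("no copies: cannot build a landscape from an empty hit list")
    fam = family_id if family_id is not None else hits[0].family_id
    # classes 0..40 inclusive at 1% width; generally floor(40 / bin_width) + 1
    n_classes = int(math.floor(MAX_DIVERGENCE_CLASS / bin_width)) + 1
    bins = np.zeros(n_classes, dtype=float)
    dropped = 0
    for h in hits:
        if h.family_id != fam:
            continue
        k = int(math.floor(h.divergence / bin_width))
        if k >= n_classes:
            dropped += 1
            continue
        bins[k] += 100.0 * h.copy_length / genome_size
    if dropped:
        log.info(
            "family %s: dropped %d copies beyond the %d%% divergence cap",
            fam, dropped, MAX_DIVERGENCE_CLASS,
        )
    return RepeatLandscape(family_id=fam, bins=bins, genome_size=genome_size, bin_width=bin_width)


def compute_indices(rl: RepeatLandscape, window: int = 2) -> LandscapeIndices:
    """Compute DIVPEAK, PEAK-SIZE, RPS, kurtosis and moments of a landscape.

    DIVPEAK is the argmax class (ties broken toward the lower divergence
    class, i.e. the more conservative degeneration estimate).  PEAK-SIZE
    sums the classes ``divpeak - window .. divpeak + window``, truncated at
    the histogram edges.  Kurtosis is the abundance-weighted *excess*
    kurtosis of the bin-center divergences (leptokurtic > 0); it is NaN for
    a landscape concentrated in a single class (zero variance).

    Raises
    ------
    LandscapeError
        If every bin is zero.
    """
    bins = rl.bins
    total = float(bins.sum())
    if total <= 0:
        raise LandscapeError(f"family {rl.family_id}: all-zero landscape has no indices")
    divpeak = int(np.argmax(bins))  # argmax returns the first (lowest) maximal class
    if np.count_nonzero(bins == bins[divpeak]) > 1:
        log.info("family %s: DIVPEAK tie broken toward class %d", rl.family_id, divpeak)
    lo = max(0, divpeak - window)
    hi = min(rl.n_classes - 1, divpeak + window)
    peak_size = float(bins[lo : hi + 1].sum())
    rps = peak_size / total
    centers = rl.bin_centers()
    w = bins / total
    mean = float(np.sum(w * centers))
    var = float(np.sum(w * (centers - mean) ** 2))
    if var > 0:
        kurt = float(np.sum(w * (centers - mean) ** 4) / var**2 - 3.0)
    else:
        kurt = float("nan")
    nz = np.nonzero(bins)[0]
    max_div = float(nz[-1] * rl.bin_width)
    return LandscapeIndices(
        family_id=rl.family_id,
        divpeak=divpeak,
        peak_size=peak_size,
        rps=rps,
        kurtosis=kurt,
        total_abundance=total,
        mean_divergence=mean,
        max_divergence=max_div,
    )


# ---------------------------------------------------------------------------
# divergence-summary (".divsum" dialect) I/O
# ---------------------------------------------------------------------------

_MATRIX_HEADER = "Coverage for each repeat class and divergence"


def parse_divsum(stream: TextIO | str, genome_size: int) -> list[RepeatLandscape]:
    """Parse a RepeatMasker divergence-summary file into landscapes.

    The file carries free-form per-repeat statistics followed by an
    abundance matrix introduced by a ``Coverage for each repeat class and
    divergence`` line: a ``Div`` header naming one column per family, then
    one row per divergence class holding aligned nucleotides.  Coverage is
    converted to percent of `genome_size`.  Families whose column is all
    zeros are retained and flagged (logged) as empty.

    Raises
    ------
    LandscapeError
        If the abundance matrix section is missing or truncated.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip().startswith(_MATRIX_HEADER))
    except StopIteration:
        raise LandscapeError(
            f"format error: missing abundance matrix section ({_MATRIX_HEADER!r})"
        ) from None
    header_idx = None
    for i in range(start + 1, len(lines)):
        if lines[i].strip().startswith("Div"):
            header_idx = i
            break
    if header_idx is None:
        raise LandscapeError("format error: abundance matrix is truncated (no 'Div' header row)")
    families = lines[header_idx].split()[1:]
    if not families:
        raise LandscapeError("format error: 'Div' header names no family columns")
    n_classes = MAX_DIVERGENCE_CLASS + 1
    cov = np.zeros((n_classes, len(families)), dtype=float)
    n_rows = 0
    for lineno, ln in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not ln.strip():
            continue
        parts = ln.split()
        try:
            klass = int(float(parts[0]))
            vals = [float(x) for x in parts[1:]]
        except ValueError:
            log.warning("divsum line %d unparseable, skipped: %r", lineno, ln)
            continue
        if len(vals) != len(families):
            log.warning("divsum line %d has %d values for %d families, skipped",
                        lineno, len(vals), len(families))
            continue
        if 0 <= klass < n_classes:
            cov[klass] += vals
            n_rows += 1
    if n_rows == 0:
        raise LandscapeError("format error: abundance matrix is truncated (no data rows)")
    out = []
    for j, fam in enumerate(families):
        bins = 100.0 * cov[:, j] / genome_size
        rl = RepeatLandscape(family_id=fam, bins=bins, genome_size=genome_size)
        if rl.is_empty():
            log.info("family %s: all-zero abundance column (retained, flagged empty)", fam)
        out.append(rl)
    return out


def write_divsum(landscapes: Sequence[RepeatLandscape], stream: TextIO) -> None:
    """Write landscapes in the divergence-summary matrix dialect.

    Percent abundances are converted back to aligned-nucleotide coverage
    using each landscape's genome size; all landscapes must share one
    genome size and class count.
    """
    if not landscapes:
        raise LandscapeError("nothing to write")
    gsize = landscapes[0].genome_size
    n_classes = landscapes[0].n_classes
    stream.write(_MATRIX_HEADER + "\n")
    stream.write("Div " + " ".join(rl.family_id for rl in landscapes) + "\n")
    for k in range(n_classes):
        row = [str(k)]
        for rl in landscapes:
            row.append(f"{rl.bins[k] * gsize / 100.0:.2f}")
        stream.write(" ".join(row) + "\n")


def read_landscape_tsv(stream: TextIO | str, genome_size: int) -> list[RepeatLandscape]:
    """Read the TSV fallback format: family_id <tab> class <tab> abundance(%)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    per_family: dict[str, np.ndarray] = {}
    for lineno, ln in enumerate(stream, start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("family"):
            continue
        fam, klass, abund = ln.split("\t")
        arr = per_family.setdefault(fam, np.zeros(MAX_DIVERGENCE_CLASS + 1))
        k = int(klass)
        if not 0 <= k <= MAX_DIVERGENCE_CLASS:
            log.warning("landscape TSV line %d: class %d out of range, skipped", lineno, k)
            continue
        arr[k] += float(abund)
    return [
        RepeatLandscape(family_id=fam, bins=bins, genome_size=genome_size)
        for fam, bins in per_family.items()
    ]


def write_landscape_tsv(landscapes: Sequence[RepeatLandscape], stream: TextIO) -> None:
    stream.write("family\tclass\tabundance\n")
    for rl in landscapes:
        for k in range(rl.n_classes):
            stream.write(f"{rl.family_id}\t{k}\t{rl.bins[k]:.10g}\n")


INDEX_COLUMNS = (
    "family", "divpeak", "peak_size", "rps", "kurtosis",
    "total_abundance", "mean_divergence",
)


def write_indices_tsv(indices: Sequence[LandscapeIndices], stream: TextIO) -> None:
    """Write per-family index tables with a stable column order."""
    stream.write("\t".join(INDEX_COLUMNS) + "\n")
    for ix in indices:
        stream.write(
            f"{ix.family_id}\t{ix.divpeak}\t{ix.peak_size:.6g}\t{ix.rps:.6g}\t"
            f"{ix.kurtosis:.6g}\t{ix.total_abundance:.6g}\t{ix.mean_divergence:.6g}\n"
        )
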