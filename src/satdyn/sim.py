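"""Forward simulator of the amplification--degeneration model of satDNA.

SatDNA families evolve by two mutation classes: *point mutation*, which
degrades copies independently and moves the repeat landscape toward
higher divergence, and *tandem duplication*, whose massive episodes
(*amplifications*) inject many identical copies of one source sequence
and re-homogenize the family.  The simulator evolves a family in a
common ancestor, splits it into two lineages, applies per-lineage
amplification schedules, lays copies out into tandem arrays inside a
synthetic genome, and samples paired short reads and noisy long reads
from it -- so that every pipeline stage (landscapes, K2P/CTR/CEI/ILibS,
TSI, MAL) can be exercised against known truth.

Units: time in Ma; mutation rate ``mu`` in substitutions per site per
Ma; ``kappa`` is the transition/transversion rate ratio of a Kimura
two-parameter process (so distances estimated downstream are
self-consistent with the mutation model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_B2I[c] for c in seq.upper()), dtype=np.uint8, count=len(seq))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return _BASE_BYTES[arr].tobytes().decode("ascii")


@dataclass(frozen=True)
class Amplification:
    """One amplification burst: `burst_size` new copies of one source.

    `time` is Ma after the lineage split (0 = split, `split_time` =
    present); `source` picks the template copy.
    """

    time: float
    burst_size: int
    lineage: Literal["A", "B"]
    source: Literal["random_copy", "consensus"] = "random_copy"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated orthologous satDNA family.

    Defaults emulate a grasshopper-like satellite: ~185 nt monomers, two
    lineages split 22.81 Ma ago, and a per-site substitution rate of
    0.01/Ma, the order implied by consensus turnover rates of ~1% per Ma.
    """

    seed: int
    monomer_length: int = 185
    mu: float = 0.01
    kappa: float = 2.0
    ancestral_time: float = 5.0
    split_time: float = 22.81
    initial_copies: int = 30
    amplifications: tuple[Amplification, ...] = ()
    array_layout: tuple[int, ...] | None = None  # array sizes in copies; None = one array
    flank_length: int = 2000
    read_length: int = 101
    insert_size: int = 180

    def validate(self) -> None:
        if self.monomer_length <= 0 or self.initial_copies <= 0:
            raise ValueError("monomer_length and initial_copies must be > 0")
        if min(self.mu, self.kappa, self.ancestral_time, self.split_time) < 0:
            raise ValueError("rates and durations must be >= 0")
        for amp in self.amplifications:
            if not 0.0 <= amp.time <= self.split_time:
                raise ValueError(
                    f"amplification at {amp.time} Ma outside [0, {self.split_time}]"
                )


@dataclass
class CopyRecord:
    copy_id: int
    lineage: str
    parent: int  # -1 for initial copies
    birth_time: float  # Ma after the split; negative = ancestral


@dataclass
class SimTruth:
    """Generating parameters and genealogy of a simulated family."""

    config: SimConfig
    ancestral_consensus: str
    genealogy: dict[str, list[CopyRecord]]
    arrays: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class SimResult:
    copies: dict[str, np.ndarray]  # lineage -> (n_copies, monomer_length) base codes
    genomes: dict[str, str]
    truth: SimTruth

    def monomers(self, lineage: str) -> list[str]:
        return [decode(row) for row in self.copies[lineage]]


def evolve_copies(
    copies: np.ndarray,
    duration: float,
    mu: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutate each site of each copy as an independent Poisson process.

    Events hit a site at rate `mu`; each event is a transition with
    probability ``kappa / (kappa + 2)``, otherwise one of the two
    transversions.  With bases coded A=0, C=1, G=2, T=3, a transition is
    ``base ^ 2`` and the transversions are ``base ^ 1`` and ``base ^ 3``.
    Copies evolve independently; multiple hits per site are applied in
    sequence, so back-mutation and saturation arise naturally.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    out = copies.copy()
    if duration == 0 or mu == 0 or out.size == 0:
        return out
    n_events = rng.poisson(mu * duration, size=out.shape)
    p_ts = kappa / (kappa + 2.0) if np.isfinite(kappa) else 1.0
    sites = np.argwhere(n_events > 0)
    for i, j in sites:
        for _ in range(n_events[i, j]):
            if rng.random() < p_ts:
                out[i, j] ^= 2
            else:
                out[i, j] ^= 1 if rng.random() < 0.5 else 3
    return out


def amplify(
    copies: np.ndarray,
    burst_size: int,
    source: Literal["random_copy", "consensus"],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Append `burst_size` identical copies of a chosen source.

    Returns the grown copy matrix and the source row index (-1 when the
    source is the majority consensus rather than a physical copy).
    """
    if copies.shape[0] < 1:
        raise ValueError("need at least one existing copy to amplify")
    if burst_size == 0:
        return copies.copy(), -1
    if source == "random_copy":
        idx = int(rng.integers(copies.shape[0]))
        template = copies[idx]
    elif source == "consensus":
        idx = -1
        template = majority_consensus(copies)
    else:
        raise ValueError(f"unknown source policy: {source!r}")
    new = np.tile(template, (burst_size, 1))
    return np.vstack([copies, new]), idx


def majority_consensus(copies: np.ndarray) -> np.ndarray:
    """Per-site majority base over a copy matrix (ties to the lowest code)."""
    counts = np.stack([(copies == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.uint8)


def simulate_satellitome(cfg: SimConfig) -> SimResult:
    """Run the two-lineage amplification--degeneration forward model.

    A random ancestral monomer is expanded to `initial_copies` and
    mutates for `ancestral_time` Ma (standing ancestral polymorphism).
    At the split both lineages inherit the same copy set, then evolve
    independently for `split_time` Ma, interrupted by their scheduled
    amplification bursts.  Finally copies are laid out into tandem
    arrays (per `array_layout`, one array by default) separated by
    random flanking sequence, giving one synthetic genome per lineage.
    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ancestor = rng.integers(0, 4, size=cfg.monomer_length).astype(np.uint8)
    pool = np.tile(ancestor, (cfg.initial_copies, 1))
    pool = evolve_copies(pool, cfg.ancestral_time, cfg.mu, cfg.kappa, rng)
    genealogy: dict[str, list[CopyRecord]] = {}
    copies: dict[str, np.ndarray] = {}
    for lineage in ("A", "B"):
        recs = [
            CopyRecord(copy_id=i, lineage=lineage, parent=-1, birth_time=-cfg.ancestral_time)
            for i in range(cfg.initial_copies)
        ]
        cur = pool.copy()
        t = 0.0
        schedule = sorted(
            (a for a in cfg.amplifications if a.lineage == lineage), key=lambda a: a.time
        )
        for amp in schedule:
            cur = evolve_copies(cur, amp.time - t, cfg.mu, cfg.kappa, rng)
            t = amp.time
            before = cur.shape[0]
            cur, src = amplify(cur, amp.burst_size, amp.source, rng)
            recs.extend(
                CopyRecord(copy_id=before + i, lineage=lineage, parent=src, birth_time=t)
                for i in range(amp.burst_size)
            )
        cur = evolve_copies(cur, cfg.split_time - t, cfg.mu, cfg.kappa, rng)
        copies[lineage] = cur
        genealogy[lineage] = recs
    truth = SimTruth(
        config=cfg, ancestral_consensus=decode(ancestor), genealogy=genealogy
    )
    genomes = {}
    for lineage in ("A", "B"):
        genome, arrays = _layout_genome(copies[lineage], cfg, rng)
        genomes[lineage] = genome
        truth.arrays[lineage] = arrays
    return SimResult(copies=copies, genomes=genomes, truth=truth)


def _layout_genome(
    copies: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    n = copies.shape[0]
    layout = list(cfg.array_layout) if cfg.array_layout else [n]
    if sum(layout) > n:
        raise ValueError("array_layout asks for more copies than exist")
    order = rng.permutation(n)
    pieces: list[str] = []
    arrays: list[tuple[int, int]] = []
    pos = 0
    used = 0
    for size in layout:
        flank = decode(rng.integers(0, 4, size=cfg.flank_length).astype(np.uint8))
        pieces.append(flank)
        pos += len(flank)
        start = pos
        for k in range(size):
            mono = decode(copies[order[used + k]])
            pieces.append(mono)
            pos += len(mono)
        arrays.append((start, pos))
        used += size
    # leftover copies are dispersed as single monomers between flanks
    for k in range(used, n):
        flank = decode(rng.integers(0, 4, size=cfg.flank_length).astype(np.uint8))
        pieces.append(flank)
        pos += len(flank)
        mono = decode(copies[order[k]])
        pieces.append(mono)
        arrays.append((pos, pos + len(mono)))
        pos += len(mono)
    tail = decode(rng.integers(0, 4, size=cfg.flank_length).astype(np.uint8))
    pieces.append(tail)
    return "".join(pieces), arrays


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    genome: str,
    read_length: int,
    insert_size: int,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Sample innie-oriented paired reads uniformly from a genome.

    Returns ``(pair_id, mate1, mate2)`` with mate2 reverse-complemented,
    as a sequencer would deliver it.
    """
    if n_pairs == 0:
        return []
    if len(genome) <= insert_size:
        raise ValueError("genome must be longer than the insert size")
    if insert_size < read_length:
        raise ValueError("insert size must be >= read length")
    starts = rng.integers(0, len(genome) - insert_size + 1, size=n_pairs)
    out = []
    for i, s in enumerate(starts):
        m1 = genome[s : s + read_length]
        m2 = genome[s + insert_size - read_length : s + insert_size].translate(_RC)[::-1]
        out.append((f"pair{i}", m1, m2))
    return out


def simulate_long_reads(
    genome: str,
    n_reads: int,
    mean_length: float,
    rng: np.random.Generator,
    sub_rate: float = 0.03,
    indel_rate: float = 0.03,
    min_length: int = 200,
) -> list[tuple[str, str, int]]:
    """Sample noisy long reads (gamma-distributed lengths, subs + indels).

    Returns ``(read_id, sequence, start)`` with `start` the error-free
    genomic start, so simulated truth stays recoverable.  Error model:
    independent per-base substitution, deletion and single-base insertion
    at `sub_rate` / `indel_rate` (indels split evenly), emulating noisy
    nanopore-style base calls.
    """
    out = []
    for i in range(n_reads):
        length = int(max(min_length, rng.gamma(shape=3.0, scale=mean_length / 3.0)))
        length = min(length, len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        raw = genome[start : start + length]
        read = _apply_errors(raw, sub_rate, indel_rate, rng)
        out.append((f"long{i}", read, start))
    return out


def _apply_errors(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    out = []
    p_del = indel_rate / 2.0
    p_ins = indel_rate / 2.0
    for ch in seq:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_del + p_ins:
            out.append(BASES[rng.integers(4)])
        if r < p_del + p_ins + sub_rate and r >= p_del + p_ins:
            alts = [b for b in BASES if b != ch]
            out.append(alts[rng.integers(3)])
        else:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# convenience scenario: one family, one amplification of known age
# ---------------------------------------------------------------------------

def single_amplification_config(
    seed: int,
    age_ma: float,
    burst_size: int = 150,
    mu: float = 0.01,
    monomer_length: int = 200,
    split_time: float = 22.81,
) -> SimConfig:
    """A family whose lineage A underwent one burst `age_ma` Ma ago.

    The burst dominates the copy pool, so the landscape DIVPEAK of
    lineage A estimates the divergence accumulated since the burst,
    about ``100 * mu * age_ma`` percent.
    """
    if age_ma >= split_time:
        raise ValueError("amplification age must postdate the split")
    amp = Amplification(time=split_time - age_ma, burst_size=burst_size, lineage="A")
    return SimConfig(
        seed=seed,
        monomer_length=monomer_length,
        mu=mu,
        initial_copies=10,
        amplifications=(amp,),
    )
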