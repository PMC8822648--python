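"""Glue between raw monomer copies and the landscape/turnover indices.

These helpers run the measurement pipeline on a set of monomer copies
(simulated or real): build the family consensus, align every copy back
to it, bin copy divergences into a repeat landscape, and derive the
turnover and concerted-evolution quantities for a two-lineage family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satdyn.distances import align_pair, cei, ctr, k2p
from satdyn.landscape import CopyHit, LandscapeIndices, RepeatLandscape, build_landscape, compute_indices
from satdyn.sim import SimResult, decode, majority_consensus


def copy_divergences(monomers: list[str], consensus: str) -> list[float]:
    """K2P percent divergence of each copy from the family consensus."""
    out = []
    for m in monomers:
        res = k2p(align_pair(m, consensus))
        out.append(res.percent if res.defined else 100.0)
    return out


def landscape_from_copies(
    monomers: list[str],
    consensus: str | None = None,
    family_id: str = "fam",
    genome_size: int | None = None,
) -> RepeatLandscape:
    """Repeat landscape of a copy set relative to its consensus.

    With the default ``genome_size`` equal to the summed copy length, the
    landscape expresses the family's internal abundance distribution
    (bins sum to 100%).
    """
    if consensus is None:
        from satdyn.classify import build_consensus

        consensus = build_consensus(monomers)
    if genome_size is None:
        genome_size = sum(len(m) for m in monomers)
    hits = [
        CopyHit(family_id=family_id, copy_length=len(m), divergence=min(d, 100.0))
        for m, d in zip(monomers, copy_divergences(monomers, consensus))
    ]
    return build_landscape(hits, genome_size=genome_size, family_id=family_id)


@dataclass(frozen=True)
class FamilyComparison:
    """Turnover and concerted-evolution quantities for one simulated family."""

    k2p_inter: float
    k2p_intra: dict[str, float]
    cei_difference: dict[str, float]
    cei_log2: dict[str, float]
    ctr: float
    indices: dict[str, LandscapeIndices]


def analyze_two_lineages(result: SimResult, T: float | None = None) -> FamilyComparison:
    """Run the interspecific comparison on a simulated two-lineage family.

    Per lineage, the consensus is the per-site majority over its copies;
    intraspecific divergence is the abundance-weighted mean copy-to-
    consensus divergence of the repeat landscape (all copies share one
    monomer length, so the weighting is uniform).  Interspecific
    divergence is the K2P distance between the two lineage consensuses.
    """
    cfg = result.truth.config
    if T is None:
        T = cfg.split_time
    cons = {lin: decode(majority_consensus(result.copies[lin])) for lin in ("A", "B")}
    res_inter = k2p(align_pair(cons["A"], cons["B"]))
    inter = res_inter.percent if res_inter.defined else float("nan")
    intra = {}
    indices = {}
    for lin in ("A", "B"):
        rl = landscape_from_copies(result.monomers(lin), consensus=cons[lin], family_id=lin)
        ix = compute_indices(rl)
        indices[lin] = ix
        intra[lin] = ix.mean_divergence
    return FamilyComparison(
        k2p_inter=inter,
        k2p_intra=intra,
        cei_difference={lin: cei(inter, intra[lin], "difference") for lin in intra},
        cei_log2={lin: cei(inter, intra[lin], "log2_ratio") for lin in intra},
        ctr=ctr(inter, T),
        indices=indices,
    )
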