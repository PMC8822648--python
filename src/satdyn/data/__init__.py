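"""Packaged reference tables."""

from importlib import resources

import pandas as pd


def load_ortholog_table() -> pd.DataFrame:
    """Load the packaged two-species ortholog-pair table.

    One row per orthologous family pair between the *Oedaleus decorus*
    and *Locusta migratoria* satellitomes: family names, subfamily
    counts, FISH pattern, abundance, RPS, DIVPEAK, maximum array length,
    per-species concerted-evolution indices, and interspecific identity
    and K2P divergence of their consensus sequences.  Derived turnover
    columns (CTR, ILibS) are recomputed by
    :func:`satdyn.distances.turnover_table`; the ``*_printed`` columns
    hold the values as originally published, for cross-checks only.
    """
    with resources.files(__package__).joinpath("ortholog_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
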