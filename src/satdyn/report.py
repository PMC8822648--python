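"""End-to-end satellitome comparison report.

Bundles the pipeline outputs of a two-species comparison into stable
TSV tables and repeat-landscape plots: per-group effect-size contrasts
(shared vs non-shared families, between and within species), the
ortholog turnover table with its summary row, and a rank-correlation
matrix with the Holm family-wise correction.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from satdyn.distances import turnover_summary, turnover_table
from satdyn.landscape import RepeatLandscape
from satdyn.stats import bootstrap_mean_diff, holm, spearman

log = logging.getLogger(__name__)

#: per-family feature columns contrasted between groups
CONTRAST_FEATURES = ("rul", "at_content", "abundance", "divergence")
#: feature pairs entering the correlation matrix when present
CORRELATION_FEATURES = ("divergence", "rps", "divpeak", "rul", "at_content", "tsi", "abundance")


def group_contrasts(
    families_a: pd.DataFrame,
    families_b: pd.DataFrame,
    features: Sequence[str] = CONTRAST_FEATURES,
    n_boot: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Effect-size contrasts in the style of an estimation-statistics table.

    Both inputs need a boolean ``shared`` column plus the feature
    columns.  Contrasts: species A vs B over all families, over shared
    families, over non-shared families (unpaired), and shared vs
    non-shared within each species (unpaired).  Each row carries the
    bootstrap mean difference, its 95% CI and the includes-zero call;
    the sampling mode of every contrast is labelled explicitly.
    """
    contrasts = [
        ("all:A-B", families_a, families_b, None),
        ("shared:A-B", families_a[families_a["shared"]], families_b[families_b["shared"]], None),
        ("nonshared:A-B", families_a[~families_a["shared"]], families_b[~families_b["shared"]], None),
        ("A:shared-nonshared", families_a[families_a["shared"]], families_a[~families_a["shared"]], None),
        ("B:shared-nonshared", families_b[families_b["shared"]], families_b[~families_b["shared"]], None),
    ]
    rows = []
    rng = np.random.default_rng(seed)
    for name, ga, gb, _ in contrasts:
        for feat in features:
            if feat not in ga.columns or feat not in gb.columns:
                continue
            a = ga[feat].dropna().to_numpy(dtype=float)
            b = gb[feat].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            es = bootstrap_mean_diff(a, b, paired=False, n_boot=n_boot,
                                     seed=int(rng.integers(2**31)))
            rows.append({
                "contrast": name, "feature": feat, "mode": "unpaired",
                "mean_a": a.mean(), "mean_b": b.mean(),
                "mean_difference": es.point,
                "ci_low": es.ci_low, "ci_high": es.ci_high,
                "includes_zero": es.includes_zero, "n_a": len(a), "n_b": len(b),
            })
    return pd.DataFrame(rows)


def correlation_matrix(
    families: pd.DataFrame,
    features: Sequence[str] = CORRELATION_FEATURES,
) -> pd.DataFrame:
    """Pairwise Spearman correlations with Holm-corrected p-values."""
    feats = [f for f in features if f in families.columns]
    rows = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            sub = families[[feats[i], feats[j]]].dropna()
            if len(sub) < 3:
                continue
            res = spearman(sub[feats[i]], sub[feats[j]])
            if not res.defined:
                continue
            rows.append({
                "x": feats[i], "y": feats[j], "r_s": res.r_s,
                "t": res.t, "p": res.p, "n": res.n,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = holm(out["p"].to_numpy())
    return out


def plot_landscapes(landscapes: Sequence[RepeatLandscape], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for rl in landscapes:
        ax.plot(np.arange(rl.n_classes) * rl.bin_width, rl.bins, label=rl.family_id)
    ax.set_xlabel("divergence from consensus (%)")
    ax.set_ylabel("abundance (% of genome)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def build_report(
    families_a: pd.DataFrame,
    families_b: pd.DataFrame,
    ortholog_pairs: pd.DataFrame | None,
    out_dir: str | Path,
    T: float = 22.81,
    landscapes: Sequence[RepeatLandscape] = (),
    seed: int | None = None,
    n_boot: int = 2000,
) -> dict:
    """Assemble the full comparison report bundle under `out_dir`.

    Writes ``contrasts.tsv``, ``correlations_<species>.tsv``,
    ``orthologs.tsv`` (with a summary JSON alongside), optional
    landscape plots, and a run manifest.  Given a seed, every table is
    byte-stable across runs.  Returns the bundle as a dict of frames.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in (("families_a", families_a), ("families_b", families_b)):
        if "shared" not in df.columns:
            raise ValueError(f"missing upstream artifact: {name} lacks a 'shared' column")
    bundle: dict = {}
    contrasts = group_contrasts(families_a, families_b, n_boot=n_boot, seed=seed)
    contrasts.to_csv(out_dir / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")
    bundle["contrasts"] = contrasts
    for label, fams in (("a", families_a), ("b", families_b)):
        corr = correlation_matrix(fams)
        corr.to_csv(out_dir / f"correlations_{label}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        bundle[f"correlations_{label}"] = corr
    if ortholog_pairs is None or not len(ortholog_pairs):
        (out_dir / "orthologs.tsv").write_text("# no shared families\n")
        bundle["orthologs"] = None
        summary = {"n_pairs": 0, "note": "no shared families"}
    else:
        table = turnover_table(ortholog_pairs, T=T)
        table.to_csv(out_dir / "orthologs.tsv", sep="\t", index=False, float_format="%.6g")
        bundle["orthologs"] = table
        summary = turnover_summary(table, T=T)
    (out_dir / "ortholog_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    bundle["summary"] = summary
    if landscapes:
        plot_landscapes(landscapes, out_dir / "landscapes.svg")
    manifest = {
        "seed": seed,
        "T_ma": T,
        "n_boot": n_boot,
        "n_families_a": int(len(families_a)),
        "n_families_b": int(len(families_b)),
        "n_ortholog_pairs": 0 if ortholog_pairs is None else int(len(ortholog_pairs)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
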