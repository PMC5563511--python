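"""Pooled-replicate intron expression and fold-change analysis.

Replicate reads are pooled per condition before quantification; introns with
fewer than ``min_reads`` pooled reads in *every* condition are dropped.  The
fold change is the RPKM ratio of the knockdown condition over the control.
Introns expressed in the knockdown but silent in the control (denominator
zero) are flagged "exclusive" and carry no numeric fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def intron_rpkm(counts: pd.Series, lengths: pd.Series, mapped_total: float) -> pd.Series:
    if mapped_total <= 0:
        raise ValueError("mapped total must be positive")
    return counts / (mapped_total / 1e6 * lengths / 1e3)


def intron_fold_change(
    pooled_counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_totals: pd.Series,
    knockdown: str,
    control: str,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Intron RPKM per condition and knockdown/control fold change.

    ``pooled_counts``: introns x conditions pooled read counts; ``lengths``
    in nt; ``mapped_totals`` per condition.  Introns below ``min_reads`` in
    all conditions are removed.  Returns per-condition RPKM columns,
    ``fold_change`` (NaN when the control is silent), and boolean
    ``exclusive`` / ``retained`` flags.
    """
    for cond in (knockdown, control):
        if cond not in pooled_counts.columns:
            raise ValueError(f"condition {cond!r} missing from pooled counts")
    missing_tot = [c for c in pooled_counts.columns if c not in mapped_totals.index]
    if missing_tot:
        raise ValueError(f"mapped totals missing for conditions: {missing_tot}")

    lengths = lengths.reindex(pooled_counts.index)
    if lengths.isna().any():
        raise ValueError("length missing for some introns")

    keep = (pooled_counts >= min_reads).any(axis=1)
    kept = pooled_counts.loc[keep]

    rpkm = pd.DataFrame(index=kept.index)
    for cond in pooled_counts.columns:
        rpkm[f"RPKM_{cond}"] = intron_rpkm(kept[cond], lengths.loc[kept.index],
                                           float(mapped_totals[cond]))

    kd_rpkm = rpkm[f"RPKM_{knockdown}"]
    ctrl_rpkm = rpkm[f"RPKM_{control}"]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ctrl_rpkm > 0, kd_rpkm / ctrl_rpkm, np.nan)
    exclusive = (ctrl_rpkm == 0) & (kept[knockdown] >= min_reads)

    out = pd.DataFrame(
        {
            **{c: kept[c] for c in pooled_counts.columns},
            **{c: rpkm[c] for c in rpkm.columns},
            "fold_change": fc,
            "exclusive": exclusive,
            "retained": (fc > 1.0) | exclusive.to_numpy(),
        },
        index=kept.index,
    )
    out.index.name = pooled_counts.index.name or "intron_id"
    return out
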