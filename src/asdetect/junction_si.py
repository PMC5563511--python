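"""Junction splicing-index (SI) pipeline.

Each junction j of gene g is quantified per sample as RPKM_j; the gene-level
RPKM_g is the sum over the gene's junctions, and the normalized intensity
NI = RPKM_j / RPKM_g is the junction's fractional contribution (NI sums to 1
across a gene's junctions within a sample).  Between two conditions the
splicing index is the natural-log ratio of group-mean NI:

    SI_j = ln(mean NI_j | group B) - ln(mean NI_j | group A).

Candidate junctions pass a filter cascade: gene expressed in both groups
(> gene_min reads), junction reads above background (>= min_reads in at least
half the replicates of either group), unpaired two-tailed t-test on
per-replicate NI (raw p <= 0.05; Sidak-adjusted p reported alongside), and
|SI| >= the cutoff (1.0 by default).  Survivors are ranked by t-test p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .splice_model import DEFAULT_JUNCTION_LENGTH

FLAG_LOW_READS = 1
FLAG_GENE_UNEXPRESSED = 2
FLAG_NS_TTEST = 4
FLAG_SI_BELOW_CUTOFF = 8
FLAG_UNEVALUABLE = 16


@dataclass
class SiParams:
    si_cutoff: float = 1.0
    min_reads: int = 4
    gene_min: int = 5
    junction_length: int = DEFAULT_JUNCTION_LENGTH
    t_alpha: float = 0.05
    sidak_scope: str = "global"  # or "per_gene"


def junction_rpkm(count, mapped_reads, junction_length: float = DEFAULT_JUNCTION_LENGTH):
    """Reads per kilobase of junction segment per million mapped reads."""
    mapped_reads = np.asarray(mapped_reads, dtype=float)
    if np.any(mapped_reads <= 0):
        raise ValueError("mapped_reads must be positive")
    if junction_length <= 0:
        raise ValueError("junction_length must be positive")
    return np.asarray(count, dtype=float) / (mapped_reads / 1e6 * junction_length / 1e3)


def gene_rpkm(junction_rpkms) -> float:
    """Gene-level RPKM: plain sum over the gene's junction RPKMs (0 if none)."""
    arr = np.asarray(list(junction_rpkms), dtype=float)
    return float(arr.sum()) if arr.size else 0.0


def splicing_index(ni_mut: float, ni_wt: float) -> float:
    """SI = ln(NI_mut) - ln(NI_wt); NaN (unevaluable) if either group NI is 0."""
    if ni_mut <= 0 or ni_wt <= 0:
        return float("nan")
    return float(np.log(ni_mut) - np.log(ni_wt))


def _sidak(p: np.ndarray, m: int) -> np.ndarray:
    return 1.0 - (1.0 - p) ** m


def si_pipeline(
    counts: pd.DataFrame,
    gene_of_junction: dict[str, str],
    groups: dict[str, str],
    group_order: tuple[str, str],
    params: SiParams | None = None,
    mapped_reads: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Quantify NI/SI for every junction and apply the filter cascade.

    ``counts``: junction x sample read-count table.  ``group_order`` is
    (test, reference): SI is ln NI(test) - ln NI(reference).  Mapped totals
    default to per-sample column sums of the junction matrix.  Returns a
    frame with per-group mean NI, SI, t-test p, Sidak-adjusted p, bitset
    ``flags`` and boolean ``survivor``, ranked survivors first by t-test p.
    """
    params = params or SiParams()
    test_g, ref_g = group_order
    samples = list(counts.columns)
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    s_test = [s for s in samples if groups[s] == test_g]
    s_ref = [s for s in samples if groups[s] == ref_g]
    if len(s_test) < 2 or len(s_ref) < 2:
        raise ValueError("each group needs at least two replicates")

    genes = pd.Series({j: gene_of_junction[j] for j in counts.index}, name="gene_id")
    mat = counts.to_numpy(dtype=float)
    if mapped_reads is None:
        totals = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        totals = np.array([mapped_reads[s] for s in samples], dtype=float)

    # junctions with zero expression in both datasets are excluded up front
    keep = mat.sum(axis=1) > 0
    counts = counts.loc[keep]
    genes = genes.loc[keep]
    mat = mat[keep, :]

    rpkm = junction_rpkm(mat, totals[None, :], params.junction_length)
    rpkm_df = pd.DataFrame(rpkm, index=counts.index, columns=samples)
    gene_sum = rpkm_df.groupby(genes).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        ni = rpkm_df / gene_sum
    ni = ni.where(gene_sum > 0)

    idx_test = [samples.index(s) for s in s_test]
    idx_ref = [samples.index(s) for s in s_ref]
    ni_test = ni.iloc[:, idx_test]
    ni_ref = ni.iloc[:, idx_ref]
    mean_ni_test = ni_test.mean(axis=1)
    mean_ni_ref = ni_ref.mean(axis=1)

    si = pd.Series(
        [splicing_index(a, b) for a, b in zip(mean_ni_test, mean_ni_ref)],
        index=counts.index,
    )

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate (constant-NI) junctions legitimately yield NaN here
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, t_p = sps.ttest_ind(ni_test, ni_ref, axis=1)
    t_p = pd.Series(t_p, index=counts.index)

    # filter cascade -----------------------------------------------------
    flags = pd.Series(0, index=counts.index, dtype=int)

    gene_reads_test = counts.iloc[:, idx_test].sum(axis=1).groupby(genes).transform("sum")
    gene_reads_ref = counts.iloc[:, idx_ref].sum(axis=1).groupby(genes).transform("sum")
    gene_ok = (gene_reads_test > params.gene_min) & (gene_reads_ref > params.gene_min)
    flags[~gene_ok] |= FLAG_GENE_UNEXPRESSED

    above_test = (counts.iloc[:, idx_test] >= params.min_reads).mean(axis=1) >= 0.5
    above_ref = (counts.iloc[:, idx_ref] >= params.min_reads).mean(axis=1) >= 0.5
    flags[~(above_test | above_ref)] |= FLAG_LOW_READS

    evaluable = si.notna() & t_p.notna()
    flags[~evaluable] |= FLAG_UNEVALUABLE

    # Sidak family: junctions still alive when the test is reached
    tested = gene_ok & (above_test | above_ref) & evaluable
    if params.sidak_scope == "per_gene":
        m_of = genes[tested].groupby(genes[tested]).transform("size")
        adj = pd.Series(np.nan, index=counts.index)
        adj[tested] = _sidak(t_p[tested].to_numpy(), m_of.to_numpy())
    else:
        m = int(tested.sum())
        adj = pd.Series(np.nan, index=counts.index)
        if m:
            adj[tested] = _sidak(t_p[tested].to_numpy(), m)

    flags[evaluable & (t_p > params.t_alpha)] |= FLAG_NS_TTEST
    flags[evaluable & (si.abs() < params.si_cutoff)] |= FLAG_SI_BELOW_CUTOFF

    out = pd.DataFrame(
        {
            "junction_id": counts.index,
            "gene_id": genes.values,
            f"mean_NI_{test_g}": mean_ni_test.values,
            f"mean_NI_{ref_g}": mean_ni_ref.values,
            "SI": si.values,
            "t_p": t_p.values,
            "adj_p": adj.values,
            "flags": flags.values,
            "survivor": (flags == 0).values,
        }
    ).set_index("junction_id")
    for s in samples:
        out[f"NI_{s}"] = ni[s].values
    out = out.sort_values(by=["survivor", "t_p"], ascending=[False, True])
    return out


def top2_junction_table(results: pd.DataFrame, group_order: tuple[str, str]) -> pd.DataFrame:
    """Per-gene two-junction matrix for heat-map export.

    For each gene with >=2 surviving junctions, emit the two with the
    smallest t-test p (ties broken by junction id, i.e. lower coordinate).
    Genes with fewer than two survivors are excluded.
    """
    test_g, ref_g = group_order
    surv = results[results["survivor"]].copy()
    rows = []
    for gene, sub in surv.groupby("gene_id"):
        if len(sub) < 2:
            continue
        # ties in p broken by junction id (lower coordinate first)
        top = sub.sort_index(kind="stable").sort_values(by="t_p", kind="stable").iloc[:2]
        row = {"gene_id": gene}
        for rank, (jid, jrow) in enumerate(top.iterrows(), start=1):
            row[f"J{rank}_id"] = jid
            row[f"J{rank}_NI_{test_g}"] = jrow[f"mean_NI_{test_g}"]
            row[f"J{rank}_NI_{ref_g}"] = jrow[f"mean_NI_{ref_g}"]
            row[f"J{rank}_SI"] = jrow["SI"]
            row[f"J{rank}_p"] = jrow["t_p"]
        rows.append(row)
    cols = ["gene_id"]
    for rank in (1, 2):
        cols += [f"J{rank}_id", f"J{rank}_NI_{test_g}", f"J{rank}_NI_{ref_g}",
                 f"J{rank}_SI", f"J{rank}_p"]
    return pd.DataFrame(rows, columns=cols)
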