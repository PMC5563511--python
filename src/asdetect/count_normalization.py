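"""Term-level count matrices, TMM scale factors and log2-CPM expression values.

Counts for exons, introns and junctions are kept in a single matrix (terms x
samples).  Library composition is corrected with the trimmed mean of M-values
(TMM): each sample is compared to a reference sample, log-ratios (M) and
average log-abundances (A) are doubly trimmed (30% / 5%), and the remaining
M-values are averaged with inverse approximate-variance weights.  Factors are
rescaled so their product is 1, anchoring the expression scale.

Expression values are log2 counts-per-million with the usual half-count and
unit-library offsets:  log2((count + 0.5) / (lib * factor + 1) * 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TermCountMatrix:
    """Integer read counts for every term across samples."""

    term_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (terms, samples)
    library_sizes: np.ndarray  # (samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.term_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.term_ids)} terms x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral")
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise ValueError("library_sizes must have one entry per sample")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library_sizes must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, library_sizes=None) -> "TermCountMatrix":
        counts = df.to_numpy(dtype=float)
        libs = counts.sum(axis=0) if library_sizes is None else np.asarray(library_sizes, float)
        return cls(list(df.index), list(df.columns), counts, libs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.term_ids, columns=self.sample_ids)

    def subset_terms(self, term_ids: list[str]) -> "TermCountMatrix":
        idx = [self.term_ids.index(t) for t in term_ids]
        return TermCountMatrix(term_ids, list(self.sample_ids),
                               self.counts[idx, :], self.library_sizes.copy())


@dataclass
class ExpressionMatrix:
    """log2-CPM values after TMM scaling, same layout as the count matrix."""

    term_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    norm_factors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.term_ids, columns=self.sample_ids)


def read_counts_tsv(path, library_sizes_path=None) -> TermCountMatrix:
    """Read a TSV count matrix (first column term_id, header sample ids).

    An optional two-column library-size file (sample_id <tab> total) overrides
    the default column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    libs = None
    if library_sizes_path is not None:
        lib_df = pd.read_csv(library_sizes_path, sep="\t", index_col=0, header=None, comment="#")
        libs = lib_df.iloc[:, 0].reindex(df.columns).to_numpy(float)
        if np.any(~np.isfinite(libs)):
            raise ValueError("library-size file does not cover every sample")
    return TermCountMatrix.from_frame(df, library_sizes=libs)


def write_counts_tsv(matrix: TermCountMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "term_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TMM

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse of the delta-method binomial variance of M
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(sel) or np.sum(w[sel]) == 0:
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f) or abs(f) < 1e-10:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    matrix: TermCountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scale factors, rescaled so their product is 1.

    The reference sample is the one whose upper-quartile relative expression is
    closest to the mean upper quartile across samples.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    col_nonzero = (counts > 0).any(axis=0)
    if not col_nonzero.all():
        bad = [s for s, ok in zip(matrix.sample_ids, col_nonzero) if not ok]
        raise ValueError(f"all-zero sample(s): {bad}")

    libs = matrix.library_sizes
    with np.errstate(divide="ignore"):
        q75 = np.array([np.quantile(counts[:, j] / libs[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair_factor(
                counts[:, j], counts[:, ref_idx], libs[j], libs[ref_idx],
                logratio_trim=logratio_trim, sum_trim=sum_trim,
            )
    # anchor: geometric mean 1 => product 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(matrix: TermCountMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """log2((count + 0.5) / (library * factor + 1) * 1e6), strictly increasing in count."""
    if factors is None:
        factors = np.ones(len(matrix.sample_ids))
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("norm factors must be positive")
    eff_lib = matrix.library_sizes * factors
    values = np.log2((matrix.counts + 0.5) / (eff_lib + 1.0) * 1e6)
    return ExpressionMatrix(
        list(matrix.term_ids), list(matrix.sample_ids), values, factors
    )
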