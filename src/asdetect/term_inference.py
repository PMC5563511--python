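"""Per-term linear models with empirical-Bayes variance moderation.

Each term's log2-CPM vector r is modelled as r = D @ alpha + error, with D a
samples x conditions indicator design.  A contrast matrix C picks the tested
combination beta = C' alpha (e.g. "treated - control").  Residual variances
are shrunk toward a scaled inverse-chi-square prior fitted by the method of
moments on log variances; moderated t-statistics use the posterior variance
with df + d0 degrees of freedom.  Two-tailed p-values are converted to signed
one-tailed p-values with the sign of beta, so that a term moving *up* under
the contrast gets p_one < 0.5 and one moving down gets p_one > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .count_normalization import ExpressionMatrix

_TINY_P = np.nextafter(0.0, 1.0)
_D0_CAP = 1e6


@dataclass
class DesignSpec:
    """Group-indicator design matrix plus a single contrast column.

    ``design`` is samples x conditions with exactly one 1 per row; the
    contrast column must sum to zero (a comparison, not an average).
    """

    design: np.ndarray
    contrast: np.ndarray
    condition_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float).reshape(-1)
        n, k = self.design.shape
        if np.linalg.matrix_rank(self.design) < k:
            raise ValueError("design matrix is rank-deficient")
        if not np.all((self.design == 0) | (self.design == 1)):
            raise ValueError("design must be a 0/1 indicator matrix")
        if not np.all(self.design.sum(axis=1) == 1):
            raise ValueError("each sample must belong to exactly one condition")
        if self.contrast.shape != (k,):
            raise ValueError("contrast length must equal the number of conditions")
        if abs(self.contrast.sum()) > 1e-12:
            raise ValueError("contrast must sum to zero")

    @classmethod
    def from_groups(cls, sample_groups: dict[str, str], contrast: str) -> "DesignSpec":
        """Build from a sample -> group mapping and a contrast string "B - A"."""
        labels = sorted(set(sample_groups.values()))
        samples = list(sample_groups)
        design = np.zeros((len(samples), len(labels)))
        for i, s in enumerate(samples):
            design[i, labels.index(sample_groups[s])] = 1.0
        pos, _, neg = contrast.partition("-")
        pos, neg = pos.strip(), neg.strip()
        if pos not in labels or neg not in labels:
            raise ValueError(f"contrast {contrast!r} names unknown groups (have {labels})")
        c = np.zeros(len(labels))
        c[labels.index(pos)] = 1.0
        c[labels.index(neg)] = -1.0
        return cls(design, c, labels, samples)

    @classmethod
    def from_table(cls, path, contrast: str) -> "DesignSpec":
        """Two-column TSV (sample_id, group), no header required."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError("design table needs two columns: sample_id, group")
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        return cls.from_groups(mapping, contrast)

    def negated(self) -> "DesignSpec":
        return DesignSpec(self.design.copy(), -self.contrast, list(self.condition_labels),
                          list(self.sample_ids))


def fit_term_model(expr: ExpressionMatrix, spec: DesignSpec):
    """OLS per term: returns (beta, residual_variance, residual_df, contrast_var_factor).

    beta is the contrast coefficient in log2-CPM units; the variance factor is
    c' (D'D)^{-1} c, so var(beta) = residual_variance * factor.
    """
    y = np.asarray(expr.values, dtype=float)
    d = spec.design
    n, k = d.shape
    if y.shape[1] != n:
        raise ValueError("expression matrix and design disagree on sample count")
    counts_per_cond = d.sum(axis=0)
    involved = spec.contrast != 0
    if np.any(counts_per_cond[involved] < 2):
        raise ValueError("each condition in the contrast needs at least two samples")
    dtd_inv = np.linalg.inv(d.T @ d)
    proj = dtd_inv @ d.T                      # (k, n)
    alphas = y @ proj.T                       # (terms, k) group means
    resid = y - alphas @ d.T
    df = n - k
    s2 = (resid ** 2).sum(axis=1) / df
    beta = alphas @ spec.contrast
    var_factor = float(spec.contrast @ dtd_inv @ spec.contrast)
    return beta, s2, df, var_factor


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def moderate_variances(residual_variances: np.ndarray, residual_df) -> tuple[np.ndarray, float, float]:
    """Fit a scaled inverse-chi-square prior and return posterior variances.

    Returns (posterior_variances, prior_df d0, prior_variance s0^2).  The fit
    matches the mean and excess spread of log sample variances against the
    log-chi-square moments implied by the residual df.  When the observed
    spread does not exceed the chi-square sampling spread (e.g. all variances
    identical), d0 is infinite and every posterior variance equals the
    geometric-mean variance.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    if np.sum(df > 0) < 10:
        raise ValueError("need at least 10 terms with positive df")
    ok = (df > 0) & (s2 > 0)
    if ok.sum() == 0:
        # every residual variance is exactly zero: degenerate point-mass prior
        return np.zeros_like(s2), np.inf, 0.0

    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2.0)))

    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling noise (e.g. all equal):
        # point mass at the geometric-mean variance
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))

    if np.isinf(d0):
        posterior = np.full_like(s2, s0_sq)
    else:
        posterior = (d0 * s0_sq + df * s2) / (d0 + df)
    return posterior, d0, s0_sq


def moderated_t_pvalues(beta, posterior_var, var_factor, df, d0):
    """Moderated t and two-tailed p on df + d0 degrees of freedom (d0 capped)."""
    beta = np.asarray(beta, dtype=float)
    posterior_var = np.asarray(posterior_var, dtype=float)
    total_df = df + min(d0, _D0_CAP)
    se = np.sqrt(posterior_var * var_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p_two = 2.0 * stats.t.sf(np.abs(t), total_df)
    # zero residual variance with nonzero beta: smallest representable p, flagged upstream
    p_two = np.where((se == 0) & (beta != 0), _TINY_P, p_two)
    p_two = np.clip(p_two, _TINY_P, 1.0)
    return t, p_two


def one_tailed(p_two, beta):
    """Signed one-tailed conversion: p/2 if beta>0, 1-p/2 if beta<0, 0.5 if beta=0."""
    p_two = np.asarray(p_two, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = np.where(beta > 0, p_two / 2.0, np.where(beta < 0, 1.0 - p_two / 2.0, 0.5))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class TermStats:
    """Vectorized per-term statistics for one contrast."""

    term_ids: list[str]
    beta: np.ndarray
    residual_variance: np.ndarray
    residual_df: float
    posterior_variance: np.ndarray
    prior_df: float
    prior_variance: float
    moderated_t: np.ndarray
    p_two: np.ndarray
    p_one: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term_id": self.term_ids,
                "beta": self.beta,
                "residual_variance": self.residual_variance,
                "residual_df": self.residual_df,
                "posterior_variance": self.posterior_variance,
                "moderated_t": self.moderated_t,
                "p_two": self.p_two,
                "p_one": self.p_one,
            }
        ).set_index("term_id")

    def p_one_lookup(self) -> dict[str, float]:
        return dict(zip(self.term_ids, self.p_one))


def term_statistics(expr: ExpressionMatrix, spec: DesignSpec) -> TermStats:
    """Full per-term inference: fit, moderate, convert to one-tailed p-values."""
    beta, s2, df, var_factor = fit_term_model(expr, spec)
    posterior, d0, s0_sq = moderate_variances(s2, df)
    t, p_two = moderated_t_pvalues(beta, posterior, var_factor, df, d0)
    p_one = one_tailed(p_two, beta)
    return TermStats(
        term_ids=list(expr.term_ids),
        beta=beta,
        residual_variance=s2,
        residual_df=df,
        posterior_variance=posterior,
        prior_df=d0,
        prior_variance=s0_sq,
        moderated_t=t,
        p_two=p_two,
        p_one=p_one,
    )
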