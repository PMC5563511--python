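"""Irwin-Hall combination of one-tailed term p-values into event-level calls.

For a candidate event with inclusion set H_e and skipping set S_e the
statistic is

    x_e = sum_{k in H_e} p_k  +  sum_{k in S_e} (1 - p_k),

where p_k is the one-tailed term p-value.  Under the null every summand is
Uniform(0,1), so x_e follows the Irwin-Hall distribution with n = |H_e| +
|S_e| terms.  A spliced-in event (inclusion terms up, skipping terms down)
drives x_e toward 0; spliced-out drives it toward n.  The combined two-sided
p-value is 2 * min(F(x_e), 1 - F(x_e)) with F the exact Irwin-Hall CDF; for
x_e <= 1 this reduces to 2 * x_e^n / n!.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_normalization import TermCountMatrix, log_cpm, tmm_factors
from .splice_model import EventDefinition, EventType
from .term_inference import DesignSpec, TermStats, term_statistics

MAX_EVENT_TERMS = 12


@dataclass
class EventResult:
    event_id: str
    gene_id: str
    event_type: EventType
    n_terms: int
    x_e: float
    cdf: float
    p_overall: float
    direction: str  # "spliced_in" | "spliced_out"
    term_p_one: tuple[float, ...]
    significant: bool = False
    p_adjusted: float | None = None


def event_statistic(p_one: dict[str, float], event: EventDefinition) -> float:
    """x_e = sum of inclusion p-values plus sum of (1 - p) over skipping terms."""
    missing = [t for t in (*event.inclusion_terms, *event.skipping_terms) if t not in p_one]
    if missing:
        raise KeyError(f"event {event.event_id}: no term statistic for {missing}")
    inc = math.fsum(p_one[t] for t in event.inclusion_terms)
    skp = math.fsum(1.0 - p_one[t] for t in event.skipping_terms)
    return inc + skp


def irwin_hall_cdf(x: float, n: int) -> float:
    """Exact CDF of a sum of n independent Uniform(0,1) variables.

    F(x) = (1/n!) * sum_{k=0}^{floor(x)} (-1)^k C(n,k) (x-k)^n.  For x <= 1
    this is x^n / n!.  The alternating sum is evaluated with compensated
    summation; n is small (<= 12) so cancellation stays mild.
    """
    if not 1 <= n <= MAX_EVENT_TERMS:
        raise ValueError(f"n must be in [1, {MAX_EVENT_TERMS}], got {n}")
    if x < 0 or x > n:
        raise ValueError(f"x must be in [0, {n}], got {x}")
    if x == n:
        return 1.0
    terms = [((-1) ** k) * math.comb(n, k) * (x - k) ** n for k in range(int(math.floor(x)) + 1)]
    f = math.fsum(terms) / math.factorial(n)
    return min(max(f, 0.0), 1.0)


def irwin_hall_pvalue(x_e: float, n: int) -> tuple[float, str]:
    """Two-sided combined p and direction from the Irwin-Hall CDF.

    p = min(1, 2*min(F, 1-F)); direction is spliced_in when F < 0.5 (x_e in
    the lower tail, i.e. inclusion terms significantly up).
    """
    f = irwin_hall_cdf(x_e, n)
    p = min(1.0, 2.0 * min(f, 1.0 - f))
    direction = "spliced_in" if f < 0.5 else "spliced_out"
    return p, direction


def summarize_event(p_one: dict[str, float], event: EventDefinition) -> EventResult:
    x_e = event_statistic(p_one, event)
    n = event.n_terms
    f = irwin_hall_cdf(x_e, n)
    p, direction = irwin_hall_pvalue(x_e, n)
    return EventResult(
        event_id=event.event_id,
        gene_id=event.gene_id,
        event_type=event.event_type,
        n_terms=n,
        x_e=x_e,
        cdf=f,
        p_overall=p,
        direction=direction,
        term_p_one=tuple(
            p_one[t] for t in (*event.inclusion_terms, *event.skipping_terms)
        ),
    )


def _context_expressed(counts: TermCountMatrix, spec: DesignSpec,
                       term_ids: tuple[str, ...], min_reads: int,
                       index: dict[str, int]) -> bool:
    """Every context exon must reach min_reads in a majority of replicates of
    at least one condition."""
    design = spec.design
    for tid in term_ids:
        if tid not in index:
            return False
        row = counts.counts[index[tid], :]
        ok_any = False
        for j in range(design.shape[1]):
            mask = design[:, j] == 1
            if mask.sum() == 0:
                continue
            if np.mean(row[mask] >= min_reads) >= 0.5:
                ok_any = True
                break
        if not ok_any:
            return False
    return True


def detect_events(
    counts: TermCountMatrix,
    events: list[EventDefinition],
    spec: DesignSpec,
    alpha: float = 0.05,
    min_reads: int = 4,
    correction: str = "none",
    keep_all: bool = False,
) -> tuple[list[EventResult], TermStats]:
    """Run the full event pipeline: TMM -> log-CPM -> moderated t -> Irwin-Hall.

    An event is reported as significant only if (a) every context flanking
    exon reaches ``min_reads`` in a replicate majority of at least one
    condition, (b) every inclusion/skipping term has a nonzero count in at
    least one sample, and (c) its combined p-value passes ``alpha``
    (Benjamini-Hochberg-adjusted when ``correction="bh"``).  Returned events
    are sorted by p_overall; with ``keep_all`` filtered events are retained
    (marked non-significant) instead of dropped.
    """
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    factors = tmm_factors(counts)
    expr = log_cpm(counts, factors)
    stats = term_statistics(expr, spec)
    p_one = stats.p_one_lookup()
    index = {t: i for i, t in enumerate(counts.term_ids)}

    results: list[EventResult] = []
    evaluable: list[EventResult] = []
    for event in events:
        terms = (*event.inclusion_terms, *event.skipping_terms)
        if any(t not in index for t in terms):
            continue
        res = summarize_event(p_one, event)
        nonzero = all(counts.counts[index[t], :].sum() > 0 for t in terms)
        context_ok = _context_expressed(counts, spec, event.context_terms, min_reads, index)
        if nonzero and context_ok:
            evaluable.append(res)
        results.append(res)

    if correction == "bh" and evaluable:
        m = len(evaluable)
        order = np.argsort([r.p_overall for r in evaluable])
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            val = min(prev, evaluable[i].p_overall * m / (rank_pos + 1))
            adj[i] = val
            prev = val
        for r, a in zip(evaluable, adj):
            r.p_adjusted = float(a)

    for r in evaluable:
        gate = r.p_adjusted if correction == "bh" else r.p_overall
        r.significant = gate <= alpha

    out = results if keep_all else [r for r in results if r.significant]
    out.sort(key=lambda r: (r.p_overall, r.event_id))
    return out, stats


def results_frame(results: list[EventResult]) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "gene_id": r.gene_id,
            "event_type": r.event_type.value,
            "n": r.n_terms,
            "x_e": r.x_e,
            "F": r.cdf,
            "p_overall": r.p_overall,
            "p_adjusted": r.p_adjusted if r.p_adjusted is not None else np.nan,
            "direction": r.direction,
            "significant": r.significant,
            "term_p_one": ",".join(f"{p:.6g}" for p in r.term_p_one),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "event_type", "n", "x_e", "F", "p_overall",
                 "p_adjusted", "direction", "significant", "term_p_one"],
    )
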