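"""Synthetic splice graphs, count matrices with planted AS events, and PTC cohorts.

The generator emulates the statistical structure of a two-group bulk RNA-seq
splicing study: four biological replicates per group by default,
negative-binomial term counts with variance mean + dispersion * mean^2, and
*reciprocal* planted events — for a spliced-in cassette event the inclusion
terms (exon and flanking junctions) rise by the effect fold in the test group
while the skipping junction falls by the same fold, mirroring the reciprocal
read patterns that distinguish genuine splicing shifts from expression
changes.  Intron-retention events perturb the intron against its excising
junction(s) the same way.  Every planted event is recorded in a ground-truth
table keyed by the same event ids the detection pipeline emits, so recovery
can be scored exactly.

PTC cohorts are pairs of functionally-spliced (FS) and intron-retaining (AS)
transcripts; the retained intron carries an in-frame stop at a recorded
offset, giving a known 3'UTR extension.

All draws flow from a single mandatory seed; a fixed seed yields
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_normalization import TermCountMatrix
from .splice_model import (
    EventType,
    ExonRecord,
    SpliceGraph,
    build_splice_graphs,
    enumerate_events,
    term_metadata_frame,
)

_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-group splicing experiment."""

    seed: int
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 5)
    replicates: int = 4
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    cassette_fraction: float = 0.0
    ir_fraction: float = 0.0
    effect_size: float = 4.0
    libsize_spread: float = 1.2
    skip_junction_prob: float = 1.0
    reciprocal: bool = True
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 600)
    # PTC cohort
    n_ptc_pairs: int = 100
    cds_codons: tuple[int, int] = (50, 200)
    utr3_length: tuple[int, int] = (40, 200)
    ptc_intron_length: tuple[int, int] = (200, 2000)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.cassette_fraction, self.ir_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("event fractions must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.libsize_spread < 1.0:
            raise ValueError("libsize_spread must be >= 1")


@dataclass
class SimTruth:
    """Ground truth for planted events and PTC transcripts."""

    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["event_id", "gene_id", "event_type", "direction", "effect_size"]))
    transcripts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["transcript_id", "pair_id", "role", "ptc_offset", "utr3_extension"]))

    def write_events(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    def write_transcripts(self, path) -> None:
        self.transcripts.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_events(path) -> "SimTruth":
        return SimTruth(events=pd.read_csv(path, sep="\t", comment="#"))

    @staticmethod
    def read_transcripts(path) -> "SimTruth":
        return SimTruth(transcripts=pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# gene models

def simulate_gene_models(config: SimConfig) -> dict[str, SpliceGraph]:
    """Random multi-exon gene models on one synthetic chromosome.

    Each gene gets a full-length transcript; with probability
    ``skip_junction_prob`` genes with an internal exon also get a
    skipping isoform omitting one internal exon, which is what creates
    annotated skipping junctions and hence cassette-event candidates.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ExonRecord] = []
    cursor = 1000
    for g in range(config.n_genes):
        gene_id = f"g{g:05d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos = pos + length + int(rng.integers(config.intron_length[0],
                                                  config.intron_length[1] + 1))
        cursor = pos + 5000
        strand = "+" if rng.random() < 0.5 else "-"
        for s, e in exons:
            records.append(ExonRecord(gene_id, f"{gene_id}.t1", "chrS", s, e, strand))
        if n_ex >= 3 and rng.random() < config.skip_junction_prob:
            skipped = int(rng.integers(1, n_ex - 1))
            for i, (s, e) in enumerate(exons):
                if i != skipped:
                    records.append(ExonRecord(gene_id, f"{gene_id}.t2", "chrS", s, e, strand))
    return build_splice_graphs(records)


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + dispersion*mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    graphs: dict[str, SpliceGraph], config: SimConfig
) -> tuple[TermCountMatrix, SimTruth]:
    """Draw NB term counts with reciprocally planted events.

    Group labels are A (reference) and B (test).  For a planted spliced-in
    event the inclusion-term means are multiplied by the effect fold and the
    skipping-term means divided by it in group B; spliced-out events reverse
    the roles.  At most one event is planted per gene, and cassette/IR genes
    are disjoint.
    """
    if (config.cassette_fraction > 0 or config.ir_fraction > 0) and config.effect_size <= 1:
        raise ValueError("effect_size must exceed 1 when events are planted")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    meta = term_metadata_frame(graphs.values())
    term_ids = list(meta["term_id"])
    term_index = {t: i for i, t in enumerate(term_ids)}
    n_terms = len(term_ids)
    n_rep = config.replicates
    sample_ids = [f"A{i+1}" for i in range(n_rep)] + [f"B{i+1}" for i in range(n_rep)]
    group_b = np.array([s.startswith("B") for s in sample_ids])

    gene_ids = sorted(graphs)
    events_by_gene = {g: enumerate_events(graphs[g]) for g in gene_ids}
    cassette_ok = [g for g in gene_ids
                   if any(e.event_type is EventType.CASSETTE_EXON for e in events_by_gene[g])]
    ir_ok = [g for g in gene_ids
             if any(e.event_type is EventType.INTRON_RETENTION for e in events_by_gene[g])]

    n_cas = int(round(config.cassette_fraction * len(gene_ids)))
    n_ir = int(round(config.ir_fraction * len(gene_ids)))
    if n_cas > len(cassette_ok):
        raise ValueError(f"only {len(cassette_ok)} genes have cassette candidates, "
                         f"requested {n_cas}")
    cas_genes = list(rng.choice(cassette_ok, size=n_cas, replace=False)) if n_cas else []
    ir_pool = [g for g in ir_ok if g not in set(cas_genes)]
    if n_ir > len(ir_pool):
        raise ValueError(f"only {len(ir_pool)} genes left for IR planting, requested {n_ir}")
    ir_genes = list(rng.choice(ir_pool, size=n_ir, replace=False)) if n_ir else []

    base = np.full((n_terms, 2), config.baseline_mean)  # columns: group A mean, group B mean
    truth_rows = []
    for gene, wanted in [(g, EventType.CASSETTE_EXON) for g in cas_genes] + \
                        [(g, EventType.INTRON_RETENTION) for g in ir_genes]:
        candidates = [e for e in events_by_gene[gene] if e.event_type is wanted]
        event = candidates[int(rng.integers(len(candidates)))]
        direction = "spliced_in" if rng.random() < 0.5 else "spliced_out"
        up, down = (config.effect_size, 1.0 / config.effect_size)
        if direction == "spliced_out":
            up, down = down, up
        for t in event.inclusion_terms:
            base[term_index[t], 1] *= up
        if config.reciprocal:
            for t in event.skipping_terms:
                base[term_index[t], 1] *= down
        truth_rows.append(
            {"event_id": event.event_id, "gene_id": gene,
             "event_type": wanted.value, "direction": direction,
             "effect_size": config.effect_size}
        )

    lib_scale = rng.uniform(1.0 / config.libsize_spread, config.libsize_spread,
                            size=len(sample_ids))
    means = np.where(group_b[None, :], base[:, 1:2], base[:, 0:1]) * lib_scale[None, :]
    counts = _nb_draw(rng, means, config.dispersion).astype(np.int64)

    matrix = TermCountMatrix(term_ids, sample_ids, counts, counts.sum(axis=0).astype(float))
    truth = SimTruth(events=pd.DataFrame(
        truth_rows, columns=["event_id", "gene_id", "event_type", "direction", "effect_size"]))
    return matrix, truth


def design_groups(config: SimConfig) -> dict[str, str]:
    """Sample -> group mapping matching :func:`simulate_counts` sample ids."""
    return {f"A{i+1}": "A" for i in range(config.replicates)} | \
           {f"B{i+1}": "B" for i in range(config.replicates)}


# ---------------------------------------------------------------------------
# PTC cohort

def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_ptc_cohort(config: SimConfig):
    """FS/AS transcript pairs with a planted in-frame stop in the retained intron.

    Returns (records, cds_table, truth): ``records`` is a list of
    (transcript_id, sequence); the CDS table carries transcript_id, gene_id,
    cds_start, annotated_stop_offset, pair_id, role.  The AS member retains
    one intron inserted at a codon boundary; its prefix codons are stop-free
    so the planted TAA is guaranteed to be the first in-frame stop.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records: list[tuple[str, str]] = []
    cds_rows, truth_rows = [], []
    for i in range(config.n_ptc_pairs):
        pair = f"pair{i:04d}"
        gene = f"ptcg{i:04d}"
        u5 = int(rng.integers(10, 60))
        k = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        u3 = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
        cds = _random_codons(rng, k)
        fs_seq = _random_seq(rng, u5) + "ATG" + cds + "TAA" + _random_seq(rng, u3)
        fs_stop = u5 + 3 + 3 * k  # offset of the TAA

        intron_total = int(rng.integers(config.ptc_intron_length[0],
                                        config.ptc_intron_length[1] + 1))
        intron_total -= intron_total % 3  # codon-aligned insertion keeps the frame
        m_prefix = int(rng.integers(0, min(10, intron_total // 3 - 1) + 1))
        tail_len = intron_total - 3 * m_prefix - 3
        intron = _random_codons(rng, m_prefix) + "TAA" + _random_seq(rng, tail_len)
        insert_codon = int(rng.integers(1, k))  # after this many CDS codons
        insert_at = u5 + 3 + 3 * insert_codon
        as_seq = fs_seq[:insert_at] + intron + fs_seq[insert_at:]
        ptc_offset = insert_at + 3 * m_prefix
        as_stop_annot = fs_stop + len(intron)

        fs_id, as_id = f"{gene}.fs", f"{gene}.as"
        records.append((fs_id, fs_seq))
        records.append((as_id, as_seq))
        cds_rows.append({"transcript_id": fs_id, "gene_id": gene, "cds_start": u5,
                         "annotated_stop_offset": fs_stop, "pair_id": pair, "role": "FS"})
        cds_rows.append({"transcript_id": as_id, "gene_id": gene, "cds_start": u5,
                         "annotated_stop_offset": as_stop_annot, "pair_id": pair, "role": "AS"})
        fs_utr3 = len(fs_seq) - (fs_stop + 3)
        as_utr3 = len(as_seq) - (ptc_offset + 3)
        truth_rows.append({"transcript_id": as_id, "pair_id": pair, "role": "AS",
                           "ptc_offset": ptc_offset, "utr3_extension": as_utr3 - fs_utr3})
        truth_rows.append({"transcript_id": fs_id, "pair_id": pair, "role": "FS",
                           "ptc_offset": -1, "utr3_extension": 0})

    cds = pd.DataFrame(cds_rows, columns=["transcript_id", "gene_id", "cds_start",
                                          "annotated_stop_offset", "pair_id", "role"])
    truth = SimTruth(transcripts=pd.DataFrame(
        truth_rows, columns=["transcript_id", "pair_id", "role", "ptc_offset",
                             "utr3_extension"]))
    return records, cds, truth


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def toy_junction_study() -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Hand-constructed 8-junction, 4v4 study exercising every SI filter.

    Gene A carries a clean reciprocal usage shift (both junctions survive);
    gene B has one surviving junction, one below the read floor and one whose
    SI falls short of the cutoff; gene C is unexpressed; gene D has a single
    junction (NI constantly 1, untestable).  Returns (counts, junction ->
    gene map, sample -> group map); groups are "wt" and "mut".
    """
    samples = [f"wt{i}" for i in range(1, 5)] + [f"mut{i}" for i in range(1, 5)]
    counts = pd.DataFrame(
        {
            "jA1": [80, 78, 82, 81, 19, 21, 20, 22],
            "jA2": [20, 22, 19, 21, 81, 79, 82, 80],
            "jB1": [20, 21, 19, 22, 168, 172, 170, 166],
            "jB2": [3, 2, 3, 3, 3, 3, 2, 3],
            "jB3": [100, 98, 103, 99, 118, 122, 120, 117],
            "jC1": [1, 1, 0, 1, 1, 0, 1, 1],
            "jC2": [1, 0, 1, 0, 0, 1, 1, 0],
            "jD1": [50, 52, 49, 51, 55, 53, 54, 52],
        },
        index=samples,
    ).T
    gene_of = {"jA1": "geneA", "jA2": "geneA", "jB1": "geneB", "jB2": "geneB",
               "jB3": "geneB", "jC1": "geneC", "jC2": "geneC", "jD1": "geneD"}
    groups = {s: ("mut" if s.startswith("mut") else "wt") for s in samples}
    return counts, gene_of, groups


# ---------------------------------------------------------------------------
# recovery scoring

def evaluate_recovery(detected, truth: SimTruth) -> dict:
    """Precision / recall / direction accuracy / empirical FDR of detected events.

    ``detected``: list of EventResult or a frame with event_id and direction
    columns.  Direction accuracy is computed over true positives; empty
    denominators yield NaN.
    """
    if isinstance(detected, pd.DataFrame):
        det_dir = dict(zip(detected["event_id"], detected["direction"]))
    else:
        det_dir = {r.event_id: r.direction for r in detected}
    true_dir = dict(zip(truth.events["event_id"], truth.events["direction"]))

    det_ids, true_ids = set(det_dir), set(true_dir)
    tp_ids = det_ids & true_ids
    n_det, n_true, n_tp = len(det_ids), len(true_ids), len(tp_ids)
    precision = n_tp / n_det if n_det else float("nan")
    recall = n_tp / n_true if n_true else float("nan")
    fdr = (n_det - n_tp) / n_det if n_det else float("nan")
    if tp_ids:
        dir_acc = sum(det_dir[e] == true_dir[e] for e in tp_ids) / n_tp
    else:
        dir_acc = float("nan")
    return {
        "n_detected": n_det,
        "n_true": n_true,
        "n_true_positive": n_tp,
        "precision": precision,
        "recall": recall,
        "direction_accuracy": dir_acc,
        "empirical_fdr": fdr,
    }
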