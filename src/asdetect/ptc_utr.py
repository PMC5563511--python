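"""In-silico translation: first-stop scanning and 3'UTR extension metrics.

Intron-retaining transcripts frequently carry an in-frame premature
termination codon (PTC) inside the retained intron, which both marks them as
nonsense-mediated-decay substrates and extends the 3'UTR.  This module scans
spliced sense-strand mRNA sequences codon-by-codon from the annotated start,
reports the first stop (standard nuclear code: TAA, TAG, TGA), flags it as a
PTC when it precedes the annotated stop, and measures the distance from the
first nucleotide after the stop codon to the transcript 3' end (the 3'UTR
length).  Cohorts of functionally-spliced (FS) / alternatively-spliced (AS)
transcript pairs are summarized by the medians of the two distance columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced sense-strand transcript with annotated CDS offsets (0-based)."""

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    annotated_stop_offset: int
    is_intron_retaining: bool = False
    retained_intron_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.transcript_id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if not (0 <= self.cds_start < self.annotated_stop_offset <= len(seq) - 3):
            raise ValueError(
                f"{self.transcript_id}: need cds_start < annotated_stop <= len-3 "
                f"({self.cds_start}, {self.annotated_stop_offset}, {len(seq)})"
            )


@dataclass(frozen=True)
class PtcReport:
    transcript_id: str
    first_stop_offset: int | None  # None: non-stop transcript
    is_ptc: bool
    stop_to_3prime_distance: int | None
    normal_stop_to_3prime_distance: int | None = None


def find_first_stop(transcript: TranscriptModel) -> tuple[int | None, bool]:
    """Scan codons from cds_start; return (offset of first stop, is_ptc).

    Codons containing N are skipped as non-stop.  A transcript with no
    in-frame stop returns (None, False): a "non-stop" transcript, reported
    rather than raised.
    """
    seq = transcript.sequence
    for off in range(transcript.cds_start, len(seq) - 2, 3):
        codon = seq[off:off + 3]
        if codon in STOP_CODONS:
            return off, off < transcript.annotated_stop_offset
    return None, False


def utr3_length(transcript: TranscriptModel, stop_offset: int | None) -> int | None:
    """Distance from the first nt after the stop codon to the transcript 3' end."""
    if stop_offset is None:
        return None
    return len(transcript.sequence) - (stop_offset + 3)


def utr3_metrics(fs: TranscriptModel, as_model: TranscriptModel) -> PtcReport:
    """Pair a functionally-spliced and an intron-retaining transcript.

    Returns the AS member's report with both 3'UTR distances: its own (from
    the first stop, typically a PTC) and the FS partner's (from the normal
    stop).
    """
    as_stop, as_is_ptc = find_first_stop(as_model)
    fs_stop, _ = find_first_stop(fs)
    return PtcReport(
        transcript_id=as_model.transcript_id,
        first_stop_offset=as_stop,
        is_ptc=as_is_ptc,
        stop_to_3prime_distance=utr3_length(as_model, as_stop),
        normal_stop_to_3prime_distance=utr3_length(fs, fs_stop),
    )


def cohort_utr_summary(reports: list[PtcReport], bins: int = 20) -> dict:
    """Median PTC-to-3'-end and normal-stop-to-3'-end distances plus a
    frequency-distribution table over both columns (shared bin edges)."""
    ptc_d = [r.stop_to_3prime_distance for r in reports if r.stop_to_3prime_distance is not None]
    normal_d = [r.normal_stop_to_3prime_distance for r in reports
                if r.normal_stop_to_3prime_distance is not None]
    if not ptc_d and not normal_d:
        import warnings

        warnings.warn("empty PTC cohort: no distances to summarize", stacklevel=2)
        return {"median_stop_to_3prime": None, "median_normal_stop_to_3prime": None,
                "histogram": pd.DataFrame(columns=["bin_left", "bin_right",
                                                   "n_ptc", "n_normal"])}
    all_d = np.array(ptc_d + normal_d, dtype=float)
    edges = np.histogram_bin_edges(all_d, bins=bins)
    n_ptc, _ = np.histogram(ptc_d, bins=edges)
    n_normal, _ = np.histogram(normal_d, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_ptc": n_ptc, "n_normal": n_normal}
    )
    return {
        "median_stop_to_3prime": float(np.median(ptc_d)) if ptc_d else None,
        "median_normal_stop_to_3prime": float(np.median(normal_d)) if normal_d else None,
        "histogram": hist,
    }


# ---------------------------------------------------------------------------
# file I/O

def read_transcripts(fasta_path, cds_table_path) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Load transcript models from FASTA plus a CDS table.

    CDS table columns: transcript_id, gene_id, cds_start,
    annotated_stop_offset, pair_id, role ("FS" or "AS").
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    cds = pd.read_csv(cds_table_path, sep="\t", comment="#")
    models = []
    for row in cds.itertuples():
        if row.transcript_id not in seqs:
            raise ValueError(f"transcript {row.transcript_id} absent from FASTA")
        models.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence=seqs[row.transcript_id],
                cds_start=int(row.cds_start),
                annotated_stop_offset=int(row.annotated_stop_offset),
                is_intron_retaining=(row.role == "AS"),
            )
        )
    return models, cds


def scan_pairs(models: list[TranscriptModel], cds: pd.DataFrame) -> list[PtcReport]:
    """Pair FS/AS transcripts by pair_id and run the 3'UTR comparison."""
    by_id = {m.transcript_id: m for m in models}
    reports = []
    for pair_id, sub in cds.groupby("pair_id"):
        roles = dict(zip(sub["role"], sub["transcript_id"]))
        if "FS" not in roles or "AS" not in roles:
            raise ValueError(f"pair {pair_id} needs one FS and one AS transcript")
        reports.append(utr3_metrics(by_id[roles["FS"]], by_id[roles["AS"]]))
    return reports


def reports_frame(reports: list[PtcReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "first_stop_offset": r.first_stop_offset,
                "is_ptc": r.is_ptc,
                "stop_to_3prime_distance": r.stop_to_3prime_distance,
                "normal_stop_to_3prime_distance": r.normal_stop_to_3prime_distance,
            }
            for r in reports
        ],
        columns=["transcript_id", "first_stop_offset", "is_ptc",
                 "stop_to_3prime_distance", "normal_stop_to_3prime_distance"],
    )
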