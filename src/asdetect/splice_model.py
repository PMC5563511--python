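"""Splice graphs of countable terms (exons, introns, junctions) and AS event definitions.

A gene is represented as a :class:`SpliceGraph` whose nodes are *terms*: the
features a short-read counter can assign reads to. Exons and introns are
genomic intervals; junctions are donor/acceptor pairs whose effective mapped
length is the junction-database segment length (default 80 nt), not the
spanned genomic distance.

Candidate alternative-splicing events are derived purely from annotated
structure: a cassette-exon event needs an internal exon with both flanking
junctions plus at least one annotated skipping junction; an intron-retention
event needs an intron with at least one junction excising it. No novel
junctions are invented from read data.

Coordinates are 0-based half-open internally; GTF/GFF3 I/O converts from and
to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pandas as pd

DEFAULT_JUNCTION_LENGTH = 80


class TermType(str, Enum):
    EXON = "exon"
    INTRON = "intron"
    JUNCTION = "junction"


class EventType(str, Enum):
    CASSETTE_EXON = "cassette_exon"
    INTRON_RETENTION = "intron_retention"


@dataclass(frozen=True)
class GenomicTerm:
    """One countable feature. ``length`` for junctions is the mapped segment length."""

    term_id: str
    gene_id: str
    term_type: TermType
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    length: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.term_id}: start must be < end ({self.start}, {self.end})")
        if self.length <= 0:
            raise ValueError(f"{self.term_id}: length must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.term_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class EventDefinition:
    """A candidate AS event: inclusion terms H_e, skipping terms S_e.

    For a cassette exon H_e is (upstream junction, exon, downstream junction)
    and S_e holds every junction skipping the exon.  For intron retention H_e
    is the intron alone and S_e the junction(s) excising it.  ``context_terms``
    are the flanking exons whose expression is required for the event to be
    evaluable at all.
    """

    event_id: str
    gene_id: str
    event_type: EventType
    inclusion_terms: tuple[str, ...]
    skipping_terms: tuple[str, ...]
    context_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        h, s = set(self.inclusion_terms), set(self.skipping_terms)
        if h & s:
            raise ValueError(f"{self.event_id}: inclusion and skipping sets overlap")
        if self.event_type is EventType.CASSETTE_EXON and len(self.inclusion_terms) != 3:
            raise ValueError(f"{self.event_id}: cassette events need 3 inclusion terms")
        if self.event_type is EventType.INTRON_RETENTION and len(self.inclusion_terms) != 1:
            raise ValueError(f"{self.event_id}: intron-retention events need 1 inclusion term")
        if len(self.skipping_terms) < 1:
            raise ValueError(f"{self.event_id}: at least one skipping term required")

    @property
    def n_terms(self) -> int:
        return len(self.inclusion_terms) + len(self.skipping_terms)


class SpliceGraph:
    """All terms of one gene, with exon/junction adjacency implied by coordinates."""

    def __init__(self, gene_id: str, chrom: str, strand: str):
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.terms: dict[str, GenomicTerm] = {}
        # transcript_id -> list of exon term_ids in genomic order
        self.transcripts: dict[str, list[str]] = {}

    def add_term(self, term: GenomicTerm) -> None:
        if term.gene_id != self.gene_id:
            raise ValueError(f"term {term.term_id} belongs to {term.gene_id}, not {self.gene_id}")
        self.terms[term.term_id] = term

    def terms_of_type(self, term_type: TermType) -> list[GenomicTerm]:
        out = [t for t in self.terms.values() if t.term_type is term_type]
        out.sort(key=lambda t: (t.start, t.end))
        return out

    @property
    def exons(self) -> list[GenomicTerm]:
        return self.terms_of_type(TermType.EXON)

    @property
    def introns(self) -> list[GenomicTerm]:
        return self.terms_of_type(TermType.INTRON)

    @property
    def junctions(self) -> list[GenomicTerm]:
        return self.terms_of_type(TermType.JUNCTION)

    def __len__(self) -> int:
        return len(self.terms)


def exon_id(gene_id: str, start: int, end: int) -> str:
    return f"{gene_id}:exon:{start}-{end}"


def intron_id(gene_id: str, start: int, end: int) -> str:
    return f"{gene_id}:intron:{start}-{end}"


def junction_id(gene_id: str, donor: int, acceptor: int) -> str:
    return f"{gene_id}:junc:{donor}-{acceptor}"


# ---------------------------------------------------------------------------
# annotation parsing

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


@dataclass(frozen=True)
class ExonRecord:
    """One exon line from an annotation, 0-based half-open."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str


def _parse_attributes(attr_field: str) -> dict[str, str]:
    if "=" in attr_field and '"' not in attr_field:
        return dict(_GFF3_ATTR.findall(attr_field))
    return dict(_GTF_ATTR.findall(attr_field))


def read_annotation(path) -> list[ExonRecord]:
    """Read exon features from a GTF or GFF3 file (1-based inclusive on disk)."""
    records: list[ExonRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2].lower() != "exon":
                continue
            attrs = _parse_attributes(fields[8])
            gene = attrs.get("gene_id") or attrs.get("gene")
            tx = attrs.get("transcript_id") or attrs.get("Parent")
            if gene is None or tx is None:
                raise ValueError(f"exon feature without gene/transcript attributes: {line!r}")
            records.append(
                ExonRecord(
                    gene_id=gene,
                    transcript_id=tx,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return records


def write_gtf(graphs: Iterable[SpliceGraph], path) -> None:
    """Write the transcript exon structure of each graph as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for graph in graphs:
            for tx_id in sorted(graph.transcripts):
                for ex_tid in graph.transcripts[tx_id]:
                    t = graph.terms[ex_tid]
                    attrs = f'gene_id "{graph.gene_id}"; transcript_id "{tx_id}";'
                    fh.write(
                        "\t".join(
                            [t.chrom, "asdetect", "exon", str(t.start + 1), str(t.end),
                             ".", t.strand, ".", attrs]
                        )
                        + "\n"
                    )


def write_junction_bed(graphs: Iterable[SpliceGraph], path) -> None:
    """BED6 of junction terms; name = gene_id|junction_id, score unused."""
    with open(path, "w") as fh:
        for graph in graphs:
            for j in graph.junctions:
                name = f"{graph.gene_id}|{j.term_id}"
                fh.write(
                    "\t".join([j.chrom, str(j.start), str(j.end), name, "0", j.strand]) + "\n"
                )


def read_junction_bed(path, gene_ids: bool = True) -> list[tuple[str, str, str, int, int, str]]:
    """Read a BED6 junction file back as (gene_id, junction_id, chrom, start, end, strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            gene, _, jid = name.partition("|")
            out.append((gene, jid, chrom, int(start), int(end), strand))
    return out


def term_metadata_frame(graphs: Iterable[SpliceGraph]) -> pd.DataFrame:
    """Flat TSV-ready table of every term across graphs."""
    rows = []
    for graph in graphs:
        for t in sorted(graph.terms.values(), key=lambda t: (t.start, t.end, t.term_id)):
            rows.append(
                {
                    "term_id": t.term_id,
                    "gene_id": t.gene_id,
                    "term_type": t.term_type.value,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "length": t.length,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["term_id", "gene_id", "term_type", "chrom", "start", "end", "strand", "length"],
    )


def write_term_metadata(graphs: Iterable[SpliceGraph], path) -> None:
    term_metadata_frame(graphs).to_csv(path, sep="\t", index=False)


def read_term_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"term_id", "gene_id", "term_type", "chrom", "start", "end", "strand", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"term metadata missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# graph construction

def build_splice_graphs(
    records: Sequence[ExonRecord],
    junction_length: int = DEFAULT_JUNCTION_LENGTH,
) -> dict[str, SpliceGraph]:
    """Build one splice graph per gene from exon records.

    Introns are the gaps between consecutive exons of each transcript;
    junctions are every exon-exon adjacency observed in any transcript
    (including exon-skipping adjacencies present in annotated isoforms),
    keyed by (donor, acceptor, strand).
    """
    by_gene: dict[str, list[ExonRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    graphs: dict[str, SpliceGraph] = {}
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        strands = {r.strand for r in recs}
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id} has exons on both strands")
        chroms = {r.chrom for r in recs}
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        strand, chrom = strands.pop(), chroms.pop()
        graph = SpliceGraph(gene_id, chrom, strand)

        by_tx: dict[str, list[ExonRecord]] = {}
        for r in recs:
            by_tx.setdefault(r.transcript_id, []).append(r)

        for tx_id in sorted(by_tx):
            exons = sorted(by_tx[tx_id], key=lambda r: (r.start, r.end))
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"transcript {tx_id}: overlapping exons "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
            tx_exon_ids = []
            for ex in exons:
                tid = exon_id(gene_id, ex.start, ex.end)
                if tid not in graph.terms:
                    graph.add_term(
                        GenomicTerm(tid, gene_id, TermType.EXON, chrom, ex.start, ex.end,
                                    strand, ex.end - ex.start)
                    )
                tx_exon_ids.append(tid)
            graph.transcripts[tx_id] = tx_exon_ids
            for a, b in zip(exons, exons[1:]):
                donor, acceptor = a.end, b.start
                jid = junction_id(gene_id, donor, acceptor)
                if jid not in graph.terms:
                    graph.add_term(
                        GenomicTerm(jid, gene_id, TermType.JUNCTION, chrom, donor, acceptor,
                                    strand, junction_length)
                    )

        # introns: gaps between consecutive exons of each transcript; a gap
        # containing another annotated exon is a skipped region, not an intron
        all_exons = graph.exons
        for tx_id, tx_exon_ids in graph.transcripts.items():
            exons = [graph.terms[tid] for tid in tx_exon_ids]
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    if any(e.start >= a.end and e.end <= b.start for e in all_exons):
                        continue
                    iid = intron_id(gene_id, a.end, b.start)
                    if iid not in graph.terms:
                        graph.add_term(
                            GenomicTerm(iid, gene_id, TermType.INTRON, chrom, a.end, b.start,
                                        strand, b.start - a.end)
                        )
        graphs[gene_id] = graph
    return graphs


def build_splice_graph(records: Sequence[ExonRecord]) -> SpliceGraph:
    """Single-gene convenience wrapper around :func:`build_splice_graphs`."""
    graphs = build_splice_graphs(records)
    if len(graphs) != 1:
        raise ValueError(f"expected exactly one gene, got {sorted(graphs)}")
    return next(iter(graphs.values()))


# ---------------------------------------------------------------------------
# event enumeration

def enumerate_events(
    graph: SpliceGraph,
    canonical_skip_only: bool = False,
) -> list[EventDefinition]:
    """Enumerate candidate cassette-exon and intron-retention events of one gene.

    Pure function of the graph; output is ordered by genomic coordinate.  When
    several junctions excise the same intron (alternate donors/acceptors) all
    of them enter the skipping set unless ``canonical_skip_only`` restricts the
    set to the junction matching the intron boundaries exactly.
    """
    events: list[EventDefinition] = []
    junctions = graph.junctions
    exons = graph.exons

    # cassette exons: internal exon with both flanking junctions and >=1 skip junction
    for ex in exons:
        up = [j for j in junctions if j.end == ex.start]
        down = [j for j in junctions if j.start == ex.end]
        if not up or not down:
            continue
        # nearest flanking junctions: shortest intron on each side
        up_j = max(up, key=lambda j: j.start)
        down_j = min(down, key=lambda j: j.end)
        skips = [
            j for j in junctions
            if j.start <= ex.start and j.end >= ex.end and j.start < ex.start and j.end > ex.end
        ]
        if not skips:
            continue
        context = tuple(
            e.term_id for e in exons if e.end == up_j.start or e.start == down_j.end
        )
        events.append(
            EventDefinition(
                event_id=f"{graph.gene_id}:CE:{ex.start}-{ex.end}",
                gene_id=graph.gene_id,
                event_type=EventType.CASSETTE_EXON,
                inclusion_terms=(up_j.term_id, ex.term_id, down_j.term_id),
                skipping_terms=tuple(j.term_id for j in sorted(skips, key=lambda j: (j.start, j.end))),
                context_terms=context,
            )
        )

    # intron retention: intron with >=1 junction spanning it
    for it in graph.introns:
        spanning = [j for j in junctions if j.start <= it.start and j.end >= it.end]
        if canonical_skip_only:
            spanning = [j for j in spanning if j.start == it.start and j.end == it.end]
        if not spanning:
            continue
        context = tuple(
            e.term_id for e in exons if e.end == it.start or e.start == it.end
        )
        events.append(
            EventDefinition(
                event_id=f"{graph.gene_id}:IR:{it.start}-{it.end}",
                gene_id=graph.gene_id,
                event_type=EventType.INTRON_RETENTION,
                inclusion_terms=(it.term_id,),
                skipping_terms=tuple(j.term_id for j in sorted(spanning, key=lambda j: (j.start, j.end))),
                context_terms=context,
            )
        )

    events.sort(key=lambda e: (e.event_id,))
    # stable coordinate order: parse start from the id suffix
    events.sort(key=lambda e: (int(e.event_id.rsplit(":", 1)[1].split("-")[0]), e.event_id))
    return events


def enumerate_all_events(
    graphs: dict[str, SpliceGraph], canonical_skip_only: bool = False
) -> list[EventDefinition]:
    out: list[EventDefinition] = []
    for gene_id in sorted(graphs):
        out.extend(enumerate_events(graphs[gene_id], canonical_skip_only=canonical_skip_only))
    return out
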