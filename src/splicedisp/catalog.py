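"""Splice-event catalog: donor/acceptor graph and acceptor mode labels.

An intron is a splice event joining a donor site (first intronic base, the
G of GT in canonical introns) to an acceptor site (last intronic base, the
G of AG).  Across the transcripts of an annotation the distinct donor and
acceptor sites form a bipartite graph; the pairing structure defines the
acceptor splicing mode:

* ``common``        one acceptor, one donor, both degree 1 (one-to-one);
* ``constitutive``  the acceptor pairs with several donors, each of
  degree 1 (one acceptor to many donors);
* ``alternative``   the acceptor has a single donor which itself pairs
  with several acceptors (many acceptors to one donor);
* ``ambiguous``     many-to-many pairings, excluded downstream.

Alternative acceptors are further placed relative to the reference
exon/intron model of their shared donor: at the annotated intron-exon
junction (``normal``), strictly inside an exon (``exonic``) or strictly
inside an intron (``intronic``).  The reference model is taken from the
transcripts supporting the donor's majority pairing; ties make the
acceptor ``unclassifiable`` and it is excluded.

All coordinates are 1-based genomic positions; sites are identified by the
intronic boundary coordinate, strand-normalized so "upstream" means 5' in
transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

import pandas as pd

MODES = ("common", "constitutive", "alternative", "ambiguous")
SUBMODES = ("normal", "exonic", "intronic", "not_applicable", "unclassifiable")

#: a site key: (chrom, strand, 1-based position of the intronic boundary base)
Site = Tuple[str, str, int]


class InvalidEventError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceEvent:
    """One intron: donor and acceptor boundary coordinates plus supporters."""

    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    transcript_ids: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if self.strand not in "+-":
            raise InvalidEventError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.donor_pos > self.acceptor_pos:
            raise InvalidEventError("plus-strand donor must lie left of acceptor")
        if self.strand == "-" and self.donor_pos < self.acceptor_pos:
            raise InvalidEventError("minus-strand donor must lie right of acceptor")

    @property
    def intron_length(self) -> int:
        """Intron span in bases, both boundary bases included."""
        return abs(self.acceptor_pos - self.donor_pos) + 1

    @property
    def donor_site(self) -> Site:
        return (self.chrom, self.strand, self.donor_pos)

    @property
    def acceptor_site(self) -> Site:
        return (self.chrom, self.strand, self.acceptor_pos)


@dataclass(frozen=True)
class ModeLabel:
    mode: str
    submode: str = "not_applicable"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.submode not in SUBMODES:
            raise ValueError(f"unknown submode {self.submode!r}")
        if self.submode in ("normal", "exonic", "intronic") and self.mode != "alternative":
            raise ValueError("positional submodes apply only to alternative acceptors")


@dataclass
class TranscriptModel:
    """Exon chain of one transcript; exons as 1-based inclusive intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def sorted_exons(self) -> List[Tuple[int, int]]:
        return sorted(self.exons)

    def introns(self) -> List[Tuple[int, int]]:
        """Genomic intervals between consecutive exons, ascending."""
        ex = self.sorted_exons()
        return [(ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1)]

    def events(self) -> List[SpliceEvent]:
        out = []
        for s, e in self.introns():
            if e < s:
                raise InvalidEventError(
                    f"zero-length intron between exons of {self.transcript_id}"
                )
            donor, acceptor = (s, e) if self.strand == "+" else (e, s)
            out.append(
                SpliceEvent(self.chrom, self.strand, donor, acceptor,
                            frozenset({self.transcript_id}))
            )
        return out


class SpliceGraph:
    """Bipartite adjacency between distinct donor and acceptor sites."""

    def __init__(self):
        self.donor_to_acceptors: Dict[Site, set] = {}
        self.acceptor_to_donors: Dict[Site, set] = {}
        self.support: Dict[Tuple[Site, Site], set] = {}

    def add_event(self, event: SpliceEvent) -> None:
        d, a = event.donor_site, event.acceptor_site
        self.donor_to_acceptors.setdefault(d, set()).add(a)
        self.acceptor_to_donors.setdefault(a, set()).add(d)
        self.support.setdefault((d, a), set()).update(event.transcript_ids)

    def donor_degree(self, donor: Site) -> int:
        return len(self.donor_to_acceptors[donor])

    def acceptor_degree(self, acceptor: Site) -> int:
        return len(self.acceptor_to_donors[acceptor])

    @property
    def acceptors(self) -> List[Site]:
        return sorted(self.acceptor_to_donors)


def build_splice_graph(events: Iterable[SpliceEvent]) -> SpliceGraph:
    """Deduplicate events into a bipartite splice graph.

    Duplicate (donor, acceptor) pairs collapse to a single edge whose
    supporting transcript sets are merged.
    """
    graph = SpliceGraph()
    n = 0
    for ev in events:
        graph.add_event(ev)
        n += 1
    if n == 0:
        raise InvalidEventError("no splice events supplied")
    return graph


def classify_acceptor_mode(graph: SpliceGraph, acceptor: Site) -> ModeLabel:
    """Assign common/constitutive/alternative/ambiguous from pairing degrees."""
    if acceptor not in graph.acceptor_to_donors:
        raise KeyError(f"acceptor {acceptor} not in graph")
    donors = graph.acceptor_to_donors[acceptor]
    donor_degrees = [graph.donor_degree(d) for d in donors]
    if len(donors) == 1:
        mode = "common" if donor_degrees[0] == 1 else "alternative"
    else:
        mode = "constitutive" if all(deg == 1 for deg in donor_degrees) else "ambiguous"
    return ModeLabel(mode=mode)


def _locate_in_model(model: TranscriptModel, pos: int) -> str:
    """Place a position in a transcript model.

    Returns 'junction' (an intron's acceptor-side boundary base), 'intron',
    'exon', or 'outside' the transcript span.
    """
    ex = model.sorted_exons()
    span = (ex[0][0], ex[-1][1])
    if not span[0] <= pos <= span[1]:
        return "outside"
    for s, e in model.introns():
        junction = e if model.strand == "+" else s
        if pos == junction:
            return "junction"
        if s <= pos <= e:
            return "intron"
    for s, e in ex:
        if s <= pos <= e:
            return "exon"
    return "outside"


def classify_alternative_submode(
    graph: SpliceGraph, acceptor: Site, models: Mapping[str, TranscriptModel]
) -> str:
    """Sub-mode of an alternative acceptor relative to its donor's reference model.

    The reference pairing of the shared donor is the acceptor with the most
    supporting transcripts.  The query acceptor is 'normal' when it is that
    reference junction itself (or falls on a junction of a reference
    transcript), 'exonic'/'intronic' when strictly inside a reference exon
    or intron, and 'unclassifiable' when the reference is tied or the
    reference transcripts disagree.
    """
    (donor,) = graph.acceptor_to_donors[acceptor]
    pairs = [(a, graph.support[(donor, a)]) for a in graph.donor_to_acceptors[donor]]
    best = max(len(txs) for _, txs in pairs)
    majority = [a for a, txs in pairs if len(txs) == best]
    if len(majority) != 1:
        return "unclassifiable"
    a_ref = majority[0]
    if acceptor == a_ref:
        return "normal"
    categories = set()
    for tx in sorted(graph.support[(donor, a_ref)]):
        if tx not in models:
            return "unclassifiable"
        categories.add(_locate_in_model(models[tx], acceptor[2]))
    if categories == {"junction"}:
        return "normal"
    if categories == {"exon"}:
        return "exonic"
    if categories == {"intron"}:
        return "intronic"
    return "unclassifiable"


def read_transcript_exons(gtf_path) -> Dict[str, TranscriptModel]:
    """Exon chains per transcript_id from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: Dict[str, TranscriptModel] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        model = models.setdefault(tid, TranscriptModel(tid, ex.seqid, ex.strand))
        if (model.chrom, model.strand) != (ex.seqid, ex.strand):
            raise InvalidEventError(f"transcript {tid} mixes contigs or strands")
        model.exons.append((ex.start, ex.end))
    return models


def infer_events(models: Mapping[str, TranscriptModel]) -> List[SpliceEvent]:
    """All introns of all transcripts as splice events (not deduplicated)."""
    events: List[SpliceEvent] = []
    for tid in sorted(models):
        events.extend(models[tid].events())
    return events


def classify_acceptors(
    events: Iterable[SpliceEvent],
    models: Mapping[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Mode/submode table for every distinct acceptor site.

    Columns: chrom, strand, acceptor_pos, mode, submode, n_donors,
    donor_positions (comma-joined, sorted).
    """
    graph = build_splice_graph(events)
    rows = []
    for acceptor in graph.acceptors:
        label = classify_acceptor_mode(graph, acceptor)
        submode = label.submode
        if label.mode == "alternative":
            submode = (
                classify_alternative_submode(graph, acceptor, models)
                if models is not None
                else "unclassifiable"
            )
        donors = sorted(d[2] for d in graph.acceptor_to_donors[acceptor])
        rows.append(
            {
                "chrom": acceptor[0],
                "strand": acceptor[1],
                "acceptor_pos": acceptor[2],
                "mode": label.mode,
                "submode": submode,
                "n_donors": len(donors),
                "donor_positions": ",".join(str(d) for d in donors),
            }
        )
    return pd.DataFrame(rows)


def events_frame(events: Iterable[SpliceEvent], catalog: pd.DataFrame) -> pd.DataFrame:
    """Event-level table joining each deduplicated event to its acceptor's mode."""
    graph = build_splice_graph(events)
    modes = {
        (r.chrom, r.strand, r.acceptor_pos): (r.mode, r.submode)
        for r in catalog.itertuples()
    }
    rows = []
    for (d, a), txs in sorted(graph.support.items()):
        mode, submode = modes[a]
        rows.append(
            {
                "chrom": d[0],
                "strand": d[1],
                "donor_pos": d[2],
                "acceptor_pos": a[2],
                "mode": mode,
                "submode": submode,
                "n_transcripts": len(txs),
                "transcript_ids": ",".join(sorted(txs)),
            }
        )
    return pd.DataFrame(rows)


def catalog_to_bed(catalog: pd.DataFrame) -> pd.DataFrame:
    """BED6 of acceptor sites (0-based half-open; name = mode.submode)."""
    return pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["acceptor_pos"] - 1,
            "end": catalog["acceptor_pos"],
            "name": catalog["mode"] + "." + catalog["submode"],
            "score": 0,
            "strand": catalog["strand"],
        }
    )
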