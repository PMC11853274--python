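"""Aligned 100-base acceptor windows and the 100-bp exclusion filters.

Windows are centered on the splice junction: 50 bases of intron (ending in
the canonical AG) and 50 bases of exon, in transcription orientation.
Positions carry zero-skipping site labels -50..-1, +1..+50: the junction
lies between labels -1 and +1, and the canonical A and G sit at labels -2
and -1.  ``label_to_offset``/``offset_to_label`` map between labels and
0-based string offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .catalog import SpliceEvent

WINDOW_LENGTH = 100
FLANK = 50
#: minimum intron span (bases, boundary bases included) for a retained event
MIN_INTRON_SPAN = 100
#: minimum separation between alternative acceptors sharing a donor
MIN_ALT_SEPARATION = 100

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InvalidCoordinateError(ValueError):
    pass


class BoundaryError(ValueError):
    pass


class AmbiguousBaseError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def label_to_offset(label: int) -> int:
    """Zero-skipping site label -> 0-based window offset (-50 -> 0, +1 -> 50)."""
    if -FLANK <= label <= -1:
        return label + FLANK
    if 1 <= label <= FLANK:
        return label + FLANK - 1
    raise InvalidCoordinateError(f"site label must be in [-50,-1] or [+1,+50], got {label}")


def offset_to_label(offset: int) -> int:
    """0-based window offset -> zero-skipping site label."""
    if not 0 <= offset < WINDOW_LENGTH:
        raise InvalidCoordinateError(f"offset must be in [0, {WINDOW_LENGTH}), got {offset}")
    return offset - FLANK if offset < FLANK else offset - FLANK + 1


def window_site_labels() -> List[int]:
    """The 100 base labels -50..-1, +1..+50 in window order."""
    return [offset_to_label(o) for o in range(WINDOW_LENGTH)]


@dataclass(frozen=True)
class AcceptorWindow:
    """A 100-base acceptor window in transcription orientation."""

    sequence: str
    mode: str = "common"
    submode: str = "not_applicable"
    event_id: str = ""
    chrom: str = ""
    strand: str = "+"
    acceptor_pos: int = 0

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(f"window must be {WINDOW_LENGTH} bases, got {len(self.sequence)}")

    @property
    def canonical_ag(self) -> bool:
        """True when the bases at labels -2/-1 are the canonical A and G."""
        return self.sequence[48:50] == "AG"

    def base_at(self, label: int) -> str:
        return self.sequence[label_to_offset(label)]


def _contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta or a plain str mapping."""
    if hasattr(genome, "get_seq"):
        return str(genome.get_seq(chrom, start, end))
    return genome[chrom][start - 1 : end]


def extract_window(
    genome,
    chrom: str,
    strand: str,
    acceptor_pos: int,
    mode: str = "common",
    submode: str = "not_applicable",
    event_id: str = "",
    reject_n: bool = True,
) -> AcceptorWindow:
    """Extract the 100-base window around an acceptor site.

    ``acceptor_pos`` is the 1-based genomic coordinate of the last intronic
    base (the G of AG).  Minus-strand windows are reverse-complemented so
    the returned sequence reads in transcription orientation with the
    junction between offsets 49 and 50.
    """
    try:
        contig_len = _contig_length(genome, chrom)
    except KeyError:
        raise KeyError(f"contig {chrom!r} not found in genome") from None
    if strand == "+":
        start, end = acceptor_pos - FLANK + 1, acceptor_pos + FLANK
    elif strand == "-":
        start, end = acceptor_pos - FLANK, acceptor_pos + FLANK - 1
    else:
        raise InvalidCoordinateError(f"strand must be + or -, got {strand!r}")
    if start < 1 or end > contig_len:
        raise BoundaryError(
            f"window [{start}, {end}] overruns contig {chrom} (length {contig_len})"
        )
    seq = _fetch(genome, chrom, start, end).upper()
    if strand == "-":
        seq = reverse_complement(seq)
    if "N" in seq and reject_n:
        raise AmbiguousBaseError(f"window at {chrom}:{acceptor_pos} contains N")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AmbiguousBaseError(f"non-ACGTN characters {bad} in window at {chrom}:{acceptor_pos}")
    return AcceptorWindow(
        sequence=seq,
        mode=mode,
        submode=submode,
        event_id=event_id or f"{chrom}:{strand}:{acceptor_pos}",
        chrom=chrom,
        strand=strand,
        acceptor_pos=acceptor_pos,
    )


def filter_events(
    events: pd.DataFrame,
    min_intron_span: int = MIN_INTRON_SPAN,
    min_alt_separation: int = MIN_ALT_SEPARATION,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the 100-bp exclusion filters to an event-level table.

    Two rules, both strict inequalities:

    * ``short_intron``: the intron span (|acceptor - donor| + 1 bases) is
      below ``min_intron_span``;
    * ``alt_proximity``: within the group of alternative acceptors sharing
      one donor, any two acceptors closer than ``min_alt_separation``
      are both removed.

    Returns (retained events, rejection log).  The rejection log has one
    row per (event, reason).
    """
    events = events.reset_index(drop=True)
    span = (events["acceptor_pos"] - events["donor_pos"]).abs() + 1
    reject_rows = []
    rejected = pd.Series(False, index=events.index)

    for i in events.index[span < min_intron_span]:
        rejected[i] = True
        reject_rows.append({**events.loc[i].to_dict(), "reason": "short_intron"})

    alt = events[events["mode"] == "alternative"]
    for (_, _, _), grp in alt.groupby(["chrom", "strand", "donor_pos"]):
        pos = grp["acceptor_pos"].to_numpy()
        bad = set()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(pos[i]) - int(pos[j])) < min_alt_separation:
                    bad.add(grp.index[i])
                    bad.add(grp.index[j])
        for i in sorted(bad):
            if not rejected[i]:
                rejected[i] = True
            reject_rows.append({**events.loc[i].to_dict(), "reason": "alt_proximity"})

    retained = events[~rejected].reset_index(drop=True)
    log_cols = list(events.columns) + ["reason"]
    log = pd.DataFrame(reject_rows, columns=log_cols)
    return retained, log


def extract_windows(
    genome,
    retained_events: pd.DataFrame,
    reject_n: bool = True,
    canonical_only: bool = True,
) -> Tuple[List[AcceptorWindow], pd.DataFrame]:
    """One window per distinct retained acceptor, with a rejection log.

    Ambiguous-mode and unclassifiable acceptors are skipped; windows that
    overrun a contig, contain N (when ``reject_n``) or lack the canonical
    AG (when ``canonical_only``) are logged and dropped.
    """
    windows: List[AcceptorWindow] = []
    reject_rows = []
    seen = set()
    for row in retained_events.itertuples():
        key = (row.chrom, row.strand, row.acceptor_pos)
        if key in seen:
            continue
        seen.add(key)
        reason = None
        if row.mode == "ambiguous":
            reason = "ambiguous_mode"
        elif row.mode == "alternative" and row.submode == "unclassifiable":
            reason = "unclassifiable_submode"
        if reason is None:
            try:
                win = extract_window(
                    genome, row.chrom, row.strand, row.acceptor_pos,
                    mode=row.mode, submode=row.submode, reject_n=reject_n,
                )
                if canonical_only and not win.canonical_ag:
                    reason = "non_canonical"
                else:
                    windows.append(win)
            except BoundaryError:
                reason = "contig_boundary"
            except AmbiguousBaseError:
                reason = "ambiguous_base"
        if reason is not None:
            reject_rows.append(
                {"chrom": row.chrom, "strand": row.strand,
                 "acceptor_pos": row.acceptor_pos, "mode": row.mode,
                 "submode": row.submode, "reason": reason}
            )
    log = pd.DataFrame(
        reject_rows,
        columns=["chrom", "strand", "acceptor_pos", "mode", "submode", "reason"],
    )
    return windows, log


def windows_to_fasta(windows: Iterable[AcceptorWindow], path) -> None:
    """Write windows as FASTA; header = event_id|mode|submode (no spaces)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.event_id}|{w.mode}|{w.submode}\n{w.sequence}\n")


def read_windows_fasta(path) -> List[AcceptorWindow]:
    """Read windows written by :func:`windows_to_fasta`."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    out = []
    for name in fa.keys():
        parts = name.split("|")
        event_id = parts[0]
        mode = parts[1] if len(parts) > 1 else "common"
        submode = parts[2] if len(parts) > 2 else "not_applicable"
        out.append(
            AcceptorWindow(sequence=str(fa[name][:]), mode=mode,
                           submode=submode, event_id=event_id)
        )
    return out


def windows_to_frame(windows: Iterable[AcceptorWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": w.event_id,
                "chrom": w.chrom,
                "strand": w.strand,
                "acceptor_pos": w.acceptor_pos,
                "mode": w.mode,
                "submode": w.submode,
                "canonical_ag": w.canonical_ag,
                "sequence": w.sequence,
            }
            for w in windows
        ]
    )
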