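"""Indel event calling and substitution divergence from repeat–master alignments.

Under the star-phylogeny assumption each repeat copy diverged independently
from its subfamily master sequence, so a maximal gap run in the master string
records an insertion in the copy, and a maximal gap run in the copy string
records a deletion. Terminal gap runs are never counted as events: repeat
copies (LINEs in particular) are very often 5'-truncated on arrival and the
alignments are local, so gaps touching an alignment end reflect truncation,
not indel mutation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, TextIO

from .io import RepeatAlignment

_GAP_RUN = re.compile(r"-+")

SIZE_CLASSES = ("small", "intermediate", "long")


class MalformedAlignmentError(ValueError):
    pass


class SaturationError(ValueError):
    """Divergence too high for the requested distance correction."""


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion inferred from one gap run.

    ``master_pos`` is the consensus coordinate of the first master base after
    (insertion) or under (deletion) the run, which makes recurrent events —
    the same mutation observed in several copies because the star phylogeny
    is violated — collapsible across copies.
    """

    kind: str  # 'insertion' | 'deletion'
    length: int
    master_pos: int
    copy_id: str
    subfamily: str
    inserted_seq: str = ""

    @property
    def size_class(self) -> str:
        return classify_event_size(self)


def classify_event_size(event: IndelEvent | int) -> str:
    """Size class of an indel: small (1–2 bp), intermediate (3–20), long (>20)."""
    length = event if isinstance(event, int) else event.length
    if length < 1:
        raise ValueError("indel length must be >= 1")
    if length <= 2:
        return "small"
    if length <= 20:
        return "intermediate"
    return "long"


def call_indels(aln: RepeatAlignment) -> list[IndelEvent]:
    """Extract insertion and deletion events from one alignment.

    A maximal run of '-' in the master string is one insertion (sequence =
    the copy bases over the run); a maximal run in the copy string is one
    deletion. Runs touching either end of the alignment are skipped.
    """
    master, copy = aln.master_aln, aln.copy_aln
    n = len(master)
    events: list[IndelEvent] = []

    runs = [("insertion", m) for m in _GAP_RUN.finditer(master)]
    runs += [("deletion", m) for m in _GAP_RUN.finditer(copy)]
    runs.sort(key=lambda km: km[1].start())

    # master-base count before a column, accumulated across sorted runs
    m_bases = 0
    cursor = 0
    for kind, m in runs:
        s, e = m.start(), m.end()
        seg = master[cursor:s]
        m_bases += len(seg) - seg.count("-")
        pos = m_bases  # consensus-relative coordinate at the run's left edge
        run_seg = master[s:e]
        m_bases += len(run_seg) - run_seg.count("-")
        cursor = e
        other = copy if kind == "insertion" else master
        if "-" in other[s:e]:
            raise MalformedAlignmentError(
                f"{aln.copy_id}: column gapped in both sequences near column {s}"
            )
        if s == 0 or e == n:
            continue  # terminal truncation, not an event
        if kind == "insertion":
            events.append(
                IndelEvent(
                    kind="insertion",
                    length=e - s,
                    master_pos=aln.m_start + pos,
                    copy_id=aln.copy_id,
                    subfamily=aln.subfamily,
                    inserted_seq=copy[s:e],
                )
            )
        else:
            events.append(
                IndelEvent(
                    kind="deletion",
                    length=e - s,
                    master_pos=aln.m_start + pos,
                    copy_id=aln.copy_id,
                    subfamily=aln.subfamily,
                )
            )
    return events


@dataclass(frozen=True)
class DivergenceEstimate:
    p_distance: float
    distance: float
    sites: int
    model: str


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def substitution_divergence(
    aln: RepeatAlignment, model: str = "JC69"
) -> DivergenceEstimate:
    """Substitution divergence of a copy from its master.

    Gap columns and columns with ambiguous bases are excluded from both
    numerator and denominator. ``model`` is one of 'p' (raw proportion),
    'JC69' (−3/4·ln(1−4p/3)) or 'K2P' (transition/transversion split).
    """
    sites = transitions = transversions = 0
    for m, c in zip(aln.master_aln, aln.copy_aln):
        if m == "-" or c == "-":
            continue
        m, c = m.upper(), c.upper()
        if m not in "ACGT" or c not in "ACGT":
            continue
        sites += 1
        if m == c:
            continue
        if (m in _PURINES) == (c in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise MalformedAlignmentError(f"{aln.copy_id}: no ungapped aligned columns")
    p = (transitions + transversions) / sites
    if model == "p":
        d = p
    elif model == "JC69":
        if p >= 0.75:
            raise SaturationError(f"p-distance {p:.3f} >= 0.75; JC69 undefined")
        d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    elif model == "K2P":
        P, Q = transitions / sites, transversions / sites
        inner1 = 1.0 - 2.0 * P - Q
        inner2 = 1.0 - 2.0 * Q
        if inner1 <= 0 or inner2 <= 0:
            raise SaturationError("K2P distance undefined at this divergence")
        d = -0.5 * math.log(inner1 * math.sqrt(inner2))
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    return DivergenceEstimate(p_distance=p, distance=d, sites=sites, model=model)


def _event_key(e: IndelEvent) -> tuple:
    return (
        e.subfamily,
        e.kind,
        e.master_pos,
        e.length,
        e.inserted_seq if e.kind == "insertion" else "",
    )


def collapse_recurrent_events(events: Iterable[IndelEvent]) -> list[IndelEvent]:
    """Keep only events seen exactly once across copies of a subfamily.

    Events are grouped by (subfamily, kind, master position, length, and for
    insertions the inserted sequence); any group with multiplicity > 1 is
    interpreted as one ancestral mutation inherited by several copies — a
    star-phylogeny violation — and removed entirely.
    """
    counts: dict[tuple, int] = {}
    for e in events:
        counts[_event_key(e)] = counts.get(_event_key(e), 0) + 1
    return [e for e in events if counts[_event_key(e)] == 1]


def write_events(events: Iterable[IndelEvent], stream: TextIO) -> None:
    """One row per event, deterministic column order."""
    stream.write(
        "copy_id\tsubfamily\tkind\tlength\tmaster_pos\tsize_class\tinserted_seq\n"
    )
    for e in events:
        stream.write(
            f"{e.copy_id}\t{e.subfamily}\t{e.kind}\t{e.length}\t"
            f"{e.master_pos}\t{e.size_class}\t{e.inserted_seq}\n"
        )
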