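"""Relative subfamily activity times from nested insertions.

When a young element inserts into an older one it splits the host into two
genomic fragments that flank it. Counting who-hosts-whom across subfamilies
therefore orders subfamilies in time: if copies of subfamily B are found
nested within copies of subfamily A but not vice versa, A was active before
B. The per-subfamily relative activity time t_i (in (0,1); low t_i = old)
is estimated as a Laplace-smoothed fraction of nesting involvements in which
the subfamily was the younger (nested) partner. Only the rank order of t_i
is consumed downstream, where it normalizes window divergence for uneven
subfamily age composition across the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .io import RepeatAlignment


@dataclass(frozen=True)
class SubfamilyActivity:
    subfamily: str
    t_i: float  # relative activity time in (0,1); larger = more recent
    n_host: int  # times this subfamily hosted a nested element
    n_nested: int  # times this subfamily was the nested element


def detect_nesting(alignments: Iterable[RepeatAlignment]) -> pd.DataFrame:
    """Count nested insertions: N.loc[host, nested] increments when two
    fragments of one host copy flank, adjacently in the genome, an element
    of another subfamily lying strictly between them.
    """
    alns = sorted(alignments, key=lambda a: (a.chromosome, a.g_start))
    subfams = sorted({a.subfamily for a in alns})
    N = pd.DataFrame(0, index=subfams, columns=subfams, dtype=int)
    for e1, e2, e3 in zip(alns, alns[1:], alns[2:]):
        if e1.chromosome != e3.chromosome:
            continue
        if e1.copy_id != e3.copy_id or e1.subfamily != e3.subfamily:
            continue
        if e2.copy_id == e1.copy_id:
            continue
        if e1.g_end <= e2.g_start and e2.g_end <= e3.g_start:
            N.loc[e1.subfamily, e2.subfamily] += 1
    return N


def activity_times(N: pd.DataFrame) -> tuple[list[SubfamilyActivity], float]:
    """Relative activity times from a nesting count matrix.

    t_i = (n_nested_i + 1) / (n_nested_i + n_host_i + 2): the smoothed
    fraction of a subfamily's nesting involvements in which it was the
    younger partner. Returns the per-subfamily records and the genome mean
    t̄ (unweighted over subfamilies).
    """
    if N.shape[0] == 0 or N.shape[0] != N.shape[1]:
        raise ValueError("nesting matrix must be square with >= 1 subfamily")
    hosts = N.sum(axis=1)
    nested = N.sum(axis=0)
    activities = []
    for sf in N.index:
        h, d = int(hosts[sf]), int(nested[sf])
        activities.append(
            SubfamilyActivity(sf, t_i=(d + 1) / (d + h + 2), n_host=h, n_nested=d)
        )
    t_bar = sum(a.t_i for a in activities) / len(activities)
    return activities, t_bar


def normalization_factor(
    window_subfamilies: Sequence[str],
    activities: Iterable[SubfamilyActivity] | dict[str, float],
    t_bar: float,
) -> float:
    """Window divergence normalization factor t̄_window / t̄.

    ``window_subfamilies`` lists the subfamily of every element in the
    window (one entry per element). Multiplying a window's raw divergence by
    this factor is the identity when the window's age composition matches
    the genome and scales divergence linearly with relative recency.
    """
    if not window_subfamilies:
        raise ValueError("window has no elements; normalization undefined")
    if not isinstance(activities, dict):
        activities = {a.subfamily: a.t_i for a in activities}
    try:
        t_window = sum(activities[sf] for sf in window_subfamilies) / len(
            window_subfamilies
        )
    except KeyError as exc:
        raise KeyError(f"no activity time for subfamily {exc.args[0]!r}") from None
    return t_window / t_bar


def write_activity_table(
    activities: Iterable[SubfamilyActivity], stream: TextIO
) -> None:
    stream.write("subfamily\tt_i\tn_host\tn_nested\n")
    for a in sorted(activities, key=lambda a: a.subfamily):
        stream.write(f"{a.subfamily}\t{a.t_i:.6g}\t{a.n_host}\t{a.n_nested}\n")
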