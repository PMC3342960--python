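"""Lineage-specific indel rates and exponential decay of genome size.

Ancestral repeats shared by a focal species, a sister species and an
outgroup let every substitution and gap run be assigned to a branch by
parsimony: a gap specific to the focal sequence where sister and outgroup
retain bases is a focal-branch deletion, focal-specific bases where the
other two agree in gaps are a focal-branch insertion, and a focal base that
differs from an identical sister/outgroup base is a focal substitution.

With deletion rate D, insertion rate I and substitution rate S per branch,
net loss per substitution is (D − I)/S, and modeling neutral sequence
length as f(t) = exp(−r t) on a divergence time axis (t in substitutions
per site) forces r = −ln(1 − (D − I))/S: after one branch of its own
divergence S the remaining fraction is exactly 1 − (D − I). The cumulative
fraction of DNA lost over divergence t is then 1 − exp(−r t).

Uncertainty comes from a nonparametric bootstrap over ancestral repeats.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GAP_RUN = re.compile(r"-+")


@dataclass
class TripleRepeatAlignment:
    """One ancestral repeat aligned across focal, sister and outgroup."""

    repeat_id: str
    window_id: str
    focal: str
    sister: str
    outgroup: str

    def __post_init__(self) -> None:
        if not (len(self.focal) == len(self.sister) == len(self.outgroup)):
            raise ValueError(f"{self.repeat_id}: unequal gapped lengths")
        for f, s, o in zip(self.focal, self.sister, self.outgroup):
            if f == s == o == "-":
                raise ValueError(f"{self.repeat_id}: all-gap column")

    @property
    def length(self) -> int:
        return len(self.focal)


@dataclass
class DecayParams:
    deletion_rate: float  # D: bp deleted per ancestral bp on the focal branch
    insertion_rate: float  # I
    substitution_rate: float  # S: per site on the focal branch
    loss_per_substitution: float
    decay_rate: float  # r
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# IO (multi-FASTA, three records per repeat: id|window|role)
# ---------------------------------------------------------------------------


def read_triples(stream: TextIO) -> list[TripleRepeatAlignment]:
    by_repeat: dict[str, dict[str, str]] = {}
    windows: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(stream, "fasta"):
        try:
            repeat_id, window_id, role = rec.id.split("|")
        except ValueError:
            raise ValueError(f"triple record id {rec.id!r} is not 'repeat|window|role'")
        if repeat_id not in by_repeat:
            order.append(repeat_id)
        by_repeat.setdefault(repeat_id, {})[role] = str(rec.seq)
        windows[repeat_id] = window_id
    triples = []
    for rid in order:
        seqs = by_repeat[rid]
        missing = {"focal", "sister", "outgroup"} - set(seqs)
        if missing:
            raise ValueError(f"repeat {rid!r} missing roles: {sorted(missing)}")
        triples.append(
            TripleRepeatAlignment(
                rid, windows[rid], seqs["focal"], seqs["sister"], seqs["outgroup"]
            )
        )
    return triples


def write_triples(triples: Iterable[TripleRepeatAlignment], stream: TextIO) -> None:
    records = []
    for t in triples:
        for role, seq in (
            ("focal", t.focal),
            ("sister", t.sister),
            ("outgroup", t.outgroup),
        ):
            records.append(
                SeqRecord(Seq(seq), id=f"{t.repeat_id}|{t.window_id}|{role}", description="")
            )
    SeqIO.write(records, stream, "fasta")


# ---------------------------------------------------------------------------
# filtering and parsimony counting
# ---------------------------------------------------------------------------


def filter_triples(
    triples: Iterable[TripleRepeatAlignment], min_fraction: float = 0.8
) -> list[TripleRepeatAlignment]:
    """Keep triples whose sister AND outgroup ungapped lengths are at least
    ``min_fraction`` of the alignment length (boundary kept). Shorter
    flanking sequences indicate spurious non-repeat sequence in the block.
    """
    out = []
    for t in triples:
        s_len = len(t.sister) - t.sister.count("-")
        o_len = len(t.outgroup) - t.outgroup.count("-")
        if s_len >= min_fraction * t.length and o_len >= min_fraction * t.length:
            out.append(t)
    return out


@dataclass(frozen=True)
class _TripleCounts:
    deleted_bp: int
    inserted_bp: int
    substitutions: int
    substitution_sites: int  # three-way ungapped columns minus unassignable ones
    ancestral_sites: int  # columns where sister and outgroup both have bases


def _branch_events(
    target: str, other1: str, other2: str
) -> tuple[int, int]:
    """(deleted bp, inserted bp) on the target branch by majority-rule runs."""
    deleted = 0
    # target-specific gaps: runs of '-' in target, supported where both others
    # have bases; the whole run counts if supported at a strict majority of
    # its columns (ties excluded)
    for m in _GAP_RUN.finditer(target):
        s, e = m.span()
        support = sum(
            1 for a, b in zip(other1[s:e], other2[s:e]) if a != "-" and b != "-"
        )
        if 2 * support > (e - s):
            deleted += e - s
    # target-specific bases: runs of columns where at least one other is
    # gapped and target is not; supported where BOTH others are gapped
    inserted = 0
    run_start = None
    for i, (t, a, b) in enumerate(zip(target, other1, other2)):
        in_run = t != "-" and (a == "-" or b == "-")
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            inserted += _ins_run(target, other1, other2, run_start, i)
            run_start = None
    if run_start is not None:
        inserted += _ins_run(target, other1, other2, run_start, len(target))
    return deleted, inserted


def _ins_run(target: str, other1: str, other2: str, s: int, e: int) -> int:
    support = sum(1 for a, b in zip(other1[s:e], other2[s:e]) if a == "-" and b == "-")
    return e - s if 2 * support > (e - s) else 0


def _count_triple(t: TripleRepeatAlignment) -> _TripleCounts:
    deleted, inserted = _branch_events(t.focal, t.sister, t.outgroup)
    subs = 0
    sites = 0
    for f, s, o in zip(t.focal, t.sister, t.outgroup):
        if f == "-" or s == "-" or o == "-":
            continue
        if f == s == o:
            sites += 1
        elif s == o:  # focal-branch substitution
            subs += 1
            sites += 1
        elif f == s or f == o:  # sister- or outgroup-branch substitution
            sites += 1
        # all three differ: no parsimonious single-branch assignment; excluded
    ancestral = sum(1 for s, o in zip(t.sister, t.outgroup) if s != "-" and o != "-")
    return _TripleCounts(deleted, inserted, subs, sites, ancestral)


def lineage_rates(
    triples: Sequence[TripleRepeatAlignment], by_window: bool = True
) -> DecayParams:
    """Focal-branch D, I, S pooled genome-wide.

    Triples are concatenated within windows and window estimates are
    combined as a weighted mean with the per-window denominators as
    weights — algebraically the pooled ratio of summed counts, so the
    estimate is invariant to how repeats are grouped into windows.
    ``by_window`` is kept for symmetry with the reporting layer.
    """
    counts = [_count_triple(t) for t in triples]
    return _rates_from_counts(counts)


def _rates_from_counts(counts: Sequence[_TripleCounts]) -> DecayParams:
    deleted = sum(c.deleted_bp for c in counts)
    inserted = sum(c.inserted_bp for c in counts)
    subs = sum(c.substitutions for c in counts)
    sub_sites = sum(c.substitution_sites for c in counts)
    anc_sites = sum(c.ancestral_sites for c in counts)
    if sub_sites == 0 or anc_sites == 0:
        raise ValueError("no informative sites in the filtered triples")
    D = deleted / anc_sites
    I = inserted / anc_sites
    S = subs / sub_sites
    if S == 0:
        raise ValueError("zero substitution rate; time axis undefined")
    return DecayParams(
        deletion_rate=D,
        insertion_rate=I,
        substitution_rate=S,
        loss_per_substitution=loss_per_substitution(D, I, S),
        decay_rate=decay_rate(D, I, S),
    )


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def loss_per_substitution(D: float, I: float, S: float) -> float:
    """Net nucleotides lost per nucleotide substitution: (D − I)/S."""
    if S <= 0:
        raise ValueError("substitution rate must be positive")
    return (D - I) / S

def decay_rate(D: float, I: float, S: float) -> float:
    """Exponential decay rate r on the divergence time axis.

    Over one branch of divergence S the net observed loss is D − I, so the
    surviving fraction exp(−r·S) must equal 1 − (D − I), giving
    r = −ln(1 − (D − I)) / S.
    """
    if S <= 0:
        raise ValueError("substitution rate must be positive")
    net = D - I
    if net >= 1:
        raise ValueError("net loss per bp must be < 1")
    return -math.log(1.0 - net) / S


def fraction_lost(r: float, t: float) -> float:
    """Cumulative fraction of DNA lost after divergence t: 1 − exp(−r t)."""
    if r < 0 or t < 0:
        raise ValueError("rate and time must be non-negative")
    return 1.0 - math.exp(-r * t)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    triples: Sequence[TripleRepeatAlignment],
    replicates: int = 1000,
    seed: int = 0,
    divergence: float | None = None,
    level: float = 0.95,
) -> DecayParams:
    """Point estimates with percentile bootstrap CIs over ancestral repeats.

    Resamples whole triples with replacement and recomputes the full chain
    (D, I, S, loss per substitution, r and — when ``divergence`` t is given —
    the cumulative fraction lost) in every replicate.
    """
    if len(triples) < 2:
        raise ValueError("need at least 2 triples to bootstrap")
    counts = [_count_triple(t) for t in triples]
    arr = np.array(
        [
            (c.deleted_bp, c.inserted_bp, c.substitutions, c.substitution_sites,
             c.ancestral_sites)
            for c in counts
        ],
        dtype=float,
    )
    point = _rates_from_counts(counts)
    rng = np.random.default_rng(seed)
    n = len(counts)
    idx = rng.integers(0, n, size=(replicates, n))
    sums = arr[idx].sum(axis=1)  # (replicates, 5)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = sums[:, 0] / sums[:, 4]
        I = sums[:, 1] / sums[:, 4]
        S = sums[:, 2] / sums[:, 3]
        loss = (D - I) / S
        r = -np.log1p(-(D - I)) / S
    alpha = (1.0 - level) / 2.0
    q = [100 * alpha, 100 * (1 - alpha)]

    def ci(v):
        v = v[np.isfinite(v)]
        lo, hi = np.percentile(v, q)
        return (float(lo), float(hi))

    point.ci = {
        "deletion_rate": ci(D),
        "insertion_rate": ci(I),
        "substitution_rate": ci(S),
        "loss_per_substitution": ci(loss),
        "decay_rate": ci(r),
    }
    if divergence is not None:
        frac = 1.0 - np.exp(-r * divergence)
        point.ci["fraction_lost"] = ci(frac)
    return point
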