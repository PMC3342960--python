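"""Repeat filtering, window aggregation, and genome-structure features.

Repeat copies are filtered to LINE-class elements outside exons and off
unassigned contigs, then aggregated in non-overlapping windows (1 Mb by
default): per window, the insertion and deletion rates are the summed
event bp divided by the summed repeat (master-span) bp, the deletion bias
is deleted bp / inserted bp, and the net loss is deletion rate minus
insertion rate (positive = contraction). Windows without elements carry
missing values, never zeros, so empty regions cannot fake a correlation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .activity import SubfamilyActivity
from .indels import IndelEvent, collapse_recurrent_events
from .io import GenomeAnnotation, RecombMap, RepeatAlignment

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Repeat-filter settings.

    ``unassigned_pattern`` matches chromosome names of unassigned contigs
    (unknown genomic location); ``line_classes`` is the prefix set kept.
    """

    unassigned_pattern: str = r"Un|random"
    line_prefix: str = "LINE"
    keep_classes: tuple[str, ...] = ()  # overrides line_prefix when set


def filter_repeats(
    alignments: list[RepeatAlignment],
    annotation: GenomeAnnotation | None = None,
    config: FilterConfig | None = None,
) -> list[RepeatAlignment]:
    """Keep LINE-class repeats outside exons on assigned chromosomes.

    A repeat overlapping any exon by >= 1 bp is dropped (indels inside
    coding sequence are not neutral); so is any repeat on a chromosome
    whose name matches the unassigned-contig pattern. Counts per filter
    are logged.
    """
    config = config or FilterConfig()
    unassigned = re.compile(config.unassigned_pattern)

    exon_trees: dict[str, IntervalTree] = {}
    if annotation is not None:
        for chrom, s, e in annotation.exons():
            exon_trees.setdefault(chrom, IntervalTree()).addi(s, e)

    kept = []
    n_class = n_unassigned = n_exon = 0
    for a in alignments:
        if config.keep_classes:
            if a.repeat_class not in config.keep_classes:
                n_class += 1
                continue
        elif not a.repeat_class.startswith(config.line_prefix):
            n_class += 1
            continue
        if unassigned.search(a.chromosome):
            n_unassigned += 1
            continue
        tree = exon_trees.get(a.chromosome)
        if tree is not None and tree.overlap(a.g_start, a.g_end):
            n_exon += 1
            continue
        kept.append(a)
    logger.info(
        "filter_repeats: kept %d of %d (dropped %d non-LINE, %d unassigned, "
        "%d exon-overlapping)",
        len(kept), len(alignments), n_class, n_unassigned, n_exon,
    )
    return kept


def _window_of(start: int, window_size: int) -> int:
    return start // window_size


def window_rates(
    alignments: list[RepeatAlignment],
    events: list[IndelEvent],
    window_size: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
    recomb_map: RecombMap | None = None,
    activities: list[SubfamilyActivity] | dict[str, float] | None = None,
    t_bar: float | None = None,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Per-window indel rates, deletion bias, net loss and divergence.

    Elements are assigned to the window containing their genomic start;
    per-window sums behave as if all LINEs and their master sequences were
    concatenated within the window (divergence is mismatches over ungapped
    columns of that concatenation). In ``unique_only`` mode recurrent
    events (identical subfamily/kind/position/length) are collapsed away
    genome-wide before aggregation.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if unique_only:
        events = collapse_recurrent_events(events)

    by_copy: dict[str, list[RepeatAlignment]] = {}
    for a in alignments:
        by_copy.setdefault(a.copy_id, []).append(a)

    rows: dict[tuple[str, int], dict] = {}

    def _row(chrom: str, w: int) -> dict:
        key = (chrom, w)
        if key not in rows:
            rows[key] = {
                "chromosome": chrom,
                "start": w * window_size,
                "end": (w + 1) * window_size,
                "n_elements": 0,
                "repeat_bp": 0,
                "copy_bp": 0,
                "inserted_bp": 0,
                "deleted_bp": 0,
                "n_ins_events": 0,
                "n_del_events": 0,
                "mismatches": 0,
                "aligned_sites": 0,
                "t_sum": 0.0,
            }
        return rows[key]

    if activities is not None and not isinstance(activities, dict):
        activities = {a.subfamily: a.t_i for a in activities}

    # an element (one copy_id on one chromosome) may consist of several
    # fragments; it counts once, in the window of its first fragment
    copy_window: dict[str, tuple[str, int]] = {}
    for copy_id, frags in by_copy.items():
        frags.sort(key=lambda a: (a.chromosome, a.g_start))
        first = frags[0]
        w = _window_of(first.g_start, window_size)
        copy_window[copy_id] = (first.chromosome, w)
        row = _row(first.chromosome, w)
        row["n_elements"] += 1
        if activities is not None:
            row["t_sum"] += activities.get(first.subfamily, float("nan"))
        for frag in frags:
            row["repeat_bp"] += frag.master_span
            row["copy_bp"] += frag.copy_length
            m = np.frombuffer(frag.master_aln.upper().encode(), dtype="S1")
            c = np.frombuffer(frag.copy_aln.upper().encode(), dtype="S1")
            both = (m != b"-") & (c != b"-")
            row["aligned_sites"] += int(both.sum())
            row["mismatches"] += int(((m != c) & both).sum())

    for e in events:
        loc = copy_window.get(e.copy_id)
        if loc is None:
            continue
        row = _row(*loc)
        if e.kind == "deletion":
            row["deleted_bp"] += e.length
            row["n_del_events"] += 1
        else:
            row["inserted_bp"] += e.length
            row["n_ins_events"] += 1

    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            for w in range(int(np.ceil(size / window_size))):
                r = _row(chrom, w)
                r["end"] = min(r["end"], size)

    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["chromosome"], r["start"])))
    empty = df["n_elements"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["divergence"] = np.where(
            df["aligned_sites"] > 0, df["mismatches"] / df["aligned_sites"], np.nan
        )
        df["insertion_rate"] = np.where(
            empty, np.nan, df["inserted_bp"] / df["repeat_bp"]
        )
        df["deletion_rate"] = np.where(
            empty, np.nan, df["deleted_bp"] / df["repeat_bp"]
        )
        df["deletion_bias"] = np.where(
            empty | (df["inserted_bp"] == 0),
            np.nan,
            df["deleted_bp"] / df["inserted_bp"].replace(0, np.nan),
        )
    df["net_loss"] = df["deletion_rate"] - df["insertion_rate"]
    df["mean_line_length"] = np.where(
        empty, np.nan, df["copy_bp"] / df["n_elements"]
    )

    if activities is not None:
        t_window = np.where(empty, np.nan, df["t_sum"] / df["n_elements"])
        if t_bar is None:
            raise ValueError("t_bar is required when activities are given")
        df["normalized_divergence"] = df["divergence"] * (t_window / t_bar)
    df = df.drop(columns=["t_sum"])

    if recomb_map is not None:
        df["recomb_rate"] = [
            recomb_map.window_rate(r.chromosome, r.start, r.end)
            for r in df.itertuples()
        ]
    return df


def genome_features(
    annotation: GenomeAnnotation,
    alignments: list[RepeatAlignment],
    windows: pd.DataFrame,
    window_size: int | None = None,
) -> pd.DataFrame:
    """Attach genome-structure feature columns to a window table.

    Per window: mean intron length and mean first-intron length (introns
    assigned by midpoint; first intron = the 5'-most intron by gene
    strand), intronic and intergenic bp not covered by LINEs ('unique'
    sequence), mean intergenic interval length (by midpoint), and gene
    density as gene starts per Mb.
    """
    windows = windows.copy()
    if window_size is None:
        window_size = int((windows["end"] - windows["start"]).max())
    key_of = lambda chrom, pos: (chrom, pos // window_size)
    index = {
        key_of(r.chromosome, r.start): i for i, r in enumerate(windows.itertuples())
    }
    n = len(windows)
    intron_sum = np.zeros(n)
    intron_n = np.zeros(n)
    first_sum = np.zeros(n)
    first_n = np.zeros(n)
    unique_intron = np.zeros(n)
    unique_inter = np.zeros(n)
    inter_sum = np.zeros(n)
    inter_n = np.zeros(n)
    gene_starts = np.zeros(n)

    line_trees: dict[str, IntervalTree] = {}
    for a in alignments:
        line_trees.setdefault(a.chromosome, IntervalTree()).addi(a.g_start, a.g_end)

    def _covered(chrom: str, s: int, e: int) -> int:
        tree = line_trees.get(chrom)
        if tree is None:
            return 0
        ivs = sorted((max(iv.begin, s), min(iv.end, e)) for iv in tree.overlap(s, e))
        covered = 0
        pos = s
        for a, b in ivs:
            if b > pos:
                covered += b - max(a, pos)
                pos = max(pos, b)
        return covered

    for g in annotation.genes:
        i = index.get(key_of(g.chromosome, g.start))
        if i is not None:
            gene_starts[i] += 1
        first = g.first_intron()
        for s, e in g.introns():
            mid = (s + e) // 2
            j = index.get(key_of(g.chromosome, mid))
            if j is None:
                continue
            length = e - s
            intron_sum[j] += length
            intron_n[j] += 1
            unique_intron[j] += length - _covered(g.chromosome, s, e)
            if first is not None and (s, e) == first:
                first_sum[j] += length
                first_n[j] += 1

    for chrom, s, e in annotation.intergenic():
        mid = (s + e) // 2
        j = index.get(key_of(chrom, mid))
        if j is None:
            continue
        inter_sum[j] += e - s
        inter_n[j] += 1
        unique_inter[j] += (e - s) - _covered(chrom, s, e)

    with np.errstate(divide="ignore", invalid="ignore"):
        windows["mean_intron_length"] = np.where(intron_n > 0, intron_sum / intron_n, np.nan)
        windows["mean_first_intron_length"] = np.where(
            first_n > 0, first_sum / first_n, np.nan
        )
        windows["unique_intronic_bp"] = unique_intron
        windows["unique_intergenic_bp"] = unique_inter
        windows["intergenic_spacer_length"] = np.where(
            inter_n > 0, inter_sum / inter_n, np.nan
        )
    windows["gene_density"] = gene_starts / ((windows["end"] - windows["start"]) / 1e6)
    return windows


def size_class_summary(events: list[IndelEvent]) -> pd.DataFrame:
    """2 x 3 table of event counts and bp sums by kind and size class."""
    rows = []
    for kind in ("insertion", "deletion"):
        for cls in ("small", "intermediate", "long"):
            sel = [e for e in events if e.kind == kind and e.size_class == cls]
            rows.append(
                {
                    "kind": kind,
                    "size_class": cls,
                    "n_events": len(sel),
                    "bp": sum(e.length for e in sel),
                }
            )
    df = pd.DataFrame(rows)
    df["dominant"] = df["bp"] == df.groupby("kind")["bp"].transform("max")
    return df


def windows_to_bed(windows: pd.DataFrame, stream) -> None:
    """BED4 of window definitions for genome browsers."""
    for r in windows.itertuples():
        stream.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.chromosome}:{r.start}\n")
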