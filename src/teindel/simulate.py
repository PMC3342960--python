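"""Forward simulator of dead-on-arrival LINE family evolution.

Every downstream stage of the pipeline is testable against known ground
truth by generating a genome of repeat copies from first principles: each
subfamily has a master sequence and an activity epoch on a [0, 1] time
axis; copies descend independently from the master (star phylogeny), each
accumulating Poisson-distributed substitutions and size-distributed indels
over its elapsed time 1 − (insertion time). Copies are placed in the
windows of a simulated recombination map, optionally with a monotone link
from window recombination rate to per-copy deletion intensity
(multiplier 1 + beta * rate / mean rate), nested insertions of younger
subfamilies into older copies, and 5'-truncated (dead-on-arrival) copies.

The emitted gapped alignments are the true alignments — there is no
realignment noise — so the indel caller is expected to recover the truth
table exactly, and rate estimators can be checked for calibration rather
than alignment artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenomeAnnotation,
    Gene,
    PolymorphicIndel,
    RecombMap,
    RepeatAlignment,
    write_align,
    write_annotation,
    write_out,
    write_polymorphisms,
    write_recomb_map,
)
from .decay import TripleRepeatAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class IndelLengthModel:
    """Mixture of three size classes with geometric within-class lengths.

    Classes follow the small (1–2 bp) / intermediate (3–20 bp) / long
    (>20 bp) partition used throughout the package. Defaults put most of
    the bp turnover in the intermediate class.
    """

    weights: tuple[float, float, float] = (0.45, 0.50, 0.05)
    p_small: float = 0.5  # geometric success prob, truncated to {1, 2}
    p_intermediate: float = 0.25  # truncated to {3..20}
    p_long: float = 0.10  # shifted: 21 + geometric

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise SimConfigError("size-class weights must sum to 1")

    def _class_support(self, cls: int) -> tuple[np.ndarray, np.ndarray]:
        if cls == 0:
            lengths = np.arange(1, 3)
            p = self.p_small
        elif cls == 1:
            lengths = np.arange(3, 21)
            p = self.p_intermediate
        else:
            lengths = np.arange(21, 121)  # truncated support for the long tail
            p = self.p_long
        probs = p * (1 - p) ** (lengths - lengths[0])
        return lengths, probs / probs.sum()

    def mean_length(self) -> float:
        m = 0.0
        for cls, w in enumerate(self.weights):
            lengths, probs = self._class_support(cls)
            m += w * float(lengths @ probs)
        return m

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0, dtype=int)
        classes = rng.choice(3, size=n, p=self.weights)
        out = np.empty(n, dtype=int)
        for cls in range(3):
            mask = classes == cls
            k = int(mask.sum())
            if not k:
                continue
            lengths, probs = self._class_support(cls)
            out[mask] = rng.choice(lengths, size=k, p=probs)
        return out


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    chrom_class: str = "macro"  # macro | micro | Z | W


@dataclass
class SubfamilySpec:
    name: str
    master_length: int
    epoch_start: float
    epoch_end: float
    copy_count: int

    @property
    def epoch_midpoint(self) -> float:
        return 0.5 * (self.epoch_start + self.epoch_end)


@dataclass
class SimConfig:
    """All knobs of the generator; rates are per site per unit time."""

    seed: int = 0
    chromosomes: list[ChromosomeSpec] = field(
        default_factory=lambda: [ChromosomeSpec("chr1", 2_000_000)]
    )
    subfamilies: list[SubfamilySpec] = field(
        default_factory=lambda: [SubfamilySpec("CR1-sim1", 1000, 0.0, 0.2, 500)]
    )
    recomb_window: int = 1_000_000
    recomb_rates: dict[str, list[float]] | None = None  # per window, else drawn
    macro_mean_rate: float = 2.5  # cM/Mb
    micro_mean_rate: float = 6.0
    rate_shape: float = 4.0  # gamma shape of window-to-window variation
    substitution_rate: float = 0.10
    insertion_rate: float = 0.015  # bp inserted per site per unit time
    deletion_rate: float = 0.05  # bp deleted per site per unit time
    indel_lengths: IndelLengthModel = field(default_factory=IndelLengthModel)
    beta: float = 0.0  # recombination -> deletion link slope
    truncation_prob: float = 0.0
    truncation_min_frac: float = 0.3
    nesting_prob: float = 0.0
    genes_per_mb: float = 0.0
    exons_per_gene: int = 3
    exon_length: int = 200
    mean_intron_length: int = 2000
    n_polymorphisms: int = 0

    @property
    def deletion_bias(self) -> float:
        """Configured deletion:insertion bp bias."""
        return self.deletion_rate / self.insertion_rate

    def validate(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if r < 0:
                raise SimConfigError("rates must be >= 0")
        for sf in self.subfamilies:
            if sf.master_length <= 0:
                raise SimConfigError(f"{sf.name}: master length must be > 0")
            if not (0 <= sf.epoch_start <= sf.epoch_end <= 1):
                raise SimConfigError(f"{sf.name}: epoch must lie within [0, 1]")
        if not self.chromosomes:
            raise SimConfigError("need at least one chromosome")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class CopyTruth:
    copy_id: str
    subfamily: str
    insertion_time: float
    n_substitutions: int
    deletions: list[tuple[int, int]]  # (master pos, length)
    insertions: list[tuple[int, int, str]]  # (master pos, length, sequence)
    deletion_multiplier: float = 1.0
    truncated: bool = False
    window: tuple[str, int] | None = None  # (chromosome, window index)

    @property
    def deleted_bp(self) -> int:
        return sum(l for _, l in self.deletions)

    @property
    def inserted_bp(self) -> int:
        return sum(l for _, l, _ in self.insertions)


@dataclass
class TruthTable:
    copies: dict[str, CopyTruth]
    windows: pd.DataFrame  # chromosome, start, end, recomb, true bp sums/rates
    subfamilies: pd.DataFrame  # subfamily, epoch_start, epoch_end, midpoint


@dataclass
class SimResult:
    config: SimConfig
    alignments: list[RepeatAlignment]
    recomb_map: RecombMap
    annotation: GenomeAnnotation
    polymorphisms: list[PolymorphicIndel]
    truth: TruthTable


# ---------------------------------------------------------------------------
# per-copy evolution
# ---------------------------------------------------------------------------


def _sample_indel_events(
    rng: np.random.Generator,
    L: int,
    expected_del_bp: float,
    expected_ins_bp: float,
    model: IndelLengthModel,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Draw non-colliding deletion intervals and insertion points.

    Returns (deletions as (start, length)) and (insertions as (pos, length)),
    both in master coordinates, away from the sequence ends so that no event
    is confounded with terminal truncation. Events that cannot be placed
    without collision after bounded retries are dropped (rare at realistic
    densities).
    """
    mean_len = model.mean_length()
    n_del = rng.poisson(expected_del_bp * L / mean_len)
    n_ins = rng.poisson(expected_ins_bp * L / mean_len)
    del_lens = model.sample(rng, n_del)
    ins_lens = model.sample(rng, n_ins)

    deletions: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []  # closed intervals in master coords
    for length in del_lens:
        if length > L - 2:
            continue
        for _ in range(50):
            a = int(rng.integers(1, L - length))  # a+length <= L-1
            # keep >= 1 master base between deletions so runs stay maximal
            if all(a > e + 1 or a + length < s - 1 for s, e in occupied):
                deletions.append((a, int(length)))
                occupied.append((a, a + length))
                break
    ins_points: set[int] = set()
    insertions: list[tuple[int, int]] = []
    for length in ins_lens:
        for _ in range(50):
            p = int(rng.integers(1, L))  # 1..L-1 inclusive
            inside = any(s < p < e for s, e in occupied)
            if not inside and p not in ins_points:
                insertions.append((p, int(length)))
                ins_points.add(p)
                break
    deletions.sort()
    insertions.sort()
    return deletions, insertions


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> None:
    # replace with one of the three other bases, in place
    if len(positions) == 0:
        return
    idx = np.searchsorted(_BASES, seq[positions])
    seq[positions] = _BASES[(idx + rng.integers(1, 4, size=len(positions))) % 4]


def _build_alignment(
    master: np.ndarray,
    copy_bases: np.ndarray,
    deletions: list[tuple[int, int]],
    insertions: list[tuple[int, int, str]],
) -> tuple[str, str]:
    """Assemble the gapped master/copy strings from an event list."""
    m_parts: list[str] = []
    c_parts: list[str] = []
    master_s = master.tobytes().decode()
    copy_s = copy_bases.tobytes().decode()
    events: list[tuple[int, int, object]] = [(a, 1, l) for a, l in deletions]
    events += [(p, 0, seq) for p, _, seq in insertions]
    events.sort(key=lambda t: (t[0], t[1]))
    cursor = 0
    for pos, kind, payload in events:
        m_parts.append(master_s[cursor:pos])
        c_parts.append(copy_s[cursor:pos])
        if kind == 0:  # insertion
            m_parts.append("-" * len(payload))
            c_parts.append(payload)
            cursor = pos
        else:  # deletion of `payload` bp
            m_parts.append(master_s[pos : pos + payload])
            c_parts.append("-" * payload)
            cursor = pos + payload
    m_parts.append(master_s[cursor:])
    c_parts.append(copy_s[cursor:])
    return "".join(m_parts), "".join(c_parts)


def _evolve_copy(
    rng: np.random.Generator,
    config: SimConfig,
    master: np.ndarray,
    subfamily: SubfamilySpec,
    copy_id: str,
    multiplier: float,
) -> tuple[RepeatAlignment, CopyTruth]:
    L = subfamily.master_length
    t0 = float(rng.uniform(subfamily.epoch_start, subfamily.epoch_end))
    elapsed = 1.0 - t0
    deletions, ins_raw = _sample_indel_events(
        rng,
        L,
        config.deletion_rate * multiplier * elapsed,
        config.insertion_rate * elapsed,
        config.indel_lengths,
    )
    insertions = [
        (p, l, _random_seq(rng, l).tobytes().decode()) for p, l in ins_raw
    ]

    deleted_mask = np.zeros(L, dtype=bool)
    for a, l in deletions:
        deleted_mask[a : a + l] = True
    surviving = np.flatnonzero(~deleted_mask)
    n_sub = min(
        int(rng.poisson(config.substitution_rate * elapsed * len(surviving))),
        len(surviving),
    )
    copy_bases = master.copy()
    sub_pos = np.empty(0, dtype=int)
    if n_sub:
        sub_pos = rng.choice(surviving, size=n_sub, replace=False)
        _mutate(rng, copy_bases, sub_pos)

    m_start = 0
    truncated = False
    if config.truncation_prob > 0 and rng.random() < config.truncation_prob:
        kept = float(rng.uniform(config.truncation_min_frac, 1.0))
        c = int(round((1.0 - kept) * L))
        ins_points = {p for p, _, _ in insertions}
        for _ in range(100):
            bad = c in ins_points or any(a <= c <= a + l for a, l in deletions)
            if not bad and 0 < c < L - 1:
                break
            c += 1
            if c >= L - 1:
                c = 1
        else:
            c = 0
        if 0 < c < L - 1:
            truncated = True
            m_start = c
            deletions = [(a, l) for a, l in deletions if a >= c]
            insertions = [(p, l, s) for p, l, s in insertions if p > c]

    master_aln, copy_aln = _build_alignment(
        master[m_start:],
        copy_bases[m_start:],
        [(a - m_start, l) for a, l in deletions],
        [(p - m_start, l, s) for p, l, s in insertions],
    )
    copy_len = len(copy_aln) - copy_aln.count("-")
    aln = RepeatAlignment(
        copy_id=copy_id,
        subfamily=subfamily.name,
        chromosome="unplaced",
        g_start=0,
        g_end=copy_len,
        strand="+",
        master_aln=master_aln,
        copy_aln=copy_aln,
        m_start=m_start,
    )
    truth = CopyTruth(
        copy_id=copy_id,
        subfamily=subfamily.name,
        insertion_time=t0,
        n_substitutions=int((sub_pos >= m_start).sum()),
        deletions=deletions,
        insertions=insertions,
        deletion_multiplier=multiplier,
        truncated=truncated,
    )
    return aln, truth


def simulate_family(
    config: SimConfig,
    subfamily: SubfamilySpec,
    rng: np.random.Generator | None = None,
    multipliers: np.ndarray | None = None,
) -> tuple[list[RepeatAlignment], list[CopyTruth]]:
    """Evolve all copies of one subfamily from its master (star phylogeny).

    ``multipliers`` scales each copy's deletion intensity (the
    recombination link); default all ones. Copies are returned unplaced
    (chromosome 'unplaced', coordinates [0, copy length))."""
    config.validate()
    if subfamily.master_length <= 0:
        raise SimConfigError("master length must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if multipliers is None:
        multipliers = np.ones(subfamily.copy_count)
    master = _random_seq(rng, subfamily.master_length)
    copies, truths = [], []
    for i in range(subfamily.copy_count):
        aln, truth = _evolve_copy(
            rng, config, master, subfamily,
            f"{subfamily.name}.c{i}", float(multipliers[i]),
        )
        copies.append(aln)
        truths.append(truth)
    return copies, truths


# ---------------------------------------------------------------------------
# genome assembly: recombination map, placement, nesting, genes
# ---------------------------------------------------------------------------


def _window_grid(config: SimConfig) -> list[tuple[str, int, int]]:
    grid = []
    for chrom in config.chromosomes:
        pos = 0
        while pos < chrom.length:
            grid.append((chrom.name, pos, min(pos + config.recomb_window, chrom.length)))
            pos += config.recomb_window
    return grid


def _draw_recomb_rates(
    config: SimConfig, grid: list[tuple[str, int, int]], rng: np.random.Generator
) -> np.ndarray:
    classes = {c.name: c.chrom_class for c in config.chromosomes}
    auto_means = [
        config.micro_mean_rate if classes[c] == "micro" else config.macro_mean_rate
        for c, _, _ in grid
        if classes[c] in ("macro", "micro")
    ]
    auto_mean = float(np.mean(auto_means)) if auto_means else config.macro_mean_rate
    rates = np.zeros(len(grid))
    k = config.rate_shape
    for i, (c, _, _) in enumerate(grid):
        cls = classes[c]
        if cls == "W":
            rates[i] = 0.0  # the W chromosome never recombines
            continue
        if cls == "Z":
            mean = 0.5 * auto_mean  # Z recombines in males only
        elif cls == "micro":
            mean = config.micro_mean_rate
        else:
            mean = config.macro_mean_rate
        rates[i] = rng.gamma(k, mean / k)
    return rates


def simulate_genome(config: SimConfig) -> SimResult:
    """Simulate the full genome: families, placement, map, genes, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    grid = _window_grid(config)
    if config.recomb_rates is not None:
        rates = np.array(
            [r for c in config.chromosomes for r in config.recomb_rates[c.name]],
            dtype=float,
        )
        if len(rates) != len(grid):
            raise SimConfigError("recomb_rates does not match the window grid")
    else:
        rates = _draw_recomb_rates(config, grid, rng)
    mean_rate = float(rates.mean()) if rates.mean() > 0 else 1.0
    multiplier_per_window = 1.0 + config.beta * rates / mean_rate
    recomb_map = RecombMap(
        pd.DataFrame(
            [(c, s, e, r) for (c, s, e), r in zip(grid, rates)],
            columns=["chromosome", "start", "end", "rate"],
        )
    )

    window_lengths = np.array([e - s for _, s, e in grid], dtype=float)
    window_probs = window_lengths / window_lengths.sum()

    # per-window ordered entries; an entry is a list of fragments placed
    # contiguously (host fragment 1, nested copy, host fragment 2)
    entries: list[list[list[RepeatAlignment]]] = [[] for _ in grid]
    order = sorted(
        range(len(config.subfamilies)),
        key=lambda i: config.subfamilies[i].epoch_midpoint,
    )
    midpoint = {sf.name: sf.epoch_midpoint for sf in config.subfamilies}
    copy_truths: dict[str, CopyTruth] = {}

    for rank, i_sf in enumerate(order):
        sf = config.subfamilies[i_sf]
        win_idx = rng.choice(len(grid), size=sf.copy_count, p=window_probs)
        copies, truths = simulate_family(
            config, sf, rng=rng, multipliers=multiplier_per_window[win_idx]
        )
        for w, aln, truth in zip(win_idx, copies, truths):
            truth.window = (grid[w][0], int(w))
            copy_truths[aln.copy_id] = truth
            nested = False
            if rank > 0 and config.nesting_prob > 0 and rng.random() < config.nesting_prob:
                hosts = [
                    j
                    for j, entry in enumerate(entries[w])
                    if len(entry) == 1
                    and midpoint[entry[0].subfamily] < sf.epoch_midpoint
                    and entry[0].master_span > 60
                ]
                if hosts:
                    j = int(hosts[rng.integers(0, len(hosts))])
                    host = entries[w][j][0]
                    frags = _split_for_nesting(
                        rng, host, copy_truths[host.copy_id]
                    )
                    if frags is not None:
                        entries[w][j] = [frags[0], aln, frags[1]]
                        nested = True
            if not nested:
                entries[w].append([aln])

    alignments = _assign_coordinates(config, grid, entries, rng)

    annotation = _simulate_genes(config, rng)
    polymorphisms = _simulate_polymorphisms(config, rng)
    truth_windows = _truth_windows(grid, rates, copy_truths, alignments)
    truth_subfams = pd.DataFrame(
        [
            (sf.name, sf.epoch_start, sf.epoch_end, sf.epoch_midpoint)
            for sf in config.subfamilies
        ],
        columns=["subfamily", "epoch_start", "epoch_end", "epoch_midpoint"],
    )
    return SimResult(
        config=config,
        alignments=alignments,
        recomb_map=recomb_map,
        annotation=annotation,
        polymorphisms=polymorphisms,
        truth=TruthTable(copy_truths, truth_windows, truth_subfams),
    )


def _split_for_nesting(
    rng: np.random.Generator, host: RepeatAlignment, truth: CopyTruth
) -> tuple[RepeatAlignment, RepeatAlignment] | None:
    """Split a host alignment into two fragments at an event-free master
    coordinate, leaving at least one aligned column next to every event so
    no gap run becomes terminal in either fragment."""
    lo, hi = host.m_start + 10, host.m_end - 10
    if hi - lo < 2:
        return None
    ins_points = {p for p, _, _ in truth.insertions}
    for _ in range(60):
        c = int(rng.integers(lo, hi))
        if c in ins_points or any(a <= c <= a + l for a, l in truth.deletions):
            continue
        break
    else:
        return None
    # column index of master base c within the host alignment
    col = (c - host.m_start) + sum(l for p, l, _ in truth.insertions if host.m_start < p < c)
    f1_master, f2_master = host.master_aln[:col], host.master_aln[col:]
    f1_copy, f2_copy = host.copy_aln[:col], host.copy_aln[col:]
    mk = lambda m, cp, m_start: RepeatAlignment(
        copy_id=host.copy_id,
        subfamily=host.subfamily,
        chromosome=host.chromosome,
        g_start=0,
        g_end=len(cp) - cp.count("-"),
        strand=host.strand,
        master_aln=m,
        copy_aln=cp,
        m_start=m_start,
    )
    return mk(f1_master, f1_copy, host.m_start), mk(f2_master, f2_copy, c)


def _assign_coordinates(
    config: SimConfig,
    grid: list[tuple[str, int, int]],
    entries: list[list[list[RepeatAlignment]]],
    rng: np.random.Generator,
) -> list[RepeatAlignment]:
    out: list[RepeatAlignment] = []
    for w, (chrom, w_start, w_end) in enumerate(grid):
        ents = entries[w]
        if not ents:
            continue
        perm = rng.permutation(len(ents))
        ents = [ents[i] for i in perm]
        total_bp = sum(a.copy_length for entry in ents for a in entry)
        free = (w_end - w_start) - total_bp
        if free < len(ents) + 1:
            raise SimConfigError(
                f"placement overflow in window {chrom}:{w_start}-{w_end} "
                f"({total_bp} repeat bp in {w_end - w_start} bp)"
            )
        gaps = rng.multinomial(free - (len(ents) + 1), np.full(len(ents) + 1, 1.0 / (len(ents) + 1)))
        pos = w_start
        for entry, gap in zip(ents, gaps):
            pos += int(gap) + 1
            for frag in entry:
                frag.chromosome = chrom
                frag.g_start = pos
                frag.g_end = pos + frag.copy_length
                pos = frag.g_end
                out.append(frag)
    out.sort(key=lambda a: (a.chromosome, a.g_start))
    return out


def _simulate_genes(config: SimConfig, rng: np.random.Generator) -> GenomeAnnotation:
    genes: list[Gene] = []
    sizes = {c.name: c.length for c in config.chromosomes}
    if config.genes_per_mb <= 0:
        return GenomeAnnotation([], chrom_sizes=sizes)
    for chrom in config.chromosomes:
        n = rng.poisson(config.genes_per_mb * chrom.length / 1e6)
        last_end = -1
        starts = np.sort(rng.integers(0, max(1, chrom.length - 1), size=n))
        for i, start in enumerate(starts):
            start = int(start)
            if start <= last_end:
                continue
            exons = []
            pos = start
            for e in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_length))
                pos += config.exon_length
                if e < config.exons_per_gene - 1:
                    intron = int(rng.geometric(1.0 / config.mean_intron_length))
                    pos += max(50, intron)
            if pos > chrom.length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(f"{chrom.name}.g{i}", chrom.name, start, pos, strand, exons)
            )
            last_end = pos
    return GenomeAnnotation(genes, chrom_sizes=sizes)


def _simulate_polymorphisms(
    config: SimConfig, rng: np.random.Generator
) -> list[PolymorphicIndel]:
    if config.n_polymorphisms <= 0:
        return []
    # folded neutral site frequency spectrum over 100 sampled chromosomes
    i = np.arange(1, 51)
    w = 1.0 / i + 1.0 / (100 - i)
    w /= w.sum()
    p_del = config.deletion_rate / (config.deletion_rate + config.insertion_rate)
    chroms = [c.name for c in config.chromosomes]
    lengths = np.array([c.length for c in config.chromosomes], dtype=float)
    out = []
    for k in range(config.n_polymorphisms):
        c = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        kind = "deletion" if rng.random() < p_del else "insertion"
        maf = float(i[rng.choice(50, p=w)]) / 100.0
        context = ("intron", "intergenic", "LINE")[rng.integers(0, 3)]
        out.append(
            PolymorphicIndel(
                chromosome=chroms[c],
                position=int(rng.integers(0, config.chromosomes[c].length)),
                kind=kind,
                maf=maf,
                context=context,
            )
        )
    return out


def _truth_windows(
    grid: list[tuple[str, int, int]],
    rates: np.ndarray,
    copy_truths: dict[str, CopyTruth],
    alignments: list[RepeatAlignment],
) -> pd.DataFrame:
    repeat_bp = np.zeros(len(grid))
    # master span from fragments, truth events from the copy record (counted once)
    lookup: dict[str, list[int]] = {}
    for i, (c, _, _) in enumerate(grid):
        lookup.setdefault(c, []).append(i)
    starts = {c: np.array([grid[i][1] for i in ix]) for c, ix in lookup.items()}
    for a in alignments:
        j = int(np.searchsorted(starts[a.chromosome], a.g_start, side="right")) - 1
        repeat_bp[lookup[a.chromosome][j]] += a.master_span
    del_bp = np.zeros(len(grid))
    ins_bp = np.zeros(len(grid))
    for t in copy_truths.values():
        if t.window is None:
            continue
        _, w = t.window
        del_bp[w] += t.deleted_bp
        ins_bp[w] += t.inserted_bp
    with np.errstate(divide="ignore", invalid="ignore"):
        del_rate = np.where(repeat_bp > 0, del_bp / repeat_bp, np.nan)
        ins_rate = np.where(repeat_bp > 0, ins_bp / repeat_bp, np.nan)
    return pd.DataFrame(
        {
            "chromosome": [c for c, _, _ in grid],
            "start": [s for _, s, _ in grid],
            "end": [e for _, _, e in grid],
            "recomb_rate": rates,
            "repeat_bp": repeat_bp,
            "true_deleted_bp": del_bp,
            "true_inserted_bp": ins_bp,
            "true_deletion_rate": del_rate,
            "true_insertion_rate": ins_rate,
        }
    )


# ---------------------------------------------------------------------------
# three-species ancestral repeat triples
# ---------------------------------------------------------------------------


def simulate_triples(
    n: int,
    deletion_rate: float,
    insertion_rate: float,
    substitution_rate: float,
    length: int = 500,
    n_windows: int = 10,
    seed: int = 0,
    other_branch_sub_rate: float | None = None,
    indel_lengths: IndelLengthModel | None = None,
) -> list[TripleRepeatAlignment]:
    """Generate focal/sister/outgroup alignments of ancestral repeats.

    Indels and substitutions at the given focal-branch rates (per ancestral
    bp) are applied to the focal sequence; sister and outgroup accumulate
    their own substitutions (default: the same rate for the sister, twice
    for the outgroup) but no indels, so the configured focal rates are the
    exact truth for parsimony recovery.
    """
    rng = np.random.default_rng(seed)
    model = indel_lengths or IndelLengthModel()
    if other_branch_sub_rate is None:
        other_branch_sub_rate = substitution_rate
    triples = []
    for k in range(n):
        anc = _random_seq(rng, length)
        deletions, ins_raw = _sample_indel_events(
            rng, length, deletion_rate, insertion_rate, model
        )
        insertions = [
            (p, l, _random_seq(rng, l).tobytes().decode()) for p, l in ins_raw
        ]
        deleted = np.zeros(length, dtype=bool)
        for a, l in deletions:
            deleted[a : a + l] = True
        surviving = np.flatnonzero(~deleted)

        def mutated(base: np.ndarray, rate: float) -> np.ndarray:
            out = base.copy()
            m = min(int(rng.poisson(rate * length)), length)
            if m:
                _mutate(rng, out, rng.choice(length, size=m, replace=False))
            return out

        focal_bases = anc.copy()
        m = min(int(rng.poisson(substitution_rate * len(surviving))), len(surviving))
        if m:
            _mutate(rng, focal_bases, rng.choice(surviving, size=m, replace=False))
        sister_bases = mutated(anc, other_branch_sub_rate)
        outgroup_bases = mutated(anc, 2.0 * other_branch_sub_rate)

        f_aln, s_aln, o_aln = _triple_alignment(
            anc, focal_bases, sister_bases, outgroup_bases, deletions, insertions
        )
        triples.append(
            TripleRepeatAlignment(
                repeat_id=f"ar{k}",
                window_id=f"w{k % n_windows}",
                focal=f_aln,
                sister=s_aln,
                outgroup=o_aln,
            )
        )
    return triples


def _triple_alignment(
    anc, focal_bases, sister_bases, outgroup_bases, deletions, insertions
):
    f_parts, s_parts, o_parts = [], [], []
    f_s = focal_bases.tobytes().decode()
    s_s = sister_bases.tobytes().decode()
    o_s = outgroup_bases.tobytes().decode()
    events = [(a, 1, l) for a, l in deletions]
    events += [(p, 0, seq) for p, _, seq in insertions]
    events.sort(key=lambda t: (t[0], t[1]))
    cursor = 0
    for pos, kind, payload in events:
        f_parts.append(f_s[cursor:pos])
        s_parts.append(s_s[cursor:pos])
        o_parts.append(o_s[cursor:pos])
        if kind == 0:
            f_parts.append(payload)
            s_parts.append("-" * len(payload))
            o_parts.append("-" * len(payload))
            cursor = pos
        else:
            f_parts.append("-" * payload)
            s_parts.append(s_s[pos : pos + payload])
            o_parts.append(o_s[pos : pos + payload])
            cursor = pos + payload
    f_parts.append(f_s[cursor:])
    s_parts.append(s_s[cursor:])
    o_parts.append(o_s[cursor:])
    return "".join(f_parts), "".join(s_parts), "".join(o_parts)


# ---------------------------------------------------------------------------
# fixture emission and named scenarios
# ---------------------------------------------------------------------------


def emit_fixtures(sim: SimResult, directory: str | Path) -> dict[str, str]:
    """Write all pipeline input formats plus truth tables and a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(name: str, fn) -> None:
        path = d / name
        with open(path, "w") as fh:
            fn(fh)
        files[name] = str(path)

    _write("repeats.out", lambda fh: write_out(sim.alignments, fh))
    _write("repeats.align", lambda fh: write_align(sim.alignments, fh))
    _write("recomb.tsv", lambda fh: write_recomb_map(sim.recomb_map, fh))
    _write("genes.bed", lambda fh: write_annotation(sim.annotation, fh, "BED12"))
    _write("genes.gff3", lambda fh: write_annotation(sim.annotation, fh, "GFF3"))
    _write(
        "polymorphisms.tsv", lambda fh: write_polymorphisms(sim.polymorphisms, fh)
    )
    _write(
        "truth_windows.tsv",
        lambda fh: sim.truth.windows.to_csv(fh, sep="\t", index=False),
    )
    _write(
        "truth_subfamilies.tsv",
        lambda fh: sim.truth.subfamilies.to_csv(fh, sep="\t", index=False),
    )

    def _truth_copies(fh):
        fh.write(
            "copy_id\tsubfamily\tinsertion_time\tn_substitutions\t"
            "deleted_bp\tinserted_bp\tdeletion_multiplier\ttruncated\n"
        )
        for t in sim.truth.copies.values():
            fh.write(
                f"{t.copy_id}\t{t.subfamily}\t{t.insertion_time:.6g}\t"
                f"{t.n_substitutions}\t{t.deleted_bp}\t{t.inserted_bp}\t"
                f"{t.deletion_multiplier:.6g}\t{int(t.truncated)}\n"
            )

    _write("truth_copies.tsv", _truth_copies)

    manifest = {
        "seed": sim.config.seed,
        "config_hash": sim.config.content_hash(),
        "config": sim.config.to_dict(),
        "files": sorted(files),
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    files["manifest.json"] = str(d / "manifest.json")
    return files


def scenario_config(name: str, seed: int = 0) -> SimConfig:
    """Named study scenarios: 'null', 'contraction', 'sex-chromosome'."""
    subfams = [
        SubfamilySpec("CR1-sim1", 800, 0.00, 0.15, 400),
        SubfamilySpec("CR1-sim2", 800, 0.25, 0.40, 400),
        SubfamilySpec("CR1-sim3", 800, 0.50, 0.65, 400),
    ]
    common = dict(
        seed=seed,
        recomb_window=50_000,
        substitution_rate=0.10,
        insertion_rate=0.015,
        deletion_rate=0.05,
        truncation_prob=0.15,
        nesting_prob=0.05,
        genes_per_mb=8.0,
        n_polymorphisms=2000,
    )
    if name == "null":
        return SimConfig(
            chromosomes=[
                ChromosomeSpec("chr1", 4_000_000, "macro"),
                ChromosomeSpec("chr2", 2_000_000, "micro"),
            ],
            subfamilies=subfams,
            beta=0.0,
            **common,
        )
    if name == "contraction":
        return SimConfig(
            chromosomes=[
                ChromosomeSpec("chr1", 4_000_000, "macro"),
                ChromosomeSpec("chr2", 2_000_000, "micro"),
            ],
            subfamilies=subfams,
            beta=2.0,
            **common,
        )
    if name == "sex-chromosome":
        return SimConfig(
            chromosomes=[
                ChromosomeSpec("chr1", 3_000_000, "macro"),
                ChromosomeSpec("chr2", 1_500_000, "micro"),
                ChromosomeSpec("chrZ", 1_500_000, "Z"),
                ChromosomeSpec("chrW", 500_000, "W"),
            ],
            subfamilies=subfams,
            beta=2.0,
            **common,
        )
    raise SimConfigError(f"unknown scenario {name!r}")
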