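"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open coordinates.
Both RepeatMasker-style dialects (.out annotation table and .align pairwise
alignments) use 1-based inclusive coordinates on disk and are converted on
read; minus-strand ("C") alignments are stored on disk with the copy line in
plus-strand genomic orientation and are reverse-complemented into consensus
orientation on read, so that master (consensus) coordinates are comparable
across copies of a subfamily.

The exact grammars accepted are documented in the package README.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgtNn-", "TGCAtgcaNn-")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly gapped) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class RepeatIOError(ValueError):
    """Malformed record in an input stream (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RepeatAlignment:
    """One repeat copy aligned against its subfamily master sequence.

    The gapped strings are stored in master (consensus) orientation regardless
    of the genomic strand, and ``m_start`` gives the consensus offset (0-based)
    of the first aligned master base, so event coordinates derived from
    different copies of one subfamily live on a common axis.
    """

    copy_id: str
    subfamily: str
    chromosome: str
    g_start: int
    g_end: int
    strand: str  # '+' or '-'
    master_aln: str
    copy_aln: str
    m_start: int
    repeat_class: str = "LINE/CR1"

    def validate(self) -> None:
        if len(self.master_aln) != len(self.copy_aln):
            raise RepeatIOError(
                f"{self.copy_id}: gapped lengths differ "
                f"({len(self.master_aln)} vs {len(self.copy_aln)})"
            )
        if self.strand not in ("+", "-"):
            raise RepeatIOError(f"{self.copy_id}: unknown strand {self.strand!r}")
        ungapped = len(self.copy_aln) - self.copy_aln.count("-")
        if self.g_end - self.g_start != ungapped:
            raise RepeatIOError(
                f"{self.copy_id}: genomic span {self.g_end - self.g_start} != "
                f"ungapped copy length {ungapped}"
            )

    @property
    def copy_length(self) -> int:
        """Ungapped copy length in bp."""
        return len(self.copy_aln) - self.copy_aln.count("-")

    @property
    def master_span(self) -> int:
        """Ungapped master (consensus) bp covered by the alignment."""
        return len(self.master_aln) - self.master_aln.count("-")

    @property
    def m_end(self) -> int:
        return self.m_start + self.master_span


@dataclass
class RecombMap:
    """Sex-averaged recombination rates in non-overlapping genomic intervals."""

    table: pd.DataFrame  # columns: chromosome, start, end, rate (cM/Mb)

    def __post_init__(self) -> None:
        t = self.table
        required = ["chromosome", "start", "end", "rate"]
        if list(t.columns[:4]) != required:
            t = t.copy()
            t.columns = required + list(t.columns[4:])
            self.table = t
        if (self.table["rate"] < 0).any():
            raise RepeatIOError("negative recombination rate")
        if (self.table["end"] <= self.table["start"]).any():
            raise RepeatIOError("empty or inverted recombination interval")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise RepeatIOError(f"overlapping recombination intervals on {chrom}")

    def window_rate(self, chromosome: str, start: int, end: int) -> float:
        """Length-weighted mean rate over [start, end); NaN with no overlap."""
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            return float("nan")
        ov_start = sub["start"].clip(lower=start)
        ov_end = sub["end"].clip(upper=end)
        w = (ov_end - ov_start).clip(lower=0)
        total = w.sum()
        if total == 0:
            return float("nan")
        return float((sub["rate"] * w).sum() / total)


@dataclass
class Gene:
    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # sorted, 0-based half-open

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        out = []
        for (a_s, a_e), (b_s, b_e) in zip(self.exons, self.exons[1:]):
            if b_s > a_e:
                out.append((a_e, b_s))
        return out

    def first_intron(self) -> tuple[int, int] | None:
        """The 5'-most intron with respect to gene strand, or None."""
        intr = self.introns()
        if not intr:
            return None
        return intr[0] if self.strand != "-" else intr[-1]


@dataclass
class GenomeAnnotation:
    """Gene models plus derived intron and intergenic structure."""

    genes: list[Gene]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            for s, e in g.exons:
                if s < g.start or e > g.end:
                    raise RepeatIOError(
                        f"gene {g.name}: exon [{s},{e}) outside gene bounds"
                    )
        if not self.chrom_sizes:
            sizes: dict[str, int] = {}
            for g in self.genes:
                sizes[g.chromosome] = max(sizes.get(g.chromosome, 0), g.end)
            self.chrom_sizes = sizes

    def introns(self) -> list[tuple[str, int, int, Gene]]:
        return [
            (g.chromosome, s, e, g) for g in self.genes for (s, e) in g.introns()
        ]

    def exons(self) -> list[tuple[str, int, int]]:
        return [(g.chromosome, s, e) for g in self.genes for (s, e) in g.exons]

    def intergenic(self) -> list[tuple[str, int, int]]:
        """Per-chromosome complement of merged gene spans."""
        out: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for chrom, size in self.chrom_sizes.items():
            spans = sorted(by_chrom.get(chrom, []))
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            pos = 0
            for s, e in merged:
                if s > pos:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < size:
                out.append((chrom, pos, size))
        return out


@dataclass
class PolymorphicIndel:
    """A segregating insertion or deletion with outgroup-polarized kind."""

    chromosome: str
    position: int
    kind: str  # 'insertion' | 'deletion'
    maf: float
    context: str  # 'intron' | 'intergenic' | 'LINE'

    KINDS = ("insertion", "deletion")
    CONTEXTS = ("intron", "intergenic", "LINE")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise RepeatIOError(f"unknown indel kind {self.kind!r}")
        if self.context not in self.CONTEXTS:
            raise RepeatIOError(f"unknown context {self.context!r}")
        if not 0.0 <= self.maf <= 0.5:
            raise RepeatIOError(f"MAF {self.maf} outside [0, 0.5]")


# ---------------------------------------------------------------------------
# RepeatMasker-style .out table
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "  repeat          position in repeat\n"
    "score   div. del. ins.  sequence  begin  end          (left)   repeat"
    "  class/family  begin  end   (left)  ID\n"
    "\n"
)


def _strip_parens(tok: str) -> int:
    return int(tok.strip("()"))


def _parse_out_row(tokens: list[str], line_no: int) -> dict:
    if len(tokens) < 15:
        raise RepeatIOError(f"expected 15 fields, got {len(tokens)}", line_no)
    strand = tokens[8]
    if strand not in ("+", "C"):
        raise RepeatIOError(f"unknown strand symbol {strand!r}", line_no)
    return {
        "score": int(tokens[0]),
        "chromosome": tokens[4],
        # 1-based inclusive -> 0-based half-open
        "g_start": int(tokens[5]) - 1,
        "g_end": int(tokens[6]),
        "strand": "+" if strand == "+" else "-",
        "subfamily": tokens[9],
        "repeat_class": tokens[10],
        "r_start": _strip_parens(tokens[11]) - 1,
        "r_end": _strip_parens(tokens[12]),
        "copy_id": tokens[14],
    }


def parse_out_table(stream: TextIO) -> list[dict]:
    """Parse the .out dialect (3 header lines, then one row per repeat hit)."""
    rows = []
    for line_no, line in enumerate(stream, start=1):
        if line_no <= 3:
            continue
        tokens = line.split()
        if not tokens:
            continue
        rows.append(_parse_out_row(tokens, line_no))
    return rows


# ---------------------------------------------------------------------------
# .align dialect
# ---------------------------------------------------------------------------


def _iter_align_blocks(stream: TextIO):
    """Yield (header_tokens, copy_lines, master_lines, header_line_no)."""
    header = None
    header_no = 0
    copy_parts: list[str] = []
    master_parts: list[str] = []
    expect_copy = True
    for line_no, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        if not line.startswith(" "):
            if header is not None:
                yield header, copy_parts, master_parts, header_no
            header = line.split()
            header_no = line_no
            copy_parts, master_parts = [], []
            expect_copy = True
            continue
        if header is None:
            raise RepeatIOError("alignment line before any block header", line_no)
        tokens = line.split()
        if len(tokens) != 4:
            raise RepeatIOError(
                f"expected '<name> <start> <seq> <end>', got {len(tokens)} fields",
                line_no,
            )
        if expect_copy:
            copy_parts.append(tokens[2])
        else:
            master_parts.append(tokens[2])
        expect_copy = not expect_copy
    if header is not None:
        yield header, copy_parts, master_parts, header_no


def parse_repeat_alignments(
    out_table: TextIO, align_file: TextIO
) -> list[RepeatAlignment]:
    """Join .align blocks to .out records and normalize coordinates.

    Blocks are joined on (chromosome, genomic coordinates, subfamily);
    unmatched or ambiguously matched blocks are dropped and their count
    logged. Minus-strand blocks are reverse-complemented into consensus
    orientation.
    """
    out_rows = parse_out_table(out_table)
    index: dict[tuple, list[dict]] = {}
    for row in out_rows:
        key = (row["chromosome"], row["g_start"], row["g_end"], row["subfamily"])
        index.setdefault(key, []).append(row)

    alignments: list[RepeatAlignment] = []
    n_unmatched = 0
    for tokens, copy_parts, master_parts, line_no in _iter_align_blocks(align_file):
        head = _parse_out_row(tokens, line_no)
        copy_aln = "".join(copy_parts)
        master_aln = "".join(master_parts)
        if len(copy_aln) != len(master_aln):
            raise RepeatIOError(
                f"unequal gapped lengths ({len(copy_aln)} vs {len(master_aln)})",
                line_no,
            )
        if head["strand"] == "-":
            copy_aln = reverse_complement(copy_aln)
            master_aln = reverse_complement(master_aln)
        key = (head["chromosome"], head["g_start"], head["g_end"], head["subfamily"])
        matches = index.get(key, [])
        if len(matches) != 1:
            n_unmatched += 1
            continue
        row = matches[0]
        aln = RepeatAlignment(
            copy_id=row["copy_id"],
            subfamily=row["subfamily"],
            chromosome=row["chromosome"],
            g_start=row["g_start"],
            g_end=row["g_end"],
            strand=row["strand"],
            master_aln=master_aln,
            copy_aln=copy_aln,
            m_start=row["r_start"],
            repeat_class=row["repeat_class"],
        )
        aln.validate()
        alignments.append(aln)
    if n_unmatched:
        logger.warning(
            "dropped %d .align block(s) without a unique .out match", n_unmatched
        )
    return alignments


def _out_row_fields(a: RepeatAlignment) -> list[str]:
    n_cols = len(a.master_aln)
    mismatch = sum(
        1
        for m, c in zip(a.master_aln, a.copy_aln)
        if m != "-" and c != "-" and m.upper() != c.upper()
    )
    sites = sum(1 for m, c in zip(a.master_aln, a.copy_aln) if m != "-" and c != "-")
    div = 100.0 * mismatch / sites if sites else 0.0
    del_pct = 100.0 * a.copy_aln.count("-") / n_cols if n_cols else 0.0
    ins_pct = 100.0 * a.master_aln.count("-") / n_cols if n_cols else 0.0
    return [
        "1000",
        f"{div:.1f}",
        f"{del_pct:.1f}",
        f"{ins_pct:.1f}",
        a.chromosome,
        str(a.g_start + 1),
        str(a.g_end),
        "(0)",
        "+" if a.strand == "+" else "C",
        a.subfamily,
        a.repeat_class,
        str(a.m_start + 1),
        str(a.m_end),
        "(0)",
        str(a.copy_id),
    ]


def write_out(alignments: Iterable[RepeatAlignment], stream: TextIO) -> None:
    """Write the .out dialect (3 header lines then one row per alignment)."""
    stream.write(_OUT_HEADER)
    for a in alignments:
        stream.write(" ".join(_out_row_fields(a)) + "\n")


def write_align(
    alignments: Iterable[RepeatAlignment], stream: TextIO, width: int = 50
) -> None:
    """Write the .align dialect (block header + interleaved sequence lines)."""
    for a in alignments:
        stream.write(" ".join(_out_row_fields(a)) + "\n")
        copy_aln, master_aln = a.copy_aln, a.master_aln
        if a.strand == "-":
            # stored with the copy line in plus-strand genomic orientation
            copy_aln = reverse_complement(copy_aln)
            master_aln = reverse_complement(master_aln)
        g_pos = a.g_start
        m_pos = a.m_end if a.strand == "-" else a.m_start
        for i in range(0, len(copy_aln), width):
            c_chunk = copy_aln[i : i + width]
            m_chunk = master_aln[i : i + width]
            c_n = len(c_chunk) - c_chunk.count("-")
            m_n = len(m_chunk) - m_chunk.count("-")
            stream.write(
                f"  {a.chromosome} {g_pos + 1} {c_chunk} {g_pos + c_n}\n"
            )
            if a.strand == "-":
                stream.write(
                    f"  {a.subfamily} {m_pos} {m_chunk} {m_pos - m_n + 1}\n"
                )
                m_pos -= m_n
            else:
                stream.write(
                    f"  {a.subfamily} {m_pos + 1} {m_chunk} {m_pos + m_n}\n"
                )
                m_pos += m_n
            g_pos += c_n
        stream.write("\n")


# ---------------------------------------------------------------------------
# recombination map / annotation / polymorphisms
# ---------------------------------------------------------------------------


def parse_recomb_map(stream: TextIO) -> RecombMap:
    """Read a tab-delimited (chromosome, start, end, cM/Mb) map; header optional."""
    first = stream.readline()
    if not first:
        return RecombMap(
            pd.DataFrame(columns=["chromosome", "start", "end", "rate"])
        )
    tokens = first.rstrip("\n").split("\t")
    has_header = False
    try:
        int(tokens[1])
    except (ValueError, IndexError):
        has_header = True
    body = stream.read()
    text = body if has_header else first + body
    df = pd.read_csv(
        _stdio.StringIO(text),
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "rate"],
        dtype={"chromosome": str},
        float_precision="round_trip",
    )
    return RecombMap(df)


def write_recomb_map(rmap: RecombMap, stream: TextIO) -> None:
    rmap.table.to_csv(
        stream, sep="\t", header=False, index=False,
        columns=["chromosome", "start", "end", "rate"],
    )


def parse_annotation(
    stream: TextIO, format: str = "BED12", chrom_sizes: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Read gene models with exon structure from BED12 or GFF3."""
    fmt = format.upper()
    if fmt == "BED12":
        genes = _parse_bed12(stream)
    elif fmt == "GFF3":
        genes = _parse_gff3(stream)
    else:
        raise RepeatIOError(f"unknown annotation format {format!r}")
    return GenomeAnnotation(genes, chrom_sizes=chrom_sizes or {})


def _parse_bed12(stream: TextIO) -> list[Gene]:
    genes = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise RepeatIOError(f"BED12 needs 12 fields, got {len(f)}", line_no)
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise RepeatIOError("block count mismatch", line_no)
        exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
        genes.append(Gene(name, chrom, start, end, strand, sorted(exons)))
    return genes


def _parse_gff3(stream: TextIO) -> list[Gene]:
    attr_id = re.compile(r"(?:^|;)ID=([^;]+)")
    attr_parent = re.compile(r"(?:^|;)Parent=([^;]+)")
    genes: dict[str, Gene] = {}
    exon_buffer: list[tuple[str, int, int]] = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise RepeatIOError(f"GFF3 needs 9 fields, got {len(f)}", line_no)
        chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
        start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
        if ftype == "gene":
            m = attr_id.search(attrs)
            name = m.group(1) if m else f"gene{line_no}"
            genes[name] = Gene(name, chrom, start0, end0, strand, [])
        elif ftype == "exon":
            m = attr_parent.search(attrs)
            if not m:
                raise RepeatIOError("exon without Parent attribute", line_no)
            exon_buffer.append((m.group(1), start0, end0))
    for parent, s, e in exon_buffer:
        if parent not in genes:
            raise RepeatIOError(f"exon references unknown gene {parent!r}")
        genes[parent].exons.append((s, e))
    out = []
    for g in genes.values():
        g.exons.sort()
        out.append(g)
    return out


def write_annotation(
    annotation: GenomeAnnotation, stream: TextIO, format: str = "BED12"
) -> None:
    fmt = format.upper()
    if fmt == "BED12":
        for g in annotation.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            stream.write(
                "\t".join(
                    [
                        g.chromosome, str(g.start), str(g.end), g.name, "0",
                        g.strand, str(g.start), str(g.end), "0",
                        str(len(g.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )
    elif fmt == "GFF3":
        stream.write("##gff-version 3\n")
        for g in annotation.genes:
            stream.write(
                "\t".join(
                    [g.chromosome, "teindel", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", f"ID={g.name}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                stream.write(
                    "\t".join(
                        [g.chromosome, "teindel", "exon", str(s + 1), str(e),
                         ".", g.strand, ".", f"ID={g.name}.e{i};Parent={g.name}"]
                    )
                    + "\n"
                )
    else:
        raise RepeatIOError(f"unknown annotation format {format!r}")


def parse_polymorphisms(stream: TextIO) -> list[PolymorphicIndel]:
    """Read a tab-delimited (chrom, pos, kind, MAF, context) indel table."""
    out = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if f[0] in ("chromosome", "chrom"):
            continue
        if len(f) < 5:
            raise RepeatIOError(f"expected 5 fields, got {len(f)}", line_no)
        rec = PolymorphicIndel(f[0], int(f[1]), f[2], float(f[3]), f[4])
        try:
            rec.validate()
        except RepeatIOError as exc:
            raise RepeatIOError(str(exc), line_no) from None
        out.append(rec)
    return out


def write_polymorphisms(records: Iterable[PolymorphicIndel], stream: TextIO) -> None:
    stream.write("chromosome\tposition\tkind\tmaf\tcontext\n")
    for r in records:
        stream.write(
            f"{r.chromosome}\t{r.position}\t{r.kind}\t{r.maf:.6g}\t{r.context}\n"
        )
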