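"""Target panel model: gene/exon targets, amplicon design and design QC.

The panel is the assay's genomic footprint: a set of clinically actionable
exons, each tiled by short overlapping PCR amplicons.  Amplicons are kept
deliberately short (<=150 bp including primers) so that fragmented FFPE
templates can still be amplified.  This module holds the domain types, the
tab-separated panel/manifest readers and writers, the design-rule validator
and simple design statistics.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class PanelFormatError(ValueError):
    """A panel or manifest file is structurally malformed."""


class PanelValidationError(ValueError):
    """Panel content violates an internal invariant."""


class PoolStrand(str, enum.Enum):
    FORWARD_POOL = "FORWARD_POOL"
    REVERSE_POOL = "REVERSE_POOL"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise PanelValidationError(f"bad interval {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.contig, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return merged


def subtract_intervals(iv: GenomicInterval, others) -> list[GenomicInterval]:
    """Parts of ``iv`` not covered by any interval in ``others``."""
    pieces = [(iv.start, iv.end)]
    for other in others:
        if other.contig != iv.contig:
            continue
        nxt = []
        for s, e in pieces:
            if other.end <= s or other.start >= e:
                nxt.append((s, e))
                continue
            if other.start > s:
                nxt.append((s, other.start))
            if other.end < e:
                nxt.append((other.end, e))
        pieces = nxt
    return [GenomicInterval(iv.contig, s, e) for s, e in pieces if e > s]


@dataclass(frozen=True)
class GeneTarget:
    """One gene's contribution to the panel: transcript and hotspot exons."""

    gene_symbol: str
    transcript_accession: str
    exon_numbers: tuple[int, ...]
    hotspot_note: str = ""

    def __post_init__(self):
        if not self.exon_numbers:
            raise PanelValidationError(f"{self.gene_symbol}: empty exon list")
        if any(e <= 0 for e in self.exon_numbers):
            raise PanelValidationError(f"{self.gene_symbol}: exon numbers must be positive")
        if list(self.exon_numbers) != sorted(set(self.exon_numbers)):
            raise PanelValidationError(
                f"{self.gene_symbol}: exon numbers must be strictly increasing"
            )


@dataclass(frozen=True)
class Amplicon:
    """A primer pair plus the insert it amplifies.

    The insert interval is flanked immediately by the two primer intervals;
    ``fwd_primer_seq`` is the top-strand sequence of the forward primer and
    ``rev_primer_seq`` the sequence as it appears at the start of read 2
    (reverse complement of the top strand under the reverse primer).
    """

    amplicon_id: str
    contig: str
    insert_start: int
    insert_end: int
    fwd_primer_start: int
    fwd_primer_end: int
    rev_primer_start: int
    rev_primer_end: int
    pool_strand: PoolStrand
    fwd_primer_seq: str
    rev_primer_seq: str

    def __post_init__(self):
        if self.fwd_primer_end != self.insert_start or self.rev_primer_start != self.insert_end:
            raise PanelValidationError(
                f"{self.amplicon_id}: primer intervals must flank the insert exactly"
            )
        if self.fwd_primer_start >= self.fwd_primer_end or self.rev_primer_start >= self.rev_primer_end:
            raise PanelValidationError(f"{self.amplicon_id}: empty primer interval")
        if len(self.fwd_primer_seq) != self.fwd_primer_end - self.fwd_primer_start:
            raise PanelValidationError(f"{self.amplicon_id}: fwd primer sequence/interval mismatch")
        if len(self.rev_primer_seq) != self.rev_primer_end - self.rev_primer_start:
            raise PanelValidationError(f"{self.amplicon_id}: rev primer sequence/interval mismatch")

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start

    @property
    def length(self) -> int:
        """Total amplicon length, primers included."""
        return self.rev_primer_end - self.fwd_primer_start

    @property
    def insert_interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.insert_start, self.insert_end)


@dataclass
class PanelDesign:
    """Gene targets plus (optionally) the amplicon tiling that covers them.

    ``exon_regions`` are the raw exon intervals; ``target_regions`` are the
    same intervals extended by the intronic padding actually designed, so a
    region's padding can be recovered as ``exon.start - region.start`` /
    ``region.end - exon.end``.
    """

    genes: list[GeneTarget] = field(default_factory=list)
    exon_regions: list[GenomicInterval] = field(default_factory=list)
    target_regions: list[GenomicInterval] = field(default_factory=list)
    amplicons: list[Amplicon] = field(default_factory=list)

    def __post_init__(self):
        symbols = [g.gene_symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            raise PanelValidationError("duplicate gene symbol in panel")
        if self.exon_regions and len(self.exon_regions) != len(self.target_regions):
            raise PanelValidationError("exon_regions and target_regions must be parallel")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_exon_targets(self) -> int:
        return sum(len(g.exon_numbers) for g in self.genes)

    def footprint(self) -> list[GenomicInterval]:
        """Merged padded target regions."""
        return merge_intervals(self.target_regions)

    def total_target_bp(self) -> int:
        return sum(iv.length for iv in self.footprint())

    def amplicon_for(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def exclusive_zones(self) -> dict[str, list[GenomicInterval]]:
        """Per amplicon, the insert pieces covered by no other amplicon.

        Variants placed here are observed by a single amplicon's reads, so a
        simulated allele fraction is not diluted by overlap tiling.
        """
        zones: dict[str, list[GenomicInterval]] = {}
        for a in self.amplicons:
            others = [
                b.insert_interval
                for b in self.amplicons
                if b.amplicon_id != a.amplicon_id and b.insert_interval.overlaps(a.insert_interval)
            ]
            zones[a.amplicon_id] = subtract_intervals(a.insert_interval, others)
        return zones


# ---------------------------------------------------------------------------
# Panel table input/output


def load_panel_table(path) -> PanelDesign:
    """Read a gene/transcript/exon panel TSV into a PanelDesign (genes only).

    Expected header: ``gene  transcript  exons  note`` (note optional), with
    exons as comma-separated positive integers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelFormatError(f"{path}: empty panel table")
    for col in ("gene", "transcript", "exons"):
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing required column {col!r}")
    genes = []
    for i, row in df.iterrows():
        try:
            exons = tuple(int(x) for x in str(row["exons"]).split(",") if x.strip())
        except ValueError:
            raise PanelFormatError(f"{path}: row {i + 1} ({row['gene']}): unparseable exon list")
        if not exons:
            raise PanelFormatError(f"{path}: row {i + 1} ({row['gene']}): empty exon list")
        note = "" if "note" not in df.columns or pd.isna(row.get("note")) else str(row["note"])
        genes.append(GeneTarget(str(row["gene"]), str(row["transcript"]), exons, note))
    return PanelDesign(genes=genes)


def write_panel_table(design: PanelDesign, path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("gene\ttranscript\texons\tnote\n")
        for g in design.genes:
            exons = ",".join(str(e) for e in g.exon_numbers)
            fh.write(f"{g.gene_symbol}\t{g.transcript_accession}\t{exons}\t{g.hotspot_note}\n")


# ---------------------------------------------------------------------------
# Amplicon manifest input/output (BED6 inserts + primer TSV + target BED)


def write_manifest(design: PanelDesign, bed_path, primer_path, targets_path=None) -> None:
    """Write amplicon inserts as BED6 and primers as a companion TSV.

    The BED name column carries the amplicon id and the strand column the
    pool tag (+ for the forward pool).  Target regions, when requested, go
    to an 8-column BED whose thickStart/thickEnd columns hold the unpadded
    exon interval.
    """
    with Path(bed_path).open("w") as fh:
        for a in design.amplicons:
            strand = "+" if a.pool_strand is PoolStrand.FORWARD_POOL else "-"
            fh.write(
                f"{a.contig}\t{a.insert_start}\t{a.insert_end}\t{a.amplicon_id}\t0\t{strand}\n"
            )
    with Path(primer_path).open("w") as fh:
        fh.write(
            "amplicon_id\tfwd_primer_seq\trev_primer_seq\tfwd_start\tfwd_end\trev_start\trev_end\n"
        )
        for a in design.amplicons:
            fh.write(
                f"{a.amplicon_id}\t{a.fwd_primer_seq}\t{a.rev_primer_seq}\t"
                f"{a.fwd_primer_start}\t{a.fwd_primer_end}\t{a.rev_primer_start}\t{a.rev_primer_end}\n"
            )
    if targets_path is not None:
        with Path(targets_path).open("w") as fh:
            for region, exon in zip(design.target_regions, design.exon_regions):
                fh.write(
                    f"{region.contig}\t{region.start}\t{region.end}\ttarget\t0\t+\t"
                    f"{exon.start}\t{exon.end}\n"
                )


def load_manifest(bed_path, primer_path) -> list[Amplicon]:
    primers = pd.read_csv(primer_path, sep="\t", comment="#", dtype={"amplicon_id": str})
    primer_rows = {row.amplicon_id: row for row in primers.itertuples()}
    amplicons = []
    with Path(bed_path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise PanelFormatError(f"{bed_path}: expected BED6, got {len(fields)} columns")
            contig, start, end, name, _score, strand = fields[:6]
            if name not in primer_rows:
                raise PanelFormatError(f"{bed_path}: amplicon {name} missing from primer TSV")
            p = primer_rows[name]
            amplicons.append(
                Amplicon(
                    amplicon_id=name,
                    contig=contig,
                    insert_start=int(start),
                    insert_end=int(end),
                    fwd_primer_start=int(p.fwd_start),
                    fwd_primer_end=int(p.fwd_end),
                    rev_primer_start=int(p.rev_start),
                    rev_primer_end=int(p.rev_end),
                    pool_strand=PoolStrand.FORWARD_POOL if strand == "+" else PoolStrand.REVERSE_POOL,
                    fwd_primer_seq=str(p.fwd_primer_seq),
                    rev_primer_seq=str(p.rev_primer_seq),
                )
            )
    return amplicons


def load_targets_bed(path) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Read the 8-column target BED back into (target_regions, exon_regions)."""
    targets, exons = [], []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            targets.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            exons.append(GenomicInterval(f[0], int(f[6]), int(f[7])))
    return targets, exons


# ---------------------------------------------------------------------------
# Design validation


@dataclass(frozen=True)
class DesignConstraints:
    """Design rules the amplicon tiling must satisfy.

    Defaults mirror the assay's stated constraints: total amplicon length
    120-150 bp, primers 22-30 bases, at least 5 bp of intronic padding per
    exon side, >=1 base of overlap between adjacent amplicons, full target
    coverage, moderate primer GC, and primer footprints clear of a supplied
    common-SNP position blacklist.
    """

    amplicon_length_bounds: tuple[int, int] = (120, 150)
    primer_length_bounds: tuple[int, int] = (22, 30)
    min_exon_padding: int = 5
    min_tiling_overlap: int = 1
    primer_gc_bounds: tuple[float, float] = (0.15, 0.85)
    snp_blacklist: frozenset = frozenset()


@dataclass(frozen=True)
class Violation:
    rule: str
    amplicon_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def passed(self) -> bool:
        return not self.violations


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def validate_design(design: PanelDesign, constraints: DesignConstraints | None = None) -> ValidationReport:
    """Check every design rule; violations are data, not exceptions."""
    c = constraints or DesignConstraints()
    if not design.amplicons or not design.target_regions:
        raise PanelValidationError("validate_design needs >=1 amplicon and >=1 target region")
    violations: list[Violation] = []

    lo, hi = c.amplicon_length_bounds
    plo, phi = c.primer_length_bounds
    glo, ghi = c.primer_gc_bounds
    for a in design.amplicons:
        if not lo <= a.length <= hi:
            violations.append(
                Violation("amplicon_length", a.amplicon_id, f"length {a.length} outside [{lo},{hi}]")
            )
        for side, plen, seq, span in (
            ("fwd", a.fwd_primer_end - a.fwd_primer_start, a.fwd_primer_seq,
             (a.fwd_primer_start, a.fwd_primer_end)),
            ("rev", a.rev_primer_end - a.rev_primer_start, a.rev_primer_seq,
             (a.rev_primer_start, a.rev_primer_end)),
        ):
            if not plo <= plen <= phi:
                violations.append(
                    Violation("primer_length", a.amplicon_id, f"{side} primer {plen} outside [{plo},{phi}]")
                )
            gc = _gc_fraction(seq)
            if not glo <= gc <= ghi:
                violations.append(
                    Violation("primer_gc", a.amplicon_id, f"{side} primer GC {gc:.2f} outside [{glo},{ghi}]")
                )
            for contig, pos in c.snp_blacklist:
                if contig == a.contig and span[0] <= pos < span[1]:
                    violations.append(
                        Violation("primer_snp", a.amplicon_id, f"{side} primer overlaps SNP {contig}:{pos}")
                    )

    # padding per exon side
    for region, exon in zip(design.target_regions, design.exon_regions):
        pad_left = exon.start - region.start
        pad_right = region.end - exon.end
        if min(pad_left, pad_right) < c.min_exon_padding:
            violations.append(
                Violation(
                    "exon_padding",
                    "",
                    f"{region.contig}:{exon.start}-{exon.end} padding ({pad_left},{pad_right}) "
                    f"< {c.min_exon_padding}",
                )
            )

    # coverage and tiling overlap per target region
    inserts = [a.insert_interval for a in design.amplicons]
    covered = merge_intervals(inserts)
    for region in design.target_regions:
        gaps = subtract_intervals(region, covered)
        for gap in gaps:
            violations.append(
                Violation("target_coverage", "", f"uncovered target bases {gap.contig}:{gap.start}-{gap.end}")
            )
        tiling = sorted(
            (a for a in design.amplicons if a.insert_interval.overlaps(region)),
            key=lambda a: a.insert_start,
        )
        for prev, nxt in zip(tiling, tiling[1:]):
            overlap = prev.insert_end - nxt.insert_start
            if overlap < c.min_tiling_overlap:
                violations.append(
                    Violation(
                        "tiling_overlap",
                        nxt.amplicon_id,
                        f"overlap with {prev.amplicon_id} is {overlap} < {c.min_tiling_overlap}",
                    )
                )
    return ValidationReport(violations)


# ---------------------------------------------------------------------------
# Design statistics


@dataclass(frozen=True)
class DesignStats:
    n_amplicons: int
    amplicon_length_min: int
    amplicon_length_median: float
    amplicon_length_max: int
    insert_length_min: int
    insert_length_median: float
    insert_length_max: int
    primer_length_min: int
    primer_length_median: float
    primer_length_max: int
    total_target_bp: int
    per_gene_exon_counts: dict


def design_stats(design: PanelDesign) -> DesignStats:
    """Summaries over amplicon total lengths (primers included) and primers.

    The median of an even-length list is the mean of the two central values
    (``statistics.median`` semantics).
    """
    if not design.amplicons:
        raise PanelValidationError("design_stats needs >=1 amplicon")
    lengths = [a.length for a in design.amplicons]
    inserts = [a.insert_length for a in design.amplicons]
    primers = [len(a.fwd_primer_seq) for a in design.amplicons] + [
        len(a.rev_primer_seq) for a in design.amplicons
    ]
    return DesignStats(
        n_amplicons=len(design.amplicons),
        amplicon_length_min=min(lengths),
        amplicon_length_median=statistics.median(lengths),
        amplicon_length_max=max(lengths),
        insert_length_min=min(inserts),
        insert_length_median=statistics.median(inserts),
        insert_length_max=max(inserts),
        primer_length_min=min(primers),
        primer_length_median=statistics.median(primers),
        primer_length_max=max(primers),
        total_target_bp=design.total_target_bp(),
        per_gene_exon_counts={g.gene_symbol: len(g.exon_numbers) for g in design.genes},
    )
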