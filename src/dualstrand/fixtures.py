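"""Desk-scale fixtures: the 16-gene panel table, a toy reference and a
150-amplicon tiling, plus the printed columns of the reference-standard
control sample used for concordance regression tests.

Real genomic coordinates for the assay are not redistributable, so the
fixture generator fabricates one contig per gene and lays the 48 hotspot
exons onto it.  Exon sizes (60-220 bp) are drawn so that tiling with short
inserts yields exactly 150 amplicons; amplicon totals stay within the
120-150 bp envelope with 22-30 base primers, adjacent tiles overlap by at
least one base and every padded exon base is covered.  Regeneration from
the same seed is byte-identical.
"""

from __future__ import annotations

import numpy as np

from .panel import (
    Amplicon,
    DesignConstraints,
    GeneTarget,
    GenomicInterval,
    PanelDesign,
    PoolStrand,
    validate_design,
)
from .variants import revcomp

DEFAULT_FIXTURE_SEED = 7
EXON_PADDING = (5, 5)
# the alternative asymmetric padding profile observed after primer trimming
PADDING_PROFILES = {"symmetric5": (5, 5), "asymmetric": (7, 6)}

#: gene, transcript accession, hotspot exons, note
PANEL_ROWS = [
    ("AKT1", "NM_001014431.1", (3,), ""),
    ("ALK", "NM_004304.1", (23, 24, 25), ""),
    ("BRAF", "NM_004333.4", (11, 15), ""),
    ("EGFR", "NM_005228.3", (18, 19, 20, 21), ""),
    ("ERBB2", "NM_004448.2", (20,), ""),
    ("ERBB4", "NM_005235.2", (10, 12), "E452K and R393W"),
    ("FGFR2", "NM_000141.4", (7, 12, 14), "S252, N549, K659"),
    ("FGFR3", "NM_000142.4", (7, 9, 14), "R248 to S249 and G370 to Y373"),
    ("HRAS", "NM_005343.2", (2, 3, 4), ""),
    ("KIT", "NM_000222.2", (8, 9, 11, 13, 17, 18), ""),
    ("KRAS", "NM_033360.2", (2, 3, 4), ""),
    ("MAP2K1", "NM_002755.3", (2,), ""),
    ("MET", "NM_001127500.1", (2, 14, 15, 16, 17, 18, 19, 20), ""),
    ("NRAS", "NM_002524.3", (2, 3, 4), ""),
    ("PDGFRA", "NM_006206.4", (12, 14, 18), ""),
    ("PIK3CA", "NM_006218.2", (10, 21), ""),
]

#: printed per-variant reproducibility table of the multiplex reference
#: standard: label, expected VAF (%), and mean/SD/CV(%) of the estimated VAF
#: for each laboratory and for the inter-laboratory pooling of 6 runs.
TRUQ3_PRINTED = [
    # label, expected, lab1 (mean, sd, cv), lab2 (mean, sd, cv), inter (mean, sd, cv)
    ("BRAF_V600M", 4.0, (3.88, 0.45, 11.55), (4.10, 0.37, 9.09), (4.01, 0.37, 9.16)),
    ("EGFR_E746_A750del", 4.2, (4.13, 0.70, 16.98), (4.01, 0.23, 5.69), (4.06, 0.39, 9.64)),
    ("MET_Y1253D", 4.0, (4.25, 0.48, 11.30), (4.56, 0.33, 7.28), (4.44, 0.38, 8.45)),
    ("KRAS_A146T", 5.0, (4.43, 0.17, 3.89), (5.41, 0.10, 1.78), (5.02, 0.55, 10.86)),
    ("KRAS_G12S", 5.0, (4.78, 0.48, 9.97), (5.26, 0.34, 6.44), (5.07, 0.43, 8.46)),
    ("NRAS_Q61H", 5.0, (4.42, 0.92, 20.84), (5.17, 0.85, 16.47), (4.87, 0.86, 17.70)),
    ("PIK3CA_E542K", 5.0, (5.07, 1.09, 21.50), (6.13, 0.13, 2.12), (5.71, 0.80, 14.05)),
    ("BRAF_V600E", 8.0, (7.57, 0.39, 5.17), (7.13, 0.17, 2.42), (7.30, 0.33, 4.56)),
    ("EGFR_G719S", 16.7, (16.40, 0.44, 2.70), (15.75, 0.42, 2.68), (16.01, 0.51, 3.22)),
    ("MET_L238fs", 20.0, (20.33, 0.29, 1.41), (19.74, 0.39, 1.98), (19.97, 0.45, 2.26)),
    ("KRAS_G13D", 25.0, (25.13, 4.14, 16.49), (26.24, 0.12, 0.46), (25.80, 2.16, 8.38)),
    ("PIK3CA_H1047R", 30.0, (29.09, 0.63, 2.17), (28.45, 0.41, 1.43), (28.71, 0.55, 1.93)),
]

#: variant composition of the two control samples, as (label, gene, kind,
#: detail, target VAF fraction).  detail is (ref_base, alt_base) for an SNV
#: and the deleted length for a deletion.
TRUQ3_VARIANT_SPECS = [
    ("BRAF_V600M", "BRAF", "snv", ("G", "A"), 0.040),
    ("EGFR_E746_A750del", "EGFR", "del", 15, 0.042),
    ("MET_Y1253D", "MET", "snv", ("T", "G"), 0.040),
    ("KRAS_A146T", "KRAS", "snv", ("G", "A"), 0.050),
    ("KRAS_G12S", "KRAS", "snv", ("G", "A"), 0.050),
    ("NRAS_Q61H", "NRAS", "snv", ("A", "T"), 0.050),
    ("PIK3CA_E542K", "PIK3CA", "snv", ("G", "A"), 0.050),
    ("BRAF_V600E", "BRAF", "snv", ("T", "A"), 0.080),
    ("EGFR_G719S", "EGFR", "snv", ("G", "A"), 0.167),
    ("MET_L238fs", "MET", "del", 1, 0.200),
    ("KRAS_G13D", "KRAS", "snv", ("G", "A"), 0.250),
    ("PIK3CA_H1047R", "PIK3CA", "snv", ("A", "G"), 0.300),
]

#: FFPE-derived quantitative multiplex control: an SNV detectable at 1%,
#: the 15-bp deletion at 2% and an SNV at 3%.
FFPE_QM_VARIANT_SPECS = [
    ("EGFR_T790M", "EGFR", "snv", ("C", "T"), 0.010),
    ("EGFR_E746_A750del", "EGFR", "del", 15, 0.020),
    ("EGFR_L858R", "EGFR", "snv", ("T", "G"), 0.030),
]

_BASES = np.array(list("ACGT"))
_CONTIG_FLANK = 400
_INTRON_GAP = 250
_N_AMPLICONS = 150


def _tile_counts(rng: np.random.Generator, n_exons: int, total: int) -> np.ndarray:
    counts = rng.integers(2, 5, size=n_exons)
    order = list(rng.permutation(n_exons))
    i = 0
    while counts.sum() != total:
        idx = order[i % n_exons]
        if counts.sum() > total and counts[idx] > 2:
            counts[idx] -= 1
        elif counts.sum() < total and counts[idx] < 4:
            counts[idx] += 1
        i += 1
    return counts


def _tile_starts(a: int, b: int, insert_len: int, n: int) -> list[int]:
    """Evenly spaced insert start positions covering [a, b) with overlap >=1."""
    span = b - a
    if n == 1:
        return [a - (insert_len - span) // 2] if insert_len >= span else [a]
    return [a + round(k * (span - insert_len) / (n - 1)) for k in range(n)]


def build_toy_design(
    seed: int = DEFAULT_FIXTURE_SEED,
    padding: tuple[int, int] = EXON_PADDING,
) -> tuple[PanelDesign, dict[str, str]]:
    """Fabricate a reference genome plus a 150-amplicon panel over it.

    Returns the design and a ``{contig: sequence}`` reference.  One contig
    per gene; exons carry the gene's hotspot exon numbers from the panel
    table.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_exons = sum(len(rows[2]) for rows in PANEL_ROWS)
    counts = _tile_counts(rng, n_exons, _N_AMPLICONS)

    genes = [GeneTarget(g, t, e, note) for g, t, e, note in PANEL_ROWS]
    reference: dict[str, str] = {}
    exon_regions: list[GenomicInterval] = []
    target_regions: list[GenomicInterval] = []
    amplicons: list[Amplicon] = []
    pad_l, pad_r = padding

    exon_idx = 0
    for gene, _transcript, exon_numbers, _note in PANEL_ROWS:
        cursor = _CONTIG_FLANK
        exon_layout = []  # (exon interval, tile count, insert length)
        for _exon_number in exon_numbers:
            c = int(counts[exon_idx])
            insert_len = int(rng.integers(70, 77) if c == 4 else rng.integers(70, 93))
            lo = (c - 1) * (insert_len - 1) + 2
            hi = min(c * (insert_len - 1) + 1, 220 + pad_l + pad_r)
            target_len = int(rng.integers(lo, hi + 1))
            exon_len = target_len - pad_l - pad_r
            exon_iv = GenomicInterval(gene, cursor, cursor + exon_len)
            exon_layout.append((exon_iv, c, insert_len))
            cursor += exon_len + _INTRON_GAP
            exon_idx += 1
        contig_len = cursor - _INTRON_GAP + _CONTIG_FLANK
        seq = "".join(_BASES[rng.integers(0, 4, size=contig_len)])
        reference[gene] = seq

        for (exon_iv, c, insert_len), exon_number in zip(exon_layout, exon_numbers):
            region = GenomicInterval(gene, exon_iv.start - pad_l, exon_iv.end + pad_r)
            exon_regions.append(exon_iv)
            target_regions.append(region)
            starts = _tile_starts(region.start, region.end, insert_len, c)
            for k, s in enumerate(starts):
                e = s + insert_len
                p1 = int(rng.integers(22, 31))
                p2_lo = max(22, 120 - insert_len - p1)
                p2_hi = min(30, 150 - insert_len - p1)
                p2 = int(rng.integers(p2_lo, p2_hi + 1))
                amplicons.append(
                    Amplicon(
                        amplicon_id=f"{gene}_x{exon_number}_t{k}",
                        contig=gene,
                        insert_start=s,
                        insert_end=e,
                        fwd_primer_start=s - p1,
                        fwd_primer_end=s,
                        rev_primer_start=e,
                        rev_primer_end=e + p2,
                        pool_strand=PoolStrand.FORWARD_POOL if k % 2 == 0 else PoolStrand.REVERSE_POOL,
                        fwd_primer_seq=seq[s - p1 : s],
                        rev_primer_seq=revcomp(seq[e : e + p2]),
                    )
                )

    design = PanelDesign(
        genes=genes,
        exon_regions=exon_regions,
        target_regions=target_regions,
        amplicons=amplicons,
    )
    assert len(design.amplicons) == _N_AMPLICONS
    return design, reference


def toy_snp_blacklist(design: PanelDesign, rng_seed: int = 11, n: int = 24) -> frozenset:
    """Common-SNP positions that deliberately avoid all primer footprints."""
    rng = np.random.default_rng(rng_seed)
    positions = set()
    amps = design.amplicons
    primer_spans = [
        (a.contig, a.fwd_primer_start, a.fwd_primer_end) for a in amps
    ] + [(a.contig, a.rev_primer_start, a.rev_primer_end) for a in amps]
    while len(positions) < n:
        a = amps[int(rng.integers(len(amps)))]
        pos = int(rng.integers(a.insert_start, a.insert_end))
        if any(c == a.contig and s <= pos < e for c, s, e in primer_spans):
            continue
        positions.add((a.contig, pos))
    return frozenset(positions)


def default_constraints(design: PanelDesign) -> DesignConstraints:
    return DesignConstraints(snp_blacklist=toy_snp_blacklist(design))


def _self_check(design: PanelDesign) -> None:  # pragma: no cover - debug aid
    report = validate_design(design, default_constraints(design))
    if not report.passed:
        raise AssertionError(report.violations[:5])
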