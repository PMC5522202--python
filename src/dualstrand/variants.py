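"""Variant representation, left-normalization and VCF input/output.

All coordinates in this package are 0-based, half-open (BED convention);
they are converted to 1-based only when a record is written to VCF.
Alleles follow the VCF anchored style: an SNV is 1/1 bases, an MNV k/k,
a deletion k/1 and an insertion 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def variant_kind(ref: str, alt: str) -> str:
    """Classify an anchored REF/ALT pair as snv, mnv, ins, del or complex."""
    if len(ref) == len(alt):
        return "snv" if len(ref) == 1 else "mnv"
    if len(ref) > len(alt):
        return "del" if len(alt) == 1 else "complex"
    return "ins" if len(ref) == 1 else "complex"


def left_normalize(contig_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and minimize an anchored variant representation.

    Implements the standard normalization loop: truncate shared trailing
    bases (extending to the left with reference sequence whenever an allele
    would become empty), then truncate shared leading bases while both
    alleles are longer than one base.  The result is the unique minimal,
    left-most representation of the haplotype change.

    Parameters
    ----------
    contig_seq:
        Full sequence of the contig the variant lies on.
    pos:
        0-based position of the first REF base.
    ref, alt:
        Anchored allele strings (non-empty).
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    ref = ref.upper()
    alt = alt.upper()
    while True:
        if len(ref) > 1 or len(alt) > 1:
            if ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    if pos == 0:
                        raise ValueError("variant cannot be normalized past contig start")
                    pos -= 1
                    base = contig_seq[pos].upper()
                    ref, alt = base + ref, base + alt
                continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantKey:
    """Identity of a call after normalization; used to match across libraries."""

    contig: str
    pos: int
    ref: str
    alt: str


def _vcf_header(
    reference: Mapping[str, str],
    meta: Mapping[str, str] | None = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=dualstrand")
    for key, value in (meta or {}).items():
        header.add_line(f"##dualstrand_{key}={value}")
    for contig in sorted(reference):
        header.add_line(f"##contig=<ID={contig},length={len(reference[contig])}>")
    return header


def write_truth_vcf(
    path,
    variants: Iterable,
    reference: Mapping[str, str],
    meta: Mapping[str, str] | None = None,
) -> None:
    """Write truth variants (objects with contig/pos/ref/alt/target_vaf/label)."""
    header = _vcf_header(reference, meta)
    header.add_line('##INFO=<ID=TVAF,Number=1,Type=Float,Description="Target variant allele fraction">')
    header.add_line('##INFO=<ID=LABEL,Number=1,Type=String,Description="Variant label">')
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            rec = out.new_record(
                contig=v.contig, start=v.pos, alleles=(v.ref, v.alt), id=v.label or "."
            )
            rec.info["TVAF"] = float(v.target_vaf)
            if v.label:
                rec.info["LABEL"] = v.label
            out.write(rec)


def write_consensus_vcf(
    path,
    calls: Iterable,
    reference: Mapping[str, str],
    meta: Mapping[str, str] | None = None,
) -> None:
    """Write consensus calls with per-library VAF/depth annotations.

    FILTER is PASS for dual-library calls, ``single_library`` for calls seen
    in only one strand library and ``low_depth`` when the missing library had
    insufficient coverage to confirm or deny.
    """
    header = _vcf_header(reference, meta)
    header.add_line('##INFO=<ID=VAF1,Number=1,Type=Float,Description="VAF in library 1">')
    header.add_line('##INFO=<ID=VAF2,Number=1,Type=Float,Description="VAF in library 2">')
    header.add_line('##INFO=<ID=VAFC,Number=1,Type=Float,Description="Combined VAF">')
    header.add_line('##INFO=<ID=DP1,Number=1,Type=Integer,Description="Depth in library 1">')
    header.add_line('##INFO=<ID=DP2,Number=1,Type=Integer,Description="Depth in library 2">')
    header.add_line('##FILTER=<ID=single_library,Description="Detected in one strand library only">')
    header.add_line('##FILTER=<ID=low_depth,Description="Insufficient depth in one library">')
    filter_name = {
        "PASS": "PASS",
        "SINGLE_LIBRARY_REJECTED": "single_library",
        "LOW_DEPTH": "low_depth",
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            rec = out.new_record(contig=c.contig, start=c.pos, alleles=(c.ref, c.alt))
            rec.filter.add(filter_name[c.filter_status])
            if c.vaf_lib1 is not None:
                rec.info["VAF1"] = float(c.vaf_lib1)
            if c.vaf_lib2 is not None:
                rec.info["VAF2"] = float(c.vaf_lib2)
            if c.vaf_combined is not None:
                rec.info["VAFC"] = float(c.vaf_combined)
            if c.depth_lib1 is not None:
                rec.info["DP1"] = int(c.depth_lib1)
            if c.depth_lib2 is not None:
                rec.info["DP2"] = int(c.depth_lib2)
            out.write(rec)


def read_vcf_records(path) -> list[dict]:
    """Read a VCF back into plain dictionaries (0-based positions)."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            records.append(
                {
                    "contig": rec.contig,
                    "pos": rec.start,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "filter": list(rec.filter.keys()) or ["PASS"],
                    "info": dict(rec.info),
                }
            )
    return records
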