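"""Synthetic FFPE-like samples and dual-strand paired-end libraries.

The generator models the physics the dual-strand assay exploits:

* a double-stranded source molecule carries a true variant on *both*
  strands (with probability equal to the target allele fraction), while a
  cytosine-deamination artifact lives on exactly *one* strand;
* formalin fixation fragments DNA; molecules whose drawn fragment length is
  shorter than an amplicon cannot be amplified, which both depresses
  library yield (raising the qPCR ΔQc) and lowers achievable depth;
* each sample yields two libraries: LIB1 sequenced from forward-strand
  templates, LIB2 from reverse-strand templates.  A deamination C->T on a
  reverse-strand template shows up as G->A in forward-reference
  coordinates, confined to LIB2.

Molecules are amplicon-scoped: each amplicon has its own pool of template
fragments, and a truth variant is applied to the single amplicon whose
insert fully contains it.  All randomness flows from the supplied seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import PanelDesign
from .variants import revcomp

LIB1 = "LIB1"  # forward-strand templates
LIB2 = "LIB2"  # reverse-strand templates
FWD = "fwd"
REV = "rev"


@dataclass(frozen=True)
class TruthVariant:
    """A spiked alteration with its intended allele fraction.

    ``pos`` is 0-based; alleles use the anchored VCF style.  The reference
    allele must match the reference sequence at ``pos``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    target_vaf: float
    label: str = ""

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError(f"{self.label}: alleles must be non-empty")
        if not 0 < self.target_vaf <= 1:
            raise ValueError(f"{self.label}: target_vaf must be in (0, 1]")

    def validate_against(self, reference: dict[str, str]) -> None:
        seq = reference.get(self.contig)
        if seq is None or seq[self.pos : self.pos + len(self.ref)].upper() != self.ref.upper():
            raise ValueError(f"{self.label or self.contig}: ref allele mismatch at {self.contig}:{self.pos}")


@dataclass(frozen=True)
class DamageModel:
    """FFPE damage parameters.

    deamination_rate
        Per-cytosine, per-single-strand probability of C->T conversion.
        The default (3e-4) keeps per-site artifact fractions well below the
        1% detection floor; raise it (or use ``jackpot_sites``) to stress
        the consensus filter.
    fragment_length_median / fragment_length_sigma
        Lognormal fragmentation model (bp); a molecule survives an amplicon
        only if its drawn fragment is at least as long as the amplicon.
    crosslink_failure_rate
        Per-molecule probability that crosslinking blocks amplification.
    jackpot_sites
        ``(contig, pos, strand, fraction)`` tuples that force a C->T (fwd)
        or G->A (rev) artifact onto the given fraction of molecules —
        a stand-in for early-cycle PCR jackpots of a damaged base.
    """

    deamination_rate: float = 3e-4
    fragment_length_median: float = 1500.0
    fragment_length_sigma: float = 0.5
    crosslink_failure_rate: float = 0.0
    jackpot_sites: tuple = ()

    def __post_init__(self):
        for p in (self.deamination_rate, self.crosslink_failure_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fragment_length_median <= 0:
            raise ValueError("fragment_length_median must be positive")

    @classmethod
    def for_delta_qc(cls, delta_qc: float, reference_length: int = 130, **kwargs) -> "DamageModel":
        """Fragmentation preset whose amplifiable fraction is ~2**(-delta_qc).

        Solves the lognormal survival P(length >= reference_length) for the
        median, at the default sigma, so the qPCR ΔQc of the resulting pool
        lands near ``delta_qc`` for a typical 130 bp amplicon.
        """
        sigma = kwargs.pop("fragment_length_sigma", 0.5)
        survival = 2.0 ** (-delta_qc)
        mu = math.log(reference_length) - sigma * norm.ppf(1.0 - survival)
        return cls(
            fragment_length_median=math.exp(mu), fragment_length_sigma=sigma, **kwargs
        )


#: named presets spanning the triage bands seen in practice (ΔQc of an
#: intact sample ~0; degraded FFPE extractions span roughly 4-15).
DAMAGE_PRESETS = {
    "intact": DamageModel(),
    "mild": DamageModel.for_delta_qc(1.0),
    "degraded": DamageModel.for_delta_qc(4.3),
    "severe": DamageModel.for_delta_qc(6.6),
    "very_severe": DamageModel.for_delta_qc(10.1),
    "extreme": DamageModel.for_delta_qc(15.1),
}


@dataclass(frozen=True)
class SequencingModel:
    """Read geometry, error model and per-amplicon depth target.

    ``depth`` counts read *pairs* per amplicon per library; each pair is
    merged back into one insert-spanning fragment downstream, so the
    realized per-position depth matches ``depth``.  ``headroom`` is the
    factor by which an undamaged library overshoots the pooling
    concentration; yield-limited (damaged) samples reach full depth only
    while ``headroom * amplifiable_fraction * input_scaling >= 1``.
    """

    error_rate: float = 1e-3
    read_length: int = 100
    depth: float = 1000.0
    depth_dispersion: float = 1000.0
    headroom: float = 32.0
    q_correct: int = 30
    q_error: int = 20

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")
        if self.read_length <= 0 or self.depth < 0:
            raise ValueError("bad read geometry")


@dataclass(slots=True)
class ReadPair:
    """One paired-end read with hidden provenance.

    ``source_*`` fields are ground truth kept for oracle tests; the caller
    never reads them.
    """

    name: str
    r1: str
    q1: str
    r2: str
    q2: str
    source_amplicon: str = ""
    source_molecule: int = -1
    source_strand: str = ""
    source_damaged: bool = False


@dataclass
class LibraryReadSet:
    sample_id: str
    library_id: str
    pairs: list = field(default_factory=list)

    def __len__(self):
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Template pools

Event = tuple[int, str, str]  # (local insert position, ref run, alt run)


@dataclass
class AmpliconTemplates:
    """Per-amplicon molecule pool: survival mask plus sparse per-molecule,
    per-strand edit lists in insert-local top-strand coordinates."""

    amplicon: object
    ref_insert: str
    n_molecules: int
    survived: np.ndarray
    events: dict  # {FWD: {mol: [Event]}, REV: {mol: [Event]}}
    damaged: dict  # {FWD: set(mol), REV: set(mol)} molecules with artifacts

    @property
    def survivor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.survived)


@dataclass
class TemplatePool:
    sample_id: str
    design: PanelDesign
    reference: dict
    n_molecules: int
    amplicons: dict  # amplicon_id -> AmpliconTemplates

    def amplifiable_fraction(self) -> float:
        total = sum(at.n_molecules for at in self.amplicons.values())
        surviving = sum(int(at.survived.sum()) for at in self.amplicons.values())
        return surviving / total if total else 0.0


def _apply_events(seq: str, events: list[Event]) -> str:
    """Apply substitutions (at original coordinates) then indels right-to-left."""
    subs = [e for e in events if len(e[1]) == len(e[2])]
    indels = [e for e in events if len(e[1]) != len(e[2])]
    if subs:
        chars = list(seq)
        for pos, ref, alt in subs:
            chars[pos : pos + len(ref)] = list(alt)
        seq = "".join(chars)
    for pos, ref, alt in sorted(indels, key=lambda e: e[0], reverse=True):
        if len(ref) > len(alt):  # deletion keeps the anchor base
            seq = seq[: pos + len(alt)] + seq[pos + len(ref) :]
        else:  # insertion after the anchor base
            seq = seq[: pos + 1] + alt[len(ref) :] + seq[pos + len(ref) :]
    return seq


def make_sample(
    design: PanelDesign,
    reference: dict,
    variants: list[TruthVariant],
    damage: DamageModel,
    seed: int,
    n_molecules: int = 2000,
    sample_id: str = "sample",
) -> TemplatePool:
    """Build the single-stranded template pool for one sample.

    Every double-stranded source molecule contributes a forward and a
    reverse template.  A truth variant is carried by a molecule (both
    strands) with probability ``target_vaf``; deamination strikes each
    cytosine of each single strand independently at the model rate.
    """
    for v in variants:
        v.validate_against(reference)
        host = [
            a
            for a in design.amplicons
            if a.contig == v.contig and a.insert_start <= v.pos and v.pos + len(v.ref) <= a.insert_end
        ]
        if not host:
            raise ValueError(
                f"variant {v.label or v.contig + ':' + str(v.pos)} lies outside every amplicon insert"
            )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD5]))
    pools: dict[str, AmpliconTemplates] = {}
    for a in sorted(design.amplicons, key=lambda a: a.amplicon_id):
        insert = reference[a.contig][a.insert_start : a.insert_end]
        # fragmentation + crosslink survival
        mu = math.log(damage.fragment_length_median)
        flen = rng.lognormal(mu, damage.fragment_length_sigma, size=n_molecules)
        survived = flen >= a.length
        if damage.crosslink_failure_rate > 0:
            survived &= rng.random(n_molecules) >= damage.crosslink_failure_rate

        events = {FWD: {}, REV: {}}
        damaged = {FWD: set(), REV: set()}

        def add_event(strand, mol, event):
            events[strand].setdefault(int(mol), []).append(event)

        # truth variants carried on both strands of a molecule
        for v in variants:
            if v.contig != a.contig or not (
                a.insert_start <= v.pos and v.pos + len(v.ref) <= a.insert_end
            ):
                continue
            carriers = np.flatnonzero(rng.random(n_molecules) < v.target_vaf)
            local = (v.pos - a.insert_start, v.ref, v.alt)
            for mol in carriers:
                add_event(FWD, mol, local)
                add_event(REV, mol, local)

        # strand-specific deamination: C->T on the forward strand template,
        # G->A (its mirror) on the reverse strand template
        if damage.deamination_rate > 0:
            for strand, base, alt in ((FWD, "C", "T"), (REV, "G", "A")):
                candidates = np.array([i for i, b in enumerate(insert) if b == base], dtype=int)
                if candidates.size == 0:
                    continue
                hits = rng.binomial(candidates.size, damage.deamination_rate, size=n_molecules)
                for mol in np.flatnonzero(hits):
                    chosen = rng.choice(candidates, size=int(hits[mol]), replace=False)
                    for pos in chosen:
                        add_event(strand, mol, (int(pos), base, alt))
                        damaged[strand].add(int(mol))

        for contig, pos, strand, fraction in damage.jackpot_sites:
            if contig != a.contig or not (a.insert_start <= pos < a.insert_end):
                continue
            local_pos = pos - a.insert_start
            base, alt = ("C", "T") if strand == FWD else ("G", "A")
            if insert[local_pos] != base:
                raise ValueError(f"jackpot site {contig}:{pos} is not a {base} on that strand")
            for mol in np.flatnonzero(rng.random(n_molecules) < fraction):
                add_event(strand, mol, (local_pos, base, alt))
                damaged[strand].add(int(mol))

        pools[a.amplicon_id] = AmpliconTemplates(
            amplicon=a,
            ref_insert=insert,
            n_molecules=n_molecules,
            survived=survived,
            events=events,
            damaged=damaged,
        )
    return TemplatePool(
        sample_id=sample_id,
        design=design,
        reference=reference,
        n_molecules=n_molecules,
        amplicons=pools,
    )


# ---------------------------------------------------------------------------
# Library simulation


def _template_insert(at: AmpliconTemplates, mol: int, strand: str) -> str:
    ev = at.events[strand].get(mol)
    return _apply_events(at.ref_insert, ev) if ev else at.ref_insert


def simulate_libraries(
    pool: TemplatePool,
    seqmodel: SequencingModel,
    seed: int,
    concentration: float = 4.0,
    input_scaling: float = 1.0,
) -> tuple[LibraryReadSet, LibraryReadSet]:
    """Sequence the pool into the two strand-specific libraries.

    Per amplicon and library, the number of read pairs is drawn from a
    negative binomial around the depth target, scaled linearly by
    ``concentration`` (relative to the 4 nM pooling standard) and capped by
    the yield model (headroom x amplifiable fraction x input scaling).
    Read 1 runs from the forward-primer end of the amplicon, read 2 from
    the opposite end; substitution errors are applied at the model rate
    with a lowered quality value.
    """
    if not pool.amplicons:
        raise ValueError("empty template pool")
    rl = seqmodel.read_length
    q_ok = chr(33 + seqmodel.q_correct)
    q_err = chr(33 + seqmodel.q_error)
    conc_scale = concentration / 4.0
    readsets = []
    for lib, strand in ((LIB1, FWD), (LIB2, REV)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0, 0 if lib == LIB1 else 1]))
        pairs: list[ReadPair] = []
        for amp_id in sorted(pool.amplicons):
            at = pool.amplicons[amp_id]
            a = at.amplicon
            survivors = at.survivor_indices
            frac = survivors.size / at.n_molecules
            mean = seqmodel.depth * conc_scale * min(1.0, seqmodel.headroom * frac * input_scaling)
            if survivors.size == 0 or mean <= 0:
                continue
            r = seqmodel.depth_dispersion
            n_pairs = int(rng.negative_binomial(r, r / (r + mean)))
            if n_pairs == 0:
                continue
            mols = rng.choice(survivors, size=n_pairs)
            err_counts = rng.binomial(2 * rl, seqmodel.error_rate, size=n_pairs)

            contig_seq = pool.reference[a.contig]
            fwd_flank = contig_seq[a.fwd_primer_start : a.fwd_primer_end]
            rev_flank = contig_seq[a.rev_primer_start : a.rev_primer_end]
            clean_amp = fwd_flank + at.ref_insert + rev_flank
            clean_r1 = clean_amp[:rl]
            clean_r2 = revcomp(clean_amp)[:rl]
            clean_q1 = q_ok * len(clean_r1)
            clean_q2 = q_ok * len(clean_r2)
            has_events = at.events[strand]
            damaged = at.damaged[strand]

            for serial, (mol, n_err) in enumerate(zip(mols, err_counts)):
                mol = int(mol)
                if mol in has_events:
                    amp_seq = fwd_flank + _template_insert(at, mol, strand) + rev_flank
                    r1, q1 = amp_seq[:rl], q_ok * min(rl, len(amp_seq))
                    r2, q2 = revcomp(amp_seq)[:rl], q_ok * min(rl, len(amp_seq))
                else:
                    r1, q1, r2, q2 = clean_r1, clean_q1, clean_r2, clean_q2
                if n_err:
                    len1, len2 = len(r1), len(r2)
                    for p in rng.integers(0, 2 * rl, size=int(n_err)):
                        p = int(p)
                        if p < len1:
                            which, idx = 1, p
                        elif p - rl < len2 and p >= rl:
                            which, idx = 2, p - rl
                        else:
                            continue  # binomial thinning for short reads
                        seq = r1 if which == 1 else r2
                        current = seq[idx]
                        alt = str(rng.choice([b for b in "ACGT" if b != current]))
                        seq = seq[:idx] + alt + seq[idx + 1 :]
                        if which == 1:
                            r1, q1 = seq, q1[:idx] + q_err + q1[idx + 1 :]
                        else:
                            r2, q2 = seq, q2[:idx] + q_err + q2[idx + 1 :]
                pairs.append(
                    ReadPair(
                        name=f"{pool.sample_id}:{lib}:{amp_id}:{serial}",
                        r1=r1,
                        q1=q1,
                        r2=r2,
                        q2=q2,
                        source_amplicon=amp_id,
                        source_molecule=mol,
                        source_strand=strand,
                        source_damaged=mol in damaged,
                    )
                )
        readsets.append(LibraryReadSet(sample_id=pool.sample_id, library_id=lib, pairs=pairs))
    return readsets[0], readsets[1]


# ---------------------------------------------------------------------------
# qPCR quality model


def simulate_qpcr(pool: TemplatePool, reference_pool: TemplatePool, cq0: float = 24.0) -> tuple[float, float]:
    """qPCR Cq values for the sample and the undamaged control.

    Cq = cq0 - log2(amplifiable fraction); a fully dead pool returns +inf.
    """
    def cq(p: TemplatePool) -> float:
        frac = p.amplifiable_fraction()
        return math.inf if frac == 0 else cq0 - math.log2(frac)

    return cq(pool), cq(reference_pool)


# ---------------------------------------------------------------------------
# Reference-standard truth sets


def _place_variant(
    design: PanelDesign,
    reference: dict,
    zones: dict,
    gene: str,
    kind: str,
    detail,
    used: list,
    start_region: int,
) -> tuple[str, int, str, str]:
    """Find a position for a control variant inside a single-amplicon zone."""
    from .variants import left_normalize

    regions = [r for r in design.target_regions if r.contig == gene]
    order = list(range(start_region, len(regions))) + list(range(start_region))
    seq = reference[gene]
    for ri in order:
        region = regions[ri]
        for amp in design.amplicons:
            if amp.contig != gene or not amp.insert_interval.overlaps(region):
                continue
            for zone in zones[amp.amplicon_id]:
                lo = max(zone.start, amp.insert_start + 3)
                hi = min(zone.end, amp.insert_end - 3)
                for pos in range(lo, hi):
                    if kind == "snv":
                        ref_base, alt_base = detail
                        if seq[pos] != ref_base:
                            continue
                        span = (gene, pos, pos + 1)
                    elif kind == "del":
                        k = detail
                        if pos + k + 1 > hi:
                            continue
                        span = (gene, pos, pos + k + 1)
                    elif kind == "mnv":
                        ref_run, alt_run = detail
                        if seq[pos : pos + len(ref_run)] != ref_run or pos + len(ref_run) > hi:
                            continue
                        span = (gene, pos, pos + len(ref_run))
                    else:
                        raise ValueError(kind)
                    if any(c == gene and not (span[2] + 20 <= s or e + 20 <= span[1]) for c, s, e in used):
                        continue
                    if kind == "snv":
                        ref, alt = detail
                        npos, nref, nalt = pos, ref, alt
                    elif kind == "mnv":
                        nref, nalt = detail
                        npos = pos
                    else:
                        k = detail
                        ref = seq[pos : pos + k + 1]
                        alt = seq[pos]
                        npos, nref, nalt = left_normalize(seq, pos, ref, alt)
                        if npos != pos:  # keep only normalization-stable anchors
                            continue
                    used.append(span)
                    return gene, npos, nref, nalt
    raise ValueError(f"could not place a {kind} variant in {gene}")


def make_reference_standards(
    design: PanelDesign, reference: dict, which: str
) -> list[TruthVariant]:
    """Variant sets mimicking the two control samples.

    ``which`` is ``"TRUQ3"`` (12 variants, expected VAF 4-30%, including a
    15-bp and a 1-bp deletion) or ``"FFPE_QM"`` (SNVs at 1% and 3% plus the
    15-bp deletion at 2%).  Placement is deterministic given the design:
    the first suitable position inside a single-amplicon zone of the gene's
    targets.
    """
    from .fixtures import FFPE_QM_VARIANT_SPECS, TRUQ3_VARIANT_SPECS

    specs = {"TRUQ3": TRUQ3_VARIANT_SPECS, "FFPE_QM": FFPE_QM_VARIANT_SPECS}[which]
    zones = design.exclusive_zones()
    used: list = []
    per_gene_counter: dict[str, int] = {}
    variants = []
    for label, gene, kind, detail, vaf in specs:
        start_region = per_gene_counter.get(gene, 0)
        contig, pos, ref, alt = _place_variant(
            design, reference, zones, gene, kind, detail, used, start_region
        )
        per_gene_counter[gene] = start_region + 1
        variants.append(TruthVariant(contig, pos, ref, alt, vaf, label))
    return variants


# ---------------------------------------------------------------------------
# FASTQ and truth-table input/output


def write_fastq(readset: LibraryReadSet, r1_path, r2_path) -> None:
    """Write the pair as two 4-line-record FASTQ files (gzip if *.gz)."""
    def opener(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for p in readset.pairs:
            f1.write(f"@{p.name}\n{p.r1}\n+\n{p.q1}\n")
            f2.write(f"@{p.name}\n{p.r2}\n+\n{p.q2}\n")


def read_fastq_pair(r1_path, r2_path, sample_id: str = "", library_id: str = "") -> LibraryReadSet:
    def records(path):
        path = str(path)
        op = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
        with op as fh:
            while True:
                header = fh.readline().rstrip("\n")
                if not header:
                    return
                seq = fh.readline().rstrip("\n")
                fh.readline()
                qual = fh.readline().rstrip("\n")
                yield header[1:], seq, qual

    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(records(r1_path), records(r2_path)):
        if n1 != n2:
            raise ValueError(f"read name mismatch: {n1} vs {n2}")
        fields = n1.split(":")
        src = fields[2] if len(fields) >= 3 else ""
        pairs.append(ReadPair(name=n1, r1=s1, q1=q1, r2=s2, q2=q2, source_amplicon=src))
    if pairs and not sample_id:
        sample_id = pairs[0].name.split(":")[0]
    if pairs and not library_id:
        library_id = pairs[0].name.split(":")[1]
    return LibraryReadSet(sample_id=sample_id, library_id=library_id, pairs=pairs)


def write_truth_tsv(variants: list[TruthVariant], path, meta: dict | None = None) -> None:
    with Path(path).open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("contig\tpos\tref\talt\ttarget_vaf\tlabel\n")
        for v in variants:
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.target_vaf:.4f}\t{v.label}\n")


def read_truth_tsv(path) -> list[TruthVariant]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str, "ref": str, "alt": str})
    return [
        TruthVariant(r.contig, int(r.pos), r.ref, r.alt, float(r.target_vaf), str(r.label))
        for r in df.itertuples()
    ]
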