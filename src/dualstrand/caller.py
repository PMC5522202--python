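"""Dual-strand amplicon variant caller.

Reads are amplicon copies, so mapping is primer-anchored rather than a
general gapped alignment: read 1 is matched to an amplicon by its
forward-primer prefix (within a mismatch tolerance), both primers are
trimmed, the pair is merged back into a single insert-spanning fragment,
and the fragment is compared against the reference insert — positionally
when lengths agree, otherwise by a banded edit-distance alignment.  Per
library this yields a pileup of substitution/indel observations; a variant
is called per library when it clears the depth/alt-count/VAF floors, and
only variants called independently in *both* strand libraries are reported
PASS.  A chemical artifact lives on one strand, hence in one library, and
is rejected by the consensus.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .panel import PanelDesign
from .simulate import LibraryReadSet
from .variants import VariantKey, left_normalize, revcomp, variant_kind


@dataclass(frozen=True)
class CallerParams:
    """Per-library calling thresholds and sample-level gates.

    Defaults detect a 1% VAF variant at ~1000-2000x per library with high
    power while the dual-library intersection controls artifacts; all are
    overridable.  ``depth_cutoff`` is the sample-level median per-amplicon
    depth below which a library renders the sample not interpretable.
    """

    primer_mismatch_tolerance: int = 2
    base_quality_floor: int = 20
    min_depth: int = 100
    min_alt_count: int = 4
    min_vaf: float = 0.005
    depth_cutoff: int = 700
    mnv_shared_fraction: float = 0.9
    combine: str = "mean"  # or "pooled"

    def __post_init__(self):
        if min(self.primer_mismatch_tolerance, self.base_quality_floor, self.min_depth,
               self.min_alt_count) < 0 or self.min_vaf < 0:
            raise ValueError("thresholds must be non-negative")
        if self.depth_cutoff < 0:
            raise ValueError("depth cutoff must be non-negative")


class FilterStatus(str, enum.Enum):
    PASS = "PASS"
    SINGLE_LIBRARY_REJECTED = "SINGLE_LIBRARY_REJECTED"
    LOW_DEPTH = "LOW_DEPTH"


@dataclass(frozen=True)
class LibraryVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    library_id: str
    alt_count: int
    depth: int
    vaf: float

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref, self.alt)

    @property
    def kind(self) -> str:
        return variant_kind(self.ref, self.alt)


@dataclass(frozen=True)
class ConsensusVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    filter_status: str
    vaf_lib1: float | None = None
    vaf_lib2: float | None = None
    vaf_combined: float | None = None
    depth_lib1: int | None = None
    depth_lib2: int | None = None

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref, self.alt)

    @property
    def kind(self) -> str:
        return variant_kind(self.ref, self.alt)


# ---------------------------------------------------------------------------
# Primer assignment and trimming


@dataclass
class AssignedReads:
    """Trimmed read pairs grouped by amplicon, plus bookkeeping counters."""

    library_id: str
    by_amplicon: dict = field(default_factory=dict)  # amplicon_id -> [(r1, q1, r2, q2)]
    n_assigned: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    """Mismatch count if <= limit else None (early exit)."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return None
    return mism


def assign_and_trim(reads: LibraryReadSet, design: PanelDesign, k: int = 2) -> AssignedReads:
    """Assign each pair to the amplicon whose primer prefix matches read 1.

    A read is assigned to the amplicon with the strictly smallest number of
    prefix mismatches within tolerance ``k``; equal-best ties are discarded
    and counted.  The reverse-primer prefix of read 2 must also match
    within ``k``.  Pairs are kept whole here — because a read can run
    through a short (deletion-bearing) molecule into the opposite primer,
    primer bases are removed from the *merged* fragment
    (:func:`merge_and_trim`), before any pileup sees an observation.
    """
    exact = {}  # primer length -> {prefix: amplicon}
    for a in design.amplicons:
        exact.setdefault(len(a.fwd_primer_seq), {})[a.fwd_primer_seq] = a
    lengths = sorted(exact)
    out = AssignedReads(library_id=reads.library_id)
    for pair in reads.pairs:
        amp = None
        for plen in lengths:
            hit = exact[plen].get(pair.r1[:plen])
            if hit is not None:
                amp = hit
                break
        if amp is None:
            best, best_mism, tie = None, k + 1, False
            for a in design.amplicons:
                plen = len(a.fwd_primer_seq)
                mism = _hamming_leq(pair.r1[:plen], a.fwd_primer_seq, min(k, best_mism))
                if mism is None:
                    continue
                if mism < best_mism:
                    best, best_mism, tie = a, mism, False
                elif mism == best_mism:
                    tie = True
            if best is None or best_mism > k:
                out.n_unassigned += 1
                continue
            if tie:
                out.n_ambiguous += 1
                continue
            amp = best
        p2len = len(amp.rev_primer_seq)
        if _hamming_leq(pair.r2[:p2len], amp.rev_primer_seq, k) is None:
            out.n_unassigned += 1
            continue
        out.by_amplicon.setdefault(amp.amplicon_id, []).append(
            (pair.r1, pair.q1, pair.r2, pair.q2)
        )
        out.n_assigned += 1
    return out


# ---------------------------------------------------------------------------
# Pair merging and fragment alignment


def _merge_pair(r1: str, q1: str, r2c: str, q2c: str, expected_len: int):
    """Overlap-merge a primer-trimmed pair into one insert fragment.

    ``r2c`` is read 2 reverse-complemented into top-strand orientation (its
    quality string reversed to match).  The expected overlap for an
    indel-free molecule is tried first; otherwise overlaps are scanned from
    longest to shortest and the first (near-)exact one wins.  Returns
    (sequence, quality) or None when no acceptable overlap exists.
    """
    len1, len2 = len(r1), len(r2c)
    ov0 = len1 + len2 - expected_len
    candidates = []
    if 1 <= ov0 <= min(len1, len2):
        candidates.append(ov0)
    candidates.extend(
        ov for ov in range(min(len1, len2), 0, -1) if ov != ov0
    )
    for ov in candidates:
        tail, head = r1[len1 - ov :], r2c[:ov]
        limit = 0 if ov < 8 else 2
        mism = _hamming_leq(tail, head, limit)
        if mism is None:
            continue
        if mism == 0:
            return r1 + r2c[ov:], q1 + q2c[ov:]
        # resolve disagreements by base quality (read 1 wins ties)
        seq = list(r1 + r2c[ov:])
        qual = list(q1 + q2c[ov:])
        for i in range(ov):
            j = len1 - ov + i
            if r1[j] != head[i] and q2c[i] > q1[j]:
                seq[j], qual[j] = head[i], q2c[i]
        return "".join(seq), "".join(qual)
    return None


def merge_and_trim(r1: str, q1: str, r2: str, q2: str, amplicon) -> tuple[str, str] | None:
    """Reconstruct one molecule's insert from a full read pair.

    The pair is overlap-merged across the whole amplicon (read 2 is
    reverse-complemented first), then the primer flanks are cut away so
    only insert bases remain.  Returns None if no acceptable overlap
    exists.
    """
    merged = _merge_pair(r1, q1, revcomp(r2), q2[::-1], amplicon.length)
    if merged is None:
        return None
    seq, qual = merged
    p1 = len(amplicon.fwd_primer_seq)
    p2 = len(amplicon.rev_primer_seq)
    if len(seq) <= p1 + p2:
        return None
    return seq[p1 : len(seq) - p2], qual[p1 : len(qual) - p2]


_MISMATCH = 3
_GAP_OPEN = 6
_GAP_EXTEND = 1


def _banded_align_events(obs: str, ref: str, band: int = 20) -> list:
    """Global banded affine-gap alignment (Gotoh); returns
    (local_pos, ref_run, alt_run) events.

    Affine penalties keep a long deletion in one piece instead of letting
    chance matches split it into several gaps.  Runs of adjacent
    mismatches stay merged (MNV candidates); indel events are anchored
    VCF-style on the base before the gap (anchor may be -1 for a gap at
    the very start, resolved to contig coordinates upstream).
    """
    na, nb = len(obs), len(ref)
    band = max(band, abs(na - nb) + 5)
    INF = 10 ** 9

    # three layers: M (diagonal), U (gap in ref = insertion in obs),
    # L (gap in obs = deletion from ref)
    M = [[INF] * (nb + 1) for _ in range(na + 1)]
    U = [[INF] * (nb + 1) for _ in range(na + 1)]
    L = [[INF] * (nb + 1) for _ in range(na + 1)]
    bM = [[0] * (nb + 1) for _ in range(na + 1)]  # 0 from M, 1 from U, 2 from L
    bU = [[0] * (nb + 1) for _ in range(na + 1)]  # 0 open (from M), 1 extend
    bL = [[0] * (nb + 1) for _ in range(na + 1)]
    M[0][0] = 0
    for i in range(1, na + 1):
        if i > band:
            break
        U[i][0] = _GAP_OPEN + _GAP_EXTEND * i
        bU[i][0] = 1 if i > 1 else 0
    for j in range(1, nb + 1):
        if j > band:
            break
        L[0][j] = _GAP_OPEN + _GAP_EXTEND * j
        bL[0][j] = 1 if j > 1 else 0
    for i in range(1, na + 1):
        jlo = max(1, i - band)
        jhi = min(nb, i + band)
        for j in range(jlo, jhi + 1):
            sub = 0 if obs[i - 1] == ref[j - 1] or obs[i - 1] == "N" else _MISMATCH
            cands = (M[i - 1][j - 1], U[i - 1][j - 1], L[i - 1][j - 1])
            best = min(cands)
            if best < INF:
                M[i][j] = best + sub
                bM[i][j] = cands.index(best)
            u_from_m = M[i - 1][j] + _GAP_OPEN + _GAP_EXTEND
            u_from_l = L[i - 1][j] + _GAP_OPEN + _GAP_EXTEND
            u_ext = U[i - 1][j] + _GAP_EXTEND
            u_best = min(u_ext, u_from_m, u_from_l)
            if u_best < INF:
                U[i][j] = u_best
                bU[i][j] = 1 if u_best == u_ext else (0 if u_best == u_from_m else 2)
            l_from_m = M[i][j - 1] + _GAP_OPEN + _GAP_EXTEND
            l_from_u = U[i][j - 1] + _GAP_OPEN + _GAP_EXTEND
            l_ext = L[i][j - 1] + _GAP_EXTEND
            l_best = min(l_ext, l_from_m, l_from_u)
            if l_best < INF:
                L[i][j] = l_best
                bL[i][j] = 1 if l_best == l_ext else (0 if l_best == l_from_m else 2)
    # traceback from the best terminal layer
    i, j = na, nb
    finals = (M[i][j], U[i][j], L[i][j])
    layer = finals.index(min(finals))
    ops = []  # ('X'|'='|'I'|'D', obs_index, ref_index)
    while i > 0 or j > 0:
        if j == 0:
            layer = 1
        elif i == 0:
            layer = 2
        if layer == 0:
            prev_layer = bM[i][j]
            i, j = i - 1, j - 1
            same = obs[i] == ref[j] or obs[i] == "N"
            ops.append(("=" if same else "X", i, j))
            layer = prev_layer
        elif layer == 1:
            src = bU[i][j]
            i -= 1
            ops.append(("I", i, j))
            layer = 1 if src == 1 else (0 if src == 0 else 2)
        else:
            src = bL[i][j]
            j -= 1
            ops.append(("D", i, j))
            layer = 1 if src == 2 else (2 if src == 1 else 0)
    ops.reverse()
    events = []
    idx = 0
    while idx < len(ops):
        op, oi, ri = ops[idx]
        if op == "X":
            end = idx
            while end + 1 < len(ops) and ops[end + 1][0] == "X":
                end += 1
            r0, r1_ = ops[idx][2], ops[end][2]
            o0, o1_ = ops[idx][1], ops[end][1]
            events.append((r0, ref[r0 : r1_ + 1], obs[o0 : o1_ + 1]))
            idx = end + 1
        elif op == "D":
            end = idx
            while end + 1 < len(ops) and ops[end + 1][0] == "D":
                end += 1
            r0, r1_ = ops[idx][2], ops[end][2]
            anchor = r0 - 1
            anchor_base = ref[anchor] if anchor >= 0 else ""
            events.append((anchor, anchor_base + ref[r0 : r1_ + 1], anchor_base or "-"))
            idx = end + 1
        elif op == "I":
            end = idx
            while end + 1 < len(ops) and ops[end + 1][0] == "I":
                end += 1
            o0, o1_ = ops[idx][1], ops[end][1]
            anchor = ops[idx][2] - 1
            anchor_base = ref[anchor] if anchor >= 0 else ""
            events.append((anchor, anchor_base or "-", (anchor_base or "") + obs[o0 : o1_ + 1]))
            idx = end + 1
        else:
            idx += 1
    return events


def _positional_events(obs: str, ref: str) -> list:
    events = []
    i = 0
    n = len(obs)
    while i < n:
        if obs[i] != ref[i] and obs[i] != "N":
            j = i
            while j + 1 < n and obs[j + 1] != ref[j + 1] and obs[j + 1] != "N":
                j += 1
            events.append((i, ref[i : j + 1], obs[i : j + 1]))
            i = j + 1
        else:
            i += 1
    return events


# ---------------------------------------------------------------------------
# Pileup


@dataclass
class Pileup:
    """Per-library observation tallies in forward-reference coordinates.

    ``depth`` holds a per-contig array of fragment coverage.  Substitution
    runs (length 1 = SNV candidate, length >=2 = MNV candidate) and
    normalized indels are tallied separately; ``deletion_spanning`` counts,
    per position, fragments observed to delete that base.
    """

    library_id: str
    depth: dict = field(default_factory=dict)  # contig -> np.ndarray
    snv_counts: Counter = field(default_factory=Counter)  # VariantKey -> n
    mnv_counts: Counter = field(default_factory=Counter)
    indel_counts: Counter = field(default_factory=Counter)
    deletion_spanning: Counter = field(default_factory=Counter)  # (contig, pos) -> n
    insertion_anchored: Counter = field(default_factory=Counter)
    amplicon_depth: dict = field(default_factory=dict)  # amplicon_id -> fragments
    n_merge_failed: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0

    def depth_at(self, contig: str, pos: int) -> int:
        arr = self.depth.get(contig)
        if arr is None or not 0 <= pos < len(arr):
            return 0
        return int(arr[pos])

    def base_counts(self, contig: str, pos: int, reference: dict) -> dict:
        """A/C/G/T/DEL/INS tallies at one position (reference base inferred)."""
        counts = {b: 0 for b in "ACGT"}
        for key, n in self.snv_counts.items():
            if key.contig == contig and key.pos == pos:
                counts[key.alt] += n
        for key, n in self.mnv_counts.items():
            if key.contig == contig and key.pos <= pos < key.pos + len(key.ref):
                counts[key.alt[pos - key.pos]] += n
        counts["DEL"] = self.deletion_spanning.get((contig, pos), 0)
        counts["INS"] = self.insertion_anchored.get((contig, pos), 0)
        ref_base = reference[contig][pos]
        observed_alt = sum(v for k, v in counts.items() if k != ref_base)
        counts[ref_base] = max(self.depth_at(contig, pos) - observed_alt, 0)
        return counts

    def median_amplicon_depth(self, design: PanelDesign) -> float:
        depths = [self.amplicon_depth.get(a.amplicon_id, 0) for a in design.amplicons]
        return float(median(depths)) if depths else 0.0


def build_pileup(
    assigned: AssignedReads,
    design: PanelDesign,
    reference: dict,
    params: CallerParams | None = None,
) -> Pileup:
    """Merge trimmed pairs into fragments and tally them against the panel."""
    params = params or CallerParams()
    q_floor = chr(33 + params.base_quality_floor)
    pileup = Pileup(library_id=assigned.library_id)
    pileup.n_unassigned = assigned.n_unassigned
    pileup.n_ambiguous = assigned.n_ambiguous
    for contig_set in {a.contig for a in design.amplicons}:
        pileup.depth[contig_set] = np.zeros(len(reference[contig_set]), dtype=np.int32)

    for a in design.amplicons:
        group = assigned.by_amplicon.get(a.amplicon_id, [])
        if not group:
            pileup.amplicon_depth[a.amplicon_id] = 0
            continue
        ref_insert = reference[a.contig][a.insert_start : a.insert_end]
        contig_seq = reference[a.contig]
        n_fragments = 0
        for r1, q1, r2, q2 in group:
            merged = merge_and_trim(r1, q1, r2, q2, a)
            if merged is None:
                pileup.n_merge_failed += 1
                continue
            obs, qual = merged
            if any(q < q_floor for q in qual):
                obs = "".join(
                    b if q >= q_floor else "N" for b, q in zip(obs, qual)
                )
            n_fragments += 1
            if obs == ref_insert:
                continue
            if len(obs) == len(ref_insert):
                events = _positional_events(obs, ref_insert)
            else:
                events = _banded_align_events(obs, ref_insert)
            for local_pos, ref_run, alt_run in events:
                gpos = a.insert_start + local_pos
                if ref_run != "-" and alt_run != "-" and len(ref_run) == len(alt_run):
                    key = VariantKey(a.contig, gpos, ref_run, alt_run)
                    (pileup.snv_counts if len(ref_run) == 1 else pileup.mnv_counts)[key] += 1
                else:
                    # a gap at the insert's first base has no in-insert anchor;
                    # re-anchor on the preceding contig base
                    if ref_run == "-":
                        base = contig_seq[gpos]
                        ref_run, alt_run = base, base + alt_run
                    elif alt_run == "-":
                        base = contig_seq[gpos]
                        ref_run, alt_run = base + ref_run, base
                    npos, nref, nalt = left_normalize(contig_seq, gpos, ref_run, alt_run)
                    key = VariantKey(a.contig, npos, nref, nalt)
                    pileup.indel_counts[key] += 1
                    if len(nref) > len(nalt):
                        for dpos in range(npos + len(nalt), npos + len(nref)):
                            pileup.deletion_spanning[(a.contig, dpos)] += 1
                    else:
                        pileup.insertion_anchored[(a.contig, npos)] += 1
        pileup.amplicon_depth[a.amplicon_id] = n_fragments
        if n_fragments:
            pileup.depth[a.contig][a.insert_start : a.insert_end] += n_fragments
    return pileup


# ---------------------------------------------------------------------------
# Per-library calling


def call_library(
    pileup: Pileup, params: CallerParams | None = None
) -> tuple[list[LibraryVariant], set]:
    """Emit per-library variants passing the depth/alt-count/VAF floors.

    Adjacent substitutions are reported as one MNV when at least
    ``mnv_shared_fraction`` of the reads supporting each component carry
    the full run; otherwise the run count is folded back into the
    component SNVs.  Returns the calls plus the set of (contig, pos) sites
    where evidence existed but depth was below the floor.
    """
    params = params or CallerParams()
    calls: list[LibraryVariant] = []
    low_depth: set = set()
    snv_counts = Counter(pileup.snv_counts)

    def try_emit(key: VariantKey, count: int):
        depth = pileup.depth_at(key.contig, key.pos)
        if depth < params.min_depth:
            if count >= params.min_alt_count:
                low_depth.add((key.contig, key.pos))
            return
        vaf = count / depth
        if count >= params.min_alt_count and vaf >= params.min_vaf:
            calls.append(
                LibraryVariant(
                    key.contig, key.pos, key.ref, key.alt, pileup.library_id, count, depth, vaf
                )
            )

    for key, m in pileup.mnv_counts.items():
        components = [
            VariantKey(key.contig, key.pos + i, key.ref[i], key.alt[i])
            for i in range(len(key.ref))
            if key.ref[i] != key.alt[i]
        ]
        shared = [m / (m + snv_counts.get(c, 0)) for c in components]
        if min(shared) >= params.mnv_shared_fraction:
            try_emit(key, m)
        else:
            for c in components:
                snv_counts[c] += m
    for key, count in snv_counts.items():
        try_emit(key, count)
    for key, count in pileup.indel_counts.items():
        try_emit(key, count)
    calls.sort(key=lambda v: (v.contig, v.pos, v.ref, v.alt))
    return calls, low_depth


def consensus(
    calls_lib1: list[LibraryVariant],
    calls_lib2: list[LibraryVariant],
    pileup_lib1: Pileup | None = None,
    pileup_lib2: Pileup | None = None,
    params: CallerParams | None = None,
) -> list[ConsensusVariant]:
    """Combine the two strand libraries into consensus calls.

    A variant present in both libraries is PASS with the combined VAF (the
    arithmetic mean by default, pooled counts with ``combine="pooled"``).
    A variant seen in exactly one library is kept for audit as
    SINGLE_LIBRARY_REJECTED — or LOW_DEPTH when the other library simply
    lacked the coverage to confirm it — and is never PASS.
    """
    params = params or CallerParams()
    by_key1 = {v.key: v for v in calls_lib1}
    by_key2 = {v.key: v for v in calls_lib2}
    out: list[ConsensusVariant] = []
    for key in sorted(set(by_key1) | set(by_key2), key=lambda k: (k.contig, k.pos, k.ref, k.alt)):
        v1, v2 = by_key1.get(key), by_key2.get(key)
        if v1 and v2:
            if params.combine == "pooled":
                combined = (v1.alt_count + v2.alt_count) / (v1.depth + v2.depth)
            else:
                combined = (v1.vaf + v2.vaf) / 2.0
            out.append(
                ConsensusVariant(
                    key.contig, key.pos, key.ref, key.alt, FilterStatus.PASS.value,
                    vaf_lib1=v1.vaf, vaf_lib2=v2.vaf, vaf_combined=combined,
                    depth_lib1=v1.depth, depth_lib2=v2.depth,
                )
            )
        else:
            present, other_pileup = (v1, pileup_lib2) if v1 else (v2, pileup_lib1)
            status = FilterStatus.SINGLE_LIBRARY_REJECTED.value
            if other_pileup is not None and other_pileup.depth_at(key.contig, key.pos) < params.min_depth:
                status = FilterStatus.LOW_DEPTH.value
            out.append(
                ConsensusVariant(
                    key.contig, key.pos, key.ref, key.alt, status,
                    vaf_lib1=v1.vaf if v1 else None,
                    vaf_lib2=v2.vaf if v2 else None,
                    depth_lib1=v1.depth if v1 else None,
                    depth_lib2=v2.depth if v2 else None,
                )
            )
    return out


def sample_interpretability(
    pileup_lib1: Pileup,
    pileup_lib2: Pileup,
    design: PanelDesign,
    params: CallerParams | None = None,
) -> tuple[bool, tuple[float, float]]:
    """A sample is interpretable iff both libraries clear the depth cutoff.

    Returns (interpretable, (median depth lib1, median depth lib2)); the
    median is taken over per-amplicon fragment counts.
    """
    params = params or CallerParams()
    med1 = pileup_lib1.median_amplicon_depth(design)
    med2 = pileup_lib2.median_amplicon_depth(design)
    return (med1 >= params.depth_cutoff and med2 >= params.depth_cutoff), (med1, med2)
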