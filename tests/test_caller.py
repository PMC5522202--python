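"""Caller: primer assignment, pileups, per-library calls and consensus."""

import numpy as np
import pytest

from dualstrand.caller import (
    CallerParams,
    Pileup,
    assign_and_trim,
    build_pileup,
    call_library,
    consensus,
    merge_and_trim,
    sample_interpretability,
)
from dualstrand.panel import Amplicon, GenomicInterval, PanelDesign, PoolStrand
from dualstrand.simulate import (
    DamageModel,
    LibraryReadSet,
    ReadPair,
    SequencingModel,
    TruthVariant,
    make_sample,
    simulate_libraries,
)
from dualstrand.variants import VariantKey, revcomp

PARAMS = CallerParams()
CLEAN = DamageModel(deamination_rate=0.0)


# ---------------------------------------------------------------------------
# Primer assignment on a hand-built two-amplicon design


@pytest.fixture(scope="module")
def tiny():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    amps = []
    for k, s in enumerate((50, 200)):
        e = s + 76
        amps.append(
            Amplicon(
                amplicon_id=f"amp{k}",
                contig="C",
                insert_start=s,
                insert_end=e,
                fwd_primer_start=s - 25,
                fwd_primer_end=s,
                rev_primer_start=e,
                rev_primer_end=e + 25,
                pool_strand=PoolStrand.FORWARD_POOL,
                fwd_primer_seq=seq[s - 25 : s],
                rev_primer_seq=revcomp(seq[e : e + 25]),
            )
        )
    design = PanelDesign(
        genes=[],
        exon_regions=[GenomicInterval("C", 55, 270)],
        target_regions=[GenomicInterval("C", 50, 276)],
        amplicons=amps,
    )
    return design, {"C": seq}


def _pair_for(amp, seq, rl=100, mutate_prefix=0):
    full = seq[amp.fwd_primer_start : amp.rev_primer_end]
    r1, r2 = full[:rl], revcomp(full)[:rl]
    if mutate_prefix:
        prefix = "".join("A" if c != "A" else "C" for c in r1[:mutate_prefix])
        r1 = prefix + r1[mutate_prefix:]
    q = "?" * len(r1)
    return ReadPair(name="s:LIB1:x:0", r1=r1, q1=q, r2=r2, q2="?" * len(r2))


def test_exact_primer_assignment_and_trim(tiny):
    design, ref = tiny
    amp = design.amplicons[0]
    rs = LibraryReadSet("s", "LIB1", [_pair_for(amp, ref["C"])])
    out = assign_and_trim(rs, design, k=2)
    assert out.n_assigned == 1 and not out.n_unassigned
    (r1, q1, r2, q2) = out.by_amplicon["amp0"][0]
    frag = merge_and_trim(r1, q1, r2, q2, amp)
    assert frag is not None
    seq, _ = frag
    # primer bases are gone: the fragment is exactly the reference insert
    assert seq == ref["C"][amp.insert_start : amp.insert_end]


def test_primer_mismatch_tolerance_boundary(tiny):
    design, ref = tiny
    amp = design.amplicons[0]
    within = LibraryReadSet("s", "LIB1", [_pair_for(amp, ref["C"], mutate_prefix=2)])
    beyond = LibraryReadSet("s", "LIB1", [_pair_for(amp, ref["C"], mutate_prefix=3)])
    assert assign_and_trim(within, design, k=2).n_assigned == 1
    out = assign_and_trim(beyond, design, k=2)
    assert out.n_assigned == 0 and out.n_unassigned == 1


def test_ambiguous_primer_tie_discarded(tiny):
    design, ref = tiny
    import dataclasses

    # duplicate amp0's forward primer onto amp1 -> every amp0 read ties
    a0, a1 = design.amplicons
    twin = dataclasses.replace(
        a1,
        fwd_primer_seq=a0.fwd_primer_seq,
        fwd_primer_start=a1.insert_start - len(a0.fwd_primer_seq),
    )
    clash = PanelDesign(
        genes=[], exon_regions=design.exon_regions,
        target_regions=design.target_regions, amplicons=[a0, twin],
    )
    rs = LibraryReadSet("s", "LIB1", [_pair_for(a0, ref["C"], mutate_prefix=1)])
    out = assign_and_trim(rs, clash, k=2)
    assert out.n_ambiguous == 1 and out.n_assigned == 0


def test_assignment_matches_hidden_tags_without_errors(small_design, reference):
    from collections import Counter

    pool = make_sample(small_design, reference, [], CLEAN, seed=31, n_molecules=200)
    lib1, _ = simulate_libraries(pool, SequencingModel(error_rate=0.0, depth=60.0), seed=32)
    out = assign_and_trim(lib1, small_design, k=2)
    truth = Counter(p.source_amplicon for p in lib1.pairs)
    assert out.n_unassigned == 0 and out.n_ambiguous == 0
    assert {k: len(v) for k, v in out.by_amplicon.items()} == dict(truth)


# ---------------------------------------------------------------------------
# call_library thresholds on hand-built pileups


def _pileup_with(counts, depth=1000, contig="C", length=2000):
    p = Pileup(library_id="LIB1")
    p.depth[contig] = np.full(length, depth, dtype=np.int32)
    for (pos, ref, alt), n in counts.items():
        key = VariantKey(contig, pos, ref, alt)
        if len(ref) == len(alt) == 1:
            p.snv_counts[key] = n
        elif len(ref) == len(alt):
            p.mnv_counts[key] = n
        else:
            p.indel_counts[key] = n
    return p


def test_call_thresholds():
    p = _pileup_with({(10, "A", "T"): 50, (20, "G", "C"): 2})
    calls, low = call_library(p, PARAMS)
    assert [(c.pos, c.vaf) for c in calls] == [(10, 0.05)]
    assert not low


def test_low_depth_site_flagged():
    p = _pileup_with({(10, "A", "T"): 5}, depth=50)
    calls, low = call_library(p, PARAMS)
    assert calls == [] and low == {("C", 10)}


def test_empty_pileup_empty_calls():
    calls, low = call_library(Pileup(library_id="LIB1"), PARAMS)
    assert calls == [] and not low


def test_mnv_merging_with_high_shared_fraction():
    p = _pileup_with({(10, "AT", "GC"): 100, (10, "A", "G"): 2, (11, "T", "C"): 2})
    calls, _ = call_library(p, PARAMS)
    assert [(c.pos, c.ref, c.alt, c.alt_count) for c in calls] == [(10, "AT", "GC", 100)]


def test_mnv_split_when_sharing_low():
    p = _pileup_with({(10, "AT", "GC"): 10, (10, "A", "G"): 90, (11, "T", "C"): 90})
    calls, _ = call_library(p, PARAMS)
    assert [(c.pos, c.ref, c.alt, c.alt_count) for c in calls] == [
        (10, "A", "G", 100),
        (11, "T", "C", 100),
    ]


# ---------------------------------------------------------------------------
# consensus


def _lv(pos, vaf, lib, ref="A", alt="T", depth=1000):
    from dualstrand.caller import LibraryVariant

    return LibraryVariant("C", pos, ref, alt, lib, int(round(vaf * depth)), depth, vaf)


def test_consensus_mean_vaf():
    out = consensus([_lv(5, 0.050, "LIB1")], [_lv(5, 0.052, "LIB2")])
    assert len(out) == 1
    c = out[0]
    assert c.filter_status == "PASS"
    assert c.vaf_combined == pytest.approx(0.051)


def test_consensus_pooled_option():
    params = CallerParams(combine="pooled")
    out = consensus([_lv(5, 0.05, "LIB1")], [_lv(5, 0.10, "LIB2", depth=3000)], params=params)
    assert out[0].vaf_combined == pytest.approx((50 + 300) / 4000)


def test_single_library_rejected_never_pass():
    p2 = _pileup_with({}, depth=1000)
    out = consensus([_lv(5, 0.05, "LIB1")], [], None, p2)
    assert [c.filter_status for c in out] == ["SINGLE_LIBRARY_REJECTED"]


def test_single_library_low_depth_classification():
    p2 = _pileup_with({}, depth=10)
    out = consensus([_lv(5, 0.05, "LIB1")], [], None, p2)
    assert [c.filter_status for c in out] == ["LOW_DEPTH"]


def test_consensus_empty_inputs():
    assert consensus([], []) == []


def test_consensus_symmetric_under_library_swap():
    c1 = [_lv(5, 0.05, "LIB1"), _lv(9, 0.02, "LIB1")]
    c2 = [_lv(5, 0.07, "LIB2")]
    a = consensus(c1, c2)
    b = consensus(c2, c1)
    va = {(c.contig, c.pos): (c.vaf_combined, c.filter_status) for c in a}
    vb = {(c.contig, c.pos): (c.vaf_combined, c.filter_status) for c in b}
    assert va == vb


# ---------------------------------------------------------------------------
# interpretability


def _pileup_with_median(design, value):
    p = Pileup(library_id="x")
    for a in design.amplicons:
        p.amplicon_depth[a.amplicon_id] = value
    return p


def test_interpretability_boundary(small_design):
    ok, meds = sample_interpretability(
        _pileup_with_median(small_design, 1000), _pileup_with_median(small_design, 1000), small_design, PARAMS
    )
    assert ok and meds == (1000, 1000)
    bad, meds = sample_interpretability(
        _pileup_with_median(small_design, 699), _pileup_with_median(small_design, 1200), small_design, PARAMS
    )
    assert not bad and meds == (699, 1200)


def test_interpretability_zero_cutoff_vacuous(small_design):
    params = CallerParams(depth_cutoff=0)
    ok, _ = sample_interpretability(
        _pileup_with_median(small_design, 0), _pileup_with_median(small_design, 0), small_design, params
    )
    assert ok


# ---------------------------------------------------------------------------
# End-to-end oracle properties


def _run_libs(design, reference, variants, damage, seqmodel, seed, params=PARAMS):
    pool = make_sample(design, reference, variants, damage, seed, n_molecules=800)
    lib1, lib2 = simulate_libraries(pool, seqmodel, seed + 1)
    pileups, calls = [], []
    for lib in (lib1, lib2):
        assigned = assign_and_trim(lib, design, params.primer_mismatch_tolerance)
        pileup = build_pileup(assigned, design, reference, params)
        c, _ = call_library(pileup, params)
        pileups.append(pileup)
        calls.append(c)
    cons = consensus(calls[0], calls[1], pileups[0], pileups[1], params)
    return calls, cons


def test_noise_free_calls_equal_truth_exactly(small_design, reference):
    """With damage and sequencing error off, PASS calls are the truth set."""
    from dualstrand.variants import left_normalize

    zones = [
        z
        for amp in small_design.amplicons
        for z in small_design.exclusive_zones()[amp.amplicon_id]
        if z.length >= 24
    ]
    assert len(zones) >= 5
    variants = []
    for i, z in enumerate(zones[:5]):
        seq = reference[z.contig]
        if i == 2:  # one clean 6-bp deletion among the SNVs
            pos = z.start + 4
            ref, alt = seq[pos : pos + 7], seq[pos]
            npos, nref, nalt = left_normalize(seq, pos, ref, alt)
            if npos < z.start + 1:  # homopolymer drift out of the zone: skip shift
                continue
            variants.append(TruthVariant(z.contig, npos, nref, nalt, 0.15, f"v{i}"))
        else:
            pos = z.start + 3
            ref = seq[pos]
            alt = "A" if ref != "A" else "G"
            variants.append(TruthVariant(z.contig, pos, ref, alt, 0.05 + 0.05 * i, f"v{i}"))
    assert len(variants) >= 4
    calls, cons = _run_libs(
        small_design, reference, variants, CLEAN,
        SequencingModel(error_rate=0.0, depth=400.0), seed=101,
    )
    pass_keys = {c.key for c in cons if c.filter_status == "PASS"}
    truth_keys = {VariantKey(v.contig, v.pos, v.ref, v.alt) for v in variants}
    assert pass_keys == truth_keys
    # PASS set is contained in both per-library call sets
    for lib_calls in calls:
        assert pass_keys <= {c.key for c in lib_calls}


def test_artifacts_called_per_library_but_suppressed_by_consensus(egfr_design, reference):
    """The central claim: strand-confined artifacts never survive consensus.

    A jackpot artifact site is planted at 2% on one strand; across 20 seeds
    the per-library caller must fire on it while the PASS set stays clean.
    """
    amp = egfr_design.amplicons[3]
    zones = egfr_design.exclusive_zones()[amp.amplicon_id]
    site = None
    for z in zones:
        for pos in range(z.start + 2, z.end - 2):
            if reference["EGFR"][pos] == "C":
                site = pos
                break
        if site:
            break
    assert site is not None
    damage = DamageModel(jackpot_sites=(("EGFR", site, "fwd", 0.02),))
    n_single = 0
    for seed in range(20):
        _, cons = _run_libs(
            egfr_design, reference, [], damage,
            SequencingModel(depth=300.0), seed=1000 + 31 * seed,
        )
        assert all(c.filter_status != "PASS" for c in cons)
        n_single += sum(
            1 for c in cons
            if c.filter_status == "SINGLE_LIBRARY_REJECTED" and c.pos == site
        )
    assert n_single > 0


def test_mnv_called_end_to_end(egfr_design, reference):
    zones = egfr_design.exclusive_zones()
    target = None
    for amp in egfr_design.amplicons:
        for z in zones[amp.amplicon_id]:
            if z.length >= 8:
                target = (z.contig, z.start + 3)
                break
        if target:
            break
    contig, pos = target
    ref_run = reference[contig][pos : pos + 2]
    alt_run = "".join("A" if b != "A" else "G" for b in ref_run)
    v = TruthVariant(contig, pos, ref_run, alt_run, 0.20, "mnv_test")
    _, cons = _run_libs(
        egfr_design, reference, [v], CLEAN,
        SequencingModel(error_rate=0.0, depth=300.0), seed=77,
    )
    pass_keys = {c.key for c in cons if c.filter_status == "PASS"}
    assert VariantKey(contig, pos, ref_run, alt_run) in pass_keys
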