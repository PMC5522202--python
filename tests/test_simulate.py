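"""Simulator: template physics, library statistics, qPCR model, truth sets."""

import math

import numpy as np
import pytest

from dualstrand.simulate import (
    DAMAGE_PRESETS,
    FWD,
    REV,
    DamageModel,
    SequencingModel,
    TruthVariant,
    make_reference_standards,
    make_sample,
    read_fastq_pair,
    simulate_libraries,
    simulate_qpcr,
    write_fastq,
)

CLEAN = DamageModel(deamination_rate=0.0)
ERRORFREE = SequencingModel(error_rate=0.0, depth=200.0)


def _first_zone_snv(design, reference, vaf, contig=None):
    """A convenient SNV inside a single-amplicon zone of the design."""
    zones = design.exclusive_zones()
    for amp in design.amplicons:
        if contig and amp.contig != contig:
            continue
        for z in zones[amp.amplicon_id]:
            if z.length >= 5:
                pos = z.start + 2
                ref = reference[z.contig][pos]
                alt = "A" if ref != "A" else "G"
                return TruthVariant(z.contig, pos, ref, alt, vaf, "test_snv")
    raise AssertionError("no zone found")


def test_damage_off_templates_are_pure(egfr_design, reference):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=1, n_molecules=300)
    for at in pool.amplicons.values():
        assert not at.events[FWD] and not at.events[REV]
    lib1, lib2 = simulate_libraries(pool, ERRORFREE, seed=2)
    for lib in (lib1, lib2):
        for amp_id in {p.source_amplicon for p in lib.pairs}:
            reads = {p.r1 for p in lib.pairs if p.source_amplicon == amp_id}
            assert len(reads) == 1  # a single observed allele everywhere


def test_target_vaf_one_is_fixed(egfr_design, reference):
    v = _first_zone_snv(egfr_design, reference, vaf=1.0)
    pool = make_sample(egfr_design, reference, [v], CLEAN, seed=3, n_molecules=200)
    host = [
        at
        for at in pool.amplicons.values()
        if at.amplicon.contig == v.contig
        and at.amplicon.insert_start <= v.pos < at.amplicon.insert_end
    ]
    assert host
    for at in host:
        for strand in (FWD, REV):
            assert len(at.events[strand]) == at.n_molecules  # every molecule carries it


def test_variant_outside_footprint_errors(egfr_design, reference):
    v = TruthVariant("EGFR", 5, reference["EGFR"][5], "A" if reference["EGFR"][5] != "A" else "C", 0.1, "off")
    with pytest.raises(ValueError, match="off"):
        make_sample(egfr_design, reference, [v], CLEAN, seed=1, n_molecules=50)


def test_ref_allele_mismatch_errors(egfr_design, reference):
    amp = egfr_design.amplicons[0]
    pos = amp.insert_start + 5
    wrong = "A" if reference["EGFR"][pos] != "A" else "C"
    with pytest.raises(ValueError, match="ref allele mismatch"):
        make_sample(
            egfr_design, reference,
            [TruthVariant("EGFR", pos, wrong, "T" if wrong != "T" else "G", 0.1, "bad")],
            CLEAN, seed=1, n_molecules=50,
        )


def test_deamination_is_strand_confined(egfr_design, reference):
    damage = DamageModel(deamination_rate=0.01)
    pool = make_sample(egfr_design, reference, [], damage, seed=4, n_molecules=400)
    n_events = 0
    for at in pool.amplicons.values():
        for mol, events in at.events[FWD].items():
            n_events += len(events)
            for pos, ref, alt in events:
                assert (ref, alt) == ("C", "T")
                # the same artifact never exists on the molecule's other strand
                assert (pos, ref, alt) not in at.events[REV].get(mol, [])
        for mol, events in at.events[REV].items():
            for pos, ref, alt in events:
                assert (ref, alt) == ("G", "A")
    assert n_events > 0
    # libraries draw from strand-matched templates only
    lib1, lib2 = simulate_libraries(pool, ERRORFREE, seed=5)
    assert {p.source_strand for p in lib1.pairs} == {FWD}
    assert {p.source_strand for p in lib2.pairs} == {REV}


def test_read_pair_count_matches_expectation(design, reference):
    pool = make_sample(design, reference, [], CLEAN, seed=6, n_molecules=500)
    lib1, lib2 = simulate_libraries(pool, SequencingModel(depth=1000.0), seed=7)
    n = len(lib1.pairs) + len(lib2.pairs)
    expected = 2 * 150 * 1000
    assert abs(n - expected) <= 5 * math.sqrt(expected)


def test_depth_scales_linearly_with_concentration(egfr_design, reference):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=8, n_molecules=500)
    lib1, lib2 = simulate_libraries(
        pool, SequencingModel(depth=1000.0), seed=9, concentration=0.03
    )
    n_amplicons = len(egfr_design.amplicons)
    mean_depth = (len(lib1.pairs) + len(lib2.pairs)) / (2 * n_amplicons)
    assert mean_depth == pytest.approx(7.5, abs=2.0)


def test_observed_vaf_binomially_consistent(egfr_design, reference):
    v = _first_zone_snv(egfr_design, reference, vaf=0.10)
    n_mol, depth = 2000, 500.0
    pool = make_sample(egfr_design, reference, [v], CLEAN, seed=10, n_molecules=n_mol)
    lib1, lib2 = simulate_libraries(pool, SequencingModel(error_rate=0.0, depth=depth), seed=11)
    ests = []
    for lib in (lib1, lib2):
        alt = sum(
            1
            for p in lib.pairs
            if p.source_amplicon and p.r1
            and _read_has_alt(p, v, egfr_design)
        )
        tot = sum(1 for p in lib.pairs if _read_covers(p, v, egfr_design))
        ests.append(alt / tot)
    est = float(np.mean(ests))
    se = math.sqrt(v.target_vaf * (1 - v.target_vaf) * (1 / n_mol + 1 / (2 * depth)))
    assert abs(est - v.target_vaf) <= 4 * se


def _read_covers(pair, v, design):
    a = design.amplicon_for(pair.source_amplicon)
    return a.contig == v.contig and a.insert_start <= v.pos < a.insert_end


def _read_has_alt(pair, v, design):
    if not _read_covers(pair, v, design):
        return False
    a = design.amplicon_for(pair.source_amplicon)
    offset = (v.pos - a.insert_start) + (a.fwd_primer_end - a.fwd_primer_start)
    return offset < len(pair.r1) and pair.r1[offset] == v.alt


# ---------------------------------------------------------------------------
# qPCR model


def test_qpcr_identical_pools_gives_zero_delta(egfr_design, reference):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=12, n_molecules=100)
    cq_s, cq_c = simulate_qpcr(pool, pool)
    assert cq_s - cq_c == 0.0


def test_qpcr_sixteenth_fraction_gives_delta_four(egfr_design, reference):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=13, n_molecules=160)
    control = make_sample(egfr_design, reference, [], CLEAN, seed=14, n_molecules=160)
    for at in pool.amplicons.values():
        at.survived[:] = False
        at.survived[:10] = True  # 10/160 = 1/16
    cq_s, cq_c = simulate_qpcr(pool, control)
    assert cq_s - cq_c == pytest.approx(4.0)


def test_qpcr_dead_pool_is_infinite(egfr_design, reference):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=15, n_molecules=50)
    control = make_sample(egfr_design, reference, [], CLEAN, seed=16, n_molecules=50)
    for at in pool.amplicons.values():
        at.survived[:] = False
    cq_s, _ = simulate_qpcr(pool, control)
    assert math.isinf(cq_s)


def test_qpcr_monotone_in_damage(egfr_design, reference):
    dqcs = []
    control = make_sample(egfr_design, reference, [], CLEAN, seed=17, n_molecules=4000)
    for preset in ("intact", "mild", "degraded", "severe", "very_severe"):
        pool = make_sample(
            egfr_design, reference, [], DAMAGE_PRESETS[preset], seed=18, n_molecules=4000
        )
        cq_s, cq_c = simulate_qpcr(pool, control)
        dqcs.append(cq_s - cq_c)
    assert dqcs == sorted(dqcs)
    assert dqcs[2] == pytest.approx(4.3, abs=1.0)  # 'degraded' preset sits in the 4.3-10.1 band


# ---------------------------------------------------------------------------
# Reference standards


def test_truq3_standard_composition(design, reference):
    variants = make_reference_standards(design, reference, "TRUQ3")
    assert len(variants) == 12
    low = [v for v in variants if 0.04 <= v.target_vaf <= 0.05]
    assert len(low) == 7
    dels = [v for v in variants if len(v.ref) > len(v.alt)]
    assert sorted(len(v.ref) - len(v.alt) for v in dels) == [1, 15]
    for v in variants:
        v.validate_against(reference)


def test_ffpe_standard_composition(design, reference):
    variants = make_reference_standards(design, reference, "FFPE_QM")
    assert min(v.target_vaf for v in variants) == pytest.approx(0.01)
    assert {round(v.target_vaf, 3) for v in variants} == {0.01, 0.02, 0.03}
    assert any(len(v.ref) - len(v.alt) == 15 for v in variants)


# ---------------------------------------------------------------------------
# Determinism and FASTQ round-trip


def test_identical_seed_byte_identical_fastq(egfr_design, reference, tmp_path):
    paths = []
    for run in (0, 1):
        pool = make_sample(egfr_design, reference, [], DamageModel(), seed=19, n_molecules=300)
        lib1, _ = simulate_libraries(pool, SequencingModel(depth=100.0), seed=20)
        r1, r2 = tmp_path / f"{run}_R1.fastq.gz", tmp_path / f"{run}_R2.fastq.gz"
        write_fastq(lib1, r1, r2)
        paths.append((r1, r2))
    # compare decompressed content (gzip headers may embed nothing variable,
    # but the guarantee we state is record-level identity)
    import gzip

    for i in (0, 1):
        assert gzip.open(paths[0][i]).read() == gzip.open(paths[1][i]).read()


def test_fastq_roundtrip(egfr_design, reference, tmp_path):
    pool = make_sample(egfr_design, reference, [], CLEAN, seed=21, n_molecules=100)
    lib1, _ = simulate_libraries(pool, SequencingModel(depth=50.0), seed=22)
    r1, r2 = tmp_path / "a_R1.fastq", tmp_path / "a_R2.fastq"
    write_fastq(lib1, r1, r2)
    loaded = read_fastq_pair(r1, r2)
    assert loaded.library_id == lib1.library_id
    assert [(p.name, p.r1, p.q1, p.r2, p.q2) for p in loaded.pairs] == [
        (p.name, p.r1, p.q1, p.r2, p.q2) for p in lib1.pairs
    ]
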