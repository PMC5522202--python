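"""End-to-end orchestration: fixture bundles, single-sample runs, control
experiments (replicates, dilution series, validation cohort) and the
file-based pipeline.

These functions are the package's "commands": ``write_fixtures`` emits the
panel/reference/manifest/truth bundle, ``run_sample`` drives
simulate -> call -> QC for one sample in memory, and ``run_pipeline`` does
the same through files (FASTQ in, VCF/TSV/JSON out) for a configured set of
samples.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .caller import (
    CallerParams,
    FilterStatus,
    assign_and_trim,
    build_pileup,
    call_library,
    consensus,
    sample_interpretability,
)
from .evaluate import ConfusionCounts, per_base_confusion
from .fixtures import (
    DEFAULT_FIXTURE_SEED,
    build_toy_design,
    default_constraints,
    toy_snp_blacklist,
)
from .panel import (
    GenomicInterval,
    PanelDesign,
    load_manifest,
    load_panel_table,
    load_targets_bed,
    validate_design,
    write_manifest,
    write_panel_table,
)
from .qc import QCRecord, DilutionPoint, delta_qc, triage
from .simulate import (
    DAMAGE_PRESETS,
    DamageModel,
    SequencingModel,
    TruthVariant,
    make_reference_standards,
    make_sample,
    read_fastq_pair,
    simulate_libraries,
    simulate_qpcr,
    write_fastq,
    write_truth_tsv,
)
from .variants import write_consensus_vcf, write_truth_vcf


def _child_seed(seed: int, *salt: int) -> int:
    """Derive a deterministic sub-seed (< 2**31) from the run seed."""
    h = hashlib.sha256(("/".join(map(str, (seed, *salt)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 1
    fixture_dir: str = "fixtures"
    out_dir: str = "out"
    samples: list = field(default_factory=list)  # [{sample_id, truth, damage, concentration}]
    depth: float = 1000.0
    error_rate: float = 1e-3
    read_length: int = 100
    n_molecules: int = 2000
    triage_threshold: float = 4.0
    depth_cutoff: int = 700
    caller: dict = field(default_factory=dict)  # CallerParams overrides

    def caller_params(self) -> CallerParams:
        return CallerParams(depth_cutoff=self.depth_cutoff, **self.caller)

    def seq_model(self) -> SequencingModel:
        return SequencingModel(
            error_rate=self.error_rate, read_length=self.read_length, depth=self.depth
        )

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Fixture bundle


def write_fixtures(outdir, seed: int = DEFAULT_FIXTURE_SEED) -> dict:
    """Write the panel TSV, toy reference FASTA, manifest, truth sets and a
    demo config; regeneration with the same seed is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, reference = build_toy_design(seed)
    meta = {"tool": f"dualstrand-{__version__}", "seed": seed}

    write_panel_table(design, outdir / "panel.tsv", meta=meta)
    write_manifest(design, outdir / "amplicons.bed", outdir / "primers.tsv", outdir / "targets.bed")
    with (outdir / "reference.fa").open("w") as fh:
        for contig in sorted(reference):
            fh.write(f">{contig}\n")
            seq = reference[contig]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with (outdir / "snp_blacklist.tsv").open("w") as fh:
        fh.write("contig\tpos\n")
        for contig, pos in sorted(toy_snp_blacklist(design)):
            fh.write(f"{contig}\t{pos}\n")

    for which in ("TRUQ3", "FFPE_QM"):
        variants = make_reference_standards(design, reference, which)
        write_truth_tsv(variants, outdir / f"truth_{which.lower()}.tsv", meta=meta)
        write_truth_vcf(
            outdir / f"truth_{which.lower()}.vcf", variants, reference,
            meta={"seed": str(seed), "version": __version__},
        )

    # paths in the demo config are relative to the bundle so that
    # regeneration is byte-identical wherever the bundle lives
    config = RunConfig(
        seed=seed,
        fixture_dir=".",
        samples=[
            {"sample_id": "truq3_control", "truth": "TRUQ3", "damage": "intact", "concentration": 4.0},
            {"sample_id": "ffpe_control", "truth": "FFPE_QM", "damage": "mild", "concentration": 4.0},
        ],
    )
    config.to_yaml(outdir / "demo_config.yaml")
    return {"design": design, "reference": reference}


def load_fixture_design(fixture_dir) -> tuple[PanelDesign, dict]:
    """Load a written fixture bundle back into a design + reference."""
    from Bio import SeqIO

    fixture_dir = Path(fixture_dir)
    design = load_panel_table(fixture_dir / "panel.tsv")
    design.amplicons = load_manifest(fixture_dir / "amplicons.bed", fixture_dir / "primers.tsv")
    design.target_regions, design.exon_regions = load_targets_bed(fixture_dir / "targets.bed")
    reference = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fixture_dir / "reference.fa"), "fasta")
    }
    return design, reference


# ---------------------------------------------------------------------------
# In-memory single-sample run


@dataclass
class SampleResult:
    sample_id: str
    qc: QCRecord
    consensus_calls: list
    lib1_calls: list
    lib2_calls: list
    pileup_lib1: object
    pileup_lib2: object
    truth: list

    @property
    def pass_calls(self) -> list:
        return [c for c in self.consensus_calls if c.filter_status == FilterStatus.PASS.value]


def run_sample(
    design: PanelDesign,
    reference: dict,
    variants: list[TruthVariant],
    damage: DamageModel,
    seqmodel: SequencingModel,
    params: CallerParams,
    seed: int,
    sample_id: str = "sample",
    concentration: float = 4.0,
    n_molecules: int = 2000,
    triage_threshold: float = 4.0,
) -> SampleResult:
    """simulate -> qPCR triage -> call -> consensus for one sample, in memory."""
    pool = make_sample(
        design, reference, variants, damage, _child_seed(seed, 1), n_molecules, sample_id
    )
    control = make_sample(
        design, reference, [], DamageModel(deamination_rate=0.0),
        _child_seed(seed, 2), n_molecules, sample_id + "_control",
    )
    cq_sample, cq_control = simulate_qpcr(pool, control)
    dqc = delta_qc(cq_sample, cq_control)
    verdict, scaling = triage(dqc, triage_threshold)

    lib1, lib2 = simulate_libraries(
        pool, seqmodel, _child_seed(seed, 3), concentration=concentration, input_scaling=scaling
    )
    pileups, calls = [], []
    for lib in (lib1, lib2):
        assigned = assign_and_trim(lib, design, params.primer_mismatch_tolerance)
        pileup = build_pileup(assigned, design, reference, params)
        lib_calls, _low = call_library(pileup, params)
        pileups.append(pileup)
        calls.append(lib_calls)
    cons = consensus(calls[0], calls[1], pileups[0], pileups[1], params)
    interpretable, (med1, med2) = sample_interpretability(pileups[0], pileups[1], design, params)

    qc = QCRecord(
        sample_id=sample_id,
        cq_sample=cq_sample,
        cq_control=cq_control,
        delta_qc=dqc,
        triage=verdict,
        input_scaling=scaling,
        median_depth_lib1=med1,
        median_depth_lib2=med2,
        interpretable=interpretable,
    )
    return SampleResult(
        sample_id=sample_id,
        qc=qc,
        consensus_calls=cons,
        lib1_calls=calls[0],
        lib2_calls=calls[1],
        pileup_lib1=pileups[0],
        pileup_lib2=pileups[1],
        truth=variants,
    )


# ---------------------------------------------------------------------------
# Control experiments


@dataclass
class ReplicateExperiment:
    """Replicated control-sample runs plus expected-vs-observed summaries."""

    variants: list
    results: list
    observed_vaf_pct: np.ndarray  # (n_variants, n_replicates); NaN where missed

    @property
    def mean_vaf_pct(self) -> np.ndarray:
        return np.nanmean(self.observed_vaf_pct, axis=1)

    def pass_labels(self, replicate: int) -> set:
        keys = {
            (c.contig, c.pos, c.ref, c.alt) for c in self.results[replicate].pass_calls
        }
        return {
            v.label for v in self.variants if (v.contig, v.pos, v.ref, v.alt) in keys
        }


def run_control_replicates(
    design: PanelDesign,
    reference: dict,
    which: str,
    n_replicates: int,
    seed: int,
    depth: float = 1000.0,
    damage: DamageModel | None = None,
    params: CallerParams | None = None,
    n_molecules: int = 2000,
) -> ReplicateExperiment:
    """Sequence a reference-standard control ``n_replicates`` times.

    Returns per-variant estimated consensus VAFs (percent) per replicate;
    a variant that fails to PASS in a replicate is NaN there.
    """
    variants = make_reference_standards(design, reference, which)
    seqmodel = SequencingModel(depth=depth)
    params = params or CallerParams()
    damage = damage or DamageModel()
    observed = np.full((len(variants), n_replicates), np.nan)
    results = []
    for rep in range(n_replicates):
        res = run_sample(
            design, reference, variants, damage, seqmodel, params,
            seed=_child_seed(seed, 10, rep), sample_id=f"{which.lower()}_r{rep}",
            n_molecules=n_molecules,
        )
        results.append(res)
        by_key = {(c.contig, c.pos, c.ref, c.alt): c for c in res.pass_calls}
        for i, v in enumerate(variants):
            call = by_key.get((v.contig, v.pos, v.ref, v.alt))
            if call is not None:
                observed[i, rep] = 100.0 * call.vaf_combined
    return ReplicateExperiment(variants=variants, results=results, observed_vaf_pct=observed)


def run_dilution_series(
    design: PanelDesign,
    reference: dict,
    concentrations: list[float],
    seed: int,
    which: str = "FFPE_QM",
    depth: float = 1000.0,
    params: CallerParams | None = None,
    n_molecules: int = 2000,
) -> list[DilutionPoint]:
    """Serial dilution of a control sample (library depth scales linearly
    with concentration relative to the 4 nM pooling standard)."""
    params = params or CallerParams()
    variants = make_reference_standards(design, reference, which)
    truth_keys = {(v.contig, v.pos, v.ref, v.alt) for v in variants}
    seqmodel = SequencingModel(depth=depth)
    points = []
    for i, conc in enumerate(sorted(concentrations, reverse=True)):
        res = run_sample(
            design, reference, variants, DamageModel(), seqmodel, params,
            seed=_child_seed(seed, 20, i), sample_id=f"dil_{conc}", concentration=conc,
            n_molecules=n_molecules,
        )
        call_keys = {(c.contig, c.pos, c.ref, c.alt) for c in res.pass_calls}
        med = min(res.qc.median_depth_lib1, res.qc.median_depth_lib2)
        points.append(
            DilutionPoint(
                concentration=conc,
                median_depth=med,
                tp=len(truth_keys & call_keys),
                fp=len(call_keys - truth_keys),
                fn=len(truth_keys - call_keys),
            )
        )
    return points


def _random_cohort_truth(
    design: PanelDesign,
    reference: dict,
    interrogated: list[GenomicInterval],
    n_variants: int,
    rng: np.random.Generator,
    min_vaf: float = 0.05,
    max_vaf: float = 0.50,
) -> list[TruthVariant]:
    """Random SNVs inside single-amplicon zones of the interrogated region."""
    zones = [
        z
        for zs in design.exclusive_zones().values()
        for z in zs
        if any(iv.contig == z.contig and z.start >= iv.start and z.end <= iv.end or iv.overlaps(z)
               for iv in interrogated)
    ]
    region = {(iv.contig, p) for iv in interrogated for p in range(iv.start, iv.end)}
    chosen: list[TruthVariant] = []
    used = set()
    attempts = 0
    while len(chosen) < n_variants:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place cohort variants")
        zone = zones[int(rng.integers(len(zones)))]
        if zone.length < 3:
            continue
        pos = int(rng.integers(zone.start + 1, zone.end - 1))
        if (zone.contig, pos) in used or (zone.contig, pos) not in region:
            continue
        ref_base = reference[zone.contig][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        vaf = float(rng.uniform(min_vaf, max_vaf))
        chosen.append(TruthVariant(zone.contig, pos, ref_base, alt, vaf, f"cohort_{len(chosen)}"))
        used.add((zone.contig, pos))
    return chosen


@dataclass
class CohortValidation:
    confusion: ConfusionCounts
    n_samples: int
    interrogated_bases: int
    truth_positions: int


def simulate_validation_cohort(
    design: PanelDesign,
    reference: dict,
    seed: int,
    total_bases: int = 53534,
    total_truth_positions: int = 135,
    depth: float = 600.0,
    min_vaf: float = 0.05,
    params: CallerParams | None = None,
    n_molecules: int = 2000,
) -> CohortValidation:
    """Re-create the per-base validation experiment at full printed scale.

    Samples are simulated over the panel until the cumulative interrogated
    region reaches ``total_bases`` (the last sample's interrogated interval
    set is truncated to land exactly); ``total_truth_positions`` spiked
    variants at VAF >= ``min_vaf`` are spread across the samples.  Returns
    pooled confusion counts over all interrogated nucleotides.
    """
    params = params or CallerParams()
    rng = np.random.default_rng(_child_seed(seed, 30))
    footprint = design.footprint()
    footprint_bp = sum(iv.length for iv in footprint)
    n_samples = math.ceil(total_bases / footprint_bp)

    # interrogated interval set per sample; truncate the last one
    per_sample_regions: list[list[GenomicInterval]] = []
    remaining = total_bases
    for _ in range(n_samples):
        if remaining >= footprint_bp:
            per_sample_regions.append(list(footprint))
            remaining -= footprint_bp
        else:
            trimmed = []
            budget = remaining
            for iv in footprint:
                if budget <= 0:
                    break
                take = min(iv.length, budget)
                trimmed.append(GenomicInterval(iv.contig, iv.start, iv.start + take))
                budget -= take
            per_sample_regions.append(trimmed)
            remaining = 0

    # spread truth positions across samples
    base = total_truth_positions // n_samples
    counts = [base] * n_samples
    for i in range(total_truth_positions - base * n_samples):
        counts[i] += 1

    seqmodel = SequencingModel(depth=depth)
    total = ConfusionCounts(0, 0, 0, 0)
    for s, (regions, n_var) in enumerate(zip(per_sample_regions, counts)):
        truth = _random_cohort_truth(design, reference, regions, n_var, rng, min_vaf=min_vaf)
        res = run_sample(
            design, reference, truth, DamageModel(), seqmodel, params,
            seed=_child_seed(seed, 31, s), sample_id=f"cohort_{s}",
            n_molecules=n_molecules,
        )
        region_set = {(iv.contig, p) for iv in regions for p in range(iv.start, iv.end)}
        calls = [c for c in res.pass_calls if (c.contig, c.pos) in region_set]
        total = total + per_base_confusion(calls, truth, regions)
    return CohortValidation(
        confusion=total,
        n_samples=n_samples,
        interrogated_bases=total_bases,
        truth_positions=total_truth_positions,
    )


# ---------------------------------------------------------------------------
# File-based pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured samples through files: FASTQ out, FASTQ back in,
    VCF + QC TSV + evaluation JSON out.  Returns a manifest of outputs."""
    fixture_dir = Path(config.fixture_dir)
    if not (fixture_dir / "panel.tsv").exists():
        raise FileNotFoundError(f"fixture bundle not found in {fixture_dir}")
    design, reference = load_fixture_design(fixture_dir)
    report = validate_design(design, default_constraints(design))
    if not report.passed:
        raise ValueError(f"fixture design fails validation: {report.violations[:3]}")

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": str(config.seed), "config": config.digest()}
    params = config.caller_params()
    seqmodel = config.seq_model()
    qc_records, outputs = [], {"vcf": [], "qc": None, "report": None}

    summary = {}
    for spec in config.samples:
        sample_id = spec["sample_id"]
        truth = make_reference_standards(design, reference, spec["truth"])
        damage = DAMAGE_PRESETS[spec.get("damage", "intact")]
        sample_seed = _child_seed(config.seed, 40, len(qc_records))

        pool = make_sample(design, reference, truth, damage, sample_seed,
                           config.n_molecules, sample_id)
        control = make_sample(design, reference, [], DamageModel(deamination_rate=0.0),
                              _child_seed(config.seed, 41, len(qc_records)),
                              config.n_molecules, sample_id + "_ctl")
        cq_s, cq_c = simulate_qpcr(pool, control)
        dqc = delta_qc(cq_s, cq_c)
        verdict, scaling = triage(dqc, config.triage_threshold)
        lib1, lib2 = simulate_libraries(
            pool, seqmodel, _child_seed(config.seed, 42, len(qc_records)),
            concentration=spec.get("concentration", 4.0), input_scaling=scaling,
        )
        # round-trip the reads through FASTQ like a real run would
        fastqs = []
        for lib in (lib1, lib2):
            r1 = outdir / f"{sample_id}_{lib.library_id}_R1.fastq.gz"
            r2 = outdir / f"{sample_id}_{lib.library_id}_R2.fastq.gz"
            write_fastq(lib, r1, r2)
            fastqs.append((r1, r2))
        libs = [read_fastq_pair(r1, r2) for r1, r2 in fastqs]

        pileups, calls = [], []
        for lib in libs:
            assigned = assign_and_trim(lib, design, params.primer_mismatch_tolerance)
            pileup = build_pileup(assigned, design, reference, params)
            lib_calls, _ = call_library(pileup, params)
            pileups.append(pileup)
            calls.append(lib_calls)
        cons = consensus(calls[0], calls[1], pileups[0], pileups[1], params)
        interpretable, (med1, med2) = sample_interpretability(pileups[0], pileups[1], design, params)
        qc_records.append(
            QCRecord(sample_id, cq_s, cq_c, dqc, verdict, scaling, med1, med2, interpretable)
        )
        vcf_path = outdir / f"{sample_id}.vcf"
        write_consensus_vcf(vcf_path, cons, reference, meta=meta)
        outputs["vcf"].append(str(vcf_path))

        pass_keys = {
            (c.contig, c.pos, c.ref, c.alt)
            for c in cons
            if c.filter_status == FilterStatus.PASS.value
        }
        truth_keys = {(v.contig, v.pos, v.ref, v.alt) for v in truth}
        summary[sample_id] = {
            "interpretable": interpretable,
            "delta_qc": dqc if math.isfinite(dqc) else None,
            "n_pass": len(pass_keys),
            "n_truth": len(truth_keys),
            "tp": len(pass_keys & truth_keys),
            "fp": len(pass_keys - truth_keys),
            "fn": len(truth_keys - pass_keys),
        }

    from .qc import write_qc_tsv

    qc_path = outdir / "qc.tsv"
    write_qc_tsv(qc_records, qc_path, meta=meta)
    outputs["qc"] = str(qc_path)
    report_path = outdir / "report.json"
    with report_path.open("w") as fh:
        json.dump({"meta": meta, "samples": summary}, fh, indent=2, sort_keys=True)
    outputs["report"] = str(report_path)
    return outputs
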