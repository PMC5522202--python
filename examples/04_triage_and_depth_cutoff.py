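"""ΔQc triage of degraded samples and data-driven depth-cutoff choice.

Part 1: samples with increasing FFPE damage get rising qPCR ΔQc scores;
samples over the threshold are flagged DEGRADED_ATTEMPT but still
sequenced, and interpretability is decided afterwards from median depth.

Part 2: a serial dilution of the FFPE control (4 -> 0.03 nM) shows where
concordance with the known truth set breaks down; the depth cutoff is the
lowest median depth of the still-concordant points.
"""

from dualstrand.caller import CallerParams
from dualstrand.fixtures import build_toy_design
from dualstrand.qc import determine_depth_cutoff
from dualstrand.simulate import DAMAGE_PRESETS, SequencingModel, make_reference_standards
from dualstrand.workflow import run_dilution_series, run_sample

design, reference = build_toy_design()
variants = make_reference_standards(design, reference, "FFPE_QM")

print("damage preset -> ΔQc, triage, median depth, interpretable")
for preset in ("intact", "degraded", "severe", "very_severe"):
    res = run_sample(
        design, reference, variants, DAMAGE_PRESETS[preset],
        SequencingModel(depth=1000.0), CallerParams(), seed=3, sample_id=preset,
    )
    q = res.qc
    print(f"  {preset:<12} ΔQc {q.delta_qc:5.2f}  {q.triage:<17} "
          f"depth ({q.median_depth_lib1:.0f}, {q.median_depth_lib2:.0f})  {q.interpretable}")

print("\nserial dilution of the FFPE control:")
points = run_dilution_series(
    design, reference, [4.0, 2.0, 1.0, 0.5, 0.25, 0.03], seed=9, depth=1000.0
)
for p in points:
    print(f"  {p.concentration:5.2f} nM  median depth {p.median_depth:7.1f}  "
          f"TP {p.tp}  FP {p.fp}  FN {p.fn}")
print(f"depth cutoff (lowest fully concordant depth): {determine_depth_cutoff(points):.0f}x")

# Below the cutoff the 1-2% control variants start dropping out (false
# negatives); a laboratory would refuse to interpret samples sequenced
# shallower than this.
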