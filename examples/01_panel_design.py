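"""Build the bundled 16-gene panel and inspect its amplicon design.

Generates the toy reference plus the 150-amplicon tiling, validates it
against the assay's design rules (amplicon 120-150 bp, primers 22-30 bases,
>=5 bp exon padding, >=1 base tiling overlap, full coverage, SNP-free
primers) and prints the design statistics.
"""

from dualstrand.fixtures import build_toy_design, default_constraints
from dualstrand.panel import design_stats, validate_design

design, reference = build_toy_design()
report = validate_design(design, default_constraints(design))
stats = design_stats(design)

print(f"genes: {design.n_genes}, exon targets: {design.n_exon_targets}")
print(f"amplicons: {stats.n_amplicons}")
print(
    "amplicon length (bp): "
    f"min {stats.amplicon_length_min}, median {stats.amplicon_length_median}, "
    f"max {stats.amplicon_length_max}"
)
print(
    "primer length (bases): "
    f"min {stats.primer_length_min}, median {stats.primer_length_median}, "
    f"max {stats.primer_length_max}"
)
print(f"on-target footprint: {stats.total_target_bp} bp")
print(f"design rules: {'all pass' if report.passed else report.violations}")

# Short amplicons are the point: every amplicon stays amplifiable even when
# FFPE fragmentation leaves few templates longer than ~150 bp.
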