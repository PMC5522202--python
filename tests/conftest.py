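"""Shared fixtures: the toy panel design is expensive enough to build once."""

import pytest

from dualstrand.fixtures import build_toy_design
from dualstrand.panel import PanelDesign


@pytest.fixture(scope="session")
def design_ref():
    """The bundled 16-gene / 48-exon / 150-amplicon design plus reference."""
    return build_toy_design()


@pytest.fixture(scope="session")
def design(design_ref):
    return design_ref[0]


@pytest.fixture(scope="session")
def reference(design_ref):
    return design_ref[1]


def make_subdesign(design: PanelDesign, genes: list[str]) -> PanelDesign:
    """Restrict a design to a gene subset (cheap runs for property tests)."""
    keep = set(genes)
    idx = [i for i, r in enumerate(design.target_regions) if r.contig in keep]
    return PanelDesign(
        genes=[g for g in design.genes if g.gene_symbol in keep],
        exon_regions=[design.exon_regions[i] for i in idx],
        target_regions=[design.target_regions[i] for i in idx],
        amplicons=[a for a in design.amplicons if a.contig in keep],
    )


@pytest.fixture(scope="session")
def egfr_design(design):
    """EGFR-only sub-panel (12-ish amplicons) for fast simulations."""
    return make_subdesign(design, ["EGFR"])


@pytest.fixture(scope="session")
def small_design(design):
    """Three-gene sub-panel used by oracle-equivalence runs."""
    return make_subdesign(design, ["EGFR", "KRAS", "BRAF"])
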