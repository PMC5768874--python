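"""Droplet-digital-PCR quantification arithmetic.

ddPCR reports absolute template concentrations (copies/uL). The assay uses
a single-copy reference gene (RPP30) as a surrogate for genome equivalents,
converts copies to mass at 30 ng per 10,000 genome equivalents, measures
adapter-ligation efficiency with a strand-aware factor of two (the ligation
assay only amplifies the adapter-bearing strand, the control assay both),
normalizes copy-number targets to the reference gene and then to a diploid
control sample, and computes library pooling volumes from fragments/uL.
Droplet-level Poisson correction is out of scope: inputs are the
instrument-reported concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass
class DdpcrMeasurement:
    assay: str
    copies_per_ul: float
    channel: str = "FAM"
    linkage: float | None = None  # dual-channel library assays only

    def __post_init__(self):
        if self.copies_per_ul < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class QuantConfig:
    ng_per_10k_copies: float = 30.0  # genome-equivalent mass constant
    pooling_target_fragments: float = 1.2e9  # total library fragments loaded
    dilution_factor: float = 1e-6  # dilution at which libraries are assayed

    def __post_init__(self):
        if self.ng_per_10k_copies <= 0 or self.pooling_target_fragments <= 0:
            raise ValueError("constants must be > 0")


def copies_to_ng(copies: float, config: QuantConfig | None = None) -> float:
    """Convert genome-equivalent copies to mass (ng), linearly."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    config = config or QuantConfig()
    return copies * config.ng_per_10k_copies / 10_000.0


def ng_to_copies(ng: float, config: QuantConfig | None = None) -> float:
    """Inverse of :func:`copies_to_ng`; the round trip is exact."""
    if ng < 0:
        raise ValueError("mass must be >= 0")
    config = config or QuantConfig()
    return ng * 10_000.0 / config.ng_per_10k_copies


def ligation_efficiency(ligated_copies: float, control_copies: float) -> float:
    """(2 x ligated) / control.

    The adapter-ligation assay only yields signal from the single
    adapter-bearing strand while the control assay amplifies both strands,
    hence the factor of two. Values above 1 indicate inconsistent
    measurements and are flagged with a warning, not an error.
    """
    if control_copies <= 0:
        raise ValueError("control copies must be > 0")
    if ligated_copies < 0:
        raise ValueError("ligated copies must be >= 0")
    eff = 2.0 * ligated_copies / control_copies
    if eff > 1.0:
        warnings.warn(
            f"ligation efficiency {eff:.3f} exceeds 1: "
            "ligation and control measurements are inconsistent",
            stacklevel=2)
    return eff


def normalized_copy_ratio(
    target_test: float, reference_test: float,
    target_control: float, reference_control: float,
) -> float:
    """Copy ratio of a target gene, normalized within each sample to a
    reference gene and then across samples to a diploid control:
    (target/reference)_test / (target/reference)_control."""
    for v in (target_test, reference_test, target_control, reference_control):
        if v <= 0:
            raise ValueError("all four measurements must be > 0")
    return (target_test / reference_test) / (target_control / reference_control)


def pooling_volume_ul(
    fragments_per_ul_diluted: float,
    config: QuantConfig | None = None,
    n_libraries: int = 1,
) -> float:
    """Volume of undiluted library per pool member to reach the configured
    total fragment load, given the concentration measured on the diluted
    aliquot."""
    config = config or QuantConfig()
    if fragments_per_ul_diluted <= 0:
        raise ValueError("fragment concentration must be > 0")
    if n_libraries <= 0:
        raise ValueError("n_libraries must be > 0")
    undiluted = fragments_per_ul_diluted / config.dilution_factor
    return config.pooling_target_fragments / n_libraries / undiluted
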