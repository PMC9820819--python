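"""Canonical simulation scenarios used by the validation studies.

Two named study conditions recur throughout the tests and the
reproduction script: a cohort with three planted cross-view subgroups
(the recovery benchmark) and a cohort with fully independent views (the
false-discovery benchmark)."""

from __future__ import annotations

from .cohort import CohortConfig, PlantedRedescription


def planted_config(seed: int, leak: float = 0.05) -> CohortConfig:
    """Three cross-view subgroups (supports in the 40-60 range at
    n = 193) planted on attributes measured for every patient."""
    plants = (
        PlantedRedescription(0.25, (
            ("csf_biomarkers", "VILIP-1", 150.0, 400.0),
            ("csf_elements", "Se_csf", 2.0, 3.6)), leak),
        PlantedRedescription(0.28, (
            ("csf_biomarkers", "PAPP-A", 320.0, 900.0),
            ("csf_elements", "Cu_csf", 25.0, 50.0)), leak),
        PlantedRedescription(0.22, (
            ("csf_biomarkers", "t-tau", 700.0, 2500.0),
            ("csf_elements", "K_csf", 160.0, 400.0)), leak),
    )
    return CohortConfig(planted_redescriptions=plants, seed=seed)


def null_config(seed: int) -> CohortConfig:
    """Independent views: no correlated element blocks and no coupling
    between biomarkers and elements."""
    return CohortConfig(
        factor_blocks=(), biomarker_element_coupling=0.0,
        biomarker_plasma_coupling=0.0, element_severity_coupling=0.0,
        seed=seed)
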