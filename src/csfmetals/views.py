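"""Attribute catalog: views, column names, and synthetic concentration scales.

The cohort table is split into four attribute views over the same patients:

* ``clinical`` — diagnosis (AD / MCI / HC), age, gender, MMSE, APOE
  genotype, disease duration;
* ``csf_biomarkers`` — eleven CSF analytes reflecting Alzheimer pathology
  plus the derived Abeta42/p-tau181 ratio;
* ``csf_elements`` — 24 macro-/microelement concentrations in CSF;
* ``plasma_elements`` — 21 element concentrations in plasma (Al, Ba and K
  are quantified in CSF only).

Element columns are suffixed ``_csf`` / ``_plasma`` so every column name in
the flat per-patient table is unique.
"""

from __future__ import annotations

CLINICAL = ["diagnosis", "age", "gender", "MMSE", "APOE", "disease_duration"]

DIAGNOSES = ["AD", "MCI", "HC"]
GENDERS = ["F", "M"]
APOE_GENOTYPES = ["e2e3", "e2e4", "e3e3", "e3e4", "e4e4"]

BIOMARKERS = [
    "Abeta42",
    "t-tau",
    "p-tau181",
    "p-tau199",
    "p-tau231",
    "VILIP-1",
    "NFL",
    "S100B",
    "YKL-40",
    "PAPP-A",
    "albumin",
]
RATIO = "Abeta42/p-tau181"

CSF_ONLY_ELEMENTS = ["Al", "Ba", "K"]
SHARED_ELEMENTS = [
    "As", "B", "Ca", "Cd", "Co", "Cu", "Fe", "Hg", "Li", "Mg", "Mn",
    "Mo", "Na", "Ni", "P", "Pb", "S", "Se", "Sr", "Tl", "Zn",
]
CSF_ELEMENTS = sorted(CSF_ONLY_ELEMENTS + SHARED_ELEMENTS)
PLASMA_ELEMENTS = list(SHARED_ELEMENTS)


def csf_col(element: str) -> str:
    return f"{element}_csf"


def plasma_col(element: str) -> str:
    return f"{element}_plasma"


VIEW_COLUMNS: dict[str, list[str]] = {
    "clinical": list(CLINICAL),
    "csf_biomarkers": BIOMARKERS + [RATIO],
    "csf_elements": [csf_col(e) for e in CSF_ELEMENTS],
    "plasma_elements": [plasma_col(e) for e in PLASMA_ELEMENTS],
}

CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "diagnosis": DIAGNOSES,
    "gender": GENDERS,
    "APOE": APOE_GENOTYPES,
}

# Synthetic log-normal scales (median, geometric SD on the natural-log
# scale) per element column.  Medians are placed so that typical values
# fall in physiologically plausible ranges for ICP-MS measurements of CSF
# and plasma (plasma electrolytes such as Ca and Na are tightly regulated,
# hence their small spread).  These are synthetic defaults, not measured
# reference intervals.
CSF_ELEMENT_SCALE: dict[str, tuple[float, float]] = {
    "Al": (2.2, 0.50), "As": (0.30, 0.55), "B": (120.0, 0.45),
    "Ba": (8.0, 0.60), "Ca": (47.0, 0.20), "Cd": (0.013, 0.45),
    "Co": (0.10, 0.40), "Cu": (17.0, 0.30), "Fe": (35.0, 0.45),
    "Hg": (0.12, 0.60), "K": (110.0, 0.40), "Li": (2.5, 0.70),
    "Mg": (32.0, 0.18), "Mn": (1.4, 0.45), "Mo": (0.60, 0.50),
    "Na": (3200.0, 0.18), "Ni": (1.2, 0.45), "P": (400.0, 0.45),
    "Pb": (3.0, 0.55), "S": (18.0, 0.35), "Se": (1.2, 0.40),
    "Sr": (30.0, 0.45), "Tl": (0.05, 0.55), "Zn": (70.0, 0.45),
}

PLASMA_ELEMENT_SCALE: dict[str, tuple[float, float]] = {
    "As": (1.0, 0.60), "B": (40.0, 0.40), "Ca": (78.0, 0.06),
    "Cd": (0.04, 0.35), "Co": (0.50, 0.30), "Cu": (1050.0, 0.15),
    "Fe": (480.0, 0.30), "Hg": (0.30, 0.60), "Li": (25.0, 0.50),
    "Mg": (30.0, 0.15), "Mn": (9.0, 0.40), "Mo": (2.2, 0.50),
    "Na": (3850.0, 0.02), "Ni": (1.7, 0.15), "P": (160.0, 0.20),
    "Pb": (125.0, 0.20), "S": (1100.0, 0.15), "Se": (100.0, 0.20),
    "Sr": (26.0, 0.25), "Tl": (0.05, 0.50), "Zn": (900.0, 0.30),
}

# Synthetic biomarker scales: (median, geometric SD, loading of the latent
# disease-severity score on the log concentration).  Amyloid beta falls
# with severity; tau isoforms and the neurodegeneration / glial markers
# rise, reproducing the canonical sign structure of CSF AD biomarkers.
BIOMARKER_SCALE: dict[str, tuple[float, float, float]] = {
    "Abeta42": (650.0, 0.40, -0.45),
    "t-tau": (350.0, 0.55, 0.40),
    "p-tau181": (50.0, 0.50, 0.40),
    "p-tau199": (2.0, 0.60, 0.35),
    "p-tau231": (2.0, 0.65, 0.35),
    "VILIP-1": (90.0, 0.55, 0.35),
    "NFL": (100.0, 0.50, 0.30),
    "S100B": (450.0, 0.55, 0.25),
    "YKL-40": (250000.0, 0.50, 0.25),
    "PAPP-A": (150.0, 0.55, 0.20),
    "albumin": (160.0, 0.45, 0.10),
}

# Default per-attribute missingness fractions, chosen to reproduce the
# varying pairwise-complete n of a cohort where some assays were run on
# subsets only (NFL and CSF P are the sparsest measurements).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "YKL-40": 0.08,
    "S100B": 0.18,
    "NFL": 0.38,
    "PAPP-A": 0.08,
    "albumin": 0.26,
    csf_col("P"): 0.60,
    "disease_duration": 0.05,
}
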