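"""Published FBF-2 / FBF-2:LST-1 measurements used as package inputs.

These are the printed results of the study this package models: equilibrium
dissociation constants (mean +/- SEM over three technical replicate EMSAs)
for FBF-2 alone and in complex with LST-1, and read counts of +4-resolved
compact/extended binding-element patterns in SEQRS selections and FBF-2
CLIP sites. They serve as default simulation parameters (class affinities)
and as inputs for recomputing the derived statistics (Krel, compact:extended
ratios); nothing here is a package output.
"""

from __future__ import annotations

# EMSA protein concentration series (nM), highest first, including the
# protein-free point.
EMSA_CONCENTRATIONS_NM: tuple[float, ...] = (
    4000, 2000, 1000, 500, 250, 125, 62.5, 31.2, 15.6, 7.8, 3.9, 1.95,
    0.98, 0.49, 0,
)

# When LST-1 is present at constant 4 uM, the effective FBF-2 concentration
# is corrected by this dilution factor during analysis.
PARTNER_DILUTION_FACTOR = 0.9

# Measured dissociation constants, nM: {rna_label: (kd_mean, kd_sem)}.
# Krel references: the gld-1 FBEa rows are relative to "gld-1 FBEa", the
# compact-element rows to "cFBE", separately within each protein condition.
KD_FBF2_NM: dict[str, tuple[float, float]] = {
    "gld-1 FBEa": (12.4, 2.0),
    "gld-1 -2U": (32.2, 4.7),
    "gld-1 G4A": (12.0, 1.4),
    "gld-1 C5A": (27.1, 5.4),
    "cFBE-7": (22.0, 2.7),
    "cFBE": (10.3, 2.9),
    "cFBE -1U": (46.5, 4.3),
    "PBE": (56.8, 13.7),
    "cFBE G4A": (18.8, 3.0),
    "cFBE A5C": (19.5, 2.5),
    "cFBE A5U": (25.5, 5.5),
    "cFBE G8A": (21.1, 2.5),
}

KD_COMPLEX_NM: dict[str, tuple[float, float]] = {
    "gld-1 FBEa": (46.4, 5.0),
    "gld-1 -2U": (101.3, 13.2),
    "gld-1 G4A": (34.4, 5.6),
    "gld-1 C5A": (79.2, 8.8),
    "cFBE-7": (111.7, 7.7),
    "cFBE": (38.7, 5.0),
    "cFBE -1U": (175.9, 37.8),
    "PBE": (814.0, 180.0),
    "cFBE G4A": (82.7, 16.0),
    "cFBE A5C": (82.3, 18.8),
    "cFBE A5U": (133.2, 23.8),
    "cFBE G8A": (84.4, 20.2),
}

# Krel reference RNA per row label.
KREL_REFERENCE: dict[str, str] = {
    "gld-1 FBEa": "gld-1 FBEa",
    "gld-1 -2U": "gld-1 FBEa",
    "gld-1 G4A": "gld-1 FBEa",
    "gld-1 C5A": "gld-1 FBEa",
    "cFBE-7": "cFBE",
    "cFBE": "cFBE",
    "cFBE -1U": "cFBE",
    "PBE": "cFBE",
    "cFBE G4A": "cFBE",
    "cFBE A5C": "cFBE",
    "cFBE A5U": "cFBE",
    "cFBE G8A": "cFBE",
}

# Published read counts of +4-resolved element patterns:
# {(dataset, pattern_name): count} with pattern names matching
# motif.BUILTIN_PATTERNS. Datasets: FBF-2-alone SEQRS, FBF-2/LST-1 complex
# SEQRS, and FBF-2 CLIP sites.
SEQRS_ELEMENT_COUNTS: dict[tuple[str, str], int] = {
    ("FBF-2", "extended_A4"): 119374,
    ("FBF-2", "compact_A4"): 24819,
    ("FBF-2", "extended_G4"): 1970,
    ("FBF-2", "compact_G4"): 5506,
    ("Complex", "extended_A4"): 170,
    ("Complex", "compact_A4"): 118,
    ("Complex", "extended_G4"): 113,
    ("Complex", "compact_G4"): 126,
    ("CLIP", "extended_A4"): 266,
    ("CLIP", "compact_A4"): 117,
    ("CLIP", "extended_G4"): 92,
    ("CLIP", "compact_G4"): 102,
}

# Default class affinities (nM) for the selection simulator, taken from the
# measured Kds of representative RNAs for each element class under FBF-2
# alone: cFBE (compact G4), PBE (compact A4), gld-1 FBEa (extended G4),
# gld-1 G4A (extended A4).
DEFAULT_CLASS_KD_NM: dict[str, float] = {
    "compact_G4": 10.3,
    "compact_A4": 56.8,
    "extended_G4": 12.4,
    "extended_A4": 12.0,
}
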