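"""Packaged study inputs.

Small, hand-entered tables that the pipeline treats as *inputs*: the ND1
SNP-panel definition for the two reference breeds, the published per-animal
base calls, and the platform probe counts.  Everything here is plain data;
all logic lives in the analysis modules.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# ND1 SNP panel
# ---------------------------------------------------------------------------

#: All nine panel positions carried in genotypes (1-based, ND1 start = base 1).
PANEL_POSITIONS: tuple[int, ...] = (316, 342, 369, 420, 438, 459, 489, 528, 712)

#: Reference base calls at the panel positions, per breed.
LARGE_WHITE_CALLS: dict[int, str] = {
    316: "C", 342: "T", 369: "T", 420: "T", 438: "G",
    459: "G", 489: "C", 528: "T", 712: "C",
}
DUROC_CALLS: dict[int, str] = {
    316: "C", 342: "C", 369: "C", 420: "C", 438: "A",
    459: "A", 489: "A", 528: "T", 712: "T",
}

LARGE_WHITE_ACCESSION = "AF486874"
DUROC_ACCESSION = "AY337045"

#: The seven breed-discriminating substitutions (position, Large White base,
#: Duroc base).  Positions 316 and 528 are carried but do not discriminate.
DISCRIMINATING_PANEL: tuple[tuple[int, str, str], ...] = (
    (342, "T", "C"),
    (369, "T", "C"),
    (420, "T", "C"),
    (438, "G", "A"),
    (459, "G", "A"),
    (489, "C", "A"),
    (712, "C", "T"),
)

#: Full panel for reference-pair construction: discriminating substitutions
#: plus the two shared positions (same base in both breeds).
FULL_PANEL: tuple[tuple[int, str, str], ...] = (
    (316, "C", "C"),
    (342, "T", "C"),
    (369, "T", "C"),
    (420, "T", "C"),
    (438, "G", "A"),
    (459, "G", "A"),
    (489, "C", "A"),
    (528, "T", "T"),
    (712, "C", "T"),
)

#: ND1 coding length in bases (in frame; a multiple of 3).
ND1_LENGTH = 957

# ---------------------------------------------------------------------------
# Published per-animal base calls
# ---------------------------------------------------------------------------

#: (animal_id, group, role, raw base tokens at PANEL_POSITIONS order).
#: Tokens are kept verbatim as printed; "T2" for animal 44-1 at base 316 is a
#: typesetting artifact the genotype parser reads as "T" (with a warning).
ANIMAL_PANEL_CALLS: tuple[tuple[str, str, str, tuple[str, ...]], ...] = (
    ("263-1", "deceased", "control", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("263-2", "deceased", "control", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("263-3", "deceased", "control", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("263-4", "deceased", "control", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("263-5", "deceased", "control", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("628-1", "deceased", "clone", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("629-1", "deceased", "clone", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("635-1", "deceased", "clone", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("635-2", "deceased", "clone", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("637-1", "deceased", "clone", ("C", "T", "T", "T", "G", "G", "C", "C", "C")),
    ("642-1", "deceased", "clone", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("671-5", "deceased", "clone", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("42-7", "live", "control", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("42-8", "live", "control", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("42-11", "live", "control", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("42-12", "live", "control", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("47-2", "live", "control", ("C", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("43-1", "live", "clone", ("C", "T", "T", "T", "G", "G", "C", "T", "C")),
    ("43-2", "live", "clone", ("C", "T", "T", "T", "G", "G", "C", "T", "C")),
    ("43-3", "live", "clone", ("C", "T", "T", "T", "G", "G", "C", "T", "C")),
    ("44-1", "live", "clone", ("T2", "C", "C", "C", "A", "A", "A", "T", "T")),
    ("45-1", "live", "clone", ("C", "T", "T", "T", "G", "G", "C", "T", "C")),
)

# ---------------------------------------------------------------------------
# Platform / informative-probe bookkeeping
# ---------------------------------------------------------------------------

PLATFORM_PROBES = 13_310
NUCLEAR_MITO_PROBES = 534
MTDNA_PROBES = 32

#: Published informative-probe counts per analysis group (used only as
#: *inputs* to percentage reporting, never recomputed from these numbers).
PUBLISHED_INFORMATIVE_COUNTS: dict[str, int] = {
    "deceased": 9_297,
    "live": 9_955,
}

#: Protein-coding mtDNA gene symbols used when labelling simulated probes.
MTDNA_PROTEIN_GENES: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB",
)
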