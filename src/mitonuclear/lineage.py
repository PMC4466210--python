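"""Maternal-lineage determination from ND1 SNP-panel genotypes.

Assigns each animal to a breed haplotype by exact matching at the
discriminating panel positions, flags private variants, classifies the
protein-level effect of substitutions under the vertebrate mitochondrial
genetic code, and applies a simple detectability rule for heteroplasmic
mixtures.

Coordinates are 1-based and inclusive on the ND1 coding strand, with base 1
being the first base of the gene; codon effects assume base 1 is also the
first base of codon 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

UNRESOLVED = "UNRESOLVED"

# ---------------------------------------------------------------------------
# Genetic code: vertebrate mitochondrial
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STANDARD_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
STANDARD_CODE: dict[str, str] = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(
        ((x, y, z) for x in _BASES for y in _BASES for z in _BASES),
        _STANDARD_AAS,
    )
}

#: Vertebrate mitochondrial code: standard code with the four reassignments
#: AGA/AGG -> stop, ATA -> Met, TGA -> Trp.
VERTEBRATE_MITO_CODE: dict[str, str] = {
    **STANDARD_CODE,
    "AGA": "*",
    "AGG": "*",
    "ATA": "M",
    "TGA": "W",
}

#: IUPAC nucleotide ambiguity codes mapped to the set of bases they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class LineageError(ValueError):
    """Raised for invalid genotypes, references, or panel definitions."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeReference:
    """A named breed haplotype: base calls at panel positions plus an
    optional in-frame coding sequence."""

    breed_name: str
    accession_label: str
    panel_calls: dict[int, str]
    coding_sequence: str | None = None

    def __post_init__(self) -> None:
        positions = list(self.panel_calls)
        if positions != sorted(positions):
            raise LineageError("panel positions must be strictly increasing")
        if any(p < 1 for p in positions):
            raise LineageError("panel positions are 1-based (>= 1)")
        bad = {b for b in self.panel_calls.values() if b not in "ACGT"}
        if bad:
            raise LineageError(f"reference base calls must be A/C/G/T, got {sorted(bad)}")
        if self.coding_sequence is not None:
            for pos, base in self.panel_calls.items():
                if pos > len(self.coding_sequence):
                    raise LineageError(
                        f"panel position {pos} beyond coding sequence "
                        f"length {len(self.coding_sequence)}"
                    )
                if self.coding_sequence[pos - 1] != base:
                    raise LineageError(
                        f"coding sequence disagrees with panel call at {pos}"
                    )


@dataclass
class PanelGenotype:
    """Observed base calls of one animal at the panel positions.

    ``mixed_positions`` marks calls that came from explicitly mixed
    sequencing peaks (heteroplasmy); only those may use an IUPAC ambiguity
    code for breed scoring.
    """

    animal_id: str
    group: str
    role: str
    calls: dict[int, str]
    mixed_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.calls:
            raise LineageError(f"{self.animal_id}: empty genotype")
        for pos, base in self.calls.items():
            if not base:
                raise LineageError(f"{self.animal_id}: empty call at {pos}")
            if base not in IUPAC_CODES:
                raise LineageError(
                    f"{self.animal_id}: non-IUPAC character {base!r} at position {pos}"
                )


@dataclass
class LineageCall:
    """Outcome of breed assignment for one animal."""

    animal_id: str
    assigned_breed: str
    match_score: int
    scores_per_reference: dict[str, int]
    private_variants: list[tuple[int, str, tuple[str, ...]]] = field(default_factory=list)
    codon_effects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.assigned_breed != UNRESOLVED


@dataclass(frozen=True)
class HeteroplasmyObservation:
    """A mixed-peak observation at one position with its minor fraction."""

    position: int
    major_base: str
    minor_base: str
    minor_fraction: float
    threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_fraction <= 0.5:
            raise LineageError("minor_fraction must lie in [0, 0.5]")
        if not 0.0 < self.threshold < 1.0:
            raise LineageError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def parse_base_token(token: str, *, animal_id: str = "?", position: int = 0) -> str:
    """Read one printed base token, tolerating trailing digits.

    Tokens such as ``"T2"`` (a typesetting artifact) are read as their
    leading IUPAC letter with a logged warning.
    """
    token = token.strip()
    if not token:
        raise LineageError(f"{animal_id}: empty call at position {position}")
    base = token[0].upper()
    if base not in IUPAC_CODES:
        raise LineageError(
            f"{animal_id}: non-IUPAC character {token!r} at position {position}"
        )
    if len(token) > 1:
        if not token[1:].isdigit():
            raise LineageError(
                f"{animal_id}: unparseable call {token!r} at position {position}"
            )
        logger.warning(
            "animal %s, position %d: reading token %r as base %s",
            animal_id, position, token, base,
        )
    return base


def extract_panel_genotype(
    fragment: str,
    offset: int,
    panel_positions: list[int] | tuple[int, ...],
    *,
    animal_id: str = "?",
    group: str = "?",
    role: str = "?",
    mixed_positions: frozenset[int] = frozenset(),
) -> PanelGenotype:
    """Read panel base calls out of a sequenced fragment.

    ``offset`` is the gene coordinate of the fragment's first base, so panel
    position ``p`` is read at fragment index ``p - offset + 1`` (1-based).
    """
    fragment = fragment.upper()
    missing = [p for p in panel_positions if not (offset <= p <= offset + len(fragment) - 1)]
    if missing:
        raise LineageError(
            f"{animal_id}: fragment [{offset}, {offset + len(fragment) - 1}] does not "
            f"cover panel positions {missing}"
        )
    calls: dict[int, str] = {}
    for p in sorted(panel_positions):
        base = fragment[p - offset]
        if base not in IUPAC_CODES:
            raise LineageError(
                f"{animal_id}: non-IUPAC character {base!r} at position {p}"
            )
        calls[p] = base
    return PanelGenotype(
        animal_id=animal_id, group=group, role=role,
        calls=calls, mixed_positions=mixed_positions,
    )


def discriminating_positions(
    ref_a: HaplotypeReference, ref_b: HaplotypeReference
) -> list[int]:
    """Panel positions where the two references carry different bases."""
    if set(ref_a.panel_calls) != set(ref_b.panel_calls):
        raise LineageError(
            f"references {ref_a.breed_name} and {ref_b.breed_name} "
            "cover different position sets"
        )
    return sorted(p for p in ref_a.panel_calls if ref_a.panel_calls[p] != ref_b.panel_calls[p])


def _all_discriminating(refs: list[HaplotypeReference]) -> list[int]:
    positions = set(refs[0].panel_calls)
    for r in refs[1:]:
        if set(r.panel_calls) != positions:
            raise LineageError("references cover different position sets")
    return sorted(
        p for p in positions
        if len({r.panel_calls[p] for r in refs}) > 1
    )


def _call_matches(call: str, ref_base: str, heteroplasmic: bool) -> bool:
    # An exact base always scores; an ambiguity code scores only when the
    # call is a flagged mixed peak and the reference base is in its set.
    if call == ref_base:
        return True
    if call in "ACGT":
        return False
    return heteroplasmic and ref_base in IUPAC_CODES[call]


def assign_lineage(
    genotype: PanelGenotype,
    refs: list[HaplotypeReference],
) -> LineageCall:
    """Score the genotype against each reference at the discriminating
    positions; the unique best-scoring breed wins, ties are UNRESOLVED.

    Private variants are panel positions where the observed (unambiguous)
    base differs from every reference.  When a reference carries a coding
    sequence, each private variant's codon effect is classified against it.
    """
    if len(refs) < 2:
        raise LineageError("need at least two references")
    disc = _all_discriminating(refs)
    if not disc:
        raise LineageError("references do not discriminate (no differing positions)")
    covered = [p for p in disc if p in genotype.calls]
    if not covered:
        raise LineageError(
            f"{genotype.animal_id}: genotype covers none of the discriminating "
            f"positions {disc}"
        )

    scores = {
        r.breed_name: sum(
            _call_matches(genotype.calls[p], r.panel_calls[p], p in genotype.mixed_positions)
            for p in covered
        )
        for r in refs
    }
    best = max(scores.values())
    winners = [b for b, s in scores.items() if s == best]
    if best == 0 or len(winners) > 1:
        assigned = UNRESOLVED
    else:
        assigned = winners[0]

    private: list[tuple[int, str, tuple[str, ...]]] = []
    for p in sorted(genotype.calls):
        if p not in refs[0].panel_calls:
            continue
        obs = genotype.calls[p]
        ref_bases = tuple(r.panel_calls[p] for r in refs)
        if obs in "ACGT" and all(obs != rb for rb in ref_bases):
            private.append((p, obs, ref_bases))

    effects: list[tuple[int, str]] = []
    ref_by_name = {r.breed_name: r for r in refs}
    effect_ref = ref_by_name.get(assigned, refs[0])
    for p, obs, _ in private:
        if effect_ref.coding_sequence is None:
            effects.append((p, "unknown"))
        else:
            effects.append((p, classify_codon_effect(effect_ref.coding_sequence, p, obs)))

    return LineageCall(
        animal_id=genotype.animal_id,
        assigned_breed=assigned,
        match_score=best,
        scores_per_reference=scores,
        private_variants=private,
        codon_effects=effects,
    )


def classify_codon_effect(cds: str, position: int, alt_base: str) -> str:
    """Effect of a single-base substitution under the vertebrate
    mitochondrial code: 'synonymous', 'missense', or 'nonsense'."""
    cds = cds.upper()
    alt_base = alt_base.upper()
    if len(cds) % 3 != 0:
        raise LineageError("coding sequence length is not a multiple of 3")
    if not 1 <= position <= len(cds):
        raise LineageError(f"position {position} outside coding sequence")
    if alt_base not in "ACGT":
        raise LineageError(f"alt base must be A/C/G/T, got {alt_base!r}")
    ref_base = cds[position - 1]
    if alt_base == ref_base:
        raise LineageError(f"not a substitution: {ref_base}>{alt_base} at {position}")
    codon_start = (position - 1) // 3 * 3
    within = (position - 1) % 3
    codon = cds[codon_start:codon_start + 3]
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = VERTEBRATE_MITO_CODE[codon]
    aa_alt = VERTEBRATE_MITO_CODE[alt_codon]
    if aa_alt == "*":
        return "nonsense"
    if aa_alt == aa_ref:
        return "synonymous"
    return "missense"


def detect_heteroplasmy(obs: HeteroplasmyObservation) -> bool:
    """A mixture is called detectable iff the minor fraction strictly
    exceeds the threshold (default 25%)."""
    return obs.minor_fraction > obs.threshold


def lineage_report(
    calls: list[LineageCall],
    design: pd.DataFrame,
) -> dict:
    """Tabulate breed assignments by group and role.

    ``design`` needs columns animal_id/group/role.  Returns per-(group, role)
    breed counts, the list of unresolved animals, and a survival-by-breed
    2x2 table over clones (rows: deceased/live; columns: breeds) suitable for
    :func:`mitonuclear.diffexpr.fisher_exact`.
    """
    by_animal = {c.animal_id: c for c in calls}
    missing = [a for a in design["animal_id"] if a not in by_animal]
    if missing:
        raise LineageError(f"no lineage call for animals: {missing}")

    counts: dict[tuple[str, str], dict[str, int]] = {}
    unresolved: list[str] = []
    breeds: set[str] = set()
    for _, row in design.iterrows():
        call = by_animal[row["animal_id"]]
        if not call.resolved:
            unresolved.append(call.animal_id)
            continue
        key = (row["group"], row["role"])
        counts.setdefault(key, {})
        counts[key][call.assigned_breed] = counts[key].get(call.assigned_breed, 0) + 1
        breeds.add(call.assigned_breed)

    breed_order = sorted(breeds)
    survival_table = [
        [counts.get((grp, "clone"), {}).get(b, 0) for b in breed_order]
        for grp in ("deceased", "live")
    ]
    return {
        "counts": {f"{g}/{r}": dict(v) for (g, r), v in sorted(counts.items())},
        "unresolved": unresolved,
        "survival_by_breed": {"breeds": breed_order, "table": survival_table},
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel_tsv(path: str | Path) -> list[HaplotypeReference]:
    """Read a panel definition TSV (columns: position, then one column of
    bases per breed, plus an ``accession_<breed>`` header row convention is
    not used — accessions come from a companion ``# accession:`` comment or
    default to the breed name)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    breed_cols = [c for c in df.columns if c != "position"]
    refs = []
    for breed in breed_cols:
        calls = {int(p): str(b).upper() for p, b in zip(df["position"], df[breed])}
        refs.append(HaplotypeReference(breed_name=breed, accession_label=breed, panel_calls=calls))
    return refs


def calls_to_frame(calls: list[LineageCall]) -> pd.DataFrame:
    """Flatten lineage calls to the ``lineage_calls.tsv`` schema."""
    rows = []
    for c in calls:
        rows.append({
            "animal_id": c.animal_id,
            "assigned_breed": c.assigned_breed,
            "match_score": c.match_score,
            **{f"score_{b}": s for b, s in sorted(c.scores_per_reference.items())},
            "private_variants": ";".join(
                f"{p}:{obs}>{'/'.join(rb)}" for p, obs, rb in c.private_variants
            ),
            "codon_effects": ";".join(f"{p}:{e}" for p, e in c.codon_effects),
        })
    return pd.DataFrame(rows)


def genotypes_from_printed_tokens(
    records: tuple[tuple[str, str, str, tuple[str, ...]], ...],
    positions: tuple[int, ...],
) -> list[PanelGenotype]:
    """Build genotypes from printed-table tokens (see datasets module)."""
    out = []
    for animal_id, group, role, tokens in records:
        if len(tokens) != len(positions):
            raise LineageError(f"{animal_id}: expected {len(positions)} calls")
        calls = {
            p: parse_base_token(t, animal_id=animal_id, position=p)
            for p, t in zip(positions, tokens)
        }
        out.append(PanelGenotype(animal_id=animal_id, group=group, role=role, calls=calls))
    return out
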