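"""Synthetic-data generation for every pipeline input.

Produces, from one seeded configuration: a pair of breed reference ND1
sequences whose discriminating substitutions are synonymous by construction,
a cohort of animals with panel genotypes (optionally heteroplasmic), a
latent log2 expression model with a tunable mitonuclear coordination
parameter, dye-swap two-channel slides with intensity-dependent dye bias,
and comparative-CT qPCR panels consistent with the latent expression.

Latent model: probe log2 expression = baseline + loading x factor score
(+ treatment effect on clones) (+ measurement noise at the slide stage).
Nuclear mitochondrial-function probes load on a shared factor f; mtDNA
probes load on sqrt(rho) * f + sqrt(1 - rho) * g with g independent, so
``coordination_rho`` is the fraction of mtDNA factor variance shared with
the nuclear factor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .array_processing import (
    ArraySlide,
    ExpressionMatrix,
    SAMPLE_IN_CY3,
    SAMPLE_IN_CY5,
    write_slide_tsv,
)
from .lineage import (
    IUPAC_CODES,
    HaplotypeReference,
    PanelGenotype,
    VERTEBRATE_MITO_CODE,
)

DEFAULT_COHORT: tuple[tuple[str, str, int], ...] = (
    ("deceased", "clone", 7),
    ("deceased", "control", 5),
    ("live", "clone", 5),
    ("live", "control", 5),
)

#: Position and alt base of the optional planted nonsense variant.
NONSENSE_POSITION = 528
NONSENSE_ALT_BASE = "A"

_BASE_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_CODES.items()}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the generator; identical configs give bit-identical
    outputs.

    ``dye_bias_coeffs`` are polynomial coefficients of the dye bias in M as
    a function of A, in increasing order of degree.  ``treatment_effect_scope``
    selects which probes receive treatment effects ('all', 'nuclear', or
    'none'); 'nuclear' leaves mtDNA-encoded probes unshifted.
    """

    n_probes: int = datasets.PLATFORM_PROBES
    n_nuclear_mito: int = datasets.NUCLEAR_MITO_PROBES
    n_mtdna: int = datasets.MTDNA_PROBES
    cohort: tuple[tuple[str, str, int], ...] = DEFAULT_COHORT
    coordination_rho: float = 0.8
    treatment_effect_sd: float = 0.5
    treatment_effect_scope: str = "all"
    tissue_profile_sd: float = 1.0
    noise_sd: float = 0.3
    dye_bias_coeffs: tuple[float, ...] = (0.0,)
    present_fraction_null: float = 0.05
    heteroplasmy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort = tuple(tuple(entry) for entry in self.cohort)
        self.dye_bias_coeffs = tuple(float(c) for c in self.dye_bias_coeffs)
        if self.n_nuclear_mito + self.n_mtdna > self.n_probes:
            raise SimulationError("n_nuclear_mito + n_mtdna exceeds n_probes")
        if min(self.n_probes, self.n_nuclear_mito, self.n_mtdna) < 0:
            raise SimulationError("probe counts must be non-negative")
        if not 0.0 <= self.coordination_rho <= 1.0:
            raise SimulationError("coordination_rho must lie in [0, 1]")
        for name in ("treatment_effect_sd", "tissue_profile_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("present_fraction_null", "heteroplasmy_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.treatment_effect_scope not in ("all", "nuclear", "none"):
            raise SimulationError(
                f"unknown treatment_effect_scope {self.treatment_effect_scope!r}"
            )
        for group, role, count in self.cohort:
            if group not in ("deceased", "live") or role not in ("clone", "control"):
                raise SimulationError(f"bad cohort entry ({group}, {role}, {count})")
            if count < 0:
                raise SimulationError("cohort counts must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    # Independent, reproducible streams keyed off the one config seed.
    return np.random.default_rng([config_seed, stream])


# ---------------------------------------------------------------------------
# Reference pair
# ---------------------------------------------------------------------------

def _codon_candidates(
    constraints: list[tuple[int, str, str]],
    plant_nonsense: bool,
) -> list[tuple[str, str]]:
    """All (codon_a, codon_b) satisfying the per-codon base constraints with
    every individual a->b substitution synonymous and stop-free."""
    bases = "TCAG"
    out = []
    for codon in ("".join((x, y, z)) for x in bases for y in bases for z in bases):
        if VERTEBRATE_MITO_CODE[codon] == "*":
            continue
        if any(codon[off] != a for off, a, _ in constraints):
            continue
        alt = list(codon)
        for off, _, b in constraints:
            alt[off] = b
        alt_codon = "".join(alt)
        if VERTEBRATE_MITO_CODE[alt_codon] == "*":
            continue
        if any(a != b for _, a, b in constraints):
            if VERTEBRATE_MITO_CODE[alt_codon] != VERTEBRATE_MITO_CODE[codon]:
                continue
            ok = True
            for off, a, b in constraints:
                if a == b:
                    continue
                single = codon[:off] + b + codon[off + 1:]
                if (VERTEBRATE_MITO_CODE[single] == "*"
                        or VERTEBRATE_MITO_CODE[single] != VERTEBRATE_MITO_CODE[codon]):
                    ok = False
                    break
            if not ok:
                continue
        if plant_nonsense:
            # The planted variant must be able to create a stop at the
            # nonsense offset with a single base change.
            off = (NONSENSE_POSITION - 1) % 3
            single = codon[:off] + NONSENSE_ALT_BASE + codon[off + 1:]
            if VERTEBRATE_MITO_CODE[single] != "*":
                continue
        out.append((codon, alt_codon))
    return out


def generate_reference_pair(
    seed: int,
    panel: tuple[tuple[int, str, str], ...] = datasets.FULL_PANEL,
    length: int = datasets.ND1_LENGTH,
    plant_nonsense: bool = False,
    breed_names: tuple[str, str] = ("Large White", "Duroc"),
    accessions: tuple[str, str] = (
        datasets.LARGE_WHITE_ACCESSION, datasets.DUROC_ACCESSION,
    ),
) -> tuple[HaplotypeReference, HaplotypeReference]:
    """Construct two in-frame breed reference sequences differing exactly at
    the panel positions, every substitution synonymous under the vertebrate
    mitochondrial code.

    With ``plant_nonsense`` the codon covering position 528 is chosen so
    that the single substitution 528->``A`` creates a stop codon (the
    published observed base C at a third codon position cannot produce a
    stop in this code, so the planted alt differs from the published one).
    """
    if length % 3 != 0:
        raise SimulationError("sequence length must be a multiple of 3")
    beyond = [p for p, _, _ in panel if not 1 <= p <= length]
    if beyond:
        raise SimulationError(f"panel positions beyond sequence length: {beyond}")

    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for pos, a, b in panel:
        ci = (pos - 1) // 3
        by_codon.setdefault(ci, []).append(((pos - 1) % 3, a.upper(), b.upper()))

    rng = np.random.default_rng(seed)
    n_codons = length // 3
    non_stop = sorted(c for c, aa in VERTEBRATE_MITO_CODE.items() if aa != "*")
    codons_a = list(rng.choice(non_stop, size=n_codons))
    if 0 not in by_codon:
        codons_a[0] = "ATG"
    codons_b = list(codons_a)

    for ci, constraints in sorted(by_codon.items()):
        nonsense_here = plant_nonsense and ci == (NONSENSE_POSITION - 1) // 3
        candidates = _codon_candidates(constraints, nonsense_here)
        if not candidates:
            positions = sorted(ci * 3 + off + 1 for off, _, _ in constraints)
            raise SimulationError(
                f"no synonymous codon construction possible at position(s) {positions}"
            )
        codon_a, codon_b = candidates[int(rng.integers(len(candidates)))]
        codons_a[ci] = codon_a
        codons_b[ci] = codon_b

    seq_a = "".join(codons_a)
    seq_b = "".join(codons_b)
    calls_a = {p: a.upper() for p, a, _ in panel}
    calls_b = {p: b.upper() for p, _, b in panel}
    ref_a = HaplotypeReference(breed_names[0], accessions[0], calls_a, seq_a)
    ref_b = HaplotypeReference(breed_names[1], accessions[1], calls_b, seq_b)
    return ref_a, ref_b


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Animal:
    animal_id: str
    group: str
    role: str
    breed: str
    genotype: PanelGenotype
    minor_breed: str | None = None
    minor_fraction: float = 0.0

    @property
    def heteroplasmic(self) -> bool:
        return self.minor_fraction > 0.0


def _match_breed(calls: dict[int, str], refs: tuple[HaplotypeReference, ...]) -> str:
    disc = [
        p for p in refs[0].panel_calls
        if len({r.panel_calls[p] for r in refs}) > 1
    ]
    scores = {
        r.breed_name: sum(calls.get(p) == r.panel_calls[p] for p in disc)
        for r in refs
    }
    return max(scores, key=lambda b: (scores[b], b))


def generate_cohort(
    config: SimulationConfig,
    refs: tuple[HaplotypeReference, HaplotypeReference] | None = None,
    detect_threshold: float = 0.25,
) -> list[Animal]:
    """Animals with breed labels and panel genotypes.

    The default cohort reproduces the published animal ids and base calls
    (breed labels therefore mirror the published assignments); other cohort
    designs draw breeds at random.  With ``heteroplasmy_fraction`` > 0, that
    share of clones carries a minor haplotype; mixed-peak IUPAC calls appear
    in the genotype only when the minor fraction exceeds the sequencing
    detectability threshold.
    """
    if refs is None:
        refs = generate_reference_pair(config.seed)
    rng = _rng(config.seed, 1)

    animals: list[Animal] = []
    if config.cohort == DEFAULT_COHORT:
        from .lineage import genotypes_from_printed_tokens

        genotypes = genotypes_from_printed_tokens(
            datasets.ANIMAL_PANEL_CALLS, datasets.PANEL_POSITIONS
        )
        for g in genotypes:
            animals.append(Animal(
                animal_id=g.animal_id, group=g.group, role=g.role,
                breed=_match_breed(g.calls, refs), genotype=g,
            ))
    else:
        for group, role, count in config.cohort:
            for i in range(count):
                breed_idx = int(rng.integers(2))
                ref = refs[breed_idx]
                animal_id = f"{group}-{role}-{i + 1}"
                calls = dict(ref.panel_calls)
                genotype = PanelGenotype(
                    animal_id=animal_id, group=group, role=role, calls=calls,
                )
                animals.append(Animal(
                    animal_id=animal_id, group=group, role=role,
                    breed=ref.breed_name, genotype=genotype,
                ))

    if config.heteroplasmy_fraction > 0:
        by_breed = {r.breed_name: r for r in refs}
        for animal in animals:
            if animal.role != "clone":
                continue
            if rng.random() >= config.heteroplasmy_fraction:
                continue
            other = next(b for b in by_breed if b != animal.breed)
            animal.minor_breed = other
            animal.minor_fraction = float(rng.uniform(0.05, 0.5))
            if animal.minor_fraction > detect_threshold:
                minor_calls = by_breed[other].panel_calls
                mixed = set()
                new_calls = dict(animal.genotype.calls)
                for p, base in new_calls.items():
                    minor = minor_calls.get(p)
                    if minor is not None and minor != base and base in "ACGT":
                        new_calls[p] = _BASE_TO_IUPAC[frozenset({base, minor})]
                        mixed.add(p)
                animal.genotype = PanelGenotype(
                    animal_id=animal.animal_id, group=animal.group,
                    role=animal.role, calls=new_calls,
                    mixed_positions=frozenset(mixed),
                )
    return animals


def cohort_design(animals: list[Animal]) -> pd.DataFrame:
    return pd.DataFrame([
        {"animal_id": a.animal_id, "group": a.group, "role": a.role, "breed": a.breed}
        for a in animals
    ])


# ---------------------------------------------------------------------------
# Latent expression
# ---------------------------------------------------------------------------

@dataclass
class LatentExpression:
    """True log2 expression (probes x samples) plus the generating pieces."""

    matrix: np.ndarray
    treatment_effects: np.ndarray
    factor_loadings: np.ndarray
    probe_ids: np.ndarray
    sample_ids: list[str]
    baselines: np.ndarray
    nuclear_factor: np.ndarray
    clone_mask: np.ndarray

    @property
    def signal(self) -> np.ndarray:
        """log2(sample/reference): the latent matrix minus baselines."""
        return self.matrix - self.baselines[:, None]

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def probe_ids_for(config: SimulationConfig) -> np.ndarray:
    width = max(6, len(str(config.n_probes)))
    return np.array([f"P{i + 1:0{width}d}" for i in range(config.n_probes)])


def probe_classes(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(is_nuclear_mito, is_mtdna) masks under the fixed probe layout:
    nuclear-mito probes first, then mtDNA probes, then the rest."""
    nm = np.zeros(config.n_probes, bool)
    mt = np.zeros(config.n_probes, bool)
    nm[: config.n_nuclear_mito] = True
    mt[config.n_nuclear_mito: config.n_nuclear_mito + config.n_mtdna] = True
    return nm, mt


def generate_latent(
    config: SimulationConfig,
    animals: list[Animal] | None = None,
) -> LatentExpression:
    """Draw factor scores, loadings, baselines and treatment effects."""
    if animals is None:
        animals = generate_cohort(config)
    rng = _rng(config.seed, 2)
    n_samples = len(animals)
    n = config.n_probes
    nm, mt = probe_classes(config)

    f = rng.standard_normal(n_samples)          # shared nuclear-mito factor
    g = rng.standard_normal(n_samples)          # mtDNA-private factor
    rho = config.coordination_rho
    mito_factor = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * g

    # Signed loadings keep each sample's median log ratio near zero, which
    # the within-slide normalization assumes; mtDNA loadings stay positive so
    # the mean mtDNA profile tracks the mito factor directly.
    loadings = np.empty(n)
    signs = rng.choice([-1.0, 1.0], n)
    loadings[nm] = rng.uniform(0.15, 0.45, nm.sum()) * signs[nm]
    loadings[mt] = rng.uniform(0.15, 0.45, mt.sum())
    other = ~(nm | mt)
    loadings[other] = rng.uniform(0.0, 0.2, other.sum()) * signs[other]

    factor_scores = np.empty((n, n_samples))
    factor_scores[~mt] = f[None, :]
    factor_scores[mt] = mito_factor[None, :]

    effects = rng.normal(0.0, config.treatment_effect_sd, n) \
        if config.treatment_effect_sd > 0 else np.zeros(n)
    if config.treatment_effect_scope == "none":
        effects = np.zeros(n)
    elif config.treatment_effect_scope == "nuclear":
        effects = np.where(mt, 0.0, effects)

    clone_mask = np.array([a.role == "clone" for a in animals])
    baselines = rng.uniform(6.5, 16.0, n)
    # Shared tissue profile: every sample's log ratio against the pooled
    # reference carries the same large tissue-specific component, which is
    # what makes all samples positively correlated before any treatment or
    # factor structure is layered on.
    tissue = rng.normal(0.0, config.tissue_profile_sd, n) \
        if config.tissue_profile_sd > 0 else np.zeros(n)

    signal = (tissue[:, None]
              + loadings[:, None] * factor_scores
              + np.outer(effects, clone_mask))
    matrix = baselines[:, None] + signal
    return LatentExpression(
        matrix=matrix,
        treatment_effects=effects,
        factor_loadings=loadings,
        probe_ids=probe_ids_for(config),
        sample_ids=[a.animal_id for a in animals],
        baselines=baselines,
        nuclear_factor=f,
        clone_mask=clone_mask,
    )


# ---------------------------------------------------------------------------
# Array dataset
# ---------------------------------------------------------------------------

def dye_bias(coeffs: tuple[float, ...], a: np.ndarray) -> np.ndarray:
    """Evaluate the dye-bias polynomial (coefficients in increasing degree)."""
    return np.polynomial.polynomial.polyval(a, list(coeffs))


def generate_array_dataset(
    config: SimulationConfig,
    latent: LatentExpression,
    background: float = 50.0,
) -> list[ArraySlide]:
    """Two dye-swap slides per sample.

    Channel intensities reproduce the latent log ratio plus the dye-bias
    polynomial evaluated at A plus N(0, noise_sd) per-slide noise; the
    foreground is intensity + a constant local background, so background
    subtraction is exact.  A fixed random subset of probes (share
    ``present_fraction_null``) fails the 70%-pixels rule on every slide.
    """
    if latent.n_probes != config.n_probes:
        raise SimulationError("latent probe dimension does not match config")
    if latent.n_samples != sum(c for _, _, c in config.cohort):
        raise SimulationError("latent sample dimension does not match config")
    rng = _rng(config.seed, 3)
    n = config.n_probes

    n_fail = int(round(config.present_fraction_null * n))
    fail_probes = np.zeros(n, bool)
    if n_fail:
        fail_probes[rng.choice(n, size=n_fail, replace=False)] = True

    slides: list[ArraySlide] = []
    signal = latent.signal
    for j, sample_id in enumerate(latent.sample_ids):
        m_true = signal[:, j]
        # baselines parameterize the mean log intensity of the two channels,
        # so A carries no component of M and lowess removes only the bias
        a_center = latent.baselines
        for suffix, orientation in (("a", SAMPLE_IN_CY5), ("b", SAMPLE_IN_CY3)):
            sign = 1.0 if orientation == SAMPLE_IN_CY5 else -1.0
            noise = (rng.normal(0.0, config.noise_sd, n)
                     if config.noise_sd > 0 else np.zeros(n))
            m_dye = sign * m_true + dye_bias(config.dye_bias_coeffs, a_center) + noise
            log_cy5 = a_center + 0.5 * m_dye
            log_cy3 = a_center - 0.5 * m_dye
            pct = np.where(
                fail_probes,
                rng.uniform(0.0, 0.699, (2, n)),
                rng.uniform(0.75, 1.0, (2, n)),
            )
            slides.append(ArraySlide(
                slide_id=f"{sample_id}_{suffix}",
                sample_id=sample_id,
                dye_orientation=orientation,
                probe_ids=latent.probe_ids,
                fg_cy3=np.exp2(log_cy3) + background,
                bg_cy3=np.full(n, background),
                fg_cy5=np.exp2(log_cy5) + background,
                bg_cy5=np.full(n, background),
                pct_cy3=pct[0],
                pct_cy5=pct[1],
            ))
    return slides


def simulate_expression_matrix(
    config: SimulationConfig,
    latent: LatentExpression | None = None,
) -> ExpressionMatrix:
    """Combined log-ratio matrix as the dye-swap average would deliver it
    under zero dye bias: latent signal plus the mean of two independent
    per-slide noise draws.  All probes flagged informative."""
    if latent is None:
        latent = generate_latent(config)
    rng = _rng(config.seed, 4)
    noise = rng.normal(0.0, config.noise_sd, (2, latent.n_probes, latent.n_samples)) \
        if config.noise_sd > 0 else np.zeros((2, latent.n_probes, latent.n_samples))
    values = pd.DataFrame(
        latent.signal + noise.mean(axis=0),
        index=pd.Index(latent.probe_ids, name="probe_id"),
        columns=latent.sample_ids,
    )
    return ExpressionMatrix(
        values=values,
        informative=pd.Series(True, index=values.index),
    )


# ---------------------------------------------------------------------------
# Annotation / gene sets
# ---------------------------------------------------------------------------

QPCR_CONTROL_GENE = "TBB2"

def build_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic platform annotation under the fixed probe layout.

    mtDNA probes get the 13 protein gene symbols first (members of OXPHOS),
    then generic MT symbols; a slice of nuclear-mito probes joins OXPHOS and
    another FATTY ACID METABOLISM; the first unannotated probe is the qPCR
    internal-control gene.
    """
    nm, mt = probe_classes(config)
    probe_ids = probe_ids_for(config)
    n = config.n_probes

    symbols = np.array([f"GENE{i + 1:06d}" for i in range(n)], dtype=object)
    genome = np.where(mt, "mitochondrial", "nuclear")
    gene_sets = np.array([""] * n, dtype=object)

    nm_idx = np.flatnonzero(nm)
    mt_idx = np.flatnonzero(mt)
    for k, i in enumerate(nm_idx):
        symbols[i] = f"NMITO{k + 1:04d}"
    for k, i in enumerate(mt_idx):
        if k < len(datasets.MTDNA_PROTEIN_GENES):
            symbols[i] = datasets.MTDNA_PROTEIN_GENES[k]
            gene_sets[i] = "OXPHOS"
        else:
            symbols[i] = f"MT{k + 1:03d}"

    n_oxphos = min(90, len(nm_idx))
    for i in nm_idx[:n_oxphos]:
        gene_sets[i] = "OXPHOS"
    n_fat = min(60, max(0, len(nm_idx) - n_oxphos))
    for i in nm_idx[n_oxphos:n_oxphos + n_fat]:
        gene_sets[i] = "FATTY ACID METABOLISM"

    other_idx = np.flatnonzero(~(nm | mt))
    if len(other_idx):
        symbols[other_idx[0]] = QPCR_CONTROL_GENE

    return pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": symbols,
        "genome_of_origin": genome,
        "mito_function": nm | mt,
        "gene_sets": gene_sets,
    })


def gene_sets_from_annotation(annotation: pd.DataFrame) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for _, row in annotation.iterrows():
        if not row["gene_sets"]:
            continue
        for name in str(row["gene_sets"]).split("|"):
            sets.setdefault(name, set()).add(row["gene_symbol"])
    return sets


# ---------------------------------------------------------------------------
# qPCR panel
# ---------------------------------------------------------------------------

def generate_qpcr_panel(
    latent: LatentExpression,
    genes: list[str],
    annotation: pd.DataFrame,
    noise_sd: float,
    seed: int,
    control_gene: str = QPCR_CONTROL_GENE,
    calibrator_sample: str = "REF",
    replicates: int = 3,
    baseline_ct: float = 25.0,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Ct table (sample, gene, replicate, ct) under a perfect-efficiency
    model: Ct = baseline - signal / log2(efficiency) + noise.

    The internal-control gene and the calibrator sample carry zero signal,
    so with zero noise the comparative-CT method inverts the generator
    exactly.
    """
    if efficiency <= 1.0:
        raise SimulationError("amplification efficiency must exceed 1")
    symbol_to_row = {}
    for i, sym in enumerate(annotation["gene_symbol"]):
        symbol_to_row.setdefault(sym, i)
    unknown = [g for g in genes if g not in symbol_to_row]
    if unknown:
        raise SimulationError(f"genes absent from the latent matrix: {unknown}")

    rng = np.random.default_rng(seed)
    scale = 1.0 / np.log2(efficiency)
    rows = []
    all_samples = list(latent.sample_ids) + [calibrator_sample]
    for gene in list(genes) + [control_gene]:
        for sample in all_samples:
            if gene == control_gene or sample == calibrator_sample:
                sig = 0.0
            else:
                j = latent.sample_ids.index(sample)
                sig = latent.signal[symbol_to_row[gene], j]
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({
                    "sample_id": sample,
                    "gene": gene,
                    "replicate": rep,
                    "ct": baseline_ct - sig * scale + noise,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers / top-level
# ---------------------------------------------------------------------------

FRAGMENT_OFFSET = 301
FRAGMENT_END = 720


def animal_fragment(
    animal: Animal,
    refs: tuple[HaplotypeReference, HaplotypeReference],
    offset: int = FRAGMENT_OFFSET,
    end: int = FRAGMENT_END,
) -> str:
    """Sequenced ND1 fragment for one animal: its breed's reference window
    with the animal's own panel calls written in (IUPAC for mixed peaks)."""
    ref = next(r for r in refs if r.breed_name == animal.breed)
    seq = list(ref.coding_sequence[offset - 1: end])
    for pos, base in animal.genotype.calls.items():
        if offset <= pos <= end:
            seq[pos - offset] = base
    return "".join(seq)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tsimulated\t{genes}\n")


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input below ``outdir``.

    Layout: ``references.fasta``, ``animals.fasta``, ``panel.tsv``,
    ``design.tsv``, ``annotation.tsv``, ``slides/*.tsv``, ``qpcr.tsv``,
    ``gene_sets.gmt``, ``sim_config.yaml``.  Returns a manifest of paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slides_dir = outdir / "slides"
    slides_dir.mkdir(exist_ok=True)

    refs = generate_reference_pair(config.seed)
    animals = generate_cohort(config, refs)
    latent = generate_latent(config, animals)
    slides = generate_array_dataset(config, latent)
    annotation = build_annotation(config)

    write_fasta(
        [(f"{r.accession_label} breed={r.breed_name}", r.coding_sequence) for r in refs],
        outdir / "references.fasta",
    )
    write_fasta(
        [
            (
                f"{a.animal_id} offset={FRAGMENT_OFFSET} group={a.group} role={a.role}",
                animal_fragment(a, refs),
            )
            for a in animals
        ],
        outdir / "animals.fasta",
    )

    panel = pd.DataFrame({
        "position": [p for p, _, _ in datasets.FULL_PANEL],
        refs[0].breed_name: [a for _, a, _ in datasets.FULL_PANEL],
        refs[1].breed_name: [b for _, _, b in datasets.FULL_PANEL],
    })
    panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)

    design_rows = []
    for s in slides:
        a = next(x for x in animals if x.animal_id == s.sample_id)
        design_rows.append({
            "slide_id": s.slide_id, "animal_id": a.animal_id,
            "group": a.group, "role": a.role, "breed": a.breed,
            "dye_orientation": s.dye_orientation,
        })
        write_slide_tsv(s, slides_dir / f"{s.slide_id}.tsv")
    pd.DataFrame(design_rows).to_csv(outdir / "design.tsv", sep="\t", index=False)

    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    write_gmt(gene_sets_from_annotation(annotation), outdir / "gene_sets.gmt")

    qpcr_genes = [s for s in annotation["gene_symbol"][:8]]
    qpcr = generate_qpcr_panel(
        latent, qpcr_genes, annotation, noise_sd=min(config.noise_sd, 0.2),
        seed=config.seed,
    )
    qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")

    return {
        "references": str(outdir / "references.fasta"),
        "animals": str(outdir / "animals.fasta"),
        "panel": str(outdir / "panel.tsv"),
        "design": str(outdir / "design.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "slides_dir": str(slides_dir),
        "n_slides": len(slides),
        "qpcr": str(outdir / "qpcr.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "config": str(outdir / "sim_config.yaml"),
    }
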