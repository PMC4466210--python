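"""Two-channel microarray processing.

Raw slides (per-probe foreground/background medians and pixel statistics for
the Cy3 and Cy5 channels) are turned into a normalized, filtered expression
matrix:

1. local background subtraction with a positive floor,
2. per-probe "present" calls from pixel fractions,
3. per-slide intensity-dependent (lowess) normalization of M on A,
4. dye-swap pair combination into one log2(sample/reference) per probe,
5. the three-clause informative-probe filter.

Boundary semantics follow the source wording exactly: presence is inclusive
at 70%, the presence-rate clause is strict at 90%, raw intensity strict at
100, and ratio SD strict at 1.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

SAMPLE_IN_CY5 = "sample_in_Cy5"
SAMPLE_IN_CY3 = "sample_in_Cy3"
ORIENTATIONS = (SAMPLE_IN_CY5, SAMPLE_IN_CY3)

#: Default thresholds (present %, presence rate, raw intensity, ratio SD).
PRESENT_PIXEL_FRACTION = 0.70
PRESENCE_RATE = 0.90
RAW_INTENSITY = 100.0
RATIO_SD = 1.4

_SLIDE_COLUMNS = [
    "probe_id",
    "F532_Median", "B532_Median",
    "F635_Median", "B635_Median",
    "F532_pct_sat2sd", "F635_pct_sat2sd",
]


class ArrayProcessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ArraySlide:
    """One hybridization: per-probe two-channel medians plus pixel stats.

    Cy3 is the 532 nm channel, Cy5 the 635 nm channel.  ``pct_cy3`` /
    ``pct_cy5`` hold the fraction of feature pixels more than two SDs above
    background in that channel.
    """

    slide_id: str
    sample_id: str
    dye_orientation: str
    probe_ids: np.ndarray
    fg_cy3: np.ndarray
    bg_cy3: np.ndarray
    fg_cy5: np.ndarray
    bg_cy5: np.ndarray
    pct_cy3: np.ndarray
    pct_cy5: np.ndarray

    def __post_init__(self) -> None:
        if self.dye_orientation not in ORIENTATIONS:
            raise ArrayProcessingError(
                f"{self.slide_id}: unknown dye orientation {self.dye_orientation!r}"
            )
        n = len(self.probe_ids)
        arrays = (self.fg_cy3, self.bg_cy3, self.fg_cy5, self.bg_cy5,
                  self.pct_cy3, self.pct_cy5)
        if any(len(a) != n for a in arrays):
            raise ArrayProcessingError(f"{self.slide_id}: ragged probe arrays")
        if len(np.unique(self.probe_ids)) != n:
            raise ArrayProcessingError(f"{self.slide_id}: duplicate probe ids")
        for name, a in zip(("fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5"), arrays[:4]):
            if np.any(np.asarray(a) < 0):
                raise ArrayProcessingError(f"{self.slide_id}: negative {name}")
        for name, a in zip(("pct_cy3", "pct_cy5"), arrays[4:]):
            a = np.asarray(a)
            if np.any((a < 0) | (a > 1)):
                raise ArrayProcessingError(f"{self.slide_id}: {name} outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class BackgroundCorrected:
    """Background-subtracted channel intensities with floor flags."""

    cy3: np.ndarray
    cy5: np.ndarray
    floored_cy3: np.ndarray
    floored_cy5: np.ndarray
    floor: float


@dataclass
class NormalizationFit:
    """Per-slide lowess fit of M on A and the normalized ratios.

    ``m_raw``, ``bias`` and ``m_norm`` are oriented to log2(sample/reference)
    regardless of which dye carried the sample.  Probes without positive
    corrected intensity in both channels carry NaN.
    """

    slide_id: str
    sample_id: str
    dye_orientation: str
    probe_ids: np.ndarray
    a: np.ndarray
    m_raw: np.ndarray
    bias: np.ndarray
    m_norm: np.ndarray
    span: float
    iterations: int
    present_cy3: np.ndarray = field(repr=False, default=None)
    present_cy5: np.ndarray = field(repr=False, default=None)
    corrected_cy3: np.ndarray = field(repr=False, default=None)
    corrected_cy5: np.ndarray = field(repr=False, default=None)

    def _role(self, role: str) -> tuple[np.ndarray, np.ndarray]:
        """(presence, corrected intensity) arrays for 'sample' or 'reference'."""
        sample_is_cy5 = self.dye_orientation == SAMPLE_IN_CY5
        want_cy5 = (role == "sample") == sample_is_cy5
        if want_cy5:
            return self.present_cy5, self.corrected_cy5
        return self.present_cy3, self.corrected_cy3


@dataclass
class CombinedSample:
    """Dye-swap-combined log2(sample/reference) ratios for one sample."""

    sample_id: str
    probe_ids: np.ndarray
    m: np.ndarray
    slide_ids: tuple[str, str]


@dataclass
class ExpressionMatrix:
    """Normalized log2(sample/reference) ratios, probes x samples, with
    informative flags and per-probe filter provenance."""

    values: pd.DataFrame
    informative: pd.Series
    reasons: dict[str, list[str]] = field(default_factory=dict)

    def informative_values(self) -> pd.DataFrame:
        return self.values.loc[self.informative[self.informative].index]

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def subtract_background(slide: ArraySlide, floor: float = 0.5) -> BackgroundCorrected:
    """corrected = max(foreground - background, floor); floored probes are
    flagged rather than dropped."""
    if floor <= 0:
        raise ArrayProcessingError("floor must be positive")
    raw3 = np.asarray(slide.fg_cy3, float) - np.asarray(slide.bg_cy3, float)
    raw5 = np.asarray(slide.fg_cy5, float) - np.asarray(slide.bg_cy5, float)
    return BackgroundCorrected(
        cy3=np.maximum(raw3, floor),
        cy5=np.maximum(raw5, floor),
        floored_cy3=raw3 < floor,
        floored_cy5=raw5 < floor,
        floor=floor,
    )


def call_present(
    pct_cy3: np.ndarray | float,
    pct_cy5: np.ndarray | float,
    threshold: float = PRESENT_PIXEL_FRACTION,
) -> np.ndarray | bool:
    """Present iff either channel has at least ``threshold`` of feature
    pixels above background + 2 SD (inclusive boundary)."""
    return np.maximum(np.asarray(pct_cy3), np.asarray(pct_cy5)) >= threshold


def lowess_normalize(
    slide: ArraySlide,
    corrected: BackgroundCorrected | None = None,
    span: float = 0.3,
    iterations: int = 3,
    floor: float = 0.5,
    min_probes: int = 50,
    present_threshold: float = PRESENT_PIXEL_FRACTION,
) -> NormalizationFit:
    """Fit the intensity-dependent dye bias m(A) by robust locally weighted
    regression and subtract it.

    The fit is done in dye space (M = log2(Cy5/Cy3)); the returned arrays
    are sign-oriented to log2(sample/reference).
    """
    if corrected is None:
        corrected = subtract_background(slide, floor=floor)
    cy3 = corrected.cy3
    cy5 = corrected.cy5
    usable = np.isfinite(cy3) & np.isfinite(cy5) & (cy3 > 0) & (cy5 > 0)
    # Floored probes have no believable ratio: exclude from the fit and from M.
    usable &= ~(corrected.floored_cy3 | corrected.floored_cy5)
    n_usable = int(usable.sum())
    if n_usable < min_probes:
        raise ArrayProcessingError(
            f"{slide.slide_id}: only {n_usable} usable probes (< {min_probes})"
        )

    a = np.full(slide.n_probes, np.nan)
    m_dye = np.full(slide.n_probes, np.nan)
    a[usable] = 0.5 * (np.log2(cy5[usable]) + np.log2(cy3[usable]))
    m_dye[usable] = np.log2(cy5[usable]) - np.log2(cy3[usable])

    bias_dye = np.full(slide.n_probes, np.nan)
    fitted = _sm_lowess(
        m_dye[usable], a[usable], frac=span, it=iterations, return_sorted=False
    )
    bias_dye[usable] = fitted

    sign = 1.0 if slide.dye_orientation == SAMPLE_IN_CY5 else -1.0
    return NormalizationFit(
        slide_id=slide.slide_id,
        sample_id=slide.sample_id,
        dye_orientation=slide.dye_orientation,
        probe_ids=np.asarray(slide.probe_ids),
        a=a,
        m_raw=sign * m_dye,
        bias=sign * bias_dye,
        m_norm=sign * (m_dye - bias_dye),
        span=span,
        iterations=iterations,
        present_cy3=np.asarray(slide.pct_cy3) >= present_threshold,
        present_cy5=np.asarray(slide.pct_cy5) >= present_threshold,
        corrected_cy3=cy3,
        corrected_cy5=cy5,
    )


def combine_dye_swap(fit_a: NormalizationFit, fit_b: NormalizationFit) -> CombinedSample:
    """Average the two oriented, normalized slides of one dye-swap pair.

    A probe missing on one slide takes the other slide's value; missing on
    both stays missing.
    """
    if fit_a.sample_id != fit_b.sample_id:
        raise ArrayProcessingError(
            f"slides {fit_a.slide_id}/{fit_b.slide_id} belong to different samples"
        )
    if fit_a.dye_orientation == fit_b.dye_orientation:
        raise ArrayProcessingError(
            f"sample {fit_a.sample_id}: both slides have orientation "
            f"{fit_a.dye_orientation}"
        )
    if not np.array_equal(fit_a.probe_ids, fit_b.probe_ids):
        raise ArrayProcessingError(
            f"sample {fit_a.sample_id}: slides carry different probe sets"
        )
    stacked = np.vstack([fit_a.m_norm, fit_b.m_norm])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN probes
        m = np.nanmean(stacked, axis=0)
    return CombinedSample(
        sample_id=fit_a.sample_id,
        probe_ids=fit_a.probe_ids,
        m=m,
        slide_ids=(fit_a.slide_id, fit_b.slide_id),
    )


def filter_informative(
    fits: list[NormalizationFit],
    combined: list[CombinedSample],
    presence_rate: float = PRESENCE_RATE,
    raw_intensity: float = RAW_INTENSITY,
    ratio_sd: float = RATIO_SD,
) -> ExpressionMatrix:
    """Apply the three informative-probe clauses.

    1. present in the reference channel on strictly more than
       ``presence_rate`` of the slides, OR likewise in the sample channel;
    2. median background-corrected intensity strictly above
       ``raw_intensity`` in (one of) the channel(s) satisfying clause 1;
    3. SD of the combined log2 ratios across samples strictly below
       ``ratio_sd``.

    Every excluded probe is attributed to at least one named clause.
    """
    if not fits or not combined:
        raise ArrayProcessingError("no slides/samples to filter")
    probe_ids = fits[0].probe_ids
    for f in fits:
        if not np.array_equal(f.probe_ids, probe_ids):
            raise ArrayProcessingError("slides carry different probe sets")

    pres_ref = np.vstack([f._role("reference")[0] for f in fits])
    pres_sam = np.vstack([f._role("sample")[0] for f in fits])
    raw_ref = np.vstack([f._role("reference")[1] for f in fits])
    raw_sam = np.vstack([f._role("sample")[1] for f in fits])

    rate_ref = pres_ref.mean(axis=0)
    rate_sam = pres_sam.mean(axis=0)
    c1_ref = rate_ref > presence_rate
    c1_sam = rate_sam > presence_rate
    clause1 = c1_ref | c1_sam

    med_ref = np.median(raw_ref, axis=0)
    med_sam = np.median(raw_sam, axis=0)
    clause2 = (c1_ref & (med_ref > raw_intensity)) | (c1_sam & (med_sam > raw_intensity))

    values = pd.DataFrame(
        {c.sample_id: c.m for c in combined},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    with np.errstate(invalid="ignore"):
        sd = values.std(axis=1, ddof=1).to_numpy()  # NaN-aware, NaN if <2 values
    clause3 = np.nan_to_num(sd, nan=np.inf) < ratio_sd

    informative = clause1 & clause2 & clause3
    reasons: dict[str, list[str]] = {}
    for i, pid in enumerate(probe_ids):
        if informative[i]:
            continue
        why = []
        if not clause1[i]:
            why.append("presence_rate")
        elif not clause2[i]:
            # only meaningful once a channel passed the presence clause
            why.append("raw_intensity")
        if not clause3[i]:
            why.append("ratio_sd")
        reasons[str(pid)] = why

    return ExpressionMatrix(
        values=values,
        informative=pd.Series(informative, index=values.index),
        reasons=reasons,
    )


def subset_by_origin(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    which: str,
) -> ExpressionMatrix:
    """Informative-probe view for one of the three clustering subsets:
    'global' (all informative), 'nuclear_mito' (informative, mitochondrial
    function, nuclear-encoded), or 'mtdna' (informative, mtDNA-encoded)."""
    ann = validate_annotation(annotation)
    missing = matrix.values.index.difference(ann.index)
    if len(missing):
        raise ArrayProcessingError(
            f"annotation does not cover probes: {list(missing[:5])}"
        )
    ann = ann.loc[matrix.values.index]
    if which == "global":
        mask = pd.Series(True, index=matrix.values.index)
    elif which == "nuclear_mito":
        mask = ann["mito_function"] & (ann["genome_of_origin"] == "nuclear")
    elif which == "mtdna":
        mask = ann["genome_of_origin"] == "mitochondrial"
    else:
        raise ArrayProcessingError(f"unknown subset {which!r}")
    keep = matrix.informative & mask
    idx = keep[keep].index
    return ExpressionMatrix(
        values=matrix.values.loc[idx],
        informative=matrix.informative.loc[idx],
        reasons={},
    )


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Index the annotation by probe_id and check internal consistency
    (every mtDNA-encoded probe must be a mitochondrial-function probe)."""
    ann = annotation
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    bad = ann[(ann["genome_of_origin"] == "mitochondrial") & ~ann["mito_function"]]
    if len(bad):
        raise ArrayProcessingError(
            "mtDNA-encoded probes must be mitochondrial-function probes: "
            f"{list(bad.index[:5])}"
        )
    return ann


def process_slides(
    slides: list[ArraySlide],
    span: float = 0.3,
    iterations: int = 3,
    floor: float = 0.5,
    present_threshold: float = PRESENT_PIXEL_FRACTION,
    presence_rate: float = PRESENCE_RATE,
    raw_intensity: float = RAW_INTENSITY,
    ratio_sd: float = RATIO_SD,
) -> tuple[ExpressionMatrix, list[NormalizationFit]]:
    """Full slide-to-matrix path: background subtraction, lowess, dye-swap
    combination per sample, informative filtering."""
    by_sample: dict[str, list[ArraySlide]] = {}
    for s in slides:
        by_sample.setdefault(s.sample_id, []).append(s)
    fits: list[NormalizationFit] = []
    combined: list[CombinedSample] = []
    for sample_id, pair in by_sample.items():
        if len(pair) != 2:
            raise ArrayProcessingError(
                f"sample {sample_id}: expected a dye-swap pair, got {len(pair)} slide(s)"
            )
        fa, fb = (
            lowess_normalize(
                s, span=span, iterations=iterations, floor=floor,
                present_threshold=present_threshold,
            )
            for s in pair
        )
        fits.extend([fa, fb])
        combined.append(combine_dye_swap(fa, fb))
    matrix = filter_informative(
        fits, combined,
        presence_rate=presence_rate,
        raw_intensity=raw_intensity,
        ratio_sd=ratio_sd,
    )
    return matrix, fits


def informative_percentage(informative_count: int, total_probes: int) -> float:
    """Informative probes as a percentage of the platform, one decimal."""
    if total_probes <= 0:
        raise ArrayProcessingError("total_probes must be positive")
    if not 0 <= informative_count <= total_probes:
        raise ArrayProcessingError("informative_count outside [0, total]")
    return round(100.0 * informative_count / total_probes, 1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_slide_tsv(slide: ArraySlide, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# slide_id={slide.slide_id}\n")
        fh.write(f"# sample_id={slide.sample_id}\n")
        fh.write(f"# dye_orientation={slide.dye_orientation}\n")
        fh.write("# format_version=1\n")
        df = pd.DataFrame({
            "probe_id": slide.probe_ids,
            "F532_Median": slide.fg_cy3,
            "B532_Median": slide.bg_cy3,
            "F635_Median": slide.fg_cy5,
            "B635_Median": slide.bg_cy5,
            "F532_pct_sat2sd": slide.pct_cy3,
            "F635_pct_sat2sd": slide.pct_cy5,
        })
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_slide_tsv(path: str | Path) -> ArraySlide:
    """Read one slide file; columns are located by name, so reordering is
    tolerated."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _SLIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ArrayProcessingError(f"{path}: missing columns {missing}")
    for key in ("slide_id", "sample_id", "dye_orientation"):
        if key not in meta:
            raise ArrayProcessingError(f"{path}: missing header field {key}")
    return ArraySlide(
        slide_id=meta["slide_id"],
        sample_id=meta["sample_id"],
        dye_orientation=meta["dye_orientation"],
        probe_ids=df["probe_id"].to_numpy(),
        fg_cy3=df["F532_Median"].to_numpy(float),
        bg_cy3=df["B532_Median"].to_numpy(float),
        fg_cy5=df["F635_Median"].to_numpy(float),
        bg_cy5=df["B635_Median"].to_numpy(float),
        pct_cy3=df["F532_pct_sat2sd"].to_numpy(float),
        pct_cy5=df["F635_pct_sat2sd"].to_numpy(float),
    )


def ma_plot(fit: NormalizationFit, path: str | Path) -> None:
    """Diagnostic MA scatter, raw and normalized, for one slide."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, m, title in zip(axes, (fit.m_raw, fit.m_norm), ("raw", "normalized")):
        ax.scatter(fit.a, m, s=2, alpha=0.3, rasterized=True)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("A")
        ax.set_title(f"{fit.slide_id} ({title})")
    order = np.argsort(fit.a)
    axes[0].plot(fit.a[order], fit.bias[order], color="red", lw=1)
    axes[0].set_ylabel("M")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
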