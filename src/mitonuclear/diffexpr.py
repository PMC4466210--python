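"""Differential expression and gene-set enrichment.

DE calls follow the fold-change-plus-adjusted-p rule: a probe is
differentially expressed when its clone/control geometric-mean ratio is at
least 1.5-fold in either direction (inclusive) and its Welch-t p value,
Benjamini-Hochberg adjusted across tested probes, is at most 0.05
(inclusive).  Enrichment is Fisher's exact test of the DE set against
packaged gene sets, BH-adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_processing import ExpressionMatrix, validate_annotation
from .coordination import GroupDesign

FC_THRESHOLD = 1.5
ALPHA = 0.05


class DiffExprError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Welch t and BH
# ---------------------------------------------------------------------------

def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  t compares
    mean(group_a) - mean(group_b).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise DiffExprError("need at least two values per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DiffExprError("degenerate test: zero variance in both groups")
    sa = va / len(a)
    sb = vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t over 2-D arrays (probes x samples), NaN-aware.

    Rows with fewer than two finite values in either group, or zero variance
    in both, come back as NaN.
    """
    def moments(x):
        finite = np.isfinite(x)
        n = finite.sum(axis=1)
        safe = np.where(finite, x, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = safe.sum(axis=1) / n
            var = np.where(
                n > 1,
                (np.where(finite, (x - mean[:, None]) ** 2, 0.0)).sum(axis=1)
                / np.maximum(n - 1, 1),
                np.nan,
            )
        return n, mean, var

    na, ma, va = moments(a)
    nb, mb, vb = moments(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = va / na
        sb = vb / nb
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    bad = (na < 2) | (nb < 2) | ((va == 0) & (vb == 0))
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    with np.errstate(invalid="ignore"):
        p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return t, df, np.minimum(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise DiffExprError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise DiffExprError("p values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------

def de_direction(
    fold_change: float,
    p_value: float,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> str:
    """DE decision for one probe; both boundaries inclusive."""
    if not np.isfinite(fold_change) or not np.isfinite(p_value):
        return "none"
    if p_value <= alpha:
        if fold_change >= fc_threshold:
            return "up"
        if fold_change <= 1.0 / fc_threshold:
            return "down"
    return "none"


@dataclass
class DETestResult:
    probe_id: str
    fold_change: float
    log2fc: float
    welch_t: float
    welch_df: float
    p_raw: float
    p_adj: float
    direction: str
    genome_of_origin: str


def call_de(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    annotation: pd.DataFrame | None = None,
    group: str | None = None,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    use_adjusted: bool = True,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Clone-vs-control DE over the informative probes of one analysis group.

    fold_change = 2^(mean clone log ratio - mean control log ratio).  A probe
    is DE when |fold change| reaches ``fc_threshold`` in either direction and
    the (BH-adjusted, unless ``use_adjusted`` is off) p is at most ``alpha``;
    both boundaries inclusive.  Probes missing in more than half the samples
    of either treatment are dropped with a recorded reason.
    """
    values = matrix.informative_values()
    samples = list(values.columns)
    unlabelled = [s for s in samples if s not in design.treatment]
    if unlabelled:
        raise DiffExprError(f"samples missing from design: {unlabelled}")
    if group is not None:
        samples = [s for s in samples if design.group.get(s) == group]
        if not samples:
            raise DiffExprError(f"no samples in group {group!r}")
    clones = [s for s in samples if design.treatment[s] == "clone"]
    controls = [s for s in samples if design.treatment[s] == "control"]
    if len(clones) < 2 or len(controls) < 2:
        raise DiffExprError("need at least two clones and two controls")

    a = values[clones].to_numpy(float)
    b = values[controls].to_numpy(float)
    frac_missing_a = (~np.isfinite(a)).mean(axis=1)
    frac_missing_b = (~np.isfinite(b)).mean(axis=1)
    testable = (frac_missing_a <= max_missing_fraction) & \
               (frac_missing_b <= max_missing_fraction)

    t, df, p = _welch_rows(a, b)
    testable &= np.isfinite(p)
    with np.errstate(invalid="ignore"):
        log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)

    p_adj = np.full(len(values), np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(p[testable])

    fc = np.exp2(log2fc)
    p_used = p_adj if use_adjusted else p
    de_up = (fc >= fc_threshold) & (p_used <= alpha) & testable
    de_down = (fc <= 1.0 / fc_threshold) & (p_used <= alpha) & testable
    direction = np.where(de_up, "up", np.where(de_down, "down", "none"))

    origin = pd.Series("unknown", index=values.index)
    if annotation is not None:
        ann = validate_annotation(annotation)
        origin = ann["genome_of_origin"].reindex(values.index).fillna("unknown")

    return pd.DataFrame({
        "probe_id": values.index,
        "fold_change": fc,
        "log2fc": log2fc,
        "welch_t": t,
        "welch_df": df,
        "p_raw": p,
        "p_adj": p_adj,
        "direction": direction,
        "genome_of_origin": origin.to_numpy(),
        "tested": testable,
    }).set_index("probe_id", drop=False)


def partition_by_origin(
    results: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> dict[str, dict[str, int]]:
    """Up/down DE counts split by genome of origin; counts are disjoint and
    sum to the DE total."""
    de = results[results["direction"] != "none"]
    if annotation is not None:
        ann = validate_annotation(annotation)
        origin = ann["genome_of_origin"].reindex(de.index)
    else:
        origin = de["genome_of_origin"]
    if origin.isna().any() or (origin == "unknown").any():
        missing = list(de.index[origin.isna() | (origin == "unknown")][:5])
        raise DiffExprError(f"unannotated DE probes: {missing}")
    out: dict[str, dict[str, int]] = {}
    label = {"nuclear": "nuclear", "mitochondrial": "mtdna", "other": "other"}
    for key in sorted(origin.unique()):
        sub = de[origin == key]
        out[label.get(key, key)] = {
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
        }
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test and enrichment
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float | None, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p sums the conditional hypergeometric probabilities of all tables (with
    the observed margins) no more likely than the observed one.  The odds
    ratio is the sample OR, with 0.5 added to every cell only when some cell
    is zero; a zero row or column margin yields p = 1 and no OR.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DiffExprError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise DiffExprError("table entries must be non-negative integers")
        t = t.astype(int)
    (a, b), (c, d) = t
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return None, 1.0
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(min(p, 1.0))


@dataclass
class EnrichmentResult:
    gene_set: str
    de_in_set: int
    de_not_set: int
    set_not_de: int
    neither: int
    odds_ratio: float | None
    fisher_p: float
    p_adj: float = float("nan")


def enrich(
    de_set: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Fisher's exact enrichment of the DE set in each gene set over the
    probe/gene universe, BH-adjusted across sets."""
    outside = de_set - universe
    if outside:
        raise DiffExprError(f"DE genes outside the universe: {sorted(outside)[:5]}")
    results = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        a = len(de_set & members)
        b = len(de_set - members)
        c = len(members - de_set)
        d = len(universe) - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]])
        results.append(EnrichmentResult(name, a, b, c, d, odds, p))
    if results:
        adj = bh_adjust([r.fisher_p for r in results])
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_set": r.gene_set,
        "de_in_set": r.de_in_set,
        "de_not_set": r.de_not_set,
        "set_not_de": r.set_not_de,
        "neither": r.neither,
        "odds_ratio": r.odds_ratio,
        "fisher_p": r.fisher_p,
        "p_adj": r.p_adj,
    } for r in results])


def read_gmt(path) -> dict[str, set[str]]:
    """Gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
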