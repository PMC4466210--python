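"""Comparative-CT qPCR quantification and microarray concordance.

Relative expression follows the 2^-ddCt convention: replicate Cts are
averaged per sample x gene, normalized to the internal-control gene (dCt),
referenced to the calibrator sample (ddCt), and exponentiated with a fixed
per-cycle efficiency of 2.  Group comparison applies an F-test for equal
variances and then a one-sided t-test (pooled when the F-test is not
significant, Welch otherwise) in the direction indicated by the microarray.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .coordination import GroupDesign


class QpcrError(ValueError):
    pass


REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "ct")


def validate_ct_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise QpcrError(f"Ct table missing columns {missing}")
    if (records["ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")
    return records


# ---------------------------------------------------------------------------
# Comparative CT
# ---------------------------------------------------------------------------

def comparative_ct(
    records: pd.DataFrame,
    control_gene: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression per sample x gene.

    Returns a frame with delta_ct, delta_delta_ct and rq columns; the
    calibrator sample has rq = 1 for every gene by construction.
    """
    records = validate_ct_table(records)
    if efficiency <= 1.0:
        raise QpcrError("efficiency must exceed 1")
    mean_ct = (
        records.groupby(["sample_id", "gene"], sort=False)["ct"].mean().unstack()
    )
    if control_gene not in mean_ct.columns:
        raise QpcrError(f"internal-control gene {control_gene!r} absent from table")
    if calibrator_sample not in mean_ct.index:
        raise QpcrError(f"calibrator sample {calibrator_sample!r} absent from table")
    no_control = mean_ct.index[mean_ct[control_gene].isna()]
    if len(no_control):
        raise QpcrError(
            f"samples lacking the control gene {control_gene!r}: {list(no_control)}"
        )
    no_calibrator = mean_ct.columns[mean_ct.loc[calibrator_sample].isna()]
    if len(no_calibrator):
        raise QpcrError(
            f"genes lacking the calibrator sample: {list(no_calibrator)}"
        )

    delta = mean_ct.sub(mean_ct[control_gene], axis=0)
    delta_delta = delta.sub(delta.loc[calibrator_sample], axis=1)
    rq = np.power(efficiency, -delta_delta)

    out = []
    for sample in mean_ct.index:
        for gene in mean_ct.columns:
            if np.isnan(mean_ct.loc[sample, gene]):
                continue
            out.append({
                "sample_id": sample,
                "gene": gene,
                "delta_ct": delta.loc[sample, gene],
                "delta_delta_ct": delta_delta.loc[sample, gene],
                "rq": rq.loc[sample, gene],
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    f_p: float
    t_p: float
    branch: str            # 'pooled' or 'welch'
    direction: str         # 'up' or 'down' (clones vs controls)
    significant: bool
    alpha: float


def compare_groups(
    rq_clones,
    rq_controls,
    direction: str,
    alpha: float = 0.05,
    f_alpha: float = 0.05,
) -> GroupComparison:
    """F-test for equal variances, then a one-sided t-test.

    ``direction`` ('up'/'down') is the expected sense of clones relative to
    controls, taken from the microarray result.  The pooled-variance t is
    used when the F-test is not significant, Welch's t otherwise;
    significance is strict (p < alpha).
    """
    if direction not in ("up", "down"):
        raise QpcrError(
            "direction must be 'up' or 'down' (from the microarray fold change)"
        )
    a = np.asarray(rq_clones, float)
    b = np.asarray(rq_controls, float)
    if len(a) < 2 or len(b) < 2:
        raise QpcrError("need at least two values per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise QpcrError("degenerate comparison: zero variance in both groups")

    if vb == 0 or va == 0:
        f_p = 0.0  # infinitely unequal variances
    else:
        f = va / vb
        f_p = 2.0 * min(
            stats.f.sf(f, len(a) - 1, len(b) - 1),
            stats.f.cdf(f, len(a) - 1, len(b) - 1),
        )
        f_p = min(f_p, 1.0)

    if f_p >= f_alpha:
        branch = "pooled"
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        branch = "welch"
        sa, sb = va / len(a), vb / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (
            sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1)
        )
    t_p = stats.t.sf(t, df) if direction == "up" else stats.t.cdf(t, df)
    return GroupComparison(
        f_p=float(f_p), t_p=float(t_p), branch=branch,
        direction=direction, significant=bool(t_p < alpha), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Concordance with the microarray
# ---------------------------------------------------------------------------

def qpcr_directions(
    rq: pd.DataFrame,
    design: GroupDesign,
) -> dict[str, str]:
    """Per-gene qPCR direction: 'up' when mean clone rq exceeds mean control
    rq, else 'down'.  Samples absent from the design (e.g. the calibrator)
    are ignored."""
    out = {}
    labelled = rq[rq["sample_id"].isin(design.treatment)]
    for gene, sub in labelled.groupby("gene"):
        t = sub["sample_id"].map(design.treatment)
        clones = sub.loc[t == "clone", "rq"]
        controls = sub.loc[t == "control", "rq"]
        if len(clones) == 0 or len(controls) == 0:
            continue
        out[gene] = "up" if clones.mean() > controls.mean() else "down"
    return out


def concordance(
    rq: pd.DataFrame,
    design: GroupDesign,
    microarray_fold: Mapping[str, float],
    genes: list[str],
) -> tuple[pd.DataFrame, float]:
    """Per-gene directionality agreement between platforms.

    Genes missing a fold change or qPCR measurement are reported with
    agree = NA and excluded from the summary fraction.
    """
    q_dir = qpcr_directions(rq, design)
    rows = []
    agreements = []
    for gene in genes:
        fold = microarray_fold.get(gene)
        micro = None if fold is None else ("up" if fold >= 1.0 else "down")
        qdir = q_dir.get(gene)
        agree = (micro == qdir) if (micro is not None and qdir is not None) else None
        if agree is not None:
            agreements.append(agree)
        rows.append({
            "gene": gene,
            "microarray_direction": micro,
            "qpcr_direction": qdir,
            "agree": agree,
        })
    fraction = float(np.mean(agreements)) if agreements else float("nan")
    return pd.DataFrame(rows), fraction
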