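"""Sample clustering and mitonuclear-coordination statistics.

For each probe subset (global / nuclear-mito / mtDNA) the samples are
correlated pairwise (Pearson, pairwise-complete), clustered agglomeratively
on 1 - r with average linkage, and summarized by (a) the mean within-
treatment pairwise correlation and (b) the majority purity of the 2-cluster
cut with respect to treatment.  Contrasting the nuclear-mito and mtDNA
purities yields the coordination readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_processing import ExpressionMatrix


class CoordinationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """sample_id -> (treatment, group, breed)."""

    treatment: dict[str, str]
    group: dict[str, str] = field(default_factory=dict)
    breed: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, design: pd.DataFrame) -> "GroupDesign":
        """Build from a design table with animal_id/role/group[/breed]
        columns (role 'clone'/'control' is the treatment)."""
        df = design.drop_duplicates("animal_id")
        return cls(
            treatment=dict(zip(df["animal_id"], df["role"])),
            group=dict(zip(df["animal_id"], df["group"])) if "group" in df else {},
            breed=dict(zip(df["animal_id"], df["breed"])) if "breed" in df else {},
        )


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (left, right, height, size); node ids follow the scipy
    convention (leaves 0..n-1, internal nodes n, n+1, ...).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    def leaves_of(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        left, right, _, _ = self.merges[node - self.n_leaves]
        return self.leaves_of(left) + self.leaves_of(right)

    @property
    def leaf_order(self) -> list[str]:
        root = self.n_leaves + len(self.merges) - 1
        return [self.labels[i] for i in self.leaves_of(root)]

    def cut(self, k: int = 2) -> list[set[str]]:
        """Cluster memberships after undoing the last k-1 merges."""
        if not 1 <= k <= self.n_leaves:
            raise CoordinationError(f"cannot cut into {k} clusters")
        roots: list[int] = [self.n_leaves + len(self.merges) - 1]
        while len(roots) < k:
            # Undo the highest merge among current roots.
            internal = [r for r in roots if r >= self.n_leaves]
            top = max(internal, key=lambda r: (self.merges[r - self.n_leaves][2], r))
            left, right, _, _ = self.merges[top - self.n_leaves]
            roots.remove(top)
            roots.extend([left, right])
        return [
            {self.labels[i] for i in self.leaves_of(r)} for r in sorted(roots)
        ]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": [list(m) for m in self.merges],
            "leaf_order": self.leaf_order,
        }


@dataclass
class ClusterResult:
    subset: str
    correlations: pd.DataFrame
    dendrogram: Dendrogram
    r_per_treatment: dict[str, float]
    separation_purity: float

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "r_per_treatment": {
                k: (None if v is None or np.isnan(v) else float(v))
                for k, v in self.r_per_treatment.items()
            },
            "separation_purity": float(self.separation_purity),
            "dendrogram": self.dendrogram.to_dict(),
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def correlation_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between sample columns."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise CoordinationError("need at least two samples")
    data = values.to_numpy(float)
    cols = list(values.columns)
    n = len(cols)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.isfinite(data[:, i]) & np.isfinite(data[:, j])
            if shared.sum() < min_shared:
                raise CoordinationError(
                    f"samples {cols[i]!r} and {cols[j]!r} share only "
                    f"{int(shared.sum())} probes (< {min_shared})"
                )
            x = data[shared, i]
            y = data[shared, j]
            sx = x.std()
            sy = y.std()
            if sx == 0 or sy == 0:
                raise CoordinationError(
                    f"zero variance on shared probes for pair ({cols[i]!r}, {cols[j]!r})"
                )
            corr[i, j] = corr[j, i] = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return pd.DataFrame(corr, index=cols, columns=cols)


def hierarchical_cluster(correlations: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration on the distance d = 1 - r.

    Ties in the minimum inter-cluster distance are broken by the smallest
    (left, right) node-id pair, making the merge sequence deterministic.
    Linkage updates use the Lance-Williams recurrence for average linkage.
    """
    labels = list(correlations.index)
    n = len(labels)
    dist = 1.0 - correlations.to_numpy(float)
    if not np.allclose(dist, dist.T):
        raise CoordinationError("correlation matrix is not symmetric")

    # active cluster id -> (node id, size); distances kept in a dict keyed by
    # frozen pairs of node ids.
    active: dict[int, int] = {i: 1 for i in range(n)}  # node -> size
    d: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (i, j), height = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active.pop(i), active.pop(j)
        size = si + sj
        for k in list(active):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(k, next_id), max(k, next_id))] = (si * dik + sj * djk) / size
        del d[(i, j)]
        merges.append((i, j, height, size))
        active[next_id] = size
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges, labels=labels)


def group_coherence(
    correlations: pd.DataFrame,
    design: GroupDesign,
) -> dict[str, float]:
    """Mean off-diagonal correlation within each treatment; singleton
    treatments report NaN."""
    out: dict[str, float] = {}
    samples = list(correlations.index)
    treatments = sorted({design.treatment[s] for s in samples})
    corr = correlations.to_numpy(float)
    for t in treatments:
        idx = [k for k, s in enumerate(samples) if design.treatment[s] == t]
        if len(idx) < 2:
            out[t] = float("nan")
            continue
        vals = [corr[a, b] for x, a in enumerate(idx) for b in idx[x + 1:]]
        out[t] = float(np.mean(vals))
    return out


def treatment_separation(dendrogram: Dendrogram, design: GroupDesign) -> float:
    """Cut into two clusters; purity = fraction of samples whose cluster's
    majority treatment matches their own, i.e. the per-cluster majority
    counts summed over clusters, divided by n."""
    treatments = {design.treatment[s] for s in dendrogram.labels}
    if len(treatments) < 2:
        raise CoordinationError("both treatments must be present")
    clusters = dendrogram.cut(2)
    correct = 0
    for cluster in clusters:
        counts: dict[str, int] = {}
        for s in cluster:
            t = design.treatment[s]
            counts[t] = counts.get(t, 0) + 1
        correct += max(counts.values())
    return correct / dendrogram.n_leaves


def cluster_subset(
    matrix: ExpressionMatrix | pd.DataFrame,
    design: GroupDesign,
    subset_name: str = "global",
) -> ClusterResult:
    corr = correlation_matrix(matrix)
    dendro = hierarchical_cluster(corr)
    return ClusterResult(
        subset=subset_name,
        correlations=corr,
        dendrogram=dendro,
        r_per_treatment=group_coherence(corr, design),
        separation_purity=treatment_separation(dendro, design),
    )


def coordination_contrast(
    nuclear_mito: ClusterResult,
    mtdna: ClusterResult,
    margin: float = 0.2,
) -> dict:
    """Nuclear-mito vs mtDNA purity difference; a positive difference above
    ``margin`` is labelled a disrupted mitonuclear coordination."""
    if set(nuclear_mito.correlations.index) != set(mtdna.correlations.index):
        raise CoordinationError("subset results cover different sample sets")
    diff = nuclear_mito.separation_purity - mtdna.separation_purity
    return {
        "purity_nuclear_mito": float(nuclear_mito.separation_purity),
        "purity_mtdna": float(mtdna.separation_purity),
        "purity_difference": float(diff),
        "r_per_treatment": {
            "nuclear_mito": nuclear_mito.r_per_treatment,
            "mtdna": mtdna.r_per_treatment,
        },
        "margin": margin,
        "label": "disrupted" if diff > margin else "coordinated",
    }


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export with merge heights as branch lengths."""
    heights = {i: 0.0 for i in range(dendrogram.n_leaves)}
    for k, (_, _, h, _) in enumerate(dendrogram.merges):
        heights[dendrogram.n_leaves + k] = h

    def render(node: int, parent_height: float) -> str:
        length = max(parent_height - heights[node], 0.0)
        if node < dendrogram.n_leaves:
            return f"{dendrogram.labels[node]}:{length:.6g}"
        left, right, h, _ = dendrogram.merges[node - dendrogram.n_leaves]
        return f"({render(left, h)},{render(right, h)}):{length:.6g}"

    root = dendrogram.n_leaves + len(dendrogram.merges) - 1
    return render(root, heights[root]) + ";"
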