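"""Expression analyses: moving-average enhancer counts along a relative-
expression ranking, time-course relative profiles with four-class
assignment, and the cross-dataset dysregulation screen.

Expression tables are pandas DataFrames with gene symbols as the index and
sample labels as columns; values are non-negative normalized expression
(TPM-like).  A pseudocount (1.0 by default) is added before every ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DegenerateProfilesError

logger = logging.getLogger(__name__)

__all__ = [
    "CaseControlDataset",
    "TimeCourseClassing",
    "archetype_templates",
    "moving_average_enhancer_counts",
    "relative_timecourse",
    "classify_timecourse",
    "crossdataset_dysregulated",
]


@dataclass
class CaseControlDataset:
    """One two-condition expression set with explicit sample grouping."""

    name: str
    expression: pd.DataFrame
    case_samples: list[str]
    control_samples: list[str]

    def __post_init__(self):
        missing = (set(self.case_samples) | set(self.control_samples)) - set(
            self.expression.columns
        )
        if missing:
            raise ConfigurationError(f"{self.name}: unknown samples {sorted(missing)}")


@dataclass
class TimeCourseClassing:
    """Gene-wise relative profiles, class labels, and class centroids."""

    relative_profiles: pd.DataFrame        # rows average to 1 (pre-log)
    class_of: dict[str, int]
    centroids: dict[int, np.ndarray]       # log2 relative centroid per class


def archetype_templates(n_timepoints: int) -> dict[int, np.ndarray]:
    """Log2-scale template curves for the four expression classes.

    1: biphasic (high, low mid, high); 2: monotone decreasing;
    3: monotone increasing; 4: flat.  Unit amplitude; generators and the
    classifier share these shapes.
    """
    t = np.linspace(0.0, 1.0, n_timepoints)
    return {
        1: np.cos(2 * np.pi * t),
        2: np.linspace(1.0, -1.0, n_timepoints),
        3: np.linspace(-1.0, 1.0, n_timepoints),
        4: np.zeros(n_timepoints),
    }


def moving_average_enhancer_counts(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    counts: Mapping[str, int],
    window: int = 100,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Sliding-window mean enhancer count over the relative-expression ranking.

    Genes are ranked descending by ``log2((mean_a + pc) / (mean_b + pc))``
    (ties broken by symbol); a window of size ``window``, step 1, slides
    over the per-gene enhancer counts in that order.  The output has
    ``n_genes - window + 1`` rows with columns rank (1-based window start),
    gene (at the window start), log2_ratio, and mean_count.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    shared = sorted(set(expr_a.index) & set(expr_b.index) & set(counts))
    if window > len(shared):
        raise ConfigurationError(
            f"window {window} exceeds shared gene universe ({len(shared)} genes)"
        )
    a = expr_a.loc[shared].mean(axis=1)
    b = expr_b.loc[shared].mean(axis=1)
    ratio = np.log2((a + pseudocount) / (b + pseudocount))
    order = sorted(shared, key=lambda g: (-ratio[g], g))
    seq = np.array([counts[g] for g in order], dtype=float)
    kernel = np.ones(window) / window
    means = np.convolve(seq, kernel, mode="valid")
    m = len(means)
    return pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "gene": order[:m],
            "log2_ratio": [ratio[g] for g in order[:m]],
            "mean_count": means,
        }
    )


def relative_timecourse(expr: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's profile by its mean across timepoints.

    Rows average exactly to 1; all-zero genes are excluded with a warning.
    """
    if expr.shape[1] < 2:
        raise ConfigurationError("need >= 2 timepoints")
    means = expr.mean(axis=1)
    zero = means == 0
    if zero.any():
        logger.warning(
            "excluding %d all-zero genes from relative profiles: %s",
            int(zero.sum()), list(expr.index[zero][:5]),
        )
    kept = expr.loc[~zero]
    return kept.div(kept.mean(axis=1), axis=0)


def _profile_distances(profiles: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance matrix with a defined value for constant rows."""
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return pdist(profiles, metric="euclidean")
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ centered.T) / np.outer(norms, norms)
    zero = norms == 0
    # constant vs constant: identical shape (distance 0); constant vs varying: max distance
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    r[np.ix_(zero, zero)] = 1.0
    np.fill_diagonal(r, 1.0)
    d = np.clip(1.0 - r, 0.0, None)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def classify_timecourse(
    expr: pd.DataFrame,
    n_classes: int = 4,
    pseudocount: float = 1.0,
    metric: str = "euclidean",
) -> TimeCourseClassing:
    """Hierarchically cluster log2 relative profiles into expression classes.

    Average-linkage clustering of ``log2((v + pc) / mean(v + pc))`` rows is
    cut into ``n_classes`` groups.  With four classes, groups are labeled
    by archetype: the minimum-variance centroid becomes class 4 (flat) and
    the rest are matched one-to-one to the biphasic/decreasing/increasing
    templates by maximal centroid–template correlation.  With any other
    class count, labels follow first appearance in the input.
    """
    if n_classes < 1:
        raise ConfigurationError("n_classes must be >= 1")
    if len(expr) < n_classes:
        raise ConfigurationError("fewer genes than classes")
    genes = list(expr.index)
    shifted = expr.to_numpy(dtype=float) + pseudocount
    log_rel = np.log2(shifted / shifted.mean(axis=1, keepdims=True))
    rel = expr.div(expr.mean(axis=1), axis=0)

    if n_classes == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        dists = _profile_distances(log_rel, metric)
        if np.allclose(dists, 0.0):
            raise DegenerateProfilesError(genes)
        z = linkage(dists, method="average")
        labels = fcluster(z, t=n_classes, criterion="maxclust")

    cluster_ids = sorted(set(labels.tolist()))
    centroids = {k: log_rel[labels == k].mean(axis=0) for k in cluster_ids}

    if n_classes == 4 and len(cluster_ids) == 4:
        mapping = _label_by_archetype(centroids, expr.shape[1])
    else:
        mapping, seen = {}, 0
        for lab in labels:
            if lab not in mapping:
                seen += 1
                mapping[lab] = seen

    class_of = {g: mapping[lab] for g, lab in zip(genes, labels)}
    return TimeCourseClassing(
        relative_profiles=rel,
        class_of=class_of,
        centroids={mapping[k]: c for k, c in centroids.items()},
    )


def _label_by_archetype(
    centroids: dict[int, np.ndarray], n_timepoints: int
) -> dict[int, int]:
    templates = archetype_templates(n_timepoints)
    ids = sorted(centroids)
    flat = min(ids, key=lambda k: float(np.var(centroids[k])))
    rest = [k for k in ids if k != flat]
    shaped = [1, 2, 3]
    cost = np.zeros((len(rest), len(shaped)))
    for i, k in enumerate(rest):
        c = centroids[k] - centroids[k].mean()
        cn = np.linalg.norm(c)
        for j, lab in enumerate(shaped):
            tpl = templates[lab] - templates[lab].mean()
            denom = cn * np.linalg.norm(tpl)
            cost[i, j] = -(c @ tpl) / denom if denom > 0 else 0.0
    rows, cols = linear_sum_assignment(cost)
    mapping = {flat: 4}
    for i, j in zip(rows, cols):
        mapping[rest[i]] = shaped[j]
    return mapping


def crossdataset_dysregulated(
    datasets: Sequence[CaseControlDataset],
    se_genes: Iterable[str],
    orthologs: Mapping[str, str] | None,
    extreme_fraction: float = 0.10,
    min_hits: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Intersect per-dataset extreme deciles with SE-associated orthologs.

    Per dataset, genes are ranked by ``log2((mean_case + pc) /
    (mean_control + pc))`` and the top and bottom ``floor(extreme_fraction
    * n)`` genes form the extreme sets.  A gene qualifies when it is the
    ortholog of an SE-associated gene and is extreme in at least
    ``min_hits`` datasets; direction is up/down/mixed by majority of its
    extreme hits.  Returns a DataFrame indexed by gene with columns
    direction, n_hits, n_up, n_down, and one up/down/"" column per dataset.
    """
    if len(datasets) < min_hits:
        raise ConfigurationError(
            f"only {len(datasets)} datasets for min_hits={min_hits}"
        )
    if orthologs is not None:
        candidates = {orthologs[g] for g in se_genes if g in orthologs}
    else:
        candidates = set(se_genes)
    if not candidates:
        logger.warning("empty SE-ortholog candidate set; screen returns no genes")

    hits: dict[str, dict[str, int]] = {}
    for ds in datasets:
        case = ds.expression[ds.case_samples].mean(axis=1)
        ctrl = ds.expression[ds.control_samples].mean(axis=1)
        ratio = np.log2((case + pseudocount) / (ctrl + pseudocount))
        order = sorted(ratio.index, key=lambda g: (-ratio[g], g))
        k = math.floor(extreme_fraction * len(order))
        for g in order[:k]:
            hits.setdefault(g, {})[ds.name] = 1
        for g in order[len(order) - k :]:
            hits.setdefault(g, {})[ds.name] = -1

    rows = []
    for gene in sorted(candidates):
        pattern = hits.get(gene, {})
        n_up = sum(1 for v in pattern.values() if v > 0)
        n_down = sum(1 for v in pattern.values() if v < 0)
        if n_up + n_down < min_hits:
            continue
        direction = "up" if n_up > n_down else "down" if n_down > n_up else "mixed"
        row = {"gene": gene, "direction": direction, "n_hits": n_up + n_down,
               "n_up": n_up, "n_down": n_down}
        for ds in datasets:
            v = pattern.get(ds.name, 0)
            row[ds.name] = "up" if v > 0 else "down" if v < 0 else ""
        rows.append(row)
    cols = ["gene", "direction", "n_hits", "n_up", "n_down"] + [d.name for d in datasets]
    return pd.DataFrame(rows, columns=cols).set_index("gene")
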