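"""Composite signature scoring and high/mid/low sample stratification.

The score for a sample is the mean of its row-z-scored positive-signature
genes minus the mean of its row-z-scored negative-signature genes, so a
driver-high sample (high positive-gene, low negative-gene expression) gets
a high score.  Samples are then cut into k = 2 or 3 ordered groups either
at quantiles or by exact 1-dimensional k-means (dynamic programming, so the
clustering is the true optimum, not a local one); k-means permits unequal
group sizes, quantiles fix them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import AssociationResult, ExpressionMatrix

logger = logging.getLogger(__name__)

GROUP_LABELS = {2: ("low", "high"), 3: ("low", "mid", "high")}


class StratificationError(ValueError):
    pass


def signature_score(
    expr: ExpressionMatrix,
    assoc: AssociationResult | None = None,
    pos_genes=None,
    neg_genes=None,
) -> pd.Series:
    """Per-sample composite score: mean z(pos genes) - mean z(neg genes).

    Z-scores are per gene across samples with the population (n)
    denominator.  Signature genes missing from the matrix or with zero
    variance are dropped with a warning; with under 50% coverage a warning
    is emitted, with no usable gene at all an error is raised.
    """
    if assoc is not None:
        pos_genes, neg_genes = assoc.pos_genes, assoc.neg_genes
    pos = set(pos_genes or ())
    neg = set(neg_genes or ())
    if not pos and not neg:
        raise ValueError("signature_score needs at least one pos or neg gene")

    def _zrows(genes: set[str]) -> np.ndarray | None:
        present = sorted(genes & set(expr.genes))
        if len(present) < 0.5 * len(genes):
            logger.warning("signature coverage below 50%%: %d/%d genes present",
                           len(present), len(genes))
        if not present:
            return None
        mat = expr.data.loc[present].to_numpy()
        sd = mat.std(axis=1)  # population denominator
        ok = sd > 0
        if (~ok).any():
            logger.warning("dropping %d zero-variance signature gene(s)",
                           int((~ok).sum()))
        if not ok.any():
            return None
        mat = mat[ok]
        return (mat - mat.mean(axis=1, keepdims=True)) / sd[ok, None]

    parts = []
    zp = _zrows(pos) if pos else None
    zn = _zrows(neg) if neg else None
    if zp is None and zn is None:
        raise StratificationError("no usable signature gene present in the matrix")
    score = np.zeros(len(expr.samples))
    if zp is not None:
        score = score + zp.mean(axis=0)
    if zn is not None:
        score = score - zn.mean(axis=0)
    return pd.Series(score, index=expr.samples, name="score")


@dataclass(frozen=True)
class SampleStrata:
    """Per-sample scores and ordered group assignment (low < mid < high)."""

    frame: pd.DataFrame  # columns: sample, score, group
    k: int
    method: str

    @property
    def groups(self) -> pd.Series:
        return self.frame.set_index("sample")["group"]

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.frame["group"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in GROUP_LABELS[self.k]}

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact 1-d k-means via dynamic programming on the sorted values.

    Returns (cluster index per input value, ordered by ascending cluster
    center; within-cluster sum of squares at the optimum).  O(k n^2).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    x = values[order]
    # prefix sums for O(1) segment cost
    ps = np.concatenate(([0.0], np.cumsum(x)))
    ps2 = np.concatenate(([0.0], np.cumsum(x * x)))

    inf = float("inf")
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            t = np.arange(j - 1, i)
            m = i - t
            s = ps[i] - ps[t]
            seg = (ps2[i] - ps2[t]) - s * s / m  # SSE of x[t:i]
            c = cost[j - 1, t] + seg
            arg = int(np.argmin(c))
            cost[j, i] = c[arg]
            split[j, i] = t[arg]
    # backtrack segment boundaries
    bounds = [n]
    i = n
    for j in range(k, 0, -1):
        i = split[j, i]
        bounds.append(i)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(cost[k, n])


def stratify_samples(
    scores: pd.Series,
    k: int = 2,
    method: str | None = None,
) -> SampleStrata:
    """Assign each sample to an ordered stratum from its score.

    ``method`` is "quantile" (cut at 1/k quantiles; ties resolved by stable
    sample order, so group sizes are as equal as possible) or "kmeans-1d"
    (exact optimum, unequal sizes allowed).  Default: kmeans-1d for k = 2,
    quantile for k = 3.  Group labels are ordered low < (mid) < high and
    assignment is monotone in score.
    """
    if k not in GROUP_LABELS:
        raise ValueError(f"k must be 2 or 3, got {k}")
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise StratificationError("scores must be finite")
    if len(np.unique(vals)) < k:
        raise StratificationError(
            f"need >= {k} distinct score values, got {len(np.unique(vals))}")
    if method is None:
        method = "kmeans-1d" if k == 2 else "quantile"
    labels = GROUP_LABELS[k]
    n = len(vals)
    if method == "quantile":
        order = np.argsort(vals, kind="stable")
        idx = np.empty(n, dtype=int)
        cuts = [round(c * n / k) for c in range(k + 1)]
        for c in range(k):
            idx[order[cuts[c]:cuts[c + 1]]] = c
    elif method == "kmeans-1d":
        idx, _ = kmeans_1d(vals, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    frame = pd.DataFrame({
        "sample": scores.index.astype(str),
        "score": vals,
        "group": [labels[i] for i in idx],
    })
    return SampleStrata(frame=frame, k=k, method=method)
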