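"""Driver-associated gene signatures from an expression matrix.

Given a genes x samples log-expression matrix and a driver gene, every
other gene is correlated with the driver across samples (Pearson, pairwise
complete), p-values are Benjamini-Hochberg adjusted jointly, and genes are
partitioned into a positive set (r >= r_min, q <= q_max) and a negative set
(r <= -r_min, q <= q_max).  These two sets form the composite signature
later used to score and stratify tumor samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ExpressionMatrix:
    """Genes x samples real-valued matrix (log-scale expression).

    Thin validated wrapper around a pandas DataFrame: unique gene and
    sample identifiers, float values, NaN allowed (missing entries are kept
    and handled pairwise downstream, never silently dropped).
    """

    def __init__(self, data: pd.DataFrame) -> None:
        if data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def __repr__(self) -> str:
        return (f"ExpressionMatrix({len(self.genes)} genes x "
                f"{len(self.samples)} samples, {self.n_missing} missing)")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column, sample ids in the header."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value.

    Pairs with a missing entry in either vector are removed first; at least
    3 complete pairs and non-zero variance on both sides are required.
    p is from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(xc @ yc) / math.sqrt(sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


@dataclass(frozen=True)
class AssociationResult:
    """Correlation screen of all genes against a driver, partitioned by sign."""

    driver: str
    table: pd.DataFrame  # columns: gene, r, p, q, set ("pos"/"neg"/"")
    r_min: float
    q_max: float
    min_samples: int

    @property
    def pos_genes(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["set"] == "pos", "gene"])

    @property
    def neg_genes(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["set"] == "neg", "gene"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, driver: str = "",
                 r_min: float = float("nan"), q_max: float = float("nan"),
                 min_samples: int = 0) -> "AssociationResult":
        table = pd.read_csv(path, sep="\t", keep_default_na=False,
                            dtype={"gene": str, "set": str})
        for col in ("r", "p", "q"):
            table[col] = pd.to_numeric(table[col])
        return cls(driver=driver, table=table, r_min=r_min, q_max=q_max,
                   min_samples=min_samples)


def driver_associated_genes(
    expr: ExpressionMatrix,
    driver: str,
    r_min: float = 0.3,
    q_max: float = 0.05,
    min_samples: int = 20,
    min_pairs: int = 20,
) -> AssociationResult:
    """Correlate every gene with the driver and threshold into pos/neg sets.

    Genes with fewer than ``min_pairs`` complete pairs against the driver,
    or zero variance, are skipped (logged).  BH adjustment is applied
    jointly over all tested genes.
    """
    if not 0.0 < r_min <= 1.0:
        raise ValueError(f"r_min must be in (0, 1], got {r_min}")
    if not 0.0 < q_max <= 1.0:
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    if driver not in expr.data.index:
        raise KeyError(f"driver gene {driver!r} not in expression matrix")
    if len(expr.samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples, got {len(expr.samples)}")

    values = expr.data.to_numpy()
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    drv = values[gene_index[driver]]
    others = [g for g in expr.genes if g != driver]
    genes, rs, ps = [], [], []
    n_skipped = 0
    clean = not np.isnan(values).any()
    if clean and np.std(drv) > 0:
        # fast path: no missing entries, one vectorized pass
        mat = values[[gene_index[g] for g in others]]
        n = mat.shape[1]
        mc = mat - mat.mean(axis=1, keepdims=True)
        dc = drv - drv.mean()
        denom = np.sqrt((mc ** 2).sum(axis=1) * float(dc @ dc))
        testable = denom > 0
        r_all = np.zeros(len(others))
        r_all[testable] = np.clip((mc @ dc)[testable] / denom[testable], -1, 1)
        with np.errstate(divide="ignore"):
            t = r_all * np.sqrt((n - 2) / np.maximum(1.0 - r_all ** 2, 1e-300))
        p_all = np.minimum(2.0 * stats.t.sf(np.abs(t), n - 2), 1.0)
        p_all[np.abs(r_all) == 1.0] = 0.0
        genes = [g for g, ok in zip(others, testable) if ok]
        rs = list(r_all[testable])
        ps = list(p_all[testable])
        n_skipped = int((~testable).sum())
    else:
        for gene in others:
            row = values[gene_index[gene]]
            keep = ~(np.isnan(row) | np.isnan(drv))
            if keep.sum() < min_pairs:
                n_skipped += 1
                continue
            try:
                r, p = pearson_correlation(row, drv)
            except ValueError:
                n_skipped += 1
                continue
            genes.append(gene)
            rs.append(r)
            ps.append(p)
    if n_skipped:
        logger.info("driver_associated_genes: skipped %d untestable gene(s)", n_skipped)
    rs_arr = np.array(rs)
    ps_arr = np.array(ps)
    qs = multipletests(ps_arr, method="fdr_bh")[1] if len(ps_arr) else ps_arr
    label = np.where((rs_arr >= r_min) & (qs <= q_max), "pos",
                     np.where((rs_arr <= -r_min) & (qs <= q_max), "neg", ""))
    table = pd.DataFrame({"gene": genes, "r": rs_arr, "p": ps_arr, "q": qs,
                          "set": label})
    table = table.sort_values(["r", "gene"],
                              ascending=[False, True]).reset_index(drop=True)
    return AssociationResult(driver=driver, table=table, r_min=r_min,
                             q_max=q_max, min_samples=min_samples)
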