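"""Expression core: RPKM, log2 condition ratios, z-scores, clustering.

RPKM (reads per kilobase of exon per million mapped reads) for a gene with
``c`` reads, exonic length ``L`` bp and library size ``N``:

    RPKM = c * 1e9 / (L * N)

The expression arm of the screen keeps genes that are decently expressed
in at least one condition (RPKM > 3 in parental or derivative) and change
at least two-fold (|log2 ratio| > 1); ratios are computed after flooring
RPKM at a small positive value so silent genes give bounded fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .methylation import _ordered_leaves

DEFAULT_RPKM_FLOOR = 0.01
DEFAULT_MIN_RPKM = 3.0
DEFAULT_MIN_ABS_LOG2FC = 1.0

__all__ = [
    "compute_rpkm",
    "rpkm_matrix",
    "log2_ratio",
    "zscore_rows",
    "screen_expression",
    "summarize_derivative_expression",
    "cluster_expression",
    "read_counts",
]


def compute_rpkm(count, exonic_length, total_mapped):
    """RPKM = count * 1e9 / (exonic_length * total_mapped); vectorized."""
    count = np.asarray(count, dtype=float)
    exonic_length = np.asarray(exonic_length, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(exonic_length <= 0):
        raise DataError("exonic_length must be positive")
    if np.any(total_mapped <= 0):
        raise DataError("total_mapped must be positive")
    rpkm = count * 1e9 / (exonic_length * total_mapped)
    if rpkm.ndim == 0:
        return float(rpkm)
    return rpkm


def rpkm_matrix(counts: pd.DataFrame, lengths: pd.Series,
                totals: pd.Series | None = None) -> pd.DataFrame:
    """Gene x sample counts -> gene x sample RPKM.

    ``lengths`` is indexed by gene id.  When per-sample totals are not
    supplied, column sums of the count matrix are used.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataError(f"no exonic length for genes: {list(missing[:5])}...")
    if totals is None:
        totals = counts.sum(axis=0)
    L = lengths.loc[counts.index].to_numpy(dtype=float)[:, None]
    N = totals.loc[counts.columns].to_numpy(dtype=float)[None, :]
    return pd.DataFrame(
        compute_rpkm(counts.to_numpy(dtype=float), L, N),
        index=counts.index, columns=counts.columns)


def log2_ratio(rpkm_a, rpkm_b, floor: float = DEFAULT_RPKM_FLOOR):
    """log2(b / a) with both sides floored at ``floor`` (> 0)."""
    if floor <= 0:
        raise DataError("floor must be positive")
    a = np.maximum(np.asarray(rpkm_a, dtype=float), floor)
    b = np.maximum(np.asarray(rpkm_b, dtype=float), floor)
    out = np.log2(b / a)
    if out.ndim == 0:
        return float(out)
    return out


def zscore_rows(rpkm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores with population sd (denominator n).

    Constant rows are set to all-zero and flagged.  Returns (z, flagged).
    """
    if rpkm.shape[1] < 2:
        raise DataError("z-scoring needs at least two samples")
    vals = rpkm.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flagged = pd.Series(sd[:, 0] == 0, index=rpkm.index, name="constant")
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[flagged.to_numpy()] = 0.0
    return pd.DataFrame(z, index=rpkm.index, columns=rpkm.columns), flagged


@dataclass
class ExpressionScreenInput:
    """Per-gene parental/derivative RPKM summary plus the log2 ratio."""

    table: pd.DataFrame  # index gene_id: rpkm_parental, rpkm_derivative, log2_ratio


def summarize_derivative_expression(rpkm: pd.DataFrame, parental: str,
                                    derivatives: list[str],
                                    mode: str = "mean",
                                    floor: float = DEFAULT_RPKM_FLOOR,
                                    ) -> ExpressionScreenInput:
    """Collapse derivative samples into one RPKM summary per gene.

    mode "mean": mean RPKM across derivative conditions (default).
    mode "any": per gene, the derivative whose log2 ratio to parental has
    the largest magnitude.
    """
    if parental not in rpkm.columns:
        raise DataError(f"unknown parental condition {parental!r}")
    bad = [d for d in derivatives if d not in rpkm.columns]
    if bad:
        raise DataError(f"unknown derivative conditions {bad}")
    if mode not in ("mean", "any"):
        raise DataError(f"unknown derivative summary mode {mode!r}")
    par = rpkm[parental]
    if mode == "mean":
        der = rpkm[derivatives].mean(axis=1)
    else:
        ratios = np.column_stack(
            [log2_ratio(par.to_numpy(), rpkm[d].to_numpy(), floor)
             for d in derivatives])
        pick = np.argmax(np.abs(ratios), axis=1)
        der = pd.Series(
            rpkm[derivatives].to_numpy()[np.arange(len(rpkm)), pick],
            index=rpkm.index)
    table = pd.DataFrame({
        "rpkm_parental": par,
        "rpkm_derivative": der,
        "log2_ratio": log2_ratio(par.to_numpy(), der.to_numpy(), floor),
    })
    return ExpressionScreenInput(table=table)


def screen_expression(screen_input: ExpressionScreenInput,
                      min_rpkm: float = DEFAULT_MIN_RPKM,
                      min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC) -> set:
    """Genes passing the expression gates (strict inequalities).

    Retained iff (rpkm_parental > min_rpkm OR rpkm_derivative > min_rpkm)
    AND |log2_ratio| > min_abs_log2fc.
    """
    if min_rpkm < 0 or min_abs_log2fc < 0:
        raise DataError("thresholds must be non-negative")
    t = screen_input.table
    keep = ((t["rpkm_parental"] > min_rpkm) | (t["rpkm_derivative"] > min_rpkm)) \
        & (t["log2_ratio"].abs() > min_abs_log2fc)
    return set(t.index[keep])


def cluster_expression(z: pd.DataFrame) -> list:
    """Average-linkage clustering of gene z-score profiles.

    Correlation distance; returns the dendrogram leaf order as gene ids.
    """
    if len(z) < 2:
        raise DataError("clustering needs at least two genes")
    leaves = _ordered_leaves(z.to_numpy(dtype=float), metric="correlation")
    return [z.index[i] for i in leaves]


def read_counts(path) -> pd.DataFrame:
    """Read a long-format count TSV (gene_id, sample_id, count) -> wide matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    required = {"gene_id", "sample_id", "count"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    return df.pivot(index="gene_id", columns="sample_id", values="count")
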