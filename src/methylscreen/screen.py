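"""Integrative screen: intersect methylation and expression changes.

Genes passing both gates — a promoter beta-value shift of magnitude above
``min_abs_delta_beta`` (default 0.1) and the expression gates (RPKM and
two-fold change) — are classified by the signs of (delta-beta, log2 ratio)
into four quadrants.  The tumor-suppressor-like quadrant is
``hypermethylated_down``: promoter gains methylation in the derivative
condition while expression drops; those genes carry the candidate flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import ExpressionScreenInput, screen_expression
from .methylation import BetaMatrix, DeltaBetaTable, PromoterAssignment

logger = logging.getLogger(__name__)

DEFAULT_MIN_ABS_DELTA_BETA = 0.1

QUADRANTS = (
    "hypermethylated_down",
    "hypermethylated_up",
    "hypomethylated_down",
    "hypomethylated_up",
    "not_significant",
)

__all__ = ["integrate", "candidate_report", "ScreenResult"]


@dataclass
class ScreenResult:
    """Gene-level outcome of the integrative screen.

    ``table``: one row per gene seen in either input, sorted by descending
    delta-beta then ascending log2 ratio then gene id, with columns
    log2_ratio, delta_beta, n_promoter_probes, quadrant, candidate.
    """

    table: pd.DataFrame
    min_abs_delta_beta: float
    min_rpkm: float
    min_abs_log2fc: float

    @property
    def candidates(self) -> list:
        return list(self.table.index[self.table["candidate"]])


def _quadrant(dbeta: float, log2fc: float) -> str:
    meth = "hypermethylated" if dbeta > 0 else "hypomethylated"
    expr = "up" if log2fc > 0 else "down"
    return f"{meth}_{expr}"


def integrate(expr_input: ExpressionScreenInput,
              dbeta_summary: pd.DataFrame,
              min_abs_delta_beta: float = DEFAULT_MIN_ABS_DELTA_BETA,
              min_rpkm: float = 3.0,
              min_abs_log2fc: float = 1.0) -> ScreenResult:
    """Classify genes by joint methylation and expression change.

    Parameters
    ----------
    expr_input
        Per-gene parental/derivative RPKM and log2 ratio.
    dbeta_summary
        Gene-indexed frame with columns ``delta_beta`` (derivative minus
        parental) and ``n_probes``, e.g. from
        :func:`methylscreen.methylation.summarize_delta_beta`.

    A gene is significant only if present in both inputs with
    |delta_beta| > min_abs_delta_beta and the expression gates passed
    (all strict).  Candidates additionally need delta_beta positive and
    log2 ratio < -min_abs_log2fc: promoter hypermethylation with silencing.
    """
    if min_abs_delta_beta < 0:
        raise DataError("min_abs_delta_beta must be non-negative")
    expr = expr_input.table
    expr_pass = screen_expression(expr_input, min_rpkm, min_abs_log2fc)

    genes = expr.index.union(dbeta_summary.index)
    only_meth = dbeta_summary.index.difference(expr.index)
    if len(only_meth):
        logger.info("%d genes have promoter probes but no expression; "
                    "classified not_significant", len(only_meth))

    table = pd.DataFrame(index=genes)
    table["log2_ratio"] = expr["log2_ratio"].reindex(genes)
    table["delta_beta"] = dbeta_summary["delta_beta"].reindex(genes)
    table["n_promoter_probes"] = (
        dbeta_summary["n_probes"].reindex(genes).fillna(0).astype(int))

    both = table["log2_ratio"].notna() & table["delta_beta"].notna()
    meth_pass = table["delta_beta"].abs() > min_abs_delta_beta
    in_expr_pass = table.index.isin(expr_pass)
    significant = both & meth_pass & in_expr_pass

    table["quadrant"] = "not_significant"
    sig_idx = table.index[significant]
    table.loc[sig_idx, "quadrant"] = [
        _quadrant(d, f) for d, f in
        zip(table.loc[sig_idx, "delta_beta"], table.loc[sig_idx, "log2_ratio"])
    ]
    table["candidate"] = significant \
        & (table["delta_beta"] > min_abs_delta_beta) \
        & (table["log2_ratio"] < -min_abs_log2fc)

    table = table.sort_values(
        by=["delta_beta", "log2_ratio"],
        ascending=[False, True],
        kind="mergesort",
        na_position="last",
    )
    # stable tie-break on gene id
    table = table.loc[
        table.assign(_g=table.index.astype(str))
        .sort_values(["delta_beta", "log2_ratio", "_g"],
                     ascending=[False, True, True], kind="mergesort",
                     na_position="last").index
    ]
    return ScreenResult(table=table,
                        min_abs_delta_beta=min_abs_delta_beta,
                        min_rpkm=min_rpkm,
                        min_abs_log2fc=min_abs_log2fc)


def candidate_report(result: ScreenResult, beta: BetaMatrix,
                     assignment: PromoterAssignment,
                     cond_a: str | None = None) -> pd.DataFrame:
    """Probe-level view of each candidate gene's promoter.

    One row per (candidate gene, promoter probe) with the per-condition
    beta-values and the probe's delta-beta against the parental condition
    (``cond_a``, default the first condition of the beta matrix) for every
    other condition — the machine-readable content of a per-candidate
    promoter heatmap.
    """
    conds = beta.conditions
    if cond_a is None:
        cond_a = conds[0]
    if cond_a not in conds:
        raise DataError(f"unknown condition {cond_a!r}")
    gene_to_probes = assignment.gene_to_probes
    rows = []
    for gene in result.candidates:
        for probe in sorted(gene_to_probes.get(gene, [])):
            if probe not in beta.beta.index:
                continue
            row = {"gene_id": gene, "probe_id": probe}
            for c in conds:
                row[f"beta_{c}"] = beta.beta.at[probe, c]
            for c in conds:
                if c != cond_a:
                    row[f"delta_beta_{c}"] = (
                        beta.beta.at[probe, c] - beta.beta.at[probe, cond_a])
            rows.append(row)
    if not rows:
        cols = ["gene_id", "probe_id"] + [f"beta_{c}" for c in conds] + \
            [f"delta_beta_{c}" for c in conds if c != cond_a]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
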