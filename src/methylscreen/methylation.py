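"""Methylation-array core: beta-values, promoter assignment, delta-beta, clustering.

The methylation level of a CpG probe is summarized by the beta-value

    beta = M / (M + U + offset)

where ``M`` and ``U`` are the normalized signal intensities of the
methylated and unmethylated allele and ``offset`` (default 100) regularizes
low-intensity probes.  Probes are assigned to genes when they fall in the
500 bp window immediately upstream (strand-aware) of the transcription
start site, and per-gene methylation change between two conditions is the
mean beta-value difference over the gene's promoter probes.

Coordinates are 0-based, windows half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import DataError

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_UPSTREAM_BP = 500

__all__ = [
    "compute_beta",
    "average_replicates",
    "beta_matrix_from_intensities",
    "assign_promoter_probes",
    "delta_beta",
    "summarize_delta_beta",
    "cluster_by_chromosome",
    "BetaMatrix",
    "PromoterAssignment",
    "DeltaBetaTable",
    "read_intensities",
    "read_manifest",
    "read_annotation",
]


# ---------------------------------------------------------------------------
# beta-values
# ---------------------------------------------------------------------------

def compute_beta(M, U, offset: float = DEFAULT_BETA_OFFSET):
    """Beta-value ``M / (M + U + offset)``.

    Accepts scalars or array-likes; returns the same shape.  With a
    positive offset the result is always in ``[0, 1)``.

    Raises
    ------
    DataError
        If any intensity is negative or the offset is not positive.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if offset <= 0:
        raise DataError(f"offset must be positive, got {offset}")
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise DataError("intensities must be finite")
    if np.any(M < 0) or np.any(U < 0):
        raise DataError("intensities must be non-negative")
    beta = M / (M + U + offset)
    if beta.ndim == 0:
        return float(beta)
    return beta


@dataclass
class BetaMatrix:
    """Per-condition beta-values (probe x condition) after replicate averaging."""

    beta: pd.DataFrame  # index: probe_id, columns: condition
    offset: float = DEFAULT_BETA_OFFSET
    replicate_count: dict = field(default_factory=dict)

    @property
    def conditions(self) -> list:
        return list(self.beta.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index


def average_replicates(beta_by_sample: pd.DataFrame,
                       grouping: Mapping[str, str],
                       offset: float = DEFAULT_BETA_OFFSET) -> BetaMatrix:
    """Average replicate beta columns into one column per condition.

    Parameters
    ----------
    beta_by_sample
        Probe x sample beta-values.
    grouping
        sample id -> condition label; every sample column must be mapped.

    The per-condition value is the arithmetic mean over that condition's
    replicates; single-replicate conditions pass through unchanged.
    """
    missing = [s for s in beta_by_sample.columns if s not in grouping]
    if missing:
        raise DataError(f"samples without condition assignment: {missing}")
    conditions: dict[str, list[str]] = {}
    for sample in beta_by_sample.columns:
        conditions.setdefault(grouping[sample], []).append(sample)
    for cond, samples in conditions.items():
        if not samples:
            raise DataError(f"condition {cond!r} has no samples")
    averaged = pd.DataFrame(
        {cond: beta_by_sample[samples].mean(axis=1)
         for cond, samples in conditions.items()},
        index=beta_by_sample.index,
    )
    return BetaMatrix(
        beta=averaged,
        offset=offset,
        replicate_count={c: len(s) for c, s in conditions.items()},
    )


def beta_matrix_from_intensities(intensities: pd.DataFrame,
                                 grouping: Mapping[str, str],
                                 offset: float = DEFAULT_BETA_OFFSET) -> BetaMatrix:
    """Long-format intensities (probe_id, sample_id, M, U) -> BetaMatrix."""
    required = {"probe_id", "sample_id", "M", "U"}
    if not required.issubset(intensities.columns):
        raise DataError(
            f"intensity table must have columns {sorted(required)}")
    dup = intensities.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        raise DataError("duplicate (probe, sample) intensity records")
    df = intensities.copy()
    df["beta"] = compute_beta(df["M"].to_numpy(), df["U"].to_numpy(), offset)
    wide = df.pivot(index="probe_id", columns="sample_id", values="beta")
    if wide.isna().any().any():
        raise DataError("intensity table is not complete (missing probe/sample pairs)")
    return average_replicates(wide, grouping, offset=offset)


# ---------------------------------------------------------------------------
# promoter assignment
# ---------------------------------------------------------------------------

@dataclass
class PromoterAssignment:
    """probe_id -> set of gene ids, for probes inside a promoter window."""

    probe_to_genes: dict[str, set]
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    downstream_bp: int = 0

    def genes_for(self, probe_id: str) -> set:
        return self.probe_to_genes.get(probe_id, set())

    @property
    def gene_to_probes(self) -> dict:
        out: dict[str, list] = {}
        for probe, genes in self.probe_to_genes.items():
            for g in genes:
                out.setdefault(g, []).append(probe)
        return out


def promoter_window(tss: int, strand: str,
                    upstream_bp: int = DEFAULT_UPSTREAM_BP) -> tuple[int, int]:
    """Half-open genomic interval of the promoter window for one gene.

    Plus strand, TSS ``t``: ``[t - upstream, t)`` — the upstream flank ends
    just before the TSS base.  Minus strand: upstream is to the right, so
    ``[t + 1, t + upstream + 1)``; the TSS base itself is excluded on both
    strands.
    """
    if strand == "+":
        return tss - upstream_bp, tss
    if strand == "-":
        return tss + 1, tss + upstream_bp + 1
    raise DataError(f"unknown strand {strand!r}")


def assign_promoter_probes(manifest: pd.DataFrame,
                           annotation: pd.DataFrame,
                           upstream_bp: int = DEFAULT_UPSTREAM_BP) -> PromoterAssignment:
    """Map array probes into strand-aware promoter windows.

    A probe is assigned to a gene iff it is on the same chromosome and its
    position falls in the gene's half-open window (see
    :func:`promoter_window`).  A probe may map to several genes; probes on
    chromosomes absent from the annotation are left unassigned.
    """
    for col in ("probe_id", "chrom", "pos"):
        if col not in manifest.columns:
            raise DataError(f"manifest missing column {col!r}")
    for col in ("gene_id", "chrom", "strand", "tss"):
        if col not in annotation.columns:
            raise DataError(f"annotation missing column {col!r}")

    probe_to_genes: dict[str, set] = {}
    ann_by_chrom = dict(tuple(annotation.groupby("chrom", sort=False)))
    for chrom, probes in manifest.groupby("chrom", sort=False):
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            continue  # unknown chromosome: probes stay unassigned
        starts = np.empty(len(genes), dtype=np.int64)
        ends = np.empty(len(genes), dtype=np.int64)
        for i, (tss, strand) in enumerate(zip(genes["tss"], genes["strand"])):
            starts[i], ends[i] = promoter_window(int(tss), strand, upstream_bp)
        pos = probes["pos"].to_numpy(dtype=np.int64)
        # broadcast containment: fine at array-manifest scale per chromosome
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] < ends[None, :])
        gene_ids = genes["gene_id"].to_numpy()
        probe_ids = probes["probe_id"].to_numpy()
        for pi, gi in zip(*np.nonzero(inside)):
            probe_to_genes.setdefault(probe_ids[pi], set()).add(gene_ids[gi])
    return PromoterAssignment(probe_to_genes, upstream_bp=upstream_bp)


# ---------------------------------------------------------------------------
# delta-beta
# ---------------------------------------------------------------------------

@dataclass
class DeltaBetaTable:
    """Per-gene methylation change between two conditions.

    ``genes`` has one row per gene with >=1 promoter probe: mean Delta-beta
    (arithmetic mean over the gene's promoter probes), max |Delta-beta|,
    and the probe count.  ``probes`` is the probe-level table behind it.
    """

    genes: pd.DataFrame   # index gene_id: mean_delta_beta, max_abs_delta_beta, n_probes
    probes: pd.DataFrame  # columns: probe_id, gene_id, delta_beta
    cond_a: str
    cond_b: str


def delta_beta(beta: BetaMatrix, assignment: PromoterAssignment,
               cond_a: str, cond_b: str) -> DeltaBetaTable:
    """Per-probe and per-gene ``beta(cond_b) - beta(cond_a)``.

    Genes with no assigned probe are absent from the result.
    """
    for cond in (cond_a, cond_b):
        if cond not in beta.beta.columns:
            raise DataError(f"unknown condition {cond!r}")
    dbeta = beta.beta[cond_b] - beta.beta[cond_a]
    rows = []
    for probe_id, genes in assignment.probe_to_genes.items():
        if probe_id not in dbeta.index:
            continue
        for gene in genes:
            rows.append((probe_id, gene, dbeta.loc[probe_id]))
    probes = pd.DataFrame(rows, columns=["probe_id", "gene_id", "delta_beta"])
    if len(probes):
        grouped = probes.groupby("gene_id")["delta_beta"]
        genes_df = pd.DataFrame({
            "mean_delta_beta": grouped.mean(),
            "max_abs_delta_beta": grouped.apply(lambda s: s.abs().max()),
            "n_probes": grouped.size(),
        })
    else:
        genes_df = pd.DataFrame(
            columns=["mean_delta_beta", "max_abs_delta_beta", "n_probes"])
    return DeltaBetaTable(genes=genes_df, probes=probes,
                          cond_a=cond_a, cond_b=cond_b)


def summarize_delta_beta(tables: Sequence[DeltaBetaTable],
                         mode: str = "mean") -> pd.DataFrame:
    """Combine per-derivative Delta-beta tables into one gene-level summary.

    mode "mean": average each gene's mean Delta-beta across derivatives
    (genes missing from a table contribute nothing to its average).
    mode "any": keep, per gene, the derivative value of largest magnitude,
    so a single strongly shifted derivative can drive the screen.
    """
    if not tables:
        raise DataError("no delta-beta tables to summarize")
    if mode not in ("mean", "any"):
        raise DataError(f"unknown derivative summary mode {mode!r}")
    frames = [t.genes["mean_delta_beta"].rename(i) for i, t in enumerate(tables)]
    wide = pd.concat(frames, axis=1)
    if mode == "mean":
        summary = wide.mean(axis=1)
    else:
        idx = wide.abs().to_numpy()
        idx = np.nanargmax(idx, axis=1)
        summary = pd.Series(
            wide.to_numpy()[np.arange(len(wide)), idx], index=wide.index)
    n_probes = pd.concat(
        [t.genes["n_probes"] for t in tables], axis=1).max(axis=1).astype(int)
    return pd.DataFrame({"delta_beta": summary, "n_probes": n_probes})


# ---------------------------------------------------------------------------
# clustering (heatmap row ordering)
# ---------------------------------------------------------------------------

def _ordered_leaves(matrix: np.ndarray, metric: str) -> list[int]:
    if len(matrix) == 1:
        return [0]
    dist = pdist(matrix, metric=metric)
    # correlation distance is undefined for constant rows; treat them as
    # maximally distant from everything rather than propagating NaN
    dist = np.nan_to_num(dist, nan=1.0)
    Z = linkage(dist, method="average")
    return [int(i) for i in leaves_list(Z)]


def cluster_by_chromosome(beta: BetaMatrix,
                          manifest: pd.DataFrame) -> dict[str, list[str]]:
    """Average-linkage clustering of probes within each chromosome.

    Distance is Euclidean on the per-condition beta vector.  Returns, per
    chromosome, the dendrogram leaf order as a list of probe ids
    (deterministic: scipy breaks ties by input order, lower index first).
    """
    order: dict[str, list[str]] = {}
    manifest = manifest[manifest["probe_id"].isin(beta.beta.index)]
    for chrom, probes in manifest.groupby("chrom", sort=False):
        probe_ids = probes["probe_id"].tolist()
        sub = beta.beta.loc[probe_ids].to_numpy()
        leaves = _ordered_leaves(sub, metric="euclidean")
        order[chrom] = [probe_ids[i] for i in leaves]
    return order


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_intensities(path) -> pd.DataFrame:
    """Read a probe intensity TSV (probe_id, sample_id, M, U)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample_id": str})
    required = {"probe_id", "sample_id", "M", "U"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    return df


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos); 0-based positions."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Read gene annotation TSV (gene_id, chrom, strand, tss, exonic_length).

    A headerless BED6-style file (chrom, start, end, gene_id, score, strand)
    is also accepted; then tss = start for + strand and end - 1 for - strand,
    and exonic_length = end - start.
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    if "gene_id" in head.columns:
        df = pd.read_csv(path, sep="\t",
                         dtype={"gene_id": str, "chrom": str, "strand": str})
        required = {"gene_id", "chrom", "strand", "tss", "exonic_length"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: expected columns {sorted(required)}")
        return df
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id", "score", "strand"],
                      dtype={"chrom": str, "gene_id": str, "strand": str})
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return pd.DataFrame({
        "gene_id": bed["gene_id"], "chrom": bed["chrom"],
        "strand": bed["strand"], "tss": tss,
        "exonic_length": bed["end"] - bed["start"],
    })
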