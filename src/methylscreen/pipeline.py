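"""End-to-end orchestration: simulate inputs, run the screen, write artifacts.

A run is a pure function of (config, seed): rerunning with the same YAML
config reproduces byte-identical outputs, and every run writes a manifest
(config hash, seed, version, row counts) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from . import bisulfite, expression, methylation, screen, survival, synthetic
from .synthetic import PARENTAL, SimulationConfig

logger = logging.getLogger(__name__)

SIMULATION_FILES = ("annotation.tsv", "manifest.tsv", "intensities.tsv",
                    "counts.tsv", "clones.fasta", "truth.tsv", "survival.tsv")

__all__ = ["RunConfig", "run_simulation", "run_screen", "run_bisulfite",
           "run_survival", "SIMULATION_FILES"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, loadable from one YAML file."""

    out_dir: str = "methylscreen_out"
    # input paths (default: the files run_simulation writes into out_dir)
    annotation: str | None = None
    manifest: str | None = None
    intensities: str | None = None
    counts: str | None = None
    clones: str | None = None
    survival_table: str | None = None
    # thresholds
    min_rpkm: float = 3.0
    min_abs_log2fc: float = 1.0
    min_abs_delta_beta: float = 0.1
    upstream_bp: int = 500
    beta_offset: float = 100.0
    rpkm_floor: float = 0.01
    min_conversion: float = 0.95
    # modes: how the derivative lines are collapsed before gating.
    # Methylation arrays are duplicated and precise, so the cross-line mean
    # delta-beta is stable; RNA-seq has one sample per line, so a gene is
    # called expression-changed if ANY derivative line shows the fold-change
    # (a single noisy draw in the line average would otherwise mask it).
    methylation_summary: str = "mean"   # "mean" | "any"
    expression_summary: str = "any"     # "mean" | "any"
    derivative_summary: str | None = None  # convenience: sets both when given
    parental_condition: str = PARENTAL
    # blocks
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bisulfite_sim: dict = field(default_factory=lambda: {
        "amplicon_length": 300, "n_cpg": 10, "n_clones": 10,
        "parental_meth_prob": 0.1, "derivative_meth_prob": 0.9})
    survival_sim: dict = field(default_factory=lambda: {
        "n_subjects": 200, "group_hazard_ratio": 2.0, "censor_rate": 0.2})

    def __post_init__(self):
        for name in ("min_rpkm", "min_abs_log2fc", "min_abs_delta_beta",
                     "upstream_bp", "rpkm_floor", "min_conversion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.beta_offset <= 0:
            raise ConfigError("beta_offset must be positive")
        if self.derivative_summary is not None:
            self.methylation_summary = self.derivative_summary
            self.expression_summary = self.derivative_summary
        for name in ("methylation_summary", "expression_summary"):
            if getattr(self, name) not in ("mean", "any"):
                raise ConfigError(
                    f"{name} must be 'mean' or 'any', got {getattr(self, name)!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            sim = raw.pop("simulation")
            if "seed" not in sim:
                raise ConfigError("simulation.seed is mandatory in the config")
            try:
                raw["simulation"] = SimulationConfig(**sim)
            except TypeError as exc:
                raise ConfigError(f"simulation block: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def path(self, name: str, default_file: str) -> Path:
        explicit = getattr(self, name)
        if explicit:
            return Path(explicit)
        return Path(self.out_dir) / default_file

    def content_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, step: str, row_counts: dict):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "step": step,
        "config_hash": cfg.content_hash(),
        "seed": cfg.simulation.seed,
        "version": __version__,
        "row_counts": row_counts,
    }
    with open(out / f"run_manifest_{step}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _tsv(df: pd.DataFrame, path: Path, index: bool = False):
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulation(cfg: RunConfig) -> dict:
    """Write every input the screen consumes, plus the ground truth."""
    sim = cfg.simulation
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation = synthetic.generate_annotation(sim)
    truth = synthetic.generate_ground_truth(annotation, sim)
    manifest = synthetic.generate_probe_manifest(annotation, sim, cfg.upstream_bp)
    intensities = synthetic.simulate_methylation_intensities(manifest, truth, sim)
    counts = synthetic.simulate_expression_counts(annotation, truth, sim)

    bs = cfg.bisulfite_sim
    amplicon = synthetic.random_amplicon(sim, bs["amplicon_length"], bs["n_cpg"])
    all_clones = []
    for cond in [PARENTAL] + synthetic.derivative_names(sim):
        prob = bs["parental_meth_prob"] if cond == PARENTAL \
            else bs["derivative_meth_prob"]
        clone_set, _ = synthetic.simulate_bisulfite_clones(
            amplicon, [prob] * bs["n_cpg"], bs["n_clones"], sim, sample_id=cond)
        all_clones.extend(clone_set.clones)
    clones = bisulfite.CloneSet(reference=amplicon, clones=all_clones)

    sv = cfg.survival_sim
    surv = synthetic.simulate_survival(
        sv["n_subjects"], sv["group_hazard_ratio"], sv["censor_rate"], sim)

    _tsv(annotation, out / "annotation.tsv")
    _tsv(manifest[["probe_id", "chrom", "pos"]], out / "manifest.tsv")
    _tsv(intensities, out / "intensities.tsv")
    counts_long = counts.reset_index().melt(
        id_vars="gene_id", var_name="sample_id", value_name="count")
    _tsv(counts_long.sort_values(["gene_id", "sample_id"]), out / "counts.tsv")
    bisulfite.write_clone_fasta(clones, out / "clones.fasta")
    _tsv(truth.as_frame().reset_index(), out / "truth.tsv")
    _tsv(surv, out / "survival.tsv")

    _write_manifest(cfg, "simulate", {
        "annotation": len(annotation), "manifest": len(manifest),
        "intensities": len(intensities), "counts": len(counts_long),
        "clones": len(all_clones), "survival": len(surv),
    })
    return {"annotation": annotation, "manifest": manifest, "truth": truth,
            "intensities": intensities, "counts": counts, "clones": clones,
            "survival": surv}


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def _condition_of(sample_id: str) -> str:
    """parental_rep1 -> parental; anything without _rep stays itself."""
    if "_rep" in sample_id:
        return sample_id.rsplit("_rep", 1)[0]
    return sample_id


def run_screen(cfg: RunConfig) -> screen.ScreenResult:
    """Read inputs, run methylation + expression arms, integrate, write TSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation = methylation.read_annotation(cfg.path("annotation", "annotation.tsv"))
    manifest = methylation.read_manifest(cfg.path("manifest", "manifest.tsv"))
    intensities = methylation.read_intensities(
        cfg.path("intensities", "intensities.tsv"))
    counts = expression.read_counts(cfg.path("counts", "counts.tsv"))

    grouping = {s: _condition_of(s) for s in intensities["sample_id"].unique()}
    beta = methylation.beta_matrix_from_intensities(
        intensities, grouping, offset=cfg.beta_offset)
    parental = cfg.parental_condition
    if parental not in beta.conditions:
        raise DataError(f"parental condition {parental!r} not in intensity data")
    derivatives = sorted(c for c in beta.conditions if c != parental)
    if not derivatives:
        raise DataError("no derivative conditions in intensity data")

    assignment = methylation.assign_promoter_probes(
        manifest, annotation, upstream_bp=cfg.upstream_bp)
    dbeta_tables = [methylation.delta_beta(beta, assignment, parental, d)
                    for d in derivatives]
    dbeta_summary = methylation.summarize_delta_beta(
        dbeta_tables, mode=cfg.methylation_summary)

    lengths = annotation.set_index("gene_id")["exonic_length"]
    rpkm = expression.rpkm_matrix(counts, lengths)
    expr_derivs = sorted(c for c in rpkm.columns if c != parental)
    if parental not in rpkm.columns or not expr_derivs:
        raise DataError("count table must contain the parental condition "
                        "and at least one derivative")
    expr_input = expression.summarize_derivative_expression(
        rpkm, parental, expr_derivs, mode=cfg.expression_summary,
        floor=cfg.rpkm_floor)

    result = screen.integrate(
        expr_input, dbeta_summary,
        min_abs_delta_beta=cfg.min_abs_delta_beta,
        min_rpkm=cfg.min_rpkm, min_abs_log2fc=cfg.min_abs_log2fc)
    report = screen.candidate_report(result, beta, assignment, cond_a=parental)

    _tsv(beta.beta.reset_index(), out / "beta.tsv")
    _tsv(rpkm.reset_index(), out / "rpkm.tsv")
    z, _ = expression.zscore_rows(rpkm)
    _tsv(z.reset_index(), out / "zscore.tsv")
    _tsv(result.table.rename_axis("gene_id").reset_index(), out / "screen.tsv")
    _tsv(report, out / "probe_report.tsv")
    _write_manifest(cfg, "screen", {
        "beta_probes": len(beta.beta), "screen_genes": len(result.table),
        "candidates": len(result.candidates), "probe_report": len(report),
    })
    return result


# ---------------------------------------------------------------------------
# bisulfite + survival subcommands
# ---------------------------------------------------------------------------

def run_bisulfite(clones_path, reference_path=None, out_dir="methylscreen_out",
                  min_conversion: float = 0.95) -> bisulfite.CloneCallMatrix:
    """Call clone methylation and write call-grid and fraction TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clone_set = bisulfite.read_clone_fasta(clones_path, reference_path)
    calls = bisulfite.call_methylation(clone_set, min_conversion=min_conversion)
    summary = bisulfite.lollipop_summary(calls)

    grid = calls.calls.copy()
    grid.insert(0, "sample_id", calls.sample_of)
    grid.insert(1, "retained", calls.retained)
    grid.insert(2, "conversion_efficiency", calls.conversion_efficiency)
    _tsv(grid.rename_axis("clone_id").reset_index(), out / "clone_calls.tsv")

    frac_rows = [{"sample_id": s,
                  "overall_methylated_fraction": d["overall_fraction"],
                  "n_retained_clones": len(d["grid"])}
                 for s, d in summary.items()]
    _tsv(pd.DataFrame(frac_rows), out / "methylation_fractions.tsv")
    return calls


def run_survival(table_path, out_dir="methylscreen_out") -> dict:
    """Median-split KM curves and the log-rank test; write TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = survival.read_survival_table(table_path)
    groups = survival.median_split(table["marker"].to_numpy())
    stat, p = survival.logrank_test(
        table["time"].to_numpy(), table["event"].to_numpy(), groups)
    curves = {}
    for g in ("low", "high"):
        mask = groups == g
        if mask.any():
            curves[g] = survival.km_estimator(
                table.loc[mask, "time"].to_numpy(),
                table.loc[mask, "event"].to_numpy())
    km_frames = []
    for g, curve in curves.items():
        f = curve.as_frame()
        f.insert(0, "group", g)
        km_frames.append(f)
    _tsv(pd.concat(km_frames, ignore_index=True), out / "km_curves.tsv")
    _tsv(pd.DataFrame([{"statistic": stat, "p_value": p,
                        "n_low": int(np.sum(groups == "low")),
                        "n_high": int(np.sum(groups == "high"))}]),
         out / "logrank.tsv")
    return {"statistic": stat, "p_value": p, "curves": curves, "groups": groups}
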