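"""Synthetic two-condition epigenome simulator with known ground truth.

Emulates the study design the screen was built for: one parental cell
line plus several derivative lines, methylation arrays run in duplicate
per line, a single RNA-seq sample per line.  A chosen fraction of genes
is "planted": their promoter probes gain ``delta_beta_effect`` methylation
in every derivative line and their expression is scaled by
``2**log2fc_effect`` — the hypermethylated-silenced pattern the screen
should recover.  Everything is a pure function of (inputs, seed).

Defaults encode the emulated design: 2000 genes, 3 derivative lines,
duplicate arrays, 5% planted genes with a +0.4 promoter beta shift and a
4-fold expression drop, beta noise sd 0.05 on the raw-beta scale, and
negative-binomial counts with dispersion 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .bisulfite import CloneSet, find_cpg_sites

PARENTAL = "parental"

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "generate_ground_truth",
    "generate_probe_manifest",
    "simulate_methylation_intensities",
    "simulate_expression_counts",
    "simulate_bisulfite_clones",
    "simulate_survival",
    "random_amplicon",
    "derivative_names",
]


@dataclass
class SimulationConfig:
    """Tunable knobs of the simulator; defaults are the emulated design.

    ``beta_noise_sd`` is applied on the raw-beta scale (additive Gaussian,
    clipped to [0, 0.99]).  ``intensity_scale`` is the mean total signal
    M + U per probe; because beta-values are computed with a +100 offset,
    observed beta is biased low by a factor scale/(scale+100) — accepted
    and documented.  ``count_dispersion`` is the negative-binomial alpha
    (variance = mu + alpha * mu^2); 0 means Poisson.
    """

    n_genes: int = 2000
    chrom_names: list = field(default_factory=lambda: [f"chr{i}" for i in range(1, 9)])
    probes_per_promoter: int = 3
    n_background_probes: int = 1000
    n_derivative_conditions: int = 3
    n_array_replicates: int = 2
    planted_fraction: float = 0.05
    delta_beta_effect: float = 0.4
    log2fc_effect: float = -2.0
    beta_noise_sd: float = 0.05
    intensity_scale: float = 4000.0
    count_library_size: int = 1_000_000
    count_dispersion: float = 0.1
    conversion_rate: float = 0.99
    seed: int = 0

    def __post_init__(self):
        positive = ["n_genes", "probes_per_promoter", "n_derivative_conditions",
                    "n_array_replicates", "intensity_scale", "count_library_size"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_background_probes < 0:
            raise ConfigError("n_background_probes must be non-negative")
        if not self.chrom_names:
            raise ConfigError("chrom_names must be nonempty")
        if not 0 < self.planted_fraction < 1:
            raise ConfigError(
                f"planted_fraction must be in (0,1), got {self.planted_fraction}")
        if self.n_planted < 1:
            raise ConfigError("planted_fraction * n_genes must be >= 1")
        if not 0 <= self.delta_beta_effect <= 1:
            raise ConfigError(
                f"delta_beta_effect must be in [0,1], got {self.delta_beta_effect}")
        if self.beta_noise_sd < 0:
            raise ConfigError("beta_noise_sd must be non-negative")
        if self.count_dispersion < 0:
            raise ConfigError("count_dispersion must be non-negative")
        if not 0 < self.conversion_rate <= 1:
            raise ConfigError(
                f"conversion_rate must be in (0,1], got {self.conversion_rate}")

    @property
    def n_planted(self) -> int:
        # round half-up, so a fraction hitting exactly .5 still plants a gene
        return int(np.floor(self.planted_fraction * self.n_genes + 0.5))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Which genes were planted, with their true effects."""

    planted_gene_ids: set
    true_delta_beta: pd.Series   # indexed by gene_id, 0 for unplanted
    true_log2fc: pd.Series

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "planted": self.true_delta_beta.index.isin(self.planted_gene_ids),
            "true_delta_beta": self.true_delta_beta,
            "true_log2fc": self.true_log2fc,
        })


def derivative_names(config: SimulationConfig) -> list[str]:
    return [f"derivative_{i + 1}" for i in range(config.n_derivative_conditions)]


# ---------------------------------------------------------------------------
# annotation and ground truth
# ---------------------------------------------------------------------------

_GENE_SPACING = 4000       # bp between consecutive TSS slots on a chromosome
_TSS_MIN = 1000            # upstream windows never underflow
_TSS_JITTER = 2000


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay genes out round-robin across chromosomes with non-overlapping
    promoter neighborhoods (TSS slots 4 kb apart, jittered within 2 kb)."""
    rng = config.rng(1)
    n = config.n_genes
    chroms = [config.chrom_names[i % len(config.chrom_names)] for i in range(n)]
    idx_on_chrom = {}
    slots = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        k = idx_on_chrom.get(c, 0)
        idx_on_chrom[c] = k + 1
        slots[i] = _TSS_MIN + k * _GENE_SPACING
    tss = slots + rng.integers(0, _TSS_JITTER, size=n)
    strand = rng.choice(["+", "-"], size=n)
    exonic_length = rng.integers(500, 5000, size=n)
    return pd.DataFrame({
        "gene_id": [f"gene_{i:05d}" for i in range(n)],
        "chrom": chroms,
        "strand": strand,
        "tss": tss,
        "exonic_length": exonic_length,
    })


def generate_ground_truth(annotation: pd.DataFrame,
                          config: SimulationConfig) -> GroundTruth:
    rng = config.rng(2)
    planted = set(rng.choice(annotation["gene_id"].to_numpy(),
                             size=config.n_planted, replace=False))
    idx = pd.Index(annotation["gene_id"], name="gene_id")
    is_planted = idx.isin(planted)
    return GroundTruth(
        planted_gene_ids=planted,
        true_delta_beta=pd.Series(
            np.where(is_planted, config.delta_beta_effect, 0.0), index=idx),
        true_log2fc=pd.Series(
            np.where(is_planted, config.log2fc_effect, 0.0), index=idx),
    )


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def _windows(annotation: pd.DataFrame, upstream_bp: int = 500):
    from .methylation import promoter_window
    return {
        row.gene_id: (row.chrom, *promoter_window(int(row.tss), row.strand,
                                                  upstream_bp))
        for row in annotation.itertuples()
    }


def generate_probe_manifest(annotation: pd.DataFrame,
                            config: SimulationConfig,
                            upstream_bp: int = 500) -> pd.DataFrame:
    """Place probes_per_promoter probes inside each promoter window and
    n_background_probes outside all windows.

    The returned frame carries a ``gene_id`` column (empty string for
    background probes) used internally by the intensity simulator; the
    manifest TSV on disk keeps only (probe_id, chrom, pos).
    """
    if annotation.empty:
        raise DataError("annotation is empty")
    if config.probes_per_promoter > upstream_bp:
        raise DataError(
            f"promoter window ({upstream_bp} bp) too small for "
            f"{config.probes_per_promoter} distinct probes")
    rng = config.rng(3)
    windows = _windows(annotation, upstream_bp)

    rows = []
    k = 0
    for gene_id, (chrom, start, end) in windows.items():
        pos = rng.choice(np.arange(start, end), size=config.probes_per_promoter,
                         replace=False)
        for p in sorted(int(x) for x in pos):
            rows.append((f"cg{k:07d}", chrom, p, gene_id))
            k += 1

    # background probes: rejection-sample positions outside every window
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in windows.values():
        by_chrom.setdefault(chrom, []).append((start, end))
    chrom_len = {c: max(e for _, e in iv) + 5000 for c, iv in by_chrom.items()}
    chrom_names = list(chrom_len)
    placed = 0
    while placed < config.n_background_probes:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        p = int(rng.integers(0, chrom_len[chrom]))
        if any(s <= p < e for s, e in by_chrom[chrom]):
            continue
        rows.append((f"cg{k:07d}", chrom, p, ""))
        k += 1
        placed += 1

    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id"])


# ---------------------------------------------------------------------------
# methylation intensities
# ---------------------------------------------------------------------------

def simulate_methylation_intensities(manifest: pd.DataFrame,
                                     truth: GroundTruth,
                                     config: SimulationConfig) -> pd.DataFrame:
    """Long-format (probe_id, sample_id, M, U) intensity records.

    Baseline expected beta per probe: Beta(0.5, 5) for promoter probes
    (CpG-island-like, mostly unmethylated) and Beta(5, 5) for background
    probes.  Promoter probes of planted genes are shifted by
    +delta_beta_effect in every derivative condition, clipped to [0, 0.99].
    Per replicate, Gaussian noise (sd beta_noise_sd) is added on the raw
    beta scale and intensities are back-computed as M = beta * S,
    U = (1 - beta) * S with S ~ Normal(scale, 0.1 * scale) floored at 200.
    """
    if "gene_id" not in manifest.columns:
        raise DataError("manifest must carry the simulator's gene_id column")
    unknown = set(manifest.loc[manifest["gene_id"] != "", "gene_id"]) \
        - set(truth.true_delta_beta.index)
    if unknown:
        raise DataError(f"manifest genes absent from truth: {sorted(unknown)[:5]}")
    rng = config.rng(4)
    n_probes = len(manifest)
    is_promoter = (manifest["gene_id"] != "").to_numpy()

    baseline = np.where(
        is_promoter,
        rng.beta(0.5, 5.0, size=n_probes),
        rng.beta(5.0, 5.0, size=n_probes),
    )
    planted_probe = np.zeros(n_probes, dtype=bool)
    planted_probe[is_promoter] = manifest.loc[is_promoter, "gene_id"] \
        .isin(truth.planted_gene_ids).to_numpy()
    # per-gene true shift (allows non-default per-gene effects via truth)
    shift = np.zeros(n_probes)
    shift[planted_probe] = truth.true_delta_beta.loc[
        manifest.loc[planted_probe, "gene_id"]].to_numpy()

    conditions = [PARENTAL] + derivative_names(config)
    records = []
    for cond in conditions:
        expected = baseline if cond == PARENTAL else np.clip(baseline + shift, 0, 0.99)
        for rep in range(1, config.n_array_replicates + 1):
            noisy = expected
            if config.beta_noise_sd > 0:
                noisy = expected + rng.normal(0, config.beta_noise_sd, size=n_probes)
            noisy = np.clip(noisy, 0.0, 0.99)
            S = rng.normal(config.intensity_scale, 0.1 * config.intensity_scale,
                           size=n_probes)
            S = np.maximum(S, 200.0)
            records.append(pd.DataFrame({
                "probe_id": manifest["probe_id"],
                "sample_id": f"{cond}_rep{rep}",
                "M": noisy * S,
                "U": (1.0 - noisy) * S,
            }))
    return pd.concat(records, ignore_index=True)


def sample_grouping(config: SimulationConfig) -> dict[str, str]:
    """sample_id -> condition map matching the simulated array layout."""
    grouping = {}
    for cond in [PARENTAL] + derivative_names(config):
        for rep in range(1, config.n_array_replicates + 1):
            grouping[f"{cond}_rep{rep}"] = cond
    return grouping


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

_BASELINE_RPKM_LOG_MEAN = np.log(30.0)
_BASELINE_RPKM_LOG_SD = 0.8


def simulate_expression_counts(annotation: pd.DataFrame,
                               truth: GroundTruth,
                               config: SimulationConfig) -> pd.DataFrame:
    """Gene x condition count matrix, one RNA-seq sample per condition.

    Baseline abundance per gene ~ LogNormal(ln 30, 0.8) in RPKM units;
    expected counts are rpkm * length * library_size / 1e9.  Planted
    genes' derivative means are scaled by 2**log2fc_effect.  Counts are
    negative-binomial (variance mu + alpha mu^2) or Poisson when the
    dispersion alpha is 0.
    """
    rng = config.rng(5)
    genes = annotation["gene_id"].to_numpy()
    lengths = annotation["exonic_length"].to_numpy(dtype=float)
    base_rpkm = rng.lognormal(_BASELINE_RPKM_LOG_MEAN, _BASELINE_RPKM_LOG_SD,
                              size=len(genes))
    base_mu = base_rpkm * lengths * config.count_library_size / 1e9
    fold = 2.0 ** truth.true_log2fc.loc[genes].to_numpy()

    def draw(mu):
        mu = np.maximum(mu, 1e-8)
        if config.count_dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / config.count_dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    data = {PARENTAL: draw(base_mu)}
    for cond in derivative_names(config):
        data[cond] = draw(base_mu * fold)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------

def random_amplicon(config: SimulationConfig, length: int = 300,
                    n_cpg: int = 10) -> str:
    """Random amplicon with exactly ``n_cpg`` CpG dinucleotides.

    CpG-free backbone with CpGs planted at evenly spread offsets — a
    synthetic stand-in for a promoter-region amplicon.
    """
    rng = config.rng(6)
    if length < 3 * n_cpg + 2:
        raise DataError("amplicon too short for requested CpG count")
    while True:
        seq = rng.choice(list("ACGT"), size=length)
        # break accidental CpGs so planted sites are the only ones
        for i in range(length - 1):
            while seq[i] == "C" and seq[i + 1] == "G":
                seq[i + 1] = rng.choice(list("ACT"))
        positions = np.linspace(1, length - 3, n_cpg).astype(int)
        ok = True
        prev = -10
        for p in positions:
            if p - prev < 2:
                ok = False
                break
            prev = p
        if not ok:
            continue
        for p in positions:
            seq[p], seq[p + 1] = "C", "G"
        amplicon = "".join(seq)
        if len(find_cpg_sites(amplicon)) == n_cpg:
            return amplicon


def simulate_bisulfite_clones(region_sequence: str,
                              cpg_methylation_probs,
                              n_clones: int,
                              config: SimulationConfig,
                              sample_id: str = "sample_1",
                              ) -> tuple[CloneSet, np.ndarray]:
    """In-silico bisulfite conversion and cloning of one amplicon.

    Per clone, each CpG is methylated with its per-site probability;
    unmethylated CpG cytosines and all non-CpG cytosines convert C -> T
    with probability ``conversion_rate`` (failures stay C).  Returns the
    CloneSet and the true clone x site methylation states (bool array).
    """
    region = region_sequence.upper()
    sites = find_cpg_sites(region)
    if not sites:
        raise DataError("region contains no CpG dinucleotide")
    probs = np.asarray(cpg_methylation_probs, dtype=float)
    if probs.size != len(sites):
        raise DataError(
            f"{probs.size} methylation probs for {len(sites)} CpG sites")
    if np.any((probs < 0) | (probs > 1)):
        raise DataError("methylation probs must be in [0,1]")
    rng = config.rng(7)
    site_set = set(sites)
    non_cpg_c = [i for i, b in enumerate(region) if b == "C" and i not in site_set]

    clones = []
    states = np.zeros((n_clones, len(sites)), dtype=bool)
    for ci in range(n_clones):
        seq = list(region)
        meth = rng.random(len(sites)) < probs
        states[ci] = meth
        for si, pos in enumerate(sites):
            if not meth[si] and rng.random() < config.conversion_rate:
                seq[pos] = "T"
        for pos in non_cpg_c:
            if rng.random() < config.conversion_rate:
                seq[pos] = "T"
        clones.append((f"{sample_id}_clone{ci + 1}", sample_id, "".join(seq)))
    return CloneSet(reference=region, clones=clones, cpg_sites=sites), states


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

_BASELINE_HAZARD = 0.1


def simulate_survival(n_subjects: int, group_hazard_ratio: float,
                      censor_rate: float, config: SimulationConfig,
                      ) -> pd.DataFrame:
    """Two-group exponential survival cohort keyed to an expression marker.

    Half the subjects are "high" expressors (marker ~ N(2, 0.1)) whose
    event hazard is baseline * hazard_ratio; the rest are "low"
    (marker ~ N(0, 0.1)).  A median split of the marker reproduces the
    group labels by construction.  Censoring is independent exponential,
    calibrated so the expected censored fraction equals ``censor_rate``
    within each group.
    """
    if n_subjects < 4:
        raise DataError("need at least 4 subjects")
    if group_hazard_ratio <= 0:
        raise ConfigError("group_hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ConfigError(f"censor_rate must be in [0,1), got {censor_rate}")
    rng = config.rng(8)
    n_high = n_subjects // 2
    high = np.zeros(n_subjects, dtype=bool)
    high[rng.choice(n_subjects, size=n_high, replace=False)] = True

    hazard = np.where(high, _BASELINE_HAZARD * group_hazard_ratio, _BASELINE_HAZARD)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # P(C < T) = c/(h + c) for independent exponentials => c below
        censor_hazard = hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n_subjects, dtype=int)

    marker = np.where(high, rng.normal(2.0, 0.1, n_subjects),
                      rng.normal(0.0, 0.1, n_subjects))
    return pd.DataFrame({
        "subject": [f"subj_{i:04d}" for i in range(n_subjects)],
        "time": time,
        "event": event,
        "marker": marker,
    })
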