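"""Clone bisulfite-sequencing analysis: per-CpG methylation calls.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T)
while 5-methylcytosine is protected.  Sequencing cloned PCR products of
the converted top strand therefore reads C at a CpG when that CpG was
methylated and T when it was not; every cytosine outside a CpG context
should read T, and the fraction that actually does is the clone's
conversion efficiency (a QC statistic: clones below 95% efficiency are
unreliable and excluded from sample-level fractions).

Clones are aligned globally to the reference amplicon with bisulfite-aware
scoring: a reference C aligned to a clone T counts as a match, because
conversion is the expected outcome, while all other mismatches are
penalized (match +1, mismatch -1, gap open -2, gap extend -1).  Only the
top strand is modeled: the reference amplicon is taken as the
converted-strand template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONVERSION = 0.95
MIN_ALIGNMENT_IDENTITY = 0.7

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"

__all__ = [
    "find_cpg_sites",
    "align_clone",
    "call_methylation",
    "lollipop_summary",
    "CloneSet",
    "CloneCallMatrix",
    "read_clone_fasta",
    "write_clone_fasta",
]


@dataclass
class CloneSet:
    """Reference amplicon plus sequenced clones.

    ``clones`` is a list of (clone_id, sample_id, sequence).  ``cpg_sites``
    are the 0-based reference offsets of the C of each CpG, ascending.
    """

    reference: str
    clones: list[tuple[str, str, str]]
    cpg_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.reference = self.reference.upper()
        if not self.cpg_sites:
            self.cpg_sites = find_cpg_sites(self.reference)
        for pos in self.cpg_sites:
            if self.reference[pos:pos + 2] != "CG":
                raise DataError(f"position {pos} is not the C of a CpG")


def find_cpg_sites(reference: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide, ascending."""
    reference = reference.upper()
    bad = set(reference) - set("ACGT")
    if bad:
        raise DataError(f"non-ACGT characters in reference: {sorted(bad)}")
    return [i for i in range(len(reference) - 1)
            if reference[i] == "C" and reference[i + 1] == "G"]


def _bisulfite_aligner() -> PairwiseAligner:
    # asymmetric: target (reference) C vs query (clone) T is an expected
    # conversion, scored like a match
    mat = substitution_matrices.Array(alphabet="ACGT", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = 1.0 if a == b else -1.0
    mat["C", "T"] = 1.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _bisulfite_aligner()


@dataclass
class CloneAlignment:
    """Reference-position -> clone-position map for one clone."""

    position_map: dict[int, int]
    identity: float
    score: float


def align_clone(clone: str, reference: str) -> CloneAlignment:
    """Global bisulfite-aware alignment of one clone to the reference.

    The identity is the fraction of alignment columns that are
    match-equivalent (equal bases, or reference C over clone T); columns
    with a gap count against it.  Clones with identity below 0.7 are
    rejected.
    """
    clone = clone.upper()
    reference = reference.upper()
    if not reference or not clone:
        raise DataError("empty sequence")
    if abs(len(clone) - len(reference)) > 0.2 * len(reference):
        raise DataError(
            f"clone length {len(clone)} outside 20% of reference "
            f"length {len(reference)}")
    alignment = _ALIGNER.align(reference, clone)[0]
    position_map: dict[int, int] = {}
    n_equiv = 0
    n_cols = 0
    for (rs, re_), (cs, ce) in zip(*alignment.aligned):
        for k in range(re_ - rs):
            r, c = rs + k, cs + k
            position_map[r] = c
            rb, cb = reference[r], clone[c]
            if rb == cb or (rb == "C" and cb == "T"):
                n_equiv += 1
        n_cols += re_ - rs
    # count gap columns toward the alignment length
    n_cols += (len(reference) - len(position_map)) + (len(clone) - len(position_map))
    identity = n_equiv / n_cols if n_cols else 0.0
    if identity < MIN_ALIGNMENT_IDENTITY:
        raise DataError(
            f"clone rejected: bisulfite-aware identity {identity:.3f} < "
            f"{MIN_ALIGNMENT_IDENTITY}")
    return CloneAlignment(position_map=position_map,
                          identity=identity,
                          score=float(alignment.score))


@dataclass
class CloneCallMatrix:
    """Per-clone CpG calls and conversion QC.

    ``calls``: clone x CpG-site frame of {methylated, unmethylated,
    ambiguous}.  ``conversion_efficiency``: per clone, the fraction of
    non-CpG reference cytosines read as T (denominator restricted to
    positions where the clone base is C or T).  ``retained`` marks clones
    passing the conversion QC; ``sample_of`` maps clone id -> sample id.
    """

    calls: pd.DataFrame
    conversion_efficiency: pd.Series
    retained: pd.Series
    sample_of: pd.Series
    min_conversion: float

    def sample_fraction(self, sample_id: str) -> float:
        """Methylated fraction over retained clones of one sample
        (ambiguous calls excluded from the denominator)."""
        clones = self.retained.index[
            self.retained & (self.sample_of == sample_id)]
        sub = self.calls.loc[clones]
        n_meth = (sub == METHYLATED).to_numpy().sum()
        n_unmeth = (sub == UNMETHYLATED).to_numpy().sum()
        total = n_meth + n_unmeth
        return n_meth / total if total else float("nan")


def call_methylation(clones: CloneSet,
                     min_conversion: float = DEFAULT_MIN_CONVERSION,
                     ) -> CloneCallMatrix:
    """Call per-CpG methylation for every clone against the reference.

    At each CpG site (the C base only): clone C -> methylated, clone T ->
    unmethylated, gap or any other base -> ambiguous.  Clones whose
    alignment fails, or whose conversion efficiency is below
    ``min_conversion``, are kept in the matrix (all-ambiguous for failed
    alignments) but flagged not-retained.
    """
    ref = clones.reference
    sites = clones.cpg_sites
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in set(sites)]

    call_rows, eff, retained, samples = {}, {}, {}, {}
    for clone_id, sample_id, seq in clones.clones:
        seq = seq.upper()
        samples[clone_id] = sample_id
        try:
            aln = align_clone(seq, ref)
        except DataError as exc:
            logger.warning("clone %s: %s", clone_id, exc)
            call_rows[clone_id] = [AMBIGUOUS] * len(sites)
            eff[clone_id] = float("nan")
            retained[clone_id] = False
            continue
        row = []
        for pos in sites:
            cpos = aln.position_map.get(pos)
            base = seq[cpos] if cpos is not None else None
            if base == "C":
                row.append(METHYLATED)
            elif base == "T":
                row.append(UNMETHYLATED)
            else:
                row.append(AMBIGUOUS)
        call_rows[clone_id] = row

        converted = unconverted = 0
        for pos in non_cpg_c:
            cpos = aln.position_map.get(pos)
            base = seq[cpos] if cpos is not None else None
            if base == "T":
                converted += 1
            elif base == "C":
                unconverted += 1
        denom = converted + unconverted
        e = converted / denom if denom else 1.0
        eff[clone_id] = e
        retained[clone_id] = e >= min_conversion
        if not retained[clone_id]:
            logger.warning("clone %s excluded: conversion efficiency %.3f < %.3f",
                           clone_id, e, min_conversion)

    index = pd.Index(list(call_rows), name="clone_id")
    return CloneCallMatrix(
        calls=pd.DataFrame.from_dict(call_rows, orient="index",
                                     columns=[f"cpg_{p}" for p in sites]),
        conversion_efficiency=pd.Series(eff, index=index, name="conversion_efficiency"),
        retained=pd.Series(retained, index=index, name="retained"),
        sample_of=pd.Series(samples, index=index, name="sample_id"),
        min_conversion=min_conversion,
    )


def lollipop_summary(calls: CloneCallMatrix) -> dict[str, dict]:
    """Per-sample clone x CpG-site call grid plus methylation fractions.

    For each sample: ``grid`` (retained clones x sites, call strings, the
    lollipop-figure content), ``site_fractions`` (per-site methylated
    fraction over unambiguous calls) and ``overall_fraction``.  Samples
    whose clones were all rejected get an empty grid and a warning.
    """
    out: dict[str, dict] = {}
    for sample_id in sorted(calls.sample_of.unique()):
        clone_ids = calls.retained.index[
            calls.retained & (calls.sample_of == sample_id)]
        grid = calls.calls.loc[clone_ids]
        if grid.empty:
            logger.warning("sample %s: all clones rejected", sample_id)
            out[sample_id] = {
                "grid": grid,
                "site_fractions": pd.Series(dtype=float),
                "overall_fraction": float("nan"),
            }
            continue
        meth = (grid == METHYLATED)
        unmeth = (grid == UNMETHYLATED)
        denom = (meth.sum(axis=0) + unmeth.sum(axis=0)).astype(float)
        site_fr = meth.sum(axis=0) / denom.where(denom > 0)
        total = denom.sum()
        overall = meth.to_numpy().sum() / total if total else float("nan")
        out[sample_id] = {
            "grid": grid,
            "site_fractions": site_fr,
            "overall_fraction": float(overall),
        }
    return out


# ---------------------------------------------------------------------------
# FASTA I/O (clone sample encoded as "sample=<id>" in the description)
# ---------------------------------------------------------------------------

def read_clone_fasta(clones_path, reference_path=None) -> CloneSet:
    """Read clones (and the reference amplicon) from FASTA.

    If ``reference_path`` is None, the record named "reference" in
    ``clones_path`` is used as the amplicon.
    """
    records = list(SeqIO.parse(str(clones_path), "fasta"))
    reference = None
    if reference_path is not None:
        refs = list(SeqIO.parse(str(reference_path), "fasta"))
        if not refs:
            raise DataError(f"{reference_path}: no reference record")
        reference = str(refs[0].seq)
    clones = []
    for rec in records:
        if rec.id == "reference":
            if reference is None:
                reference = str(rec.seq)
            continue
        sample = "unknown"
        for token in rec.description.split():
            if token.startswith("sample="):
                sample = token.split("=", 1)[1]
        clones.append((rec.id, sample, str(rec.seq)))
    if reference is None:
        raise DataError("no reference amplicon found")
    return CloneSet(reference=reference, clones=clones)


def write_clone_fasta(clone_set: CloneSet, path, include_reference: bool = True):
    """Write the reference (optionally) and all clones to one FASTA file."""
    records = []
    if include_reference:
        records.append(SeqRecord(Seq(clone_set.reference), id="reference",
                                 description="amplicon"))
    for clone_id, sample_id, seq in clone_set.clones:
        records.append(SeqRecord(Seq(seq), id=clone_id,
                                 description=f"sample={sample_id}"))
    SeqIO.write(records, str(path), "fasta")
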