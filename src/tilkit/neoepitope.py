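"""Somatic variant → neoepitope candidate chain.

Mirrors a tumor whole-exome / RNA-seq neoantigen discovery workflow for
single amino-acid substitutions:

1. ``filter_variants`` — depth/VAF filters: tumor depth > 10, normal depth
   > 10, tumor VAF ≥ 0.10, tumor/normal VAF ratio ≥ 5 (a variant absent
   from the germline, normal VAF = 0, passes the ratio by definition).
2. ``caller_concordance`` — keep variants reported by ≥ k of the four
   somatic callers (MuTect, SomaticSniper, Strelka, VarScan; default k=2).
3. ``build_window`` — a 25-mer mutant window centered on the substituted
   residue (truncated at protein termini, never dropping the mutation).
4. ``enumerate_peptides`` — all 8–11mer substrings of the window that span
   the mutated position (the MHC class I candidate peptides).
5. ``prioritize_fpkm`` — flag candidates whose transcript exceeds an FPKM
   threshold (default 100).
6. ``rank_candidates`` — attach per-peptide binding scores from a
   pluggable scorer and keep candidates with at least one peptide at or
   below the cutoff (default 0.5; the threshold is unit-agnostic — wire in
   an external predictor reporting nM affinity or percentile rank as
   appropriate).

Upstream steps (alignment, somatic calling, expression quantification,
the MHC binding model itself) are consumed as inputs, never recomputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "VariantRecord",
    "NeoepitopeCandidate",
    "KNOWN_CALLERS",
    "filter_variants",
    "caller_concordance",
    "build_window",
    "enumerate_peptides",
    "prioritize_fpkm",
    "rank_candidates",
    "stub_scorer",
    "read_variants_csv",
    "candidates_to_frame",
    "peptides_to_fasta",
]

KNOWN_CALLERS = frozenset({"mutect", "somaticsniper", "strelka", "varscan"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

WINDOW_FLANK = 12  # residues on each side of the mutation → 25-mer
PEPTIDE_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class VariantRecord:
    """One somatic protein-coding substitution with its evidence."""

    gene: str
    protein_context: str  # reference amino-acid sequence around the site
    position: int  # 1-based index of the mutated residue in the context
    ref_aa: str
    alt_aa: str
    tumor_depth: int
    normal_depth: int
    tumor_vaf: float
    normal_vaf: float
    callers: frozenset[str] = frozenset()
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.protein_context):
            raise DataError(
                f"{self.gene}: position {self.position} outside context "
                f"(length {len(self.protein_context)})"
            )
        if self.protein_context[self.position - 1] != self.ref_aa:
            raise DataError(
                f"{self.gene}: ref_aa {self.ref_aa!r} does not match context "
                f"residue {self.protein_context[self.position - 1]!r} at "
                f"position {self.position}"
            )
        for name, vaf in (("tumor_vaf", self.tumor_vaf), ("normal_vaf", self.normal_vaf)):
            if not 0 <= vaf <= 1:
                raise DataError(f"{self.gene}: {name}={vaf} outside [0, 1]")
        unknown = set(self.callers) - KNOWN_CALLERS
        if unknown:
            raise DataError(f"{self.gene}: unknown caller(s) {sorted(unknown)}")
        if len(self.ref_aa) != 1 or len(self.alt_aa) != 1:
            raise DataError(
                f"{self.gene}: only single amino-acid substitutions are supported "
                f"(got {self.ref_aa!r}>{self.alt_aa!r}); indels/frameshifts are out "
                "of scope"
            )


@dataclass(frozen=True)
class NeoepitopeCandidate:
    """A mutant 25-mer window and its mutation-spanning peptides."""

    variant: VariantRecord
    window25: str
    mut_index_in_window: int  # 1-based
    peptides: tuple[tuple[str, int, int], ...] = ()  # (sequence, length, start)
    prioritized: bool = False
    binding_scores: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _depth_vaf_violations(v: VariantRecord) -> list[str]:
    reasons = []
    if not v.tumor_depth > 10:
        reasons.append("tumor_depth<=10")
    if not v.normal_depth > 10:
        reasons.append("normal_depth<=10")
    if not v.tumor_vaf >= 0.10:
        reasons.append("tumor_vaf<0.10")
    # normal_vaf == 0 (germline-clean) passes the ratio by definition
    if v.normal_vaf > 0 and v.tumor_vaf / v.normal_vaf < 5:
        reasons.append("tumor_normal_vaf_ratio<5")
    return reasons


def filter_variants(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], dict[int, list[str]]]:
    """Apply the depth/VAF filter chain.

    Returns the kept records (input order preserved) and, for every
    rejected record, the full list of failed criteria keyed by input
    index.
    """
    kept: list[VariantRecord] = []
    rejected: dict[int, list[str]] = {}
    for i, v in enumerate(records):
        reasons = _depth_vaf_violations(v)
        if reasons:
            rejected[i] = reasons
        else:
            kept.append(v)
    return kept, rejected


def caller_concordance(
    records: Sequence[VariantRecord], k: int = 2
) -> list[VariantRecord]:
    """Keep variants reported by at least ``k`` of the somatic callers."""
    if k < 1:
        raise ConfigError(f"caller_concordance: k must be >= 1, got {k}")
    return [v for v in records if len(v.callers) >= k]


# ---------------------------------------------------------------------------
# Windows and peptides
# ---------------------------------------------------------------------------

def build_window(v: VariantRecord) -> NeoepitopeCandidate:
    """Mutant 25-mer window around the substituted residue.

    The window spans up to 12 residues on each side of the mutation; near
    a protein terminus it is truncated but always contains the mutated
    residue, with the substituted amino acid in place of the reference.
    """
    left = max(1, v.position - WINDOW_FLANK)
    right = min(len(v.protein_context), v.position + WINDOW_FLANK)
    window = list(v.protein_context[left - 1 : right])
    mut_index = v.position - left + 1
    window[mut_index - 1] = v.alt_aa
    return NeoepitopeCandidate(
        variant=v, window25="".join(window), mut_index_in_window=mut_index
    )


def enumerate_peptides(c: NeoepitopeCandidate) -> NeoepitopeCandidate:
    """All distinct 8–11mer substrings of the window spanning the mutation.

    Peptides are ordered by (start, length) and deduplicated on sequence;
    a window shorter than 8 residues yields an empty peptide list.
    """
    window = c.window25
    mut = c.mut_index_in_window  # 1-based
    peptides: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    for start in range(1, len(window) + 1):
        for length in PEPTIDE_LENGTHS:
            end = start + length - 1
            if end > len(window):
                continue
            if not (start <= mut <= end):
                continue
            seq = window[start - 1 : end]
            if seq in seen:
                continue
            seen.add(seq)
            peptides.append((seq, length, start))
    peptides.sort(key=lambda p: (p[2], p[1]))
    return replace(c, peptides=tuple(peptides))


def prioritize_fpkm(
    cands: Sequence[NeoepitopeCandidate], threshold: float = 100.0
) -> list[NeoepitopeCandidate]:
    """Flag candidates whose transcript level strictly exceeds ``threshold``.

    Prioritized candidates come first, then by FPKM descending; ties keep
    input order (stable sort).
    """
    if threshold < 0:
        raise ConfigError(f"prioritize_fpkm: threshold must be >= 0, got {threshold}")
    flagged = [replace(c, prioritized=c.variant.fpkm > threshold) for c in cands]
    return sorted(flagged, key=lambda c: (not c.prioritized, -c.variant.fpkm))


def stub_scorer(peptide: str) -> float:
    """Deterministic stand-in binding scorer for tests and dry runs.

    Hashes the peptide sequence to a pseudo-affinity in (0, 50]. Total
    over the 20-letter amino-acid alphabet, seed-free and platform
    independent. Not a binding model — wire an external predictor through
    ``rank_candidates`` for real scoring.
    """
    digest = hashlib.sha256(peptide.encode("ascii")).digest()
    value = int.from_bytes(digest[:8], "big") / 2**64  # uniform-ish in [0,1)
    return round(50.0 * value + 1e-9, 6)


def rank_candidates(
    cands: Sequence[NeoepitopeCandidate],
    scorer: Callable[[str], float] = stub_scorer,
    cutoff: float = 0.5,
) -> list[NeoepitopeCandidate]:
    """Score every peptide and keep candidates with ≥1 peptide ≤ cutoff.

    The cutoff is inclusive. The scorer is any callable peptide → score;
    lower scores mean stronger predicted binding.
    """
    if cutoff <= 0:
        raise ConfigError(f"rank_candidates: cutoff must be > 0, got {cutoff}")
    survivors = []
    for c in cands:
        scores = []
        for seq, _length, _start in c.peptides:
            try:
                scores.append(float(scorer(seq)))
            except Exception as exc:  # surface which peptide broke the scorer
                raise DataError(f"scorer failed on peptide {seq!r}: {exc}") from exc
        scored = replace(c, binding_scores=tuple(scores))
        if any(s <= cutoff for s in scores):
            survivors.append(scored)
    return survivors


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "gene",
    "protein_context",
    "position",
    "ref_aa",
    "alt_aa",
    "tumor_depth",
    "normal_depth",
    "tumor_vaf",
    "normal_vaf",
    "callers",
    "fpkm",
]


def read_variants_csv(path) -> list[VariantRecord]:
    """Read somatic variants from CSV (callers as a ';'-joined field)."""
    df = pd.read_csv(path)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing variant columns {missing}")
    records = []
    for i, row in df.iterrows():
        callers = frozenset(
            s for s in str(row["callers"]).split(";") if s and s != "nan"
        )
        try:
            records.append(
                VariantRecord(
                    gene=str(row["gene"]),
                    protein_context=str(row["protein_context"]),
                    position=int(row["position"]),
                    ref_aa=str(row["ref_aa"]),
                    alt_aa=str(row["alt_aa"]),
                    tumor_depth=int(row["tumor_depth"]),
                    normal_depth=int(row["normal_depth"]),
                    tumor_vaf=float(row["tumor_vaf"]),
                    normal_vaf=float(row["normal_vaf"]),
                    callers=callers,
                    fpkm=float(row["fpkm"]),
                )
            )
        except DataError as exc:
            raise DataError(f"{path} row {i}: {exc}") from exc
    return records


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in records:
        row = {c: getattr(v, c) for c in _VARIANT_COLUMNS if c != "callers"}
        row["callers"] = ";".join(sorted(v.callers))
        rows.append(row)
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def candidates_to_frame(cands: Sequence[NeoepitopeCandidate]) -> pd.DataFrame:
    """One row per peptide, with window and variant context."""
    rows = []
    for c in cands:
        scores = c.binding_scores or [float("nan")] * len(c.peptides)
        for (seq, length, start), score in zip(c.peptides, scores):
            rows.append(
                {
                    "gene": c.variant.gene,
                    "mutation": f"{c.variant.ref_aa}{c.variant.position}{c.variant.alt_aa}",
                    "window25": c.window25,
                    "mut_index_in_window": c.mut_index_in_window,
                    "peptide": seq,
                    "length": length,
                    "start_in_window": start,
                    "prioritized": c.prioritized,
                    "fpkm": c.variant.fpkm,
                    "binding_score": score,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mutation",
            "window25",
            "mut_index_in_window",
            "peptide",
            "length",
            "start_in_window",
            "prioritized",
            "fpkm",
            "binding_score",
        ],
    )


def peptides_to_fasta(cands: Sequence[NeoepitopeCandidate], path) -> None:
    """Write mutant peptides as FASTA (one record per unique peptide)."""
    with open(path, "w") as fh:
        for c in cands:
            tag = f"{c.variant.gene}_{c.variant.ref_aa}{c.variant.position}{c.variant.alt_aa}"
            for seq, length, start in c.peptides:
                fh.write(f">{tag}|len{length}|start{start}\n{seq}\n")
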