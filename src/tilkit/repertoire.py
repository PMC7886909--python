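"""TCRβ repertoire metrics on sorted T-cell subsets.

A repertoire is the list of unique TCRβ rearrangements (clones) observed in
one sorted sample — e.g. the CD103+CD39+ double-positive (DP) CD8+ TIL
subset at the day of surgery. Each clone carries its CDR3 nucleotide and
amino-acid sequence, a template count, and a productive flag. On top of
this container the module computes:

* ``clonality`` — 1 − H/ln(R), the complement of Pielou evenness of the
  clone-frequency distribution. 1 means a monoclonal population, values
  near 0 a highly polyclonal one.
* ``morisita_horn`` — the abundance-weighted Morisita–Horn overlap index
  between two repertoires, 0 (disjoint clone sets) to 1 (identical
  frequency distributions).
* ``top_n_clones`` / ``track_clones`` — dominant-clone composition and
  cross-compartment presence of the dominant clones (blood vs tumor,
  pre vs post treatment).
* ``call_reactive_clones`` — clones above a frequency cutoff, as used to
  identify the dominant clones behind an antigen-specific response.

Clone identity defaults to the CDR3 *nucleotide* sequence; amino-acid
grouping is available for convergence-style analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, EmptyRepertoireError

__all__ = [
    "CloneRecord",
    "Repertoire",
    "filter_productive",
    "clonality",
    "morisita_horn",
    "top_n_clones",
    "track_clones",
    "call_reactive_clones",
    "read_repertoire_tsv",
    "write_repertoire_tsv",
]

IdentityKey = Literal["cdr3_nt", "cdr3_aa"]


@dataclass(frozen=True)
class CloneRecord:
    """One unique TCRβ rearrangement.

    ``frequency`` is always recomputed from counts by :class:`Repertoire`;
    a stored value is never trusted.
    """

    cdr3_nt: str
    cdr3_aa: str
    count: int
    productive: bool = True
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DataError(f"clone {self.cdr3_nt!r}: count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class Repertoire:
    """A set of clones from one sorted sample.

    Frequencies of the stored clones are recomputed at construction so
    that they always sum to 1 over the clones present.
    """

    clones: tuple[CloneRecord, ...]
    sample_id: str = ""
    compartment: str = ""  # blood | drLN | TIL
    subset: str = ""       # CD4mem | CD8mem | DN | SP | DP | Treg
    timepoint: str = ""    # pre | DOS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clones:
            if c.cdr3_nt in seen:
                raise DataError(
                    f"repertoire {self.sample_id!r}: duplicate cdr3_nt {c.cdr3_nt!r}"
                )
            seen.add(c.cdr3_nt)
        total = sum(c.count for c in self.clones)
        if total > 0:
            object.__setattr__(
                self,
                "clones",
                tuple(replace(c, frequency=c.count / total) for c in self.clones),
            )

    @property
    def total_templates(self) -> int:
        return sum(c.count for c in self.clones)

    @property
    def richness(self) -> int:
        """Number of unique clones (with positive count)."""
        return sum(1 for c in self.clones if c.count > 0)

    def counts(self, identity: IdentityKey = "cdr3_nt") -> dict[str, int]:
        """Template counts keyed by clone identity (aa grouping aggregates)."""
        out: dict[str, int] = {}
        for c in self.clones:
            key = getattr(c, identity)
            out[key] = out.get(key, 0) + c.count
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3_nt": [c.cdr3_nt for c in self.clones],
                "cdr3_aa": [c.cdr3_aa for c in self.clones],
                "count": [c.count for c in self.clones],
                "frequency": [c.frequency for c in self.clones],
                "productive": [c.productive for c in self.clones],
            }
        )


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep only productive rearrangements and renormalize frequencies.

    Raises
    ------
    EmptyRepertoireError
        If no productive clone remains.
    """
    kept = tuple(c for c in rep.clones if c.productive and c.count > 0)
    if not kept:
        raise EmptyRepertoireError(
            f"repertoire {rep.sample_id!r}: no productive clones after filtering"
        )
    return replace(rep, clones=kept)


def _require_nonempty(rep: Repertoire, op: str) -> None:
    if rep.richness == 0:
        raise EmptyRepertoireError(f"{op}: repertoire {rep.sample_id!r} is empty")


def clonality(rep: Repertoire, identity: IdentityKey = "cdr3_nt") -> float:
    """Clonality C = 1 − H/ln(R) of the clone-frequency distribution.

    H is the Shannon entropy (natural log) of clone frequencies and R the
    richness. A single-clone repertoire is defined to have clonality 1
    (the monoclonal limit of the 0/0 expression).
    """
    _require_nonempty(rep, "clonality")
    counts = np.array([n for n in rep.counts(identity).values() if n > 0], dtype=float)
    if counts.size == 1:
        return 1.0
    p = counts / counts.sum()
    entropy = -float(np.sum(p * np.log(p)))
    return 1.0 - entropy / math.log(counts.size)


def morisita_horn(
    a: Repertoire,
    b: Repertoire,
    identity: IdentityKey = "cdr3_nt",
    top_n: int | None = None,
) -> float:
    """Morisita–Horn overlap index between two repertoires.

    MH = 2 Σ x_i y_i / ((d_x + d_y) X Y) where x_i, y_i are template
    counts of clone i in each repertoire, X = Σx_i, Y = Σy_i and
    d_x = Σx_i²/X², d_y = Σy_i²/Y². 0 for disjoint clone sets, 1 for
    identical frequency distributions. Symmetric and invariant under
    uniform scaling of either count vector.

    ``top_n`` restricts each repertoire to its top-N clones before the
    comparison (the all-clone computation is the default).
    """
    _require_nonempty(a, "morisita_horn")
    _require_nonempty(b, "morisita_horn")
    if top_n is not None:
        a = _restrict_top_n(a, top_n)
        b = _restrict_top_n(b, top_n)
    xa = a.counts(identity)
    xb = b.counts(identity)
    X = float(sum(xa.values()))
    Y = float(sum(xb.values()))
    cross = sum(xa[k] * xb[k] for k in xa.keys() & xb.keys())
    d_x = sum(v * v for v in xa.values()) / (X * X)
    d_y = sum(v * v for v in xb.values()) / (Y * Y)
    mh = 2.0 * cross / ((d_x + d_y) * X * Y)
    if mh < -1e-12 or mh > 1.0 + 1e-12:
        raise DataError(f"morisita_horn out of range: {mh}")
    return min(max(mh, 0.0), 1.0)


def _sorted_clones(rep: Repertoire) -> list[CloneRecord]:
    # count descending, then cdr3_nt lexicographic: deterministic tie-break
    return sorted(rep.clones, key=lambda c: (-c.count, c.cdr3_nt))


def _restrict_top_n(rep: Repertoire, n: int) -> Repertoire:
    return replace(rep, clones=tuple(_sorted_clones(rep)[:n]))


def top_n_clones(rep: Repertoire, n: int) -> tuple[list[CloneRecord], float]:
    """The top-``n`` clones by count and their cumulative frequency.

    If ``n`` exceeds the richness all clones are returned. Ties are broken
    by cdr3_nt so the ordering is platform independent.
    """
    if n < 1:
        raise ConfigError(f"top_n_clones: n must be >= 1, got {n}")
    _require_nonempty(rep, "top_n_clones")
    top = _sorted_clones(rep)[:n]
    return top, float(sum(c.frequency for c in top))


def track_clones(
    reference: Repertoire,
    others: Mapping[str, Repertoire] | Sequence[Repertoire],
    n: int = 30,
    identity: IdentityKey = "cdr3_nt",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Trace the top-``n`` reference clones through comparator repertoires.

    Used to ask, e.g., how many of the top-30 DP TIL clones at the day of
    surgery were already present in the pre-treatment biopsy or in blood.

    Returns a table with one row per tracked clone (frequency 0 where
    absent) and, per comparator, the shared-clone count (clones with
    frequency > 0).
    """
    if isinstance(others, Mapping):
        comparators = dict(others)
    else:
        comparators = {r.sample_id or f"comparator_{i}": r for i, r in enumerate(others)}
    top, _ = top_n_clones(reference, n)
    rows = []
    freq_maps = {}
    for name, rep in comparators.items():
        counts = rep.counts(identity)
        total = sum(counts.values())
        freq_maps[name] = {k: v / total for k, v in counts.items()} if total else {}
    for clone in top:
        key = getattr(clone, identity)
        row: dict[str, object] = {
            "clone": key,
            "cdr3_aa": clone.cdr3_aa,
            "reference_frequency": clone.frequency,
        }
        for name in comparators:
            row[name] = freq_maps[name].get(key, 0.0)
        rows.append(row)
    table = pd.DataFrame(rows)
    shared = {
        name: int((table[name] > 0).sum()) if len(table) else 0 for name in comparators
    }
    return table, shared


def call_reactive_clones(rep: Repertoire, cutoff: float = 0.02) -> list[CloneRecord]:
    """Clones with frequency strictly above ``cutoff``, sorted descending.

    The default 2% cutoff is the dominant-clone rule used when decomposing
    an antigen-specific response into its driving clones.
    """
    if not 0 < cutoff < 1:
        raise ConfigError(f"call_reactive_clones: cutoff must be in (0,1), got {cutoff}")
    return [c for c in _sorted_clones(rep) if c.frequency > cutoff]


# ---------------------------------------------------------------------------
# AIRR-style TSV I/O
# ---------------------------------------------------------------------------

#: AIRR Community column names (written on output, accepted on input).
AIRR_COLUMNS = {
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "count": "duplicate_count",
    "productive": "productive",
}

#: immunoSEQ-export style headers, accepted on input.
IMMUNOSEQ_COLUMNS = {
    "cdr3_nt": "nucleotide",
    "cdr3_aa": "aminoAcid",
    "count": "count (templates/reads)",
    "productive": "sequenceStatus",
}

_TRUE_TOKENS = {"t", "true", "1", "yes", "in"}
_FALSE_TOKENS = {"f", "false", "0", "no", "out", "stop"}


def _parse_productive(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise DataError(f"cannot interpret productive flag {value!r}")


def read_repertoire_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    **meta: str,
) -> Repertoire:
    """Read a repertoire from an AIRR-style tab-separated file.

    Recognizes AIRR Community headers (``junction``/``junction_aa``/
    ``duplicate_count``/``productive``) and immunoSEQ-export headers
    (``nucleotide``/``aminoAcid``/``count (templates/reads)``/
    ``sequenceStatus`` with ``In``/``Out``/``Stop`` values); any other
    layout can be declared with an explicit ``column_map`` from the
    canonical field names to file column names.

    Extra keyword arguments set repertoire metadata (sample_id,
    compartment, subset, timepoint).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map is None:
        for candidate in (AIRR_COLUMNS, IMMUNOSEQ_COLUMNS):
            if set(candidate.values()) <= set(df.columns):
                column_map = candidate
                break
        else:
            raise DataError(
                f"{path}: unrecognized repertoire columns {list(df.columns)}; "
                "pass column_map"
            )
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    clones = tuple(
        CloneRecord(
            cdr3_nt=str(row[column_map["cdr3_nt"]]),
            cdr3_aa=str(row[column_map["cdr3_aa"]]),
            count=int(row[column_map["count"]]),
            productive=_parse_productive(row[column_map["productive"]]),
        )
        for _, row in df.iterrows()
    )
    return Repertoire(clones=clones, **meta)


def write_repertoire_tsv(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire with AIRR Community column names."""
    df = rep.to_frame().rename(columns=AIRR_COLUMNS)
    df["productive"] = df["productive"].map({True: "T", False: "F"})
    df.drop(columns=["frequency"]).to_csv(path, sep="\t", index=False)
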