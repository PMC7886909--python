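"""CD8 TIL activation index from paired flow-cytometry subset panels.

The activation index summarises three baseline → day-of-surgery (DOS)
changes in the CD8 TIL compartment of one patient:

* fold change in %CD8+ of T cells,
* fold change in %CD103+CD39+ (DP) of CD8+,
* fold change in %Ki-67+ of DP.

The composite is the geometric mean of the three fold changes, AI =
(fc_cd8 · fc_dp · fc_ki67dp)^(1/3). Under the default ``geom_gate`` rule a
patient is an immunologic responder when AI exceeds the threshold (1.0)
AND every individual fold change exceeds 1 — i.e. a robust increase in
all three categories. ``geom_only`` drops the per-component gate. Both
the rule and the threshold are configurable because published index
definitions of this kind vary in whether the threshold applies to the
composite, a single component, or both.

Percentages are handled on the 0–100 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "SubsetPanel",
    "ActivationResult",
    "fold_change",
    "activation_index",
    "classify_cohort",
    "timecourse_summary",
    "read_panels_csv",
]

DEFAULT_FLOOR = 0.01  # percentage points; keeps fold changes finite
Rule = Literal["geom_gate", "geom_only"]

#: subsets required by the activation index
INDEX_SUBSETS = ("pct_cd8_of_t", "pct_dp_of_cd8", "pct_ki67_of_dp")


@dataclass(frozen=True)
class SubsetPanel:
    """Flow subset frequencies for one patient at one timepoint."""

    patient_id: str
    timepoint: str  # baseline | DOS | D12 | D19 | D34 | D55
    pct_cd8_of_t: float | None = None
    pct_dp_of_cd8: float | None = None
    pct_ki67_of_dp: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in INDEX_SUBSETS:
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 100:
                raise DataError(
                    f"patient {self.patient_id!r}: {name}={value} outside [0, 100]"
                )
        for name, value in self.extras.items():
            if not 0 <= value <= 100:
                raise DataError(
                    f"patient {self.patient_id!r}: {name}={value} outside [0, 100]"
                )


@dataclass(frozen=True)
class ActivationResult:
    """Per-patient fold changes, composite index, and responder call."""

    patient_id: str
    fc_cd8: float
    fc_dp: float
    fc_ki67dp: float
    index: float
    responder: bool
    floored: bool = False  # a component hit the zero-percentage floor


def fold_change(pre: float, post: float, floor: float = DEFAULT_FLOOR) -> float:
    """Floored ratio post/pre: FC = max(post, floor) / max(pre, floor).

    The floor (default 0.01 percentage points) keeps the ratio finite when
    a subset was undetectable at one timepoint; callers that need to know
    whether flooring occurred can compare the inputs against ``floor``.
    """
    if floor <= 0:
        raise ConfigError(f"fold_change: floor must be > 0, got {floor}")
    if pre < 0 or post < 0:
        raise DataError(f"fold_change: negative input (pre={pre}, post={post})")
    return max(post, floor) / max(pre, floor)


def _panel_value(panel: SubsetPanel, name: str) -> float:
    value = getattr(panel, name)
    if value is None:
        raise DataError(
            f"patient {panel.patient_id!r} ({panel.timepoint}): missing {name}"
        )
    return value


def activation_index(
    panel_pre: SubsetPanel,
    panel_post: SubsetPanel,
    rule: Rule = "geom_gate",
    threshold: float = 1.0,
    floor: float = DEFAULT_FLOOR,
) -> ActivationResult:
    """Compute fold changes, composite index, and the responder call.

    ``panel_pre`` is the baseline biopsy panel and ``panel_post`` the
    day-of-surgery panel of the same patient.
    """
    if panel_pre.patient_id != panel_post.patient_id:
        raise DataError(
            f"patient mismatch: {panel_pre.patient_id!r} vs {panel_post.patient_id!r}"
        )
    if rule not in ("geom_gate", "geom_only"):
        raise ConfigError(f"unknown responder rule {rule!r}")
    fcs = {}
    floored = False
    for name in INDEX_SUBSETS:
        pre = _panel_value(panel_pre, name)
        post = _panel_value(panel_post, name)
        fcs[name] = fold_change(pre, post, floor)
        floored = floored or pre < floor or post < floor
    index = float(np.prod(list(fcs.values())) ** (1.0 / 3.0))
    responder = index > threshold
    if rule == "geom_gate":
        responder = responder and min(fcs.values()) > 1.0
    return ActivationResult(
        patient_id=panel_pre.patient_id,
        fc_cd8=fcs["pct_cd8_of_t"],
        fc_dp=fcs["pct_dp_of_cd8"],
        fc_ki67dp=fcs["pct_ki67_of_dp"],
        index=index,
        responder=responder,
        floored=floored,
    )


def classify_cohort(results: Sequence[ActivationResult]) -> pd.DataFrame:
    """Cohort summary table, one row per patient, ordered by patient_id.

    Raises on duplicate patient ids. Responder counts are available as
    ``table["responder"].sum()``; the table keeps every per-patient value
    so downstream survival grouping can join on patient_id.
    """
    if not results:
        raise DataError("classify_cohort: no results")
    ids = [r.patient_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"classify_cohort: duplicate patient ids {dupes}")
    rows = sorted(results, key=lambda r: r.patient_id)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "fc_cd8": [r.fc_cd8 for r in rows],
            "fc_dp": [r.fc_dp for r in rows],
            "fc_ki67dp": [r.fc_ki67dp for r in rows],
            "activation_index": [r.index for r in rows],
            "responder": [r.responder for r in rows],
            "floored": [r.floored for r in rows],
        }
    )


def timecourse_summary(
    panels: pd.DataFrame,
    baseline: str = "baseline",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Mean fold change vs baseline per subset per timepoint.

    ``panels`` is long format with columns (patient_id, timepoint, subset,
    value). Every included patient must have a baseline value for each of
    their subsets. Returns one row per (subset, timepoint) with the mean
    and standard deviation of per-patient fold changes plus a ``peak``
    flag marking the timepoint with the largest mean fold change for that
    subset.
    """
    required = {"patient_id", "timepoint", "subset", "value"}
    if not required <= set(panels.columns):
        raise DataError(f"timecourse_summary: need columns {sorted(required)}")
    base = panels[panels["timepoint"] == baseline].set_index(["patient_id", "subset"])[
        "value"
    ]
    rows = []
    post = panels[panels["timepoint"] != baseline]
    for (subset, timepoint), grp in post.groupby(["subset", "timepoint"], sort=True):
        fcs = []
        for _, row in grp.iterrows():
            key = (row["patient_id"], subset)
            if key not in base.index:
                raise DataError(
                    f"timecourse_summary: patient {row['patient_id']!r} lacks a "
                    f"baseline value for subset {subset!r}"
                )
            fcs.append(fold_change(float(base.loc[key]), float(row["value"]), floor))
        rows.append(
            {
                "subset": subset,
                "timepoint": timepoint,
                "mean_fc": float(np.mean(fcs)),
                "sd_fc": float(np.std(fcs, ddof=1)) if len(fcs) > 1 else 0.0,
                "n": len(fcs),
            }
        )
    out = pd.DataFrame(rows)
    out["peak"] = False
    for subset, grp in out.groupby("subset"):
        out.loc[grp["mean_fc"].idxmax(), "peak"] = True
    return out


def read_panels_csv(path) -> list[SubsetPanel]:
    """Read wide-format panels: one row per patient × timepoint.

    Columns: patient_id, timepoint, the three index subsets, and any extra
    percentage columns (kept in ``extras``).
    """
    df = pd.read_csv(path)
    required = {"patient_id", "timepoint"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: need columns {sorted(required)}")
    panels = []
    extra_cols = [
        c for c in df.columns if c not in required and c not in INDEX_SUBSETS
    ]
    for _, row in df.iterrows():
        kwargs = {
            name: float(row[name])
            for name in INDEX_SUBSETS
            if name in df.columns and pd.notna(row[name])
        }
        extras = {
            c: float(row[c]) for c in extra_cols if pd.notna(row[c])
        }
        panels.append(
            SubsetPanel(
                patient_id=str(row["patient_id"]),
                timepoint=str(row["timepoint"]),
                extras=extras,
                **kwargs,
            )
        )
    return panels
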