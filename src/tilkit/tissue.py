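"""Multiplex-IHC ROI aggregation, flow–IHC concordance, ELISpot calls.

ROI tables hold per-image cell densities (cells/mm², up to six 0.36 mm²
regions of interest per tissue sample) for phenotypes such as
CD8+CD103+Ki-67+, split into tumor and stroma compartments. Aggregation
is the arithmetic mean over available ROIs (missing images are not
imputed as zero — absence of an image is not absence of cells).

``flow_ihc_concordance`` regresses flow-cytometry subset percentages on
matched IHC densities (ordinary least squares; R² = squared Pearson r),
the consistency check between the two measurement modalities.

``elispot_call`` applies the reactivity rule for IFN-γ ELISpot wells:
positive iff strictly more than 100 spot-forming cells. Background
subtraction of a mock well is available but off by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, UndefinedStatisticError
from .activation import fold_change

__all__ = [
    "DEFAULT_ROI_AREA_MM2",
    "roi_aggregate",
    "counts_to_density",
    "compartment_fold_change",
    "flow_ihc_concordance",
    "elispot_call",
    "elispot_call_table",
]

DEFAULT_ROI_AREA_MM2 = 0.36

_ROI_KEYS = ["patient_id", "timepoint", "compartment", "phenotype"]


def roi_aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean density per patient × timepoint × compartment × phenotype.

    ``records`` needs columns patient_id, timepoint, compartment,
    phenotype, density (cells/mm²). Returns ``mean_density`` plus the
    number of ROIs that contributed (``n_roi``). Groups with no ROI are
    simply absent from the output rather than reported as zero.
    """
    required = set(_ROI_KEYS + ["density"])
    if not required <= set(records.columns):
        raise DataError(f"roi_aggregate: need columns {sorted(required)}")
    if (records["density"] < 0).any():
        raise DataError("roi_aggregate: negative density")
    out = (
        records.groupby(_ROI_KEYS, sort=True)["density"]
        .agg(mean_density="mean", n_roi="count")
        .reset_index()
    )
    return out


def counts_to_density(counts, roi_area_mm2: float = DEFAULT_ROI_AREA_MM2):
    """Convert raw per-ROI cell counts to densities (cells/mm²)."""
    if roi_area_mm2 <= 0:
        raise ConfigError(f"roi_area_mm2 must be > 0, got {roi_area_mm2}")
    return np.asarray(counts, dtype=float) / roi_area_mm2


def compartment_fold_change(pre_mean: float, post_mean: float, floor: float = 0.01) -> float:
    """Post/pre density fold change with the same floored-ratio contract
    as the flow fold change (see :func:`tilkit.activation.fold_change`)."""
    return fold_change(pre_mean, post_mean, floor)


def flow_ihc_concordance(
    flow_pct: Sequence[float], ihc_density: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of flow percentages against IHC densities.

    Returns (slope, intercept, R²) with R² the squared Pearson
    correlation. Raises :class:`UndefinedStatisticError` when either
    vector has zero variance (R² undefined), and requires ≥3 pairs.
    """
    x = np.asarray(ihc_density, dtype=float)
    y = np.asarray(flow_pct, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"flow_ihc_concordance: length mismatch {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataError(f"flow_ihc_concordance: need >=3 pairs, got {x.size}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise UndefinedStatisticError("flow_ihc_concordance: zero variance input")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def elispot_call(sfc: int, cutoff: int = 100, mock_sfc: int | None = None) -> bool:
    """Positive T-cell reactivity iff SFC strictly exceeds the cutoff.

    ``mock_sfc``, when given, is subtracted first (optional background
    correction; the plain >cutoff rule is the default behaviour).
    """
    if cutoff < 0:
        raise ConfigError(f"elispot_call: cutoff must be >= 0, got {cutoff}")
    if sfc < 0 or (mock_sfc is not None and mock_sfc < 0):
        raise DataError(f"elispot_call: negative spot count (sfc={sfc}, mock={mock_sfc})")
    effective = sfc if mock_sfc is None else sfc - mock_sfc
    return effective > cutoff


def elispot_call_table(
    wells: pd.DataFrame, cutoff: int = 100, subtract_mock: bool = False
) -> pd.DataFrame:
    """Apply the positivity rule to an ELISpot well table.

    ``wells`` needs columns well_id, subset, stimulus, sfc. With
    ``subtract_mock`` the per-subset well whose stimulus is ``"mock"``
    is subtracted from that subset's wells before calling.
    """
    required = {"well_id", "subset", "stimulus", "sfc"}
    if not required <= set(wells.columns):
        raise DataError(f"elispot_call_table: need columns {sorted(required)}")
    wells = wells.copy()
    if subtract_mock:
        mock = (
            wells[wells["stimulus"] == "mock"]
            .groupby("subset")["sfc"]
            .mean()
            .to_dict()
        )
        wells["positive"] = [
            elispot_call(int(r.sfc), cutoff, mock_sfc=int(mock.get(r.subset, 0)))
            for r in wells.itertuples()
        ]
    else:
        wells["positive"] = [elispot_call(int(s), cutoff) for s in wells["sfc"]]
    return wells
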