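"""Synthetic cohort generator.

Emulates the statistical structure of a neoadjuvant immunotherapy
immune-monitoring dataset so that every downstream stage of the toolkit
can be exercised and validated without patient data:

* **Repertoires** — clone abundances follow a discrete power law over
  ranked clones (heavy-tailed, so the top-30 clones dominate, as seen in
  the DP CD8+ TIL subset). The DN and SP bystander subsets, blood, and
  draining lymph node draw most of their mass from one shared clone pool;
  the tumor-reactive DP subset carries mostly private clones — planting
  the overlap ordering MH(DN,SP) > MH(DP,DN) ≈ MH(DP,SP).
* **Flow panels** — paired baseline/day-of-surgery subset percentages.
  Responder patients receive multiplicative lifts on %DP-of-CD8 and
  %Ki-67-of-DP (default 3.4-fold) and a modest lift on %CD8 (default
  2-fold); non-responders stay at fold 1. Fold noise is a mean-one
  lognormal factor at the configured coefficient of variation. Ground-
  truth responder labels are emitted in a sidecar table, never in the
  measurement files.
* **Peripheral timecourse** — per-subset activation kinetics with the
  planted peak at D12 (CD4 Ki-67 6.8-fold, CD8 Ki-67 4–6-fold,
  plasmablasts 10-fold, Treg Ki-67 2.6-fold), decaying back toward
  baseline by D55.
* **Variants** — somatic variant tables with a configurable fraction of
  records passing the full filter chain, the rest each violating at least
  one recorded criterion.
* **Survival** — exponential event times per group with independent
  exponential censoring and an administrative horizon.
* **ROI / ELISpot tables** — densities with stroma CD3 > tumor CD3, a
  tumor-confined responder lift of the proliferating CD8+CD103+Ki-67+
  phenotype, and ELISpot wells where DP responds to the planted antigen.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
seed + config reproduces identical output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .repertoire import CloneRecord, Repertoire, write_repertoire_tsv

__all__ = [
    "RepertoireConfig",
    "CohortConfig",
    "gen_repertoires",
    "gen_flow_cohort",
    "gen_timecourse",
    "gen_variants",
    "gen_survival",
    "gen_roi_cohort",
    "gen_elispot",
    "write_fixture_cohort",
]

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

COMPARTMENTS = ("blood_pre", "blood_post", "drLN", "DN", "SP", "DP")


def _check_fraction(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class RepertoireConfig:
    """Parameters of the clone-abundance and sharing model."""

    n_clones: int = 1000
    powerlaw_alpha: float = 2.0
    depth: int = 50_000
    shared_pool_fraction: float = 0.7
    dp_private_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ConfigError(f"n_clones must be >= 2, got {self.n_clones}")
        if self.depth < self.n_clones:
            raise ConfigError(
                f"depth ({self.depth}) must be >= n_clones ({self.n_clones})"
            )
        if self.powerlaw_alpha <= 1:
            raise ConfigError(f"powerlaw_alpha must be > 1, got {self.powerlaw_alpha}")
        _check_fraction("shared_pool_fraction", self.shared_pool_fraction)
        _check_fraction("dp_private_fraction", self.dp_private_fraction)


@dataclass(frozen=True)
class CohortConfig:
    """Effect sizes and noise for the synthetic flow cohort."""

    n_patients: int = 16
    responder_fraction: float = 0.25
    dp_fold_responder: float = 3.4
    cd8_fold_responder: float = 2.0
    ki67_cd4_fold: float = 6.8
    cd8_blood_fold_range: tuple[float, float] = (4.0, 6.0)
    treg_ki67_fold: float = 2.6
    plasmablast_fold: float = 10.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        _check_fraction("responder_fraction", self.responder_fraction)
        _check_fraction("noise_cv", self.noise_cv)
        for name in (
            "dp_fold_responder",
            "cd8_fold_responder",
            "ki67_cd4_fold",
            "treg_ki67_fold",
            "plasmablast_fold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.cd8_blood_fold_range
        if lo <= 0 or hi < lo:
            raise ConfigError(
                f"cd8_blood_fold_range must be an increasing pair of positive "
                f"reals, got {self.cd8_blood_fold_range}"
            )


# ---------------------------------------------------------------------------
# Repertoires
# ---------------------------------------------------------------------------

def _random_cdr3s(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    """Unique CDR3 nucleotide sequences (length 36) and their aa strings."""
    seqs: set[str] = set()
    while len(seqs) < n:
        block = rng.choice(_NT, size=(n - len(seqs), 36))
        seqs.update("".join(row) for row in block)
    nts = sorted(seqs)
    order = rng.permutation(n)
    nts = [nts[i] for i in order]
    aas = ["".join(rng.choice(_AA, size=12)) for _ in range(n)]
    return nts, aas


def _powerlaw_probs(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Rank-frequency power law p_k ∝ k^-alpha over a shuffled rank order."""
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks**-alpha
    p /= p.sum()
    return p[rng.permutation(n)]


def gen_repertoires(cfg: RepertoireConfig) -> dict[str, Repertoire]:
    """Generate the six compartment repertoires of one synthetic patient.

    Returns repertoires keyed blood_pre, blood_post, drLN, DN, SP, DP.
    Counts in each repertoire sum to ``cfg.depth``. DN/SP (and blood,
    drLN) draw ``shared_pool_fraction`` of their expected mass from one
    shared clone distribution; DP draws ``dp_private_fraction`` from a
    DP-private pool absent everywhere else.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_clones
    nts, aas = _random_cdr3s(rng, n)

    # partition the universe: one shared pool + five private pools
    n_shared = max(1, int(round(0.4 * n)))
    remaining = n - n_shared
    private_sizes = [remaining // 5] * 5
    for i in range(remaining - sum(private_sizes)):
        private_sizes[i] += 1
    bounds = np.cumsum([n_shared] + private_sizes)
    idx_shared = np.arange(0, bounds[0])
    pools = {}
    for name, lo, hi in zip(
        ("DN", "SP", "DP", "blood", "drLN"), bounds[:-1], bounds[1:]
    ):
        pools[name] = np.arange(lo, hi)

    shared_probs = _powerlaw_probs(len(idx_shared), cfg.powerlaw_alpha, rng)
    private_probs = {
        name: _powerlaw_probs(len(idx), cfg.powerlaw_alpha, rng) if len(idx) else None
        for name, idx in pools.items()
    }

    def mixture(private_name: str, shared_weight: float) -> np.ndarray:
        probs = np.zeros(n)
        priv = private_probs[private_name]
        if priv is None or shared_weight == 1.0:
            probs[idx_shared] = shared_probs
            return probs
        probs[idx_shared] = shared_weight * shared_probs
        probs[pools[private_name]] = (1.0 - shared_weight) * priv
        return probs

    spf, dpf = cfg.shared_pool_fraction, cfg.dp_private_fraction
    dists = {
        "blood_pre": mixture("blood", spf),
        "blood_post": mixture("blood", spf),
        "drLN": mixture("drLN", spf),
        "DN": mixture("DN", spf),
        "SP": mixture("SP", spf),
        "DP": mixture("DP", 1.0 - dpf),
    }

    out = {}
    for name in COMPARTMENTS:
        counts = rng.multinomial(cfg.depth, dists[name])
        present = np.flatnonzero(counts)
        clones = tuple(
            CloneRecord(cdr3_nt=nts[i], cdr3_aa=aas[i], count=int(counts[i]))
            for i in present
        )
        compartment = "blood" if name.startswith("blood") else (
            "drLN" if name == "drLN" else "TIL"
        )
        subset = "CD8mem" if name in ("blood_pre", "blood_post", "drLN") else name
        out[name] = Repertoire(
            clones=clones,
            sample_id=name,
            compartment=compartment,
            subset=subset,
            timepoint="pre" if name == "blood_pre" else "DOS",
        )
    return out


# ---------------------------------------------------------------------------
# Flow cohort
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_flow_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired baseline/DOS flow panels plus a ground-truth sidecar.

    Returns ``(panels, truth)``: panels in wide format (one row per
    patient × timepoint with the three index subsets) and a sidecar with
    the planted responder label per patient. The panel table itself never
    reveals the label.
    """
    rng = np.random.default_rng(cfg.seed)
    n_resp = int(round(cfg.n_patients * cfg.responder_fraction))
    labels = np.zeros(cfg.n_patients, dtype=bool)
    labels[rng.choice(cfg.n_patients, size=n_resp, replace=False)] = True

    rows, truth = [], []
    for i in range(cfg.n_patients):
        pid = f"SYN{i + 1:03d}"
        responder = bool(labels[i])
        base = {
            # upper clips keep lifted values below 100% so folds stay exact
            "pct_cd8_of_t": float(np.clip(rng.lognormal(np.log(20.0), 0.3), 0.5, 45.0)),
            "pct_dp_of_cd8": float(np.clip(rng.lognormal(np.log(8.0), 0.5), 0.1, 25.0)),
            "pct_ki67_of_dp": float(np.clip(rng.lognormal(np.log(10.0), 0.5), 0.1, 25.0)),
        }
        lifts = {
            "pct_cd8_of_t": cfg.cd8_fold_responder if responder else 1.0,
            "pct_dp_of_cd8": cfg.dp_fold_responder if responder else 1.0,
            "pct_ki67_of_dp": cfg.dp_fold_responder if responder else 1.0,
        }
        post = {
            k: float(np.clip(base[k] * lifts[k] * _lognormal_factor(rng, cfg.noise_cv), 0.0, 100.0))
            for k in base
        }
        rows.append({"patient_id": pid, "timepoint": "baseline", **base})
        rows.append({"patient_id": pid, "timepoint": "DOS", **post})
        truth.append({"patient_id": pid, "responder": responder})
    return pd.DataFrame(rows), pd.DataFrame(truth)


_TIMEPOINTS = ("baseline", "D12", "D19", "D34", "D55")
# fraction of the (peak − 1) excess remaining at each post-baseline draw
_DECAY = {"D12": 1.0, "D19": 0.55, "D34": 0.15, "D55": 0.02}


def gen_timecourse(cfg: CohortConfig) -> pd.DataFrame:
    """Peripheral-blood activation kinetics in long format.

    Subsets: pct_ki67_cd4 (peak 6.8-fold), pct_ki67_cd8 (peak drawn per
    patient from ``cd8_blood_fold_range``), pct_ki67_treg (2.6-fold),
    pct_plasmablast (10-fold). The planted peak is at D12 for every
    subset, decaying toward baseline by D55. Long format: patient_id,
    timepoint, subset, value.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.cd8_blood_fold_range
    rows = []
    for i in range(cfg.n_patients):
        pid = f"SYN{i + 1:03d}"
        peaks = {
            "pct_ki67_cd4": cfg.ki67_cd4_fold,
            "pct_ki67_cd8": float(rng.uniform(lo, hi)),
            "pct_ki67_treg": cfg.treg_ki67_fold,
            "pct_plasmablast": cfg.plasmablast_fold,
        }
        baselines = {
            "pct_ki67_cd4": float(np.clip(rng.lognormal(np.log(3.0), 0.4), 0.2, 15.0)),
            "pct_ki67_cd8": float(np.clip(rng.lognormal(np.log(3.0), 0.4), 0.2, 15.0)),
            "pct_ki67_treg": float(np.clip(rng.lognormal(np.log(5.0), 0.4), 0.2, 15.0)),
            "pct_plasmablast": float(np.clip(rng.lognormal(np.log(0.5), 0.4), 0.05, 5.0)),
        }
        for subset, b in baselines.items():
            rows.append(
                {"patient_id": pid, "timepoint": "baseline", "subset": subset, "value": b}
            )
            for tp in _TIMEPOINTS[1:]:
                fold = 1.0 + (peaks[subset] - 1.0) * _DECAY[tp]
                value = b * fold * _lognormal_factor(rng, cfg.noise_cv)
                rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "subset": subset,
                        "value": float(np.clip(value, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_FILTER_RULES = (
    "tumor_depth<=10",
    "normal_depth<=10",
    "tumor_vaf<0.10",
    "tumor_normal_vaf_ratio<5",
    "callers<2",
)


def gen_variants(n: int, pass_fraction: float, seed: int = 0) -> pd.DataFrame:
    """Somatic variant table with known ground truth.

    Approximately ``pass_fraction`` of rows satisfy the full filter chain
    (depth/VAF filters plus ≥2-caller concordance); every failing row
    violates at least one criterion. Ground truth is recorded in the
    ``truth_pass`` and ``truth_violations`` columns (a sidecar the filter
    stage must never read). Protein contexts vary in length and mutation
    placement so both internal and terminus-proximal windows occur.
    """
    if n < 1:
        raise ConfigError(f"gen_variants: n must be >= 1, got {n}")
    _check_fraction("pass_fraction", pass_fraction)
    rng = np.random.default_rng(seed)
    callers = sorted({"mutect", "somaticsniper", "strelka", "varscan"})
    rows = []
    for i in range(n):
        should_pass = rng.random() < pass_fraction
        length = int(rng.integers(15, 120))
        context = "".join(rng.choice(_AA, size=length))
        position = int(rng.integers(1, length + 1))
        ref = context[position - 1]
        alt = str(rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref]))

        tumor_depth = int(rng.integers(11, 400))
        normal_depth = int(rng.integers(11, 400))
        tumor_vaf = float(rng.uniform(0.10, 0.9))
        # germline-clean or small contamination still passing the ratio
        # (the 5.2 divisor leaves margin so rounding cannot cross the cutoff)
        normal_vaf = float(rng.choice([0.0, rng.uniform(0.0, tumor_vaf / 5.2)]))
        n_callers = int(rng.integers(2, 5))

        violations: list[str] = []
        if not should_pass:
            chosen = rng.choice(len(_FILTER_RULES), size=int(rng.integers(1, 3)), replace=False)
            violations = sorted(_FILTER_RULES[j] for j in chosen)
            if "tumor_depth<=10" in violations:
                tumor_depth = int(rng.integers(1, 11))
            if "normal_depth<=10" in violations:
                normal_depth = int(rng.integers(1, 11))
            if "tumor_vaf<0.10" in violations:
                tumor_vaf = float(rng.uniform(0.01, 0.0999))
            if "tumor_normal_vaf_ratio<5" in violations:
                normal_vaf = float(rng.uniform(tumor_vaf / 4.5, min(1.0, tumor_vaf)))
            if "callers<2" in violations:
                n_callers = 1
        caller_set = rng.choice(callers, size=n_callers, replace=False)

        rows.append(
            {
                "gene": f"GENE{i + 1:04d}",
                "protein_context": context,
                "position": position,
                "ref_aa": ref,
                "alt_aa": alt,
                "tumor_depth": tumor_depth,
                "normal_depth": normal_depth,
                "tumor_vaf": round(tumor_vaf, 6),
                "normal_vaf": round(normal_vaf, 6),
                "callers": ";".join(sorted(caller_set)),
                "fpkm": round(float(rng.lognormal(np.log(30.0), 1.5)), 3),
                "truth_pass": should_pass,
                "truth_violations": ";".join(violations),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def gen_survival(
    n_per_group: int,
    hazard_ratio: float,
    censor_rate: float = 0.01,
    seed: int = 0,
    baseline_hazard: float = 0.02,
    horizon: float = 120.0,
) -> pd.DataFrame:
    """Two-group exponential survival data.

    Non-responders have hazard ``baseline_hazard`` (per month);
    responders have hazard ``baseline_hazard * hazard_ratio`` (so
    ``hazard_ratio=0`` plants an event-free responder group). Censoring
    is independent exponential at ``censor_rate`` with an administrative
    horizon (default 120 months).
    """
    if hazard_ratio < 0:
        raise ConfigError(f"hazard_ratio must be >= 0, got {hazard_ratio}")
    if censor_rate < 0:
        raise ConfigError(f"censor_rate must be >= 0, got {censor_rate}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, hazard in (
        ("responder", baseline_hazard * hazard_ratio),
        ("non-responder", baseline_hazard),
    ):
        event_times = (
            rng.exponential(1.0 / hazard, size=n_per_group)
            if hazard > 0
            else np.full(n_per_group, np.inf)
        )
        censor_times = (
            rng.exponential(1.0 / censor_rate, size=n_per_group)
            if censor_rate > 0
            else np.full(n_per_group, np.inf)
        )
        censor_times = np.minimum(censor_times, horizon)
        times = np.minimum(event_times, censor_times)
        events = event_times <= censor_times
        for j in range(n_per_group):
            rows.append(
                {
                    "patient_id": f"{group[:4].upper()}{j + 1:04d}",
                    "time": round(float(times[j]), 6),
                    "event": int(events[j]),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tissue: ROI densities and ELISpot wells
# ---------------------------------------------------------------------------

def gen_roi_cohort(
    truth: pd.DataFrame,
    seed: int = 0,
    dp_fold_tumor: float = 3.4,
    dp_fold_stroma: float = 1.12,
    noise_cv: float = 0.3,
    n_roi: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROI density table and matched flow–IHC pairs.

    ``truth`` is the responder sidecar from :func:`gen_flow_cohort`.
    Plants stroma CD3 density above tumor CD3 density, a tumor-confined
    post-treatment lift of the CD8+CD103+Ki-67+ phenotype in responders
    (fold ``dp_fold_tumor`` vs ``dp_fold_stroma`` in stroma), and returns
    flow percentages proportional to the tumor densities (with noise) so
    that tumor-based concordance is high and stroma-based concordance is
    near zero.
    """
    rng = np.random.default_rng(seed)
    roi_rows, pair_rows = [], []
    mean_density = {
        ("CD3", "tumor"): 500.0,
        ("CD3", "stroma"): 1500.0,
        ("FoxP3", "tumor"): 60.0,
        ("FoxP3", "stroma"): 200.0,
        ("CD8_CD103_Ki67", "tumor"): 40.0,
        ("CD8_CD103_Ki67", "stroma"): 50.0,
    }
    for row in truth.itertuples():
        pid, responder = row.patient_id, bool(row.responder)
        patient_scale = float(_lognormal_factor(rng, 0.4))
        densities = {}
        for (phenotype, compartment), mu in mean_density.items():
            pre = mu * patient_scale * float(_lognormal_factor(rng, noise_cv))
            if phenotype == "CD8_CD103_Ki67":
                fold = (dp_fold_tumor if compartment == "tumor" else dp_fold_stroma) if responder else 1.0
            else:
                fold = 1.0
            post = pre * fold
            densities[(phenotype, compartment)] = (pre, post)
            for timepoint, level in (("pre", pre), ("post", post)):
                for k in range(n_roi):
                    roi_rows.append(
                        {
                            "patient_id": pid,
                            "timepoint": timepoint,
                            "compartment": compartment,
                            "phenotype": phenotype,
                            "roi_index": k + 1,
                            "density": round(
                                float(level * _lognormal_factor(rng, noise_cv)), 3
                            ),
                            "roi_area": 0.36,
                        }
                    )
        # matched flow measurement tracks the tumor DP density
        tumor_post = densities[("CD8_CD103_Ki67", "tumor")][1]
        flow_pct = 0.05 * tumor_post * float(_lognormal_factor(rng, 0.3))
        stroma_post = densities[("CD8_CD103_Ki67", "stroma")][1]
        pair_rows.append(
            {
                "patient_id": pid,
                "flow_pct_dp": round(float(np.clip(flow_pct, 0.0, 100.0)), 4),
                "ihc_tumor_density": round(tumor_post, 3),
                "ihc_stroma_density": round(stroma_post, 3),
            }
        )
    return pd.DataFrame(roi_rows), pd.DataFrame(pair_rows)


def gen_elispot(
    seed: int = 0,
    n_stimuli: int = 4,
    reactive: Mapping[str, tuple[str, ...]] = None,
) -> pd.DataFrame:
    """ELISpot well table with planted reactivity.

    By default the DP subset reacts to stimulus ``peptide_1`` (and every
    subset reacts to the anti-CD3 positive control). Reactive wells draw
    200–800 SFC, non-reactive wells 0–50, mock wells 0–20.
    """
    rng = np.random.default_rng(seed)
    if reactive is None:
        reactive = {"DP": ("peptide_1",)}
    subsets = ("DN", "SP", "DP", "memory")
    stimuli = ["mock", "anti-CD3"] + [f"peptide_{i + 1}" for i in range(n_stimuli)]
    rows = []
    well = 0
    for subset in subsets:
        for stim in stimuli:
            well += 1
            if stim == "anti-CD3":
                sfc = int(rng.integers(400, 1000))
            elif stim == "mock":
                sfc = int(rng.integers(0, 20))
            elif stim in reactive.get(subset, ()):
                sfc = int(rng.integers(200, 800))
            else:
                sfc = int(rng.integers(0, 50))
            rows.append(
                {"well_id": f"W{well:03d}", "subset": subset, "stimulus": stim, "sfc": sfc}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------

def write_fixture_cohort(
    out_dir: str | Path,
    cohort: CohortConfig | None = None,
    repertoire: RepertoireConfig | None = None,
    n_variants: int = 100,
    variant_pass_fraction: float = 0.3,
    survival_n_per_group: int = 40,
    survival_hazard_ratio: float = 0.3,
) -> Path:
    """Materialize a complete toy cohort directory.

    Writes every table the analysis stages read: AIRR-style repertoire
    TSVs (one per compartment), flow panel CSV, timecourse CSV, variant
    CSV, survival CSV, ROI and ELISpot CSVs, plus ``truth_labels.csv``
    (the sidecar with planted responder labels). All derived seeds come
    from the cohort seed, so the directory is reproducible byte for byte.
    """
    cohort = cohort or CohortConfig()
    repertoire = repertoire or RepertoireConfig(seed=cohort.seed + 10)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panels, truth = gen_flow_cohort(cohort)
    panels.to_csv(out / "flow_panels.csv", index=False)
    truth.to_csv(out / "truth_labels.csv", index=False)
    gen_timecourse(cohort).to_csv(out / "flow_timecourse.csv", index=False)

    rep_dir = out / "repertoires"
    rep_dir.mkdir(exist_ok=True)
    for name, rep in gen_repertoires(repertoire).items():
        write_repertoire_tsv(rep, rep_dir / f"{name}.tsv")

    gen_variants(n_variants, variant_pass_fraction, seed=cohort.seed + 20).to_csv(
        out / "variants.csv", index=False
    )
    gen_survival(
        survival_n_per_group, survival_hazard_ratio, seed=cohort.seed + 30
    ).to_csv(out / "survival.csv", index=False)

    roi, pairs = gen_roi_cohort(truth, seed=cohort.seed + 40)
    roi.to_csv(out / "roi_densities.csv", index=False)
    pairs.to_csv(out / "flow_ihc_pairs.csv", index=False)
    gen_elispot(seed=cohort.seed + 50).to_csv(out / "elispot_wells.csv", index=False)
    return out
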