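"""Reproducible end-to-end runs and the cohort-level report.

``run_all`` ties the analysis stages together: it reads whichever input
tables the run configuration points at, executes the corresponding stages
(activation → repertoire → neoepitope → tissue → survival), and writes
per-stage CSV/JSON outputs plus one cohort summary. Outputs are
deterministic given the configuration — no timestamps or unordered
collections are ever serialized — so identical config + seed reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import activation as act
from . import neoepitope as neo
from . import repertoire as rep
from . import survival as surv
from . import tissue
from .errors import ConfigError, DataError, TilkitError

__all__ = ["RunConfig", "run_all", "make_report"]

_KNOWN_INPUTS = {
    "flow",
    "timecourse",
    "repertoires",
    "variants",
    "survival",
    "roi",
    "flow_ihc_pairs",
    "elispot",
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    output_dir: str
    inputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    activation_rule: str = "geom_gate"
    activation_threshold: float = 1.0
    fold_floor: float = 0.01
    identity: str = "cdr3_nt"
    top_n: int = 30
    reactive_cutoff: float = 0.02
    min_callers: int = 2
    fpkm_threshold: float = 100.0
    binding_cutoff: float = 0.5
    elispot_cutoff: int = 100

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _KNOWN_INPUTS
        if unknown:
            raise ConfigError(
                f"unknown input kinds {sorted(unknown)}; known: {sorted(_KNOWN_INPUTS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "output_dir" not in raw:
            raise ConfigError(f"{path}: required key 'output_dir' missing")
        return cls(**raw)

    def to_yaml(self) -> str:
        data = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return yaml.safe_dump(data, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_activation(cfg: RunConfig, out: Path, summary: dict) -> None:
    panels = act.read_panels_csv(cfg.inputs["flow"])
    by_patient: dict[str, dict[str, act.SubsetPanel]] = {}
    for p in panels:
        by_patient.setdefault(p.patient_id, {})[p.timepoint] = p
    results = []
    for pid in sorted(by_patient):
        tps = by_patient[pid]
        if "baseline" not in tps or "DOS" not in tps:
            raise DataError(f"activation: patient {pid!r} lacks baseline/DOS pair")
        results.append(
            act.activation_index(
                tps["baseline"],
                tps["DOS"],
                rule=cfg.activation_rule,  # type: ignore[arg-type]
                threshold=cfg.activation_threshold,
                floor=cfg.fold_floor,
            )
        )
    table = act.classify_cohort(results)
    table.to_csv(out / "activation_results.csv", index=False)
    summary["activation"] = {
        "n_patients": int(len(table)),
        "n_responders": int(table["responder"].sum()),
        "responder_ids": table.loc[table["responder"], "patient_id"].tolist(),
    }


def _stage_timecourse(cfg: RunConfig, out: Path, summary: dict) -> None:
    panels = pd.read_csv(cfg.inputs["timecourse"])
    tc = act.timecourse_summary(panels, floor=cfg.fold_floor)
    tc.to_csv(out / "timecourse_summary.csv", index=False)
    peaks = tc[tc["peak"]].set_index("subset")["timepoint"].to_dict()
    summary["timecourse"] = {"peak_timepoint": {k: peaks[k] for k in sorted(peaks)}}


def _stage_repertoire(cfg: RunConfig, out: Path, summary: dict) -> None:
    rep_dir = Path(cfg.inputs["repertoires"])
    reps = {}
    for path in sorted(rep_dir.glob("*.tsv")):
        r = rep.read_repertoire_tsv(path, sample_id=path.stem)
        reps[path.stem] = rep.filter_productive(r)
    if not reps:
        raise DataError(f"repertoire: no .tsv files in {rep_dir}")
    identity = cfg.identity
    clon = pd.DataFrame(
        {
            "sample": list(reps),
            "clonality": [rep.clonality(r, identity) for r in reps.values()],
            "richness": [r.richness for r in reps.values()],
            "top_n_cumfreq": [
                rep.top_n_clones(r, cfg.top_n)[1] for r in reps.values()
            ],
        }
    )
    clon.to_csv(out / "clonality.csv", index=False)

    names = list(reps)
    overlap = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        mh = rep.morisita_horn(reps[a], reps[b], identity)
        overlap.loc[a, b] = overlap.loc[b, a] = mh
    overlap.round(10).to_csv(out / "overlap_matrix.csv", index_label="sample")

    reactive = {
        name: len(rep.call_reactive_clones(r, cfg.reactive_cutoff))
        for name, r in reps.items()
    }
    summary["repertoire"] = {
        "samples": names,
        "clonality": {
            row["sample"]: round(float(row["clonality"]), 10)
            for _, row in clon.iterrows()
        },
        "reactive_clones_gt_cutoff": reactive,
    }


def _stage_neoepitope(cfg: RunConfig, out: Path, summary: dict) -> None:
    records = neo.read_variants_csv(cfg.inputs["variants"])
    kept, rejected = neo.filter_variants(records)
    kept = neo.caller_concordance(kept, k=cfg.min_callers)
    cands = [neo.enumerate_peptides(neo.build_window(v)) for v in kept]
    cands = neo.prioritize_fpkm(cands, cfg.fpkm_threshold)
    ranked = neo.rank_candidates(cands, neo.stub_scorer, cfg.binding_cutoff)
    neo.candidates_to_frame(cands).to_csv(out / "neoepitope_peptides.csv", index=False)
    neo.peptides_to_fasta(ranked, out / "neoepitope_candidates.fasta")
    summary["neoepitope"] = {
        "n_variants": len(records),
        "n_pass_filters": len(kept),
        "n_rejected": len(rejected),
        "n_peptides": int(sum(len(c.peptides) for c in cands)),
        "n_prioritized": int(sum(c.prioritized for c in cands)),
        "n_binding_candidates": len(ranked),
    }


def _stage_tissue(cfg: RunConfig, out: Path, summary: dict) -> None:
    tissue_summary: dict[str, Any] = {}
    if "roi" in cfg.inputs:
        roi = pd.read_csv(cfg.inputs["roi"])
        agg = tissue.roi_aggregate(roi)
        agg.to_csv(out / "roi_aggregate.csv", index=False)
        mean_by = agg.groupby(["compartment", "phenotype"])["mean_density"].mean()
        tissue_summary["mean_density"] = {
            f"{c}/{p}": round(float(v), 6) for (c, p), v in mean_by.items()
        }
    if "flow_ihc_pairs" in cfg.inputs:
        pairs = pd.read_csv(cfg.inputs["flow_ihc_pairs"])
        for compartment in ("tumor", "stroma"):
            col = f"ihc_{compartment}_density"
            if col in pairs.columns:
                _, _, r2 = tissue.flow_ihc_concordance(
                    pairs["flow_pct_dp"], pairs[col]
                )
                tissue_summary[f"r2_{compartment}"] = round(r2, 6)
    if "elispot" in cfg.inputs:
        wells = pd.read_csv(cfg.inputs["elispot"])
        calls = tissue.elispot_call_table(wells, cutoff=cfg.elispot_cutoff)
        calls.to_csv(out / "elispot_calls.csv", index=False)
        positive = calls[calls["positive"] & (calls["stimulus"] != "anti-CD3")]
        tissue_summary["positive_wells"] = [
            f"{r.subset}:{r.stimulus}" for r in positive.itertuples()
        ]
    summary["tissue"] = tissue_summary


def _stage_survival(cfg: RunConfig, out: Path, summary: dict) -> None:
    records = surv.read_survival_csv(cfg.inputs["survival"])
    km_all = surv.km_estimate(records)
    km_all.to_frame().to_csv(out / "km_overall.csv", index=False)
    stage: dict[str, Any] = {"n": km_all.n}
    try:
        median_fu, (lo, hi) = surv.reverse_km_followup(records)
        stage["median_followup_months"] = round(median_fu, 6)
        stage["median_followup_ci"] = [round(lo, 6), round(hi, 6)]
    except TilkitError:
        stage["median_followup_months"] = None
    groups = sorted({r.group for r in records if r.group is not None})
    if len(groups) == 2:
        a = [r for r in records if r.group == groups[0]]
        b = [r for r in records if r.group == groups[1]]
        chi2, p = surv.logrank_test(a, b)
        stage["logrank"] = {
            "groups": groups,
            "chi2": round(chi2, 6),
            "p": float(f"{p:.6g}"),
        }
        for label, recs in zip(groups, (a, b)):
            surv.km_estimate(recs).to_frame().to_csv(
                out / f"km_{label.replace(' ', '_')}.csv", index=False
            )
    summary["survival"] = stage


_STAGES = (
    ("activation", "flow", _stage_activation),
    ("timecourse", "timecourse", _stage_timecourse),
    ("repertoire", "repertoires", _stage_repertoire),
    ("neoepitope", "variants", _stage_neoepitope),
    ("tissue", ("roi", "flow_ihc_pairs", "elispot"), _stage_tissue),
    ("survival", "survival", _stage_survival),
)


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage that has inputs configured.

    Writes per-stage outputs, ``summary.json``, ``report.txt``, the
    resolved configuration, and a checksum manifest of every input file
    into ``cfg.output_dir``. Returns the output directory. A stage
    failure aborts the run with the stage name attached; the partial
    output directory is marked with an ``INCOMPLETE`` sentinel file.
    """
    if not cfg.inputs:
        raise ConfigError(
            "empty run configuration: provide at least one input "
            f"(known kinds: {sorted(_KNOWN_INPUTS)})"
        )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind, path in sorted(cfg.inputs.items()):
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"input {kind!r}: {path} does not exist")

    sentinel = out / "INCOMPLETE"
    sentinel.write_text("run in progress\n")
    (out / "config_resolved.yaml").write_text(cfg.to_yaml())
    manifest = {}
    for kind, path in sorted(cfg.inputs.items()):
        p = Path(path)
        files = sorted(p.glob("*")) if p.is_dir() else [p]
        manifest[kind] = {f.name: _sha256(f) for f in files if f.is_file()}
    _write_json(out / "input_checksums.json", {"seed": cfg.seed, "inputs": manifest})

    summary: dict[str, Any] = {"seed": cfg.seed}
    for stage_name, needs, fn in _STAGES:
        needed = (needs,) if isinstance(needs, str) else needs
        if not any(k in cfg.inputs for k in needed):
            continue
        try:
            fn(cfg, out, summary)
        except TilkitError as exc:
            raise type(exc)(f"stage {stage_name!r}: {exc}") from exc
    _write_json(out / "summary.json", summary)
    (out / "report.txt").write_text(make_report(summary))
    sentinel.unlink()
    return out


def _fmt(value: Any) -> str:
    if isinstance(value, float):
        return f"{value:.4g}"
    return str(value)


def make_report(summary: dict[str, Any]) -> str:
    """Render the cohort summary as a plain-text report.

    Section order and column order are fixed; every number is traceable
    to the stage output files the summary was built from.
    """
    lines = ["tilkit cohort report", "=" * 20, ""]
    for section in ("activation", "timecourse", "repertoire", "neoepitope", "tissue", "survival"):
        if section not in summary:
            continue
        lines.append(f"[{section}]")
        payload = summary[section]
        for key in sorted(payload):
            value = payload[key]
            if isinstance(value, dict):
                lines.append(f"  {key}:")
                for k in sorted(value):
                    lines.append(f"    {k}: {_fmt(value[k])}")
            else:
                lines.append(f"  {key}: {_fmt(value)}")
        lines.append("")
    return "\n".join(lines)
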