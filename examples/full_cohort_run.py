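"""End-to-end: materialize a toy cohort directory and run every stage.

Equivalent to the CLI sequence:
    tilkit fixtures --out cohort_dir --n-patients 16 --seed 1
    tilkit run-all --fixtures-dir cohort_dir --out cohort_dir/out
"""

import tempfile
from pathlib import Path

from tilkit.reporting import RunConfig, run_all
from tilkit.synthetic import CohortConfig, write_fixture_cohort

with tempfile.TemporaryDirectory() as tmp:
    fx = write_fixture_cohort(Path(tmp) / "cohort", cohort=CohortConfig(n_patients=16, seed=1))
    cfg = RunConfig(
        output_dir=str(fx / "out"),
        seed=1,
        inputs={
            "flow": str(fx / "flow_panels.csv"),
            "timecourse": str(fx / "flow_timecourse.csv"),
            "repertoires": str(fx / "repertoires"),
            "variants": str(fx / "variants.csv"),
            "survival": str(fx / "survival.csv"),
            "roi": str(fx / "roi_densities.csv"),
            "flow_ihc_pairs": str(fx / "flow_ihc_pairs.csv"),
            "elispot": str(fx / "elispot_wells.csv"),
        },
    )
    out = run_all(cfg)
    print((out / "report.txt").read_text())
    print("stage outputs:", sorted(p.name for p in out.iterdir()))
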