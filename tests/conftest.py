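import math

import numpy as np
import pytest

from tilkit.repertoire import CloneRecord, Repertoire
from tilkit.synthetic import CohortConfig, write_fixture_cohort


def make_repertoire(counts: dict[str, int], productive: bool = True, **meta) -> Repertoire:
    """Build a repertoire from a {cdr3_nt: count} mapping."""
    clones = tuple(
        CloneRecord(cdr3_nt=nt, cdr3_aa=nt[:4], count=c, productive=productive)
        for nt, c in counts.items()
    )
    return Repertoire(clones=clones, **meta)


def random_repertoire(rng: np.random.Generator, max_clones: int = 40) -> Repertoire:
    """A random repertoire over a small shared alphabet of clone ids."""
    n = int(rng.integers(2, max_clones))
    ids = rng.choice(200, size=n, replace=False)
    counts = {f"CLONE{i:03d}": int(rng.integers(1, 500)) for i in sorted(ids)}
    return make_repertoire(counts)


# --- independent single-pass metric oracles (kept deliberately naive) -------

def naive_clonality(counts: list[int]) -> float:
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    entropy = 0.0
    for c in counts:
        p = c / total
        entropy -= p * math.log(p)
    richness = len(counts)
    if richness == 1:
        return 1.0
    return 1.0 - entropy / math.log(richness)


def naive_morisita_horn(x: dict[str, int], y: dict[str, int]) -> float:
    X = sum(x.values())
    Y = sum(y.values())
    cross = 0.0
    for key in set(x) | set(y):
        cross += x.get(key, 0) * y.get(key, 0)
    dx = sum(v * v for v in x.values()) / X**2
    dy = sum(v * v for v in y.values()) / Y**2
    return 2.0 * cross / ((dx + dy) * X * Y)


@pytest.fixture(scope="session")
def fixture_cohort(tmp_path_factory):
    """A complete synthetic toy cohort directory (seed 1, 16 patients)."""
    out = tmp_path_factory.mktemp("cohort")
    return write_fixture_cohort(out / "fx", cohort=CohortConfig(n_patients=16, seed=1))
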