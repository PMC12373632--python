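"""Shared fixtures: toy world, tagged BAM, default characteristics, and a
small end-to-end simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ss3reads as s3


@pytest.fixture(scope="session")
def fixture_spec():
    return s3.FixtureSpec()


@pytest.fixture(scope="session")
def toy_world(fixture_spec):
    """(genome, annotation, ledger) for the standard toy reference."""
    return s3.make_toy_reference(fixture_spec, seed=11)


@pytest.fixture(scope="session")
def toy_bam(toy_world, fixture_spec, tmp_path_factory):
    """(path, ledger) for the tagged toy BAM."""
    genome, ann, _ = toy_world
    path = tmp_path_factory.mktemp("bam") / "toy.bam"
    ledger = s3.make_toy_bam(genome, ann, fixture_spec, path, seed=13)
    return path, ledger


@pytest.fixture(scope="session")
def default_chars(fixture_spec):
    return s3.make_default_characteristics(fixture_spec)


@pytest.fixture(scope="session")
def small_truth(toy_world, default_chars):
    genome, ann, _ = toy_world
    design = s3.PopulationDesign(p=2, c=4, n_diff_splicing=1,
                                 n_diff_unspliced=1)
    return s3.build_ground_truth(ann, genome, default_chars, design,
                                 k=4, n=2, n_novel_junctions=1,
                                 n_novel_exons=1, seed=17)


@pytest.fixture(scope="session")
def small_sim(small_truth, default_chars, tmp_path_factory):
    """Simulated output + truth table for the small ground truth."""
    out = tmp_path_factory.mktemp("sim") / "sim"
    config = s3.SimulationConfig(read_len=150, seed=19, paf=3.0)
    info = s3.simulate(small_truth, default_chars, config, out)
    info["truth"] = pd.read_csv(info["truth_table"], sep="\t",
                                keep_default_na=False)
    info["config"] = config
    return info


# ---------------------------------------------------------------------------
# Statistics helpers (independent of the implementation under test)
# ---------------------------------------------------------------------------

def ks_statistic(a, b) -> float:
    from scipy import stats

    return float(stats.ks_2samp(a, b).statistic)


def calibrated_ks_threshold(dist, n1: int, n2: int, seed: int,
                            n_resample: int = 500, q: float = 0.998) -> float:
    """Null KS quantile from resampling the distribution against itself at
    the observed sample sizes."""
    rng = np.random.default_rng(seed)
    stats_ = [
        ks_statistic(dist.sample(rng, size=n1), dist.sample(rng, size=n2))
        for _ in range(n_resample)
    ]
    return float(np.quantile(stats_, q))
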