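"""Shared fixtures: simulated study conditions at two scales.

The full-scale fixture (16 kb circle, 2x100 bp reads at 40x, substitution
rate 0.005, scaffold with 300 bp duplicated end and 200 bp random flanks)
is session-scoped because several end-to-end tests share it; the small
fixture keeps unit tests fast.
"""

import numpy as np
import pytest

import circinfer as ci


@pytest.fixture(scope="session")
def sim16k():
    genome = ci.simulate_circular_genome(16_000, 0.40, seed=1)
    scaffold, truth = ci.build_artifact_scaffold(
        genome, rotation=0, dup_len=300, flank5=200, flank3=200, seed=2)
    reads = ci.simulate_reads(genome, coverage=40, read_length=100,
                              insert_mean=300, insert_sd=30,
                              sub_rate=0.005, seed=3)
    return {"genome": genome, "scaffold": scaffold, "truth": truth,
            "reads": reads}


@pytest.fixture(scope="session")
def circle16k(sim16k):
    return ci.extract_circle(sim16k["scaffold"], k=31, min_span=10_000)


@pytest.fixture(scope="session")
def report16k(sim16k, circle16k):
    alignments = ci.align_all(sim16k["reads"], circle16k.flipped)
    profile = ci.position_profile(alignments, len(circle16k.flipped))
    report = ci.summarize(alignments, profile, circle16k.junction_index)
    return {"alignments": alignments, "profile": profile, "report": report}


@pytest.fixture(scope="session")
def sim2k():
    """Small study: 2 kb circle, error-free 2x50 bp reads at 20x."""
    genome = ci.simulate_circular_genome(2_000, 0.45, seed=10)
    reads = ci.simulate_reads(genome, coverage=20, read_length=50,
                              insert_mean=150, insert_sd=15,
                              sub_rate=0.0, seed=11)
    return {"genome": genome, "reads": reads}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
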