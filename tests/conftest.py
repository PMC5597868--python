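"""Shared fixtures: parameter sets, a seeded LTR-like bait set, and one small
simulated insertion experiment reused across screening/mapping/calling tests.
"""

from __future__ import annotations

import pytest

import tescreen as t
from tescreen.caller import evaluate_against_truth
from tescreen.pipeline import run_pipeline
from tescreen.screen import ScreenParams
from tescreen.simulate import random_element


@pytest.fixture(scope="session")
def hk2_params() -> ScreenParams:
    """The mutated-element parameterisation: 20-bp match at 90 % identity,
    20-bp minimum trimmed length."""
    return ScreenParams(min_match_len=20, min_identity=0.90, min_trimmed_len=20)


@pytest.fixture(scope="session")
def ltr_element() -> str:
    return random_element(968, 12345)


@pytest.fixture(scope="session")
def ltr_baits(ltr_element):
    return t.make_baits(ltr_element, 20, "ltr")


@pytest.fixture(scope="session")
def mini_fixture(tmp_path_factory):
    """A small insertion experiment: 4 x 3-kb elements in a 150-kb host,
    2x100 bp pairs at 30x."""
    d = tmp_path_factory.mktemp("minisim")
    return t.make_fixture(
        "hiv_like_20",
        d,
        seed=101,
        host_length=150_000,
        element_length=3_000,
        n_insertions=4,
        coverage=30,
    )


@pytest.fixture(scope="session")
def mini_pipeline(mini_fixture, hk2_params, tmp_path_factory):
    """Guided and single-end pipeline runs over the mini experiment."""
    d = tmp_path_factory.mktemp("minirun")
    out = {}
    for mode, guided in (("guided", True), ("single", False)):
        res = run_pipeline(
            mini_fixture.reads_fastq,
            mini_fixture.element_fasta,
            mini_fixture.host_fasta,
            d / mode,
            bait_length=20,
            screen_params=hk2_params,
            guided=guided,
        )
        out[mode] = res
        out[f"{mode}_eval"] = evaluate_against_truth(
            res.detection.novel, mini_fixture.truths, tolerance=100
        )
    return out
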