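"""Shared fixtures: synthetic captures analyzed once per session.

The imaging pipeline costs ~2 s per 640x640 capture, so every test that can
share an analysis does; the 20-seed lesion suite below backs both the
property tests and the acceptance suite.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from retscreen import synth
from retscreen.pipeline import analyze_image
from retscreen.types import BRIGHT_TYPES, DARK_TYPES

#: Seeds fixed up front; one capture per seed with the same lesion mix.
SUITE_SEEDS = tuple(range(20))
LESION_MIX = ("MA", "MA", "HEM", "EX", "CWS")


@dataclasses.dataclass
class SuiteCase:
    seed: int
    config: synth.SynthImageConfig
    image: object
    truth: synth.GroundTruth
    analysis: object


def build_case(seed: int, lesion_mix=LESION_MIX) -> SuiteCase:
    """One synthetic capture with off-vessel lesions, fully analyzed."""
    base = synth.SynthImageConfig(seed=seed)
    rng = np.random.default_rng(10_000 + seed)
    placements = synth.random_lesion_placements(base, list(lesion_mix), rng)
    cfg = dataclasses.replace(base, lesions=tuple(placements))
    image, truth = synth.generate_eye_image(cfg)
    return SuiteCase(seed=seed, config=cfg, image=image, truth=truth, analysis=analyze_image(image))


@pytest.fixture(scope="session")
def analyzed_suite() -> list[SuiteCase]:
    return [build_case(seed) for seed in SUITE_SEEDS]


@pytest.fixture(scope="session")
def clean_case() -> SuiteCase:
    """A lesion-free capture (seed 0), analyzed."""
    cfg = synth.SynthImageConfig(seed=0)
    image, truth = synth.generate_eye_image(cfg)
    return SuiteCase(seed=0, config=cfg, image=image, truth=truth, analysis=analyze_image(image))


@pytest.fixture(scope="session")
def lesion_free_suite() -> list[SuiteCase]:
    """Ten lesion-free captures for false-positive budgeting."""
    out = []
    for seed in range(10):
        cfg = synth.SynthImageConfig(seed=seed)
        image, truth = synth.generate_eye_image(cfg)
        out.append(SuiteCase(seed=seed, config=cfg, image=image, truth=truth,
                             analysis=analyze_image(image)))
    return out


def match_lesions(truth_lesions, candidates):
    """Greedily pair each placed lesion with the nearest unused candidate.

    A candidate matches when its centroid lies within max(2*radius, 10) px of
    the placement. Returns [(ltype, candidate-or-None), ...] in truth order.
    """
    used: set[int] = set()
    out = []
    for ltype, (px, py), lr in truth_lesions:
        best = None
        best_d = math.inf
        for i, cand in enumerate(candidates):
            if i in used:
                continue
            d = math.hypot(cand.centroid[0] - px, cand.centroid[1] - py)
            if d <= max(2.0 * lr, 10.0) and d < best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            out.append((ltype, candidates[best]))
        else:
            out.append((ltype, None))
    return out


def same_class(truth_type: str, detected_type: str) -> bool:
    """True when both types are dark (MA/HEM) or both bright (EX/CWS)."""
    return (truth_type in DARK_TYPES) == (detected_type in DARK_TYPES) and (
        truth_type in BRIGHT_TYPES
    ) == (detected_type in BRIGHT_TYPES)
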