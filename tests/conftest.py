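"""Shared fixtures: synthetic genomes with ground truth, small helpers."""

from __future__ import annotations

import pytest

from mitofeatures import synthetic


@pytest.fixture(scope="session")
def default_truth() -> synthetic.GroundTruth:
    """One full-featured synthetic genome reused across read-only tests."""
    return synthetic.generate(synthetic.SyntheticGenomeSpec(seed=1))


@pytest.fixture(scope="session")
def plain_truth() -> synthetic.GroundTruth:
    """A bare genome: no duplication, no repeats, no skew."""
    spec = synthetic.SyntheticGenomeSpec(
        seed=3, duplication=None, repeats=None, skew=None
    )
    return synthetic.generate(spec)


def circular_distance(a: int, b: int, L: int) -> int:
    d = abs(a - b)
    return min(d, L - d)


def reciprocal_overlap(iv, jv) -> float:
    """Overlap fraction relative to the longer of the two intervals."""
    inter = max(0, min(iv.end, jv.end) - max(iv.start, jv.start) + 1)
    return inter / max(iv.end - iv.start + 1, jv.end - jv.start + 1)


def pair_matches(found, truth, min_overlap: float = 0.8) -> bool:
    if found.orientation != truth.orientation:
        return False
    o1 = min(
        reciprocal_overlap(found.interval_a, truth.interval_a),
        reciprocal_overlap(found.interval_b, truth.interval_b),
    )
    o2 = min(
        reciprocal_overlap(found.interval_a, truth.interval_b),
        reciprocal_overlap(found.interval_b, truth.interval_a),
    )
    return max(o1, o2) >= min_overlap
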