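"""Deterministic, hand-checkable fixtures for tests and demos.

Each fixture is tiny enough to verify by hand; the manifest records the
values the construction guarantees (brute-force LD, diversity, spectrum
shape), so tests can assert implementation output against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FixtureSet:
    planted_ld_matrix: np.ndarray       # (4 genomes x 2 sites) coupling LD
    planted_ld_manifest: dict
    random_matrix: np.ndarray           # (20 x 50) for brute-force oracles
    singleton_sfs: np.ndarray           # all-singleton spectrum, k=20
    constant_trajectory_pieces: tuple   # 3-piece flat history
    manifest: dict


def make_fixtures(seed: int = 0) -> FixtureSet:
    rng = np.random.default_rng(seed)
    # haplotypes {11, 11, 00, 00}: p_A = p_B = 0.5, p_AB = 0.5 -> D = 0.25
    planted = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8)
    planted_manifest = {"D": 0.25, "sum_D": 0.25, "C": -4 * 0.25 / 2}
    random_matrix = (rng.random((50, 20)) < 0.3).astype(np.uint8)  # sites x k
    singleton = np.zeros(19)
    singleton[0] = 1.0
    pieces = ((100.0, 1000.0), (250.0, 1000.0), (np.inf, 1000.0))
    return FixtureSet(
        planted_ld_matrix=planted,
        planted_ld_manifest=planted_manifest,
        random_matrix=random_matrix,
        singleton_sfs=singleton,
        constant_trajectory_pieces=pieces,
        manifest={
            "singleton_delta_thetaw_prime": 1.0,
            "constant_trajectory_sfs": "proportional to 1/i",
            "seed": seed,
        },
    )
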