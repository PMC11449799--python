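"""Random branched morphologies as valid SWC node tables.

Each stem leaves the soma as a straight segment (depth 0); at the end of
every segment of depth < ``max_depth`` the process either bifurcates (with
probability ``branch_prob``) or continues with a single child, so
``branch_prob = 1`` yields ``n_stems * 2**max_depth`` terminal tips and
``branch_prob = 0`` an unbranched chain of ``max_depth + 1`` segments per
stem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import InvalidParameterError
from ..morpho import Morphology

__all__ = ["MorphGenParams", "generate_morphology"]

NEURITE_TYPE = 3


@dataclass(frozen=True)
class MorphGenParams:
    n_stems: int = 3
    branch_prob: float = 0.4
    segment_len_mean: float = 20.0  # um
    segment_len_cv: float = 0.25    # sd / mean; 0 = deterministic lengths
    max_depth: int = 4
    soma_radius: float = 5.0        # um
    wiggle: float = 0.4             # directional jitter per segment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise InvalidParameterError("max_depth must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise InvalidParameterError("branch_prob must be in [0, 1]")
        if self.segment_len_mean <= 0:
            raise InvalidParameterError("segment_len_mean must be > 0")
        if self.n_stems < 1:
            raise InvalidParameterError("n_stems must be >= 1")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_morphology(params: MorphGenParams) -> Morphology:
    rng = np.random.default_rng(params.seed)
    ids = [1]
    types = [1]
    xyz = [np.zeros(3)]
    radii = [params.soma_radius]
    parents = [-1]
    next_id = 2

    def seg_length() -> float:
        if params.segment_len_cv <= 0:
            return params.segment_len_mean
        sd = params.segment_len_cv * params.segment_len_mean
        return float(max(0.1 * params.segment_len_mean,
                         rng.normal(params.segment_len_mean, sd)))

    def grow(parent_id: int, pos: np.ndarray, direction: np.ndarray,
             depth: int) -> None:
        nonlocal next_id
        end = pos + seg_length() * direction
        node_id = next_id
        next_id += 1
        ids.append(node_id)
        types.append(NEURITE_TYPE)
        xyz.append(end)
        radii.append(0.5)
        parents.append(parent_id)
        if depth >= params.max_depth:
            return
        if rng.uniform() < params.branch_prob:
            n_children = 2
        else:
            n_children = 1
        for _ in range(n_children):
            d = _unit(direction + params.wiggle * rng.standard_normal(3))
            grow(node_id, end, d, depth + 1)

    for _ in range(params.n_stems):
        d = _unit(rng.standard_normal(3))
        grow(1, xyz[0] + params.soma_radius * d, d, 0)

    return Morphology(np.array(ids), np.array(types), np.array(xyz),
                      np.array(radii), np.array(parents))
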