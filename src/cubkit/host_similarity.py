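"""Similarity index (SiD) between parasite and host codon-usage vectors.

R(A, B) is the cosine of the angle between the two 59-dimensional RSCU
vectors a and b:

    R = sum(a_i * b_i) / sqrt(sum(a_i^2) * sum(b_i^2)),

and the dissimilarity D(A, B) = (1 − R) / 2. With non-negative RSCU input
R ∈ [0, 1], so D ∈ [0, 0.5]: 0 for identical usage patterns, 0.5 for
orthogonal ones. A larger D means the host's overall codon usage exerts
less (or a more divergent) influence on the parasite's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CubkitError
from .rscu import RSCUProfile


@dataclass(frozen=True)
class SiDResult:
    r_ab: float
    d_ab: float
    n_codons_used: int


def _as_mapping(profile) -> dict[str, float]:
    if isinstance(profile, RSCUProfile):
        return profile.values
    return dict(profile)


def similarity_index(a, b) -> SiDResult:
    """Cosine similarity R and dissimilarity D between two RSCU vectors.

    ``a`` and ``b`` are :class:`RSCUProfile` objects or codon→RSCU
    mappings over the same codon universe. Codons undefined (NaN/absent)
    in either vector are dropped pairwise; ``n_codons_used`` reports how
    many coordinates entered the comparison so silent shrinkage is
    visible.
    """
    ma, mb = _as_mapping(a), _as_mapping(b)
    shared = [
        c
        for c in ma
        if c in mb
        and not math.isnan(ma[c])
        and not math.isnan(mb[c])
    ]
    if not shared:
        raise CubkitError("no shared defined codons between the profiles")
    va = np.array([ma[c] for c in shared])
    vb = np.array([mb[c] for c in shared])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise CubkitError("zero-norm RSCU vector: similarity undefined")
    r = float(va @ vb / (na * nb))
    r = max(min(r, 1.0), -1.0)
    return SiDResult(r_ab=r, d_ab=(1.0 - r) / 2.0, n_codons_used=len(shared))
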