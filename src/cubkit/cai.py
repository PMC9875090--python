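"""Codon adaptation index (CAI) and its Monte-Carlo null (expected CAI).

CAI scores how closely a gene's codon choices track those of a reference
(host) organism: each sense codon gets a relative adaptiveness weight
w = RSCU / max family RSCU computed from the reference, and the gene's CAI
is the geometric mean of the weights of its codons (Met, Trp, stop and
ambiguous codons excluded). CAI ranges over (0, 1]; 1 means every codon is
the reference's favourite.

The expected CAI (e-CAI) asks what CAI a random gene of the same length
and mononucleotide composition would reach by chance: random sequences are
generated, scored, and the null's mean + z(coverage)·SD is reported as the
e-CAI threshold, with a Kolmogorov–Smirnov check that the null is
approximately normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CubkitError, ReferenceTableError
from .genetics import GeneticCode, STANDARD_CODE, to_dna
from .io import CodingSequence, counted_codons
from .rscu import RSCUProfile

#: Sharp–Li floor: a reference codon never observed still gets a small
#: positive weight so one absent codon cannot zero a gene's CAI.
WEIGHT_FLOOR = 0.01


@dataclass
class WeightTable:
    """Relative adaptiveness weights over the synonymous codon universe."""

    w: dict[str, float]
    reference_id: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.w[to_dna(codon)]


@dataclass
class ECAIResult:
    mean_cai: float
    sd_cai: float
    e_cai: float
    ks_stat: float
    ks_p: float
    n_random: int
    seed: int
    cais: np.ndarray | None = None


def _reference_to_rscu(
    ref: pd.DataFrame | dict[str, float],
    code: GeneticCode,
) -> dict[str, float]:
    """Normalise a reference table (codon→count or codon→rscu) to RSCU."""
    if isinstance(ref, pd.DataFrame):
        cols = {c.lower(): c for c in ref.columns}
        codon_col = cols.get("codon")
        if codon_col is None:
            raise ReferenceTableError("reference table lacks a codon column")
        value_col = cols.get("rscu") or cols.get("count")
        if value_col is None:
            raise ReferenceTableError(
                "reference table needs an 'rscu' or 'count' column"
            )
        mapping = {
            to_dna(c): float(v)
            for c, v in zip(ref[codon_col], ref[value_col])
        }
        is_rscu = cols.get("rscu") is not None
    else:
        mapping = {to_dna(c): float(v) for c, v in ref.items()}
        # Heuristic: counts are large, RSCU values live near [0, 6].
        is_rscu = max(mapping.values(), default=0.0) <= 6.5

    if is_rscu:
        return mapping
    out: dict[str, float] = {}
    for aa, cods in code.synonymous_families.items():
        total = sum(mapping.get(c, 0.0) for c in cods)
        if total > 0:
            for c in cods:
                out[c] = mapping.get(c, 0.0) * len(cods) / total
    return out


def weights_from_reference(
    ref: pd.DataFrame | dict[str, float] | RSCUProfile,
    code: GeneticCode = STANDARD_CODE,
    floor: float = WEIGHT_FLOOR,
    reference_id: str = "",
) -> WeightTable:
    """Build w = RSCU / max family RSCU from a host usage table.

    Accepts a codon→count or codon→RSCU table (DataFrame with ``codon``
    plus ``count`` or ``rscu`` columns, a plain mapping, or an
    :class:`RSCUProfile`). Zero or missing entries are floored at
    ``floor`` with a warning recorded in the table's reference_id.
    """
    if isinstance(ref, RSCUProfile):
        ref_rscu = {c: v for c, v in ref.values.items() if not np.isnan(v)}
    else:
        ref_rscu = _reference_to_rscu(ref, code)
    w: dict[str, float] = {}
    for aa, cods in code.synonymous_families.items():
        vals = [ref_rscu.get(c) for c in cods]
        defined = [v for v in vals if v is not None]
        if not defined or max(defined) <= 0:
            raise ReferenceTableError(
                f"reference covers no codon of amino acid {aa}"
            )
        fam_max = max(defined)
        for c in cods:
            v = ref_rscu.get(c, 0.0)
            w[c] = max(v / fam_max, floor)
    return WeightTable(w=w, reference_id=reference_id)


def cai(
    seq: CodingSequence,
    weights: WeightTable,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Geometric-mean CAI of one sequence against a reference."""
    scoreable = [
        c for c in counted_codons(seq, code) if c in weights.w
    ]
    if not scoreable:
        raise CubkitError(
            f"sequence {seq.id!r} has no scoreable (synonymous-set) codons"
        )
    logs = np.log([weights.w[c] for c in scoreable])
    return float(np.exp(logs.mean()))


def _random_sequences(
    seqs: list[CodingSequence],
    n_random: int,
    rng: np.random.Generator,
) -> list[CodingSequence]:
    """Random CDSs matching the query set's length distribution and pooled
    mononucleotide composition."""
    pooled = "".join(s.nucleotides for s in seqs)
    bases = np.array(list("ACGT"))
    freqs = np.array([pooled.count(b) for b in "ACGT"], dtype=float)
    if (freqs > 0).sum() < 2:
        raise CubkitError(
            "degenerate composition: need ≥ 2 distinct bases for the null"
        )
    freqs /= freqs.sum()
    lengths = [s.length for s in seqs]
    out = []
    for i in range(n_random):
        L = lengths[int(rng.integers(len(lengths)))]
        nt = "".join(rng.choice(bases, size=L, p=freqs))
        out.append(CodingSequence(id=f"random_{i}", nucleotides=nt))
    return out


def expected_cai(
    seqs: list[CodingSequence],
    weights: WeightTable,
    n_random: int = 500,
    coverage: float = 0.95,
    seed: int = 42,
    code: GeneticCode = STANDARD_CODE,
) -> ECAIResult:
    """Monte-Carlo e-CAI of a query set under a composition-matched null.

    Generates ``n_random`` random sequences matching the query lengths and
    pooled base composition, scores each with :func:`cai`, and reports the
    null mean, SD, the one-sided normal quantile
    e_cai = mean + z(coverage)·SD, and a KS normality statistic. Fully
    reproducible under a fixed seed.
    """
    if n_random < 100:
        raise CubkitError("n_random must be ≥ 100 for a reported e-CAI")
    rng = np.random.default_rng(seed)
    randoms = _random_sequences(seqs, n_random, rng)
    cais = np.array([cai(r, weights, code) for r in randoms])
    mean, sd = float(cais.mean()), float(cais.std(ddof=1))
    z = float(stats.norm.ppf(coverage))
    if sd > 0:
        ks_stat, ks_p = stats.kstest(cais, "norm", args=(mean, sd))
    else:
        ks_stat, ks_p = 0.0, 1.0
    return ECAIResult(
        mean_cai=mean,
        sd_cai=sd,
        e_cai=min(mean + z * sd, 1.0),
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        n_random=n_random,
        seed=seed,
        cais=cais,
    )


class CAIScorer(TransformerMixin, BaseEstimator):
    """Estimator: fit on a host reference usage table, score sequences.

    Parameters
    ----------
    reference : DataFrame | mapping | RSCUProfile
        Host codon usage (counts or RSCU); may also be passed to ``fit``.
    floor : float
        Minimum relative adaptiveness for absent reference codons.

    Attributes
    ----------
    weights_ : WeightTable
        Relative adaptiveness table fitted from the reference.
    """

    def __init__(
        self,
        reference=None,
        genetic_code: GeneticCode = STANDARD_CODE,
        floor: float = WEIGHT_FLOOR,
        reference_id: str = "",
    ):
        self.reference = reference
        self.genetic_code = genetic_code
        self.floor = floor
        self.reference_id = reference_id

    def fit(self, X=None, y=None):
        ref = X if X is not None and self.reference is None else self.reference
        if ref is None:
            raise ReferenceTableError("no reference usage table supplied")
        self.weights_ = weights_from_reference(
            ref, self.genetic_code, self.floor, self.reference_id
        )
        return self

    def transform(self, X: list[CodingSequence]) -> np.ndarray:
        if not hasattr(self, "weights_"):
            self.fit()
        return np.asarray(
            [cai(s, self.weights_, self.genetic_code) for s in X]
        )

    score_sequences = transform
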