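"""Wright's effective number of codons (ENC) and the ENC–GC3s expected
curve.

ENC summarises how far a gene departs from uniform synonymous codon usage:
20 when exactly one codon is used per amino acid, 61 when all synonymous
codons are used evenly. Per amino acid with total count n ≥ 2 the
homozygosity is estimated as

    F = (n * sum(p_i^2) - 1) / (n - 1),   p_i = X_i / n,

class means F̄_k are taken over the amino acids of each degeneracy class
k ∈ {2, 3, 4, 6}, and

    ENC = 2 + 9/F̄_2 + 1/F̄_3 + 5/F̄_4 + 3/F̄_6,

capped at 61. Families with n < 2 or F ≤ 0 carry no usable signal and are
excluded from their class mean. If the single 3-fold family (Ile) is
undefined, its reciprocal contribution is estimated as the mean of 1/F̄_2
and 1/F̄_4.

The composition-only expectation at third-position G+C content s is

    ENC_expected(s) = 2 + s + 29 / (s^2 + (1 - s)^2);

genes lying well below this curve use fewer codons than their base
composition alone would produce, the classic signature of selection on
codon usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CubkitError, ENCUndefinedError
from .genetics import GeneticCode, STANDARD_CODE
from .io import CodingSequence, CodonCountTable, count_codons
from .composition import composition_profile

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class ENCResult:
    enc: float
    f_bar: dict[int, float]
    per_aa_F: dict[str, tuple[float, int]] = field(repr=False)
    notes: tuple[str, ...] = ()


def _family_F(counts: CodonCountTable, codons) -> tuple[float | None, int]:
    xs = np.array([counts[c] for c in codons], dtype=float)
    n = int(xs.sum())
    if n < 2:
        return None, n
    p = xs / n
    F = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
    return F, n


def enc(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> ENCResult:
    """Wright's ENC from a codon count table (one gene or a pooled set)."""
    per_aa_F: dict[str, tuple[float, int]] = {}
    class_F: dict[int, list[float]] = {}
    notes: list[str] = []
    for aa, cods in code.synonymous_families.items():
        F, n = _family_F(counts, cods)
        if F is None:
            continue
        if F <= 0:
            notes.append(f"F=0 for {aa} excluded")
            continue
        per_aa_F[aa] = (F, n)
        class_F.setdefault(len(cods), []).append(F)

    f_bar = {k: float(np.mean(v)) for k, v in class_F.items()}
    weights = {
        k: len(aas) for k, aas in code.degeneracy_classes.items()
    }  # 9, 1, 5, 3 for the standard code

    for k in weights:
        if k == 3:
            continue
        if k not in f_bar:
            raise ENCUndefinedError(
                f"degeneracy class {k} has no amino acid with usable counts"
            )

    total = 2.0
    for k, n_aa in weights.items():
        if k == 3 and 3 not in f_bar:
            # single 3-fold family absent: interpolate its reciprocal
            total += n_aa * 0.5 * (1.0 / f_bar[2] + 1.0 / f_bar[4])
            notes.append("F_bar_3 interpolated from classes 2 and 4")
            continue
        total += n_aa / f_bar[k]

    value = min(total, ENC_MAX)
    if value < ENC_MIN - 1e-9:
        raise CubkitError(
            f"computed ENC {value:.3f} below the theoretical minimum 20"
        )
    return ENCResult(
        enc=value, f_bar=f_bar, per_aa_F=per_aa_F, notes=tuple(notes)
    )


def expected_enc(s: float) -> float:
    """Expected ENC at third-position G+C content ``s`` ∈ [0, 1]."""
    if not 0.0 <= s <= 1.0:
        raise CubkitError(f"s={s} outside [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_gc3_table(
    seqs: list[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    s_source: str = "gc3s",
) -> pd.DataFrame:
    """Plot-ready rows (id, s, enc, expected_enc) for the ENC–GC3s plot.

    ``s_source`` chooses the abscissa: GC3s (third positions of
    synonymous-set codons, the curve's natural domain) or plain GC3.
    Sequences with undefined ENC get NaN rows rather than aborting.
    """
    if s_source not in ("gc3s", "gc3"):
        raise CubkitError(f"unknown s_source {s_source!r}")
    rows = []
    for seq in seqs:
        row: dict[str, float | str] = {"sequence": seq.id}
        try:
            prof = composition_profile(seq, code)
            s = (prof.gc3s_pct if s_source == "gc3s" else prof.gc3_pct) / 100
            row["s"] = s
            row["enc"] = enc(count_codons(seq, code), code).enc
            row["expected_enc"] = expected_enc(s)
        except CubkitError:
            row.setdefault("s", np.nan)
            row["enc"] = np.nan
            row["expected_enc"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sequence")


class ENCScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping sequences to their per-gene ENC values."""

    def __init__(self, genetic_code: GeneticCode = STANDARD_CODE):
        self.genetic_code = genetic_code

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[CodingSequence]) -> np.ndarray:
        out = []
        for s in X:
            try:
                out.append(enc(count_codons(s, self.genetic_code)).enc)
            except CubkitError:
                out.append(np.nan)
        return np.asarray(out)
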