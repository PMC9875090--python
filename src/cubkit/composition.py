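"""Per-sequence nucleotide-composition indices.

For each CDS the profile reports overall base percentages (A, C, G, T),
third-codon-position percentages (A3, C3, G3, T3), G+C content by codon
position (GC1, GC2, GC3), their first/second-position mean GC12, overall
GC/AT, AT3, and GC3s — G+C at third positions restricted to codons of the
synonymous (multi-codon-family) set. GC3s is the ``s`` of the ENC–GC3s
expected curve; GC3 over all counted codons is what compositional tables
conventionally print. Both are computed.

All percentages are carried at full precision; rounding happens only when
reports are written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import UndefinedProfileError
from .genetics import GeneticCode, STANDARD_CODE
from .io import CodingSequence, counted_codons

#: Column order of the standard compositional report.
TABLE_COLUMNS = [
    "A", "C", "T", "G", "GC", "AT",
    "GC1", "GC2", "GC3", "A3", "C3", "T3", "G3", "AT3",
    "GC12", "GC3s",
]


@dataclass(frozen=True)
class CompositionProfile:
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    a3_pct: float
    c3_pct: float
    g3_pct: float
    t3_pct: float
    gc1_pct: float
    gc2_pct: float
    gc3_pct: float
    gc12_pct: float
    gc_pct: float
    at_pct: float
    at3_pct: float
    gc3s_pct: float
    n_codons: int

    def as_row(self) -> dict[str, float]:
        return {
            "A": self.a_pct, "C": self.c_pct, "T": self.t_pct,
            "G": self.g_pct, "GC": self.gc_pct, "AT": self.at_pct,
            "GC1": self.gc1_pct, "GC2": self.gc2_pct, "GC3": self.gc3_pct,
            "A3": self.a3_pct, "C3": self.c3_pct, "T3": self.t3_pct,
            "G3": self.g3_pct, "AT3": self.at3_pct,
            "GC12": self.gc12_pct, "GC3s": self.gc3s_pct,
        }


def composition_profile(
    seq: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = False,
) -> CompositionProfile:
    """Compute the compositional profile of one validated CDS.

    Statistics are taken over *counted* codons: stop codons (unless
    ``include_stop``) and codons containing ambiguity symbols are excluded,
    so base percentages, positional GC and third-position fractions all
    share one basis.
    """
    codons = counted_codons(seq, code, include_stop=include_stop)
    if not codons:
        raise UndefinedProfileError(
            f"sequence {seq.id!r} has no counted codons"
        )
    n = len(codons)
    syn = set(code.synonymous_codons)

    base = {b: 0 for b in "ACGT"}
    pos_gc = [0, 0, 0]
    third = {b: 0 for b in "ACGT"}
    gc3s_num = gc3s_den = 0
    for codon in codons:
        for i, b in enumerate(codon):
            base[b] += 1
            if b in "GC":
                pos_gc[i] += 1
        third[codon[2]] += 1
        if codon in syn:
            gc3s_den += 1
            if codon[2] in "GC":
                gc3s_num += 1

    tot = 3 * n
    pct = {b: 100.0 * base[b] / tot for b in "ACGT"}
    gc1, gc2, gc3 = (100.0 * g / n for g in pos_gc)
    gc = 100.0 * (base["G"] + base["C"]) / tot
    gc3s = 100.0 * gc3s_num / gc3s_den if gc3s_den else float("nan")
    return CompositionProfile(
        a_pct=pct["A"], c_pct=pct["C"], g_pct=pct["G"], t_pct=pct["T"],
        a3_pct=100.0 * third["A"] / n, c3_pct=100.0 * third["C"] / n,
        g3_pct=100.0 * third["G"] / n, t3_pct=100.0 * third["T"] / n,
        gc1_pct=gc1, gc2_pct=gc2, gc3_pct=gc3,
        gc12_pct=(gc1 + gc2) / 2.0,
        gc_pct=gc, at_pct=100.0 - gc,
        at3_pct=100.0 - gc3,
        gc3s_pct=gc3s,
        n_codons=n,
    )


def composition_table(
    seqs: list[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = False,
) -> pd.DataFrame:
    """One compositional row per sequence, in input order.

    Sequences whose profile is undefined yield an all-NaN row flagged in
    an ``error`` column rather than aborting the table.
    """
    if not seqs:
        raise UndefinedProfileError("composition_table needs ≥ 1 sequence")
    rows, errors = [], []
    for s in seqs:
        try:
            rows.append(composition_profile(s, code, include_stop).as_row())
            errors.append("")
        except UndefinedProfileError as exc:
            rows.append({c: np.nan for c in TABLE_COLUMNS})
            errors.append(str(exc))
    df = pd.DataFrame(rows, index=[s.id for s in seqs])[TABLE_COLUMNS]
    if any(errors):
        df["error"] = errors
    df.index.name = "sequence"
    return df


def summarize_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic column means and sample (n−1) standard deviations."""
    num = table.select_dtypes("number")
    out = pd.DataFrame(
        [num.mean(), num.std(ddof=1).fillna(0.0)], index=["Mean", "SD"]
    )
    out.index.name = "statistic"
    return out


class CompositionProfiler(TransformerMixin, BaseEstimator):
    """Transformer mapping coding sequences to compositional index rows.

    Parameters
    ----------
    genetic_code : GeneticCode
        Translation table (standard code by default).
    include_stop : bool
        Count stop codons in the statistics basis (off by default).
    """

    def __init__(
        self,
        genetic_code: GeneticCode = STANDARD_CODE,
        include_stop: bool = False,
    ):
        self.genetic_code = genetic_code
        self.include_stop = include_stop

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[CodingSequence]) -> pd.DataFrame:
        return composition_table(
            list(X), self.genetic_code, include_stop=self.include_stop
        )
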