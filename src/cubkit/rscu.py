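"""Relative synonymous codon usage (RSCU).

RSCU of codon *j* in the family of amino acid *i* is the observed count
X_ij scaled by the family's expectation under uniform synonymous usage:

    RSCU_ij = X_ij * n_i / sum_j X_ij

with n_i the family degeneracy, so the values of a family sum to n_i.
Single-codon families (Met, Trp) and stops are outside the universe: for
the standard code RSCU is defined over 59 codons of 18 amino acids.

An amino acid never observed in the input has *undefined* RSCU for its
codons — reported as missing, never as 0, so absence cannot masquerade as
under-representation on short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, CubkitError
from .genetics import AA3, GeneticCode, STANDARD_CODE, to_rna
from .io import CodingSequence, CodonCountTable, count_codons

#: Classification labels.
OVER, UNDER, INTERMEDIATE, MISSING = (
    "overrepresented", "underrepresented", "intermediate", "missing",
)


@dataclass
class RSCUProfile:
    """RSCU values over the synonymous codon universe (DNA alphabet keys).

    ``values[codon]`` is ``nan`` when the codon's amino acid was never
    observed; ``missing_amino_acids`` lists those families.
    """

    values: dict[str, float]
    code: GeneticCode = field(repr=False, default=STANDARD_CODE)
    source_counts: CodonCountTable | None = field(repr=False, default=None)

    @property
    def missing_amino_acids(self) -> set[str]:
        out = set()
        for aa, cods in self.code.synonymous_families.items():
            if all(math.isnan(self.values[c]) for c in cods):
                out.add(aa)
        return out

    @property
    def by_amino_acid(self) -> dict[str, list[tuple[str, float]]]:
        return {
            aa: [(c, self.values[c]) for c in cods]
            for aa, cods in self.code.synonymous_families.items()
        }

    def as_series(self, rna: bool = True) -> pd.Series:
        keys = list(self.values)
        return pd.Series(
            [self.values[k] for k in keys],
            index=[to_rna(k) if rna else k for k in keys],
            name="rscu",
        )


def rscu(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> RSCUProfile:
    """Compute RSCU from a codon count table."""
    if counts.n_codons == 0:
        raise CubkitError("empty count table: RSCU undefined")
    values: dict[str, float] = {}
    for aa, cods in code.synonymous_families.items():
        total = sum(counts[c] for c in cods)
        n_i = len(cods)
        for c in cods:
            values[c] = counts[c] * n_i / total if total else float("nan")
    return RSCUProfile(values=values, code=code, source_counts=counts)


def classify_codons(
    profile: RSCUProfile,
    over_threshold: float = 1.6,
    under_threshold: float = 0.6,
) -> dict[str, str]:
    """Classify each codon by its RSCU value.

    Strict inequalities at both thresholds: values exactly at a threshold
    are intermediate. The 1.6/0.6 defaults are the conventional cut-offs
    for over-/under-represented codons.
    """
    if over_threshold <= under_threshold:
        raise ConfigurationError(
            f"over_threshold ({over_threshold}) must exceed "
            f"under_threshold ({under_threshold})"
        )
    out = {}
    for codon, v in profile.values.items():
        if math.isnan(v):
            out[codon] = MISSING
        elif v > over_threshold:
            out[codon] = OVER
        elif v < under_threshold:
            out[codon] = UNDER
        else:
            out[codon] = INTERMEDIATE
    return out


@dataclass(frozen=True)
class PreferredCodon:
    amino_acid: str
    codon: str
    rscu: float
    tied: bool


def preferred_codons(
    profile: RSCUProfile,
) -> tuple[dict[str, PreferredCodon], dict[str, int]]:
    """Per-amino-acid maximal-RSCU codon plus an ending-base tally.

    Ties are broken alphabetically by codon and flagged. The tally counts
    preferred codons by their third base (DNA alphabet), the usual summary
    of which base the genome's favoured codons end in.
    """
    preferred: dict[str, PreferredCodon] = {}
    tally = {b: 0 for b in "ACGT"}
    for aa, pairs in profile.by_amino_acid.items():
        defined = [(c, v) for c, v in pairs if not math.isnan(v)]
        if not defined:
            continue
        best = max(v for _, v in defined)
        winners = sorted(c for c, v in defined if v == best)
        codon = winners[0]
        preferred[aa] = PreferredCodon(
            amino_acid=aa, codon=codon, rscu=best, tied=len(winners) > 1
        )
        tally[codon[2]] += 1
    return preferred, tally


def shared_preference(
    a: RSCUProfile,
    b: RSCUProfile,
    rule: str = "preferred",
) -> set[str]:
    """Codons two organisms agree on, under a selectable rule.

    ``preferred``: codons that are the per-family maximal-RSCU choice in
    both profiles. ``both_above_one``: codons with RSCU > 1 in both.
    """
    if rule == "preferred":
        pa, _ = preferred_codons(a)
        pb, _ = preferred_codons(b)
        return {
            p.codon
            for aa, p in pa.items()
            if aa in pb and pb[aa].codon == p.codon
        }
    if rule == "both_above_one":
        return {
            c
            for c, v in a.values.items()
            if not math.isnan(v) and v > 1
            and not math.isnan(b.values.get(c, float("nan")))
            and b.values[c] > 1
        }
    raise ConfigurationError(f"unknown shared-preference rule {rule!r}")


def rscu_table(
    profile: RSCUProfile,
    over_threshold: float = 1.6,
    under_threshold: float = 0.6,
) -> pd.DataFrame:
    """Report table: amino_acid, codon (RNA), rscu, class."""
    classes = classify_codons(profile, over_threshold, under_threshold)
    rows = []
    for aa, pairs in profile.by_amino_acid.items():
        for codon, v in pairs:
            rows.append(
                {
                    "amino_acid": AA3[aa],
                    "codon": to_rna(codon),
                    "rscu": v,
                    "class": classes[codon],
                }
            )
    return pd.DataFrame(rows)


class RSCUTransformer(TransformerMixin, BaseEstimator):
    """Transformer mapping sequences to an (n_sequences × 59) RSCU matrix.

    ``pooled=True`` collapses the input to a single pooled-usage row. The
    matrix (missing families as NaN) is the input of correspondence
    analysis; ``fill_missing`` replaces NaN with 0 for consumers that need
    a complete non-negative table.
    """

    def __init__(
        self,
        genetic_code: GeneticCode = STANDARD_CODE,
        pooled: bool = False,
        fill_missing: bool = False,
    ):
        self.genetic_code = genetic_code
        self.pooled = pooled
        self.fill_missing = fill_missing

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[CodingSequence]) -> pd.DataFrame:
        code = self.genetic_code
        if self.pooled:
            profiles = {"pooled": rscu(count_codons(list(X), code), code)}
        else:
            profiles = {
                s.id: rscu(count_codons(s, code), code) for s in X
            }
        df = pd.DataFrame(
            {sid: p.as_series(rna=False) for sid, p in profiles.items()}
        ).T
        df = df[list(next(iter(profiles.values())).values)]
        if self.fill_missing:
            df = df.fillna(0.0)
        df.index.name = "sequence"
        return df
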