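"""Seeded CDS generators with controllable codon-usage structure.

The generative model draws amino acids i.i.d. from a frequency vector and,
independently at each site, a codon from the amino acid's family
distribution. Family distributions are parameterised by

* ``gc3`` — the probability mass given to G/C-ending codons of each
  family, so the expected third-position G+C of synonymous codons equals
  ``gc3`` exactly;
* third-base preferences *within* the A/T-ending and G/C-ending halves of
  a family (e.g. T favoured over A), which create codon bias beyond what
  composition alone would give — the ingredient that pushes genes below
  the ENC–GC3s expected curve;
* ``gc12`` — matched by exponentially tilting the amino-acid frequencies
  toward residues whose codons are G+C-rich at positions 1–2 (solved by
  bisection), since positions 1–2 are fixed by the protein.

Met and Trp (single-codon families) are left out of the generated
proteins: they carry no synonymous-usage signal and would only couple
GC3 to the amino-acid composition. Stops are never emitted, so every
generated CDS passes strict validation.

Two panel generators encode the study conditions: an AT-rich panel
emulating a tapeworm-like CDS set (GC ≈ 31 %, GC3 ≈ 0.20, with a small
GC-rich outlier subset), and regime panels with known neutrality
structure (mutation-dominated: GC12 tracks GC3, generative slope ≈ 1;
selection-dominated: GC12 pinned, slope ≈ 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, CubkitError
from .genetics import GeneticCode, STANDARD_CODE
from .io import CodingSequence

#: Within-class third-base preferences of the AT-rich (tapeworm-like)
#: model: T strongly favoured over A, G strongly over C — mirroring the
#: near-absence of C-ending codons in AT-rich parasite genomes.
BIASED_PREF = {"T": 0.8, "A": 0.2, "G": 0.9, "C": 0.1}
#: Neutral within-class preferences: bias comes from composition only.
UNIFORM_PREF = {"T": 0.5, "A": 0.5, "G": 0.5, "C": 0.5}


@dataclass
class CodonUsageModel:
    """Parametric codon-usage model: amino-acid and per-family codon probs."""

    per_aa_probs: dict[str, dict[str, float]]
    aa_freqs: dict[str, float]
    label: str = ""
    code: GeneticCode = field(repr=False, default=STANDARD_CODE)

    def __post_init__(self):
        for aa, probs in self.per_aa_probs.items():
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"codon probabilities for {aa} sum to {s}, not 1"
                )
        s = sum(self.aa_freqs.values())
        if abs(s - 1.0) > 1e-9:
            raise ConfigurationError(f"aa_freqs sum to {s}, not 1")


@dataclass(frozen=True)
class RegimePanelSpec:
    """Settings of a neutrality-regime panel."""

    regime: str  # "mutation" | "selection"
    n_sequences: int = 100
    length_codons: int = 300
    gc3_range: tuple[float, float] = (0.10, 0.50)
    noise_sd: float = 2.0  # percentage points of jitter on targets
    seed: int = 42

    def __post_init__(self):
        if self.regime not in ("mutation", "selection"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.n_sequences < 3:
            raise ConfigurationError("n_sequences must be ≥ 3")
        lo, hi = self.gc3_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("gc3_range must lie within [0, 1]")


def _family_probs(
    codons: tuple[str, ...], gc3: float, pref: dict[str, float]
) -> dict[str, float]:
    """Split mass gc3 / (1−gc3) over the G/C- and A/T-ending halves of a
    family, then by third-base preference, then evenly among codons
    sharing a third base."""
    by_base: dict[str, list[str]] = {}
    for c in codons:
        by_base.setdefault(c[2], []).append(c)
    gc_bases = [b for b in by_base if b in "GC"]
    at_bases = [b for b in by_base if b in "AT"]
    probs: dict[str, float] = {}
    for bases, mass in ((gc_bases, gc3), (at_bases, 1.0 - gc3)):
        if not bases:
            continue
        z = sum(pref[b] for b in bases)
        for b in bases:
            share = mass * pref[b] / z
            for c in by_base[b]:
                probs[c] = share / len(by_base[b])
    z = sum(probs.values())
    return {c: p / z for c, p in probs.items()}


def _aa_gc12(aa_probs: dict[str, float]) -> float:
    """Expected G+C fraction at codon positions 1–2 under a family dist."""
    return sum(
        p * (sum(b in "GC" for b in c[:2]) / 2.0)
        for c, p in aa_probs.items()
    )


def _tilted_aa_freqs(
    per_aa_probs: dict[str, dict[str, float]], gc12: float
) -> dict[str, float]:
    """Exponential tilt of uniform amino-acid frequencies to a GC12 target."""
    aas = sorted(per_aa_probs)
    g = np.array([_aa_gc12(per_aa_probs[aa]) for aa in aas])
    lo, hi = float(g.min()), float(g.max())
    if not lo < gc12 < hi:
        raise ConfigurationError(
            f"gc12 target {gc12} outside achievable range ({lo:.2f}, "
            f"{hi:.2f})"
        )

    def mean_gc12(theta: float) -> float:
        w = np.exp(theta * (g - g.mean()))
        w /= w.sum()
        return float(w @ g)

    t_lo, t_hi = -60.0, 60.0
    for _ in range(200):
        mid = (t_lo + t_hi) / 2.0
        if mean_gc12(mid) < gc12:
            t_lo = mid
        else:
            t_hi = mid
    w = np.exp(t_lo * (g - g.mean()))
    w /= w.sum()
    return dict(zip(aas, w))


def usage_model(
    gc3: float = 0.5,
    gc12: float | None = None,
    third_base_pref: dict[str, float] = UNIFORM_PREF,
    code: GeneticCode = STANDARD_CODE,
    label: str = "",
) -> CodonUsageModel:
    """Build a :class:`CodonUsageModel` from composition targets.

    ``gc3`` sets the expected synonymous third-position G+C;
    ``gc12`` (None = uniform amino-acid frequencies) sets the expected
    positions-1–2 G+C via the amino-acid tilt.
    """
    if not 0.0 < gc3 < 1.0:
        raise ConfigurationError("gc3 must lie strictly inside (0, 1)")
    per_aa = {
        aa: _family_probs(cods, gc3, third_base_pref)
        for aa, cods in code.synonymous_families.items()
    }
    if gc12 is None:
        freqs = {aa: 1.0 / len(per_aa) for aa in per_aa}
    else:
        freqs = _tilted_aa_freqs(per_aa, gc12)
    return CodonUsageModel(
        per_aa_probs=per_aa, aa_freqs=freqs, label=label, code=code
    )


def uniform_model(code: GeneticCode = STANDARD_CODE) -> CodonUsageModel:
    """Uniform amino-acid frequencies and uniform within-family usage."""
    per_aa = {
        aa: {c: 1.0 / len(cods) for c in cods}
        for aa, cods in code.synonymous_families.items()
    }
    freqs = {aa: 1.0 / len(per_aa) for aa in per_aa}
    return CodonUsageModel(
        per_aa_probs=per_aa, aa_freqs=freqs, label="uniform", code=code
    )


def sample_cds(
    model: CodonUsageModel,
    length_codons: int,
    seed: int | np.random.Generator,
    seq_id: str = "synthetic",
) -> CodingSequence:
    """Draw one CDS from the model; bit-reproducible under a fixed seed."""
    if length_codons < 10:
        raise CubkitError("length_codons must be ≥ 10 (indices unstable)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    aas = sorted(model.aa_freqs)
    freqs = np.array([model.aa_freqs[aa] for aa in aas])
    draw_aa = rng.choice(len(aas), size=length_codons, p=freqs)
    codons = np.empty(length_codons, dtype=object)
    for i, aa in enumerate(aas):
        mask = draw_aa == i
        k = int(mask.sum())
        if k == 0:
            continue
        fam = sorted(model.per_aa_probs[aa])
        p = np.array([model.per_aa_probs[aa][c] for c in fam])
        codons[mask] = rng.choice(fam, size=k, p=p)
    return CodingSequence(id=seq_id, nucleotides="".join(codons))


def at_rich_panel(
    n: int,
    seed: int = 42,
    length_codons: int = 540,
    outlier_fraction: float = 0.06,
) -> list[CodingSequence]:
    """Panel emulating an AT-rich tapeworm CDS set.

    Most sequences come from an AT-rich model (GC3 ≈ 0.20, GC12 ≈ 0.365,
    hence GC ≈ 31 %) with strong T-over-A / G-over-C within-family
    preferences; ~6 % come from a GC-rich outlier model (GC3 ≈ 0.47),
    mirroring the handful of GC-rich strains such sets contain.
    """
    if n < 10:
        raise CubkitError("at_rich_panel needs n ≥ 10")
    rng = np.random.default_rng(seed)
    n_out = int(round(outlier_fraction * n))
    outliers = set(
        rng.choice(n, size=n_out, replace=False) if n_out else []
    )
    seqs = []
    for i in range(n):
        if i in outliers:
            gc3, gc12 = 0.47, 0.45
        else:
            gc3, gc12 = 0.20, 0.365
        gc3 = float(np.clip(gc3 + rng.normal(0, 0.01), 0.02, 0.98))
        gc12 = float(np.clip(gc12 + rng.normal(0, 0.01), 0.02, 0.98))
        model = usage_model(
            gc3=gc3, gc12=gc12, third_base_pref=BIASED_PREF,
            label="at_rich",
        )
        seqs.append(
            sample_cds(model, length_codons, rng, seq_id=f"synth_{i:03d}")
        )
    return seqs


def regime_panel(spec: RegimePanelSpec) -> list[CodingSequence]:
    """Panel with known neutrality structure.

    mutation regime
        A per-sequence composition target drawn across ``gc3_range`` is
        applied at all three codon positions (GC12 co-varies with GC3;
        generative slope ≈ 1).
    selection regime
        GC3 varies across ``gc3_range`` while the amino-acid composition
        (hence GC12) is pinned at a fixed value (generative slope ≈ 0).

    ``noise_sd`` (percentage points) is Gaussian jitter applied to the
    composition targets.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd / 100.0
    lo, hi = spec.gc3_range
    if hi == lo:
        raise ConfigurationError("gc3_range must span a nonzero interval")
    seqs = []
    for i in range(spec.n_sequences):
        t = float(rng.uniform(lo, hi))
        gc3 = float(np.clip(t + rng.normal(0, sd), 0.02, 0.98))
        if spec.regime == "mutation":
            gc12 = float(np.clip(t + rng.normal(0, sd), 0.05, 0.95))
        else:
            gc12 = float(np.clip(0.36 + rng.normal(0, sd), 0.05, 0.95))
        model = usage_model(gc3=gc3, gc12=gc12, label=spec.regime)
        seqs.append(
            sample_cds(
                model, spec.length_codons, rng, seq_id=f"{spec.regime}_{i:03d}"
            )
        )
    return seqs
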