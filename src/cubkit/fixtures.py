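"""Packaged reference tables.

``table1`` — per-strain compositional indices (A, C, T, G, GC, AT,
GC1/2/3, A3/C3/T3/G3, AT3, ENC) for 90 tapeworm coding sequences, as
printed in the study this package reproduces.

``table2`` — RSCU of the 59 synonymous codons for the parasite and its
two hosts (*Homo sapiens*, *Bos taurus*).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import CubkitError

_FIXTURES = {
    "table1": "table1_composition.tsv",
    "table2": "table2_rscu.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name (``table1`` or ``table2``)."""
    if name not in _FIXTURES:
        raise CubkitError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("cubkit") / "data" / _FIXTURES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if name == "table1":
        df = df.set_index("sequence")
    return df


def host_reference(df: pd.DataFrame, host: str) -> pd.DataFrame:
    """Extract one host's codon→RSCU reference from the table2 fixture."""
    if host not in df.columns:
        raise CubkitError(f"no column {host!r} in reference table")
    out = df[["codon", host]].rename(columns={host: "rscu"})
    return out
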