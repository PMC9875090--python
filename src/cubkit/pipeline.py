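"""One-call reproduction of the full codon-usage analysis.

``run_pipeline`` executes validate → composition → RSCU (per-sequence and
pooled) → ENC → CAI / e-CAI per host reference → SiD per reference →
neutrality regression → correspondence analysis → Spearman correlations,
collecting everything in an :class:`AnalysisReport`. Stages whose
preconditions are unmet (e.g. < 3 sequences for dataset-level fits) are
skipped with a logged reason, never silently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cai import (
    ECAIResult,
    _reference_to_rscu,
    cai as _cai,
    expected_cai,
    weights_from_reference,
)
from .coa import COAResult, axis_summary, correspondence_analysis
from .composition import composition_table, summarize_composition
from .enc import enc_gc3_table
from .errors import CubkitError
from .genetics import genetic_code
from .host_similarity import SiDResult, similarity_index
from .io import (
    CodingSequence,
    ValidationPolicy,
    count_codons,
    read_cds_fasta,
    validate_cds,
)
from .rscu import (
    RSCUTransformer,
    classify_codons,
    preferred_codons,
    rscu,
    rscu_table,
)
from .selection_mutation import (
    CorrelationMatrix,
    NeutralityFit,
    neutrality_fit,
    spearman_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Flat settings of the pipeline; defaults reproduce the conventional
    choices (standard code, stop exclusion, 1.6/0.6 RSCU thresholds,
    e-CAI at 95 % coverage)."""

    code_table: int = 1
    strict: bool = False
    drop_terminal_stop: bool = True
    over_threshold: float = 1.6
    under_threshold: float = 0.6
    ecai_n: int = 500
    ecai_coverage: float = 0.95
    seed: int = 42
    s_source: str = "gc3s"
    adjust: str = "none"
    run_ecai: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CubkitError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class AnalysisReport:
    per_sequence: pd.DataFrame
    pooled_rscu: pd.DataFrame | None = None
    preferred: pd.DataFrame | None = None
    classification_counts: dict[str, int] | None = None
    sid: dict[str, SiDResult] = field(default_factory=dict)
    ecai: dict[str, ECAIResult] = field(default_factory=dict)
    neutrality: NeutralityFit | None = None
    coa: COAResult | None = None
    correlations: CorrelationMatrix | None = None
    enc_gc3: pd.DataFrame | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def run_pipeline(
    fasta: str | Path | list[CodingSequence],
    references: dict[str, pd.DataFrame] | None = None,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> AnalysisReport:
    """Run every analysis stage on a CDS set.

    ``references`` maps a host label to a codon→count/RSCU table. When
    ``outdir`` is given, each stage's table is written as TSV (floats at 4
    decimals, compositional columns at 2).
    """
    cfg = config or AnalysisConfig()
    code = genetic_code(cfg.code_table)
    policy = ValidationPolicy(
        strict=cfg.strict, drop_terminal_stop=cfg.drop_terminal_stop
    )
    raw = (
        read_cds_fasta(fasta)
        if isinstance(fasta, (str, Path))
        else list(fasta)
    )
    seqs, rejected = [], {}
    for s in raw:
        try:
            seqs.append(validate_cds(s, code, policy))
        except CubkitError as exc:
            rejected[s.id] = str(exc)
            logger.warning("rejected %s: %s", s.id, exc)
    if not seqs:
        raise CubkitError(
            f"no valid sequences; rejections: {rejected or 'input empty'}"
        )
    logger.info("validated %d/%d sequences", len(seqs), len(raw))

    report = AnalysisReport(per_sequence=pd.DataFrame())
    report.provenance = {
        "tool": f"cubkit {__version__}",
        "n_input": len(raw),
        "n_valid": len(seqs),
        "rejected": rejected,
        "code_table": cfg.code_table,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
    }

    comp = composition_table(seqs, code)
    enc_tbl = enc_gc3_table(seqs, code, s_source=cfg.s_source)
    per_seq = comp.join(enc_tbl[["enc"]].rename(columns={"enc": "ENC"}))
    report.enc_gc3 = enc_tbl

    pooled_counts = count_codons(seqs, code)
    pooled = rscu(pooled_counts, code)
    report.pooled_rscu = rscu_table(
        pooled, cfg.over_threshold, cfg.under_threshold
    )
    classes = classify_codons(
        pooled, cfg.over_threshold, cfg.under_threshold
    )
    counts: dict[str, int] = {}
    for v in classes.values():
        counts[v] = counts.get(v, 0) + 1
    report.classification_counts = counts
    pref, tally = preferred_codons(pooled)
    report.preferred = pd.DataFrame(
        [dataclasses.asdict(p) for p in pref.values()]
    )
    report.provenance["preferred_third_base_tally"] = tally

    for label, ref in (references or {}).items():
        weights = weights_from_reference(
            ref, code, reference_id=label
        )
        per_seq[f"CAI_{label}"] = [
            _cai(s, weights, code) for s in seqs
        ]
        host_rscu = _reference_to_rscu(ref, code)
        report.sid[label] = similarity_index(pooled, host_rscu)
        if cfg.run_ecai:
            report.ecai[label] = expected_cai(
                seqs,
                weights,
                n_random=cfg.ecai_n,
                coverage=cfg.ecai_coverage,
                seed=cfg.seed,
                code=code,
            )
    report.per_sequence = per_seq

    if len(seqs) >= 3:
        report.neutrality = neutrality_fit(comp)
    else:
        report.skipped["neutrality"] = "needs ≥ 3 sequences"
        logger.info("skipping neutrality: %s", report.skipped["neutrality"])

    if len(seqs) >= 3:
        matrix = RSCUTransformer(code, fill_missing=True).fit_transform(seqs)
        try:
            report.coa = correspondence_analysis(matrix)
        except CubkitError as exc:
            report.skipped["coa"] = str(exc)
            logger.info("skipping coa: %s", exc)
    else:
        report.skipped["coa"] = "needs ≥ 3 sequences"
        logger.info("skipping coa: %s", report.skipped["coa"])

    if len(seqs) >= 4:
        corr_cols = [
            "A", "C", "G", "T", "GC", "AT", "GC1", "GC2", "GC3",
            "A3", "C3", "G3", "T3", "AT3", "ENC",
        ]
        report.correlations = spearman_matrix(
            per_seq[corr_cols], adjust=cfg.adjust
        )
    else:
        report.skipped["correlations"] = "needs ≥ 4 sequences"
        logger.info(
            "skipping correlations: %s", report.skipped["correlations"]
        )

    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _fmt(df: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    return df.round(decimals)


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _fmt(report.per_sequence, 2).to_csv(outdir / "per_sequence.tsv", sep="\t")
    if report.pooled_rscu is not None:
        _fmt(report.pooled_rscu).to_csv(
            outdir / "pooled_rscu.tsv", sep="\t", index=False
        )
    if report.preferred is not None:
        _fmt(report.preferred).to_csv(
            outdir / "preferred_codons.tsv", sep="\t", index=False
        )
    if report.enc_gc3 is not None:
        _fmt(report.enc_gc3).to_csv(outdir / "enc_gc3.tsv", sep="\t")
    if report.sid:
        pd.DataFrame(
            [
                {
                    "reference_id": k,
                    "R": v.r_ab,
                    "D": v.d_ab,
                    "n_codons_used": v.n_codons_used,
                }
                for k, v in report.sid.items()
            ]
        ).round(4).to_csv(outdir / "sid.tsv", sep="\t", index=False)
    if report.neutrality is not None:
        pd.DataFrame([dataclasses.asdict(report.neutrality)]).round(4).to_csv(
            outdir / "neutrality.tsv", sep="\t", index=False
        )
    if report.coa is not None:
        _fmt(report.coa.row_coords).to_csv(outdir / "coa_rows.tsv", sep="\t")
        summary = axis_summary(report.coa, k=min(2, report.coa.n_axes))
        pd.DataFrame(
            {
                "axis": [
                    f"axis{i+1}" for i in range(len(summary["proportions"]))
                ],
                "proportion": summary["proportions"],
                "proportion_renormalized": summary[
                    "proportions_renormalized"
                ],
            }
        ).round(4).to_csv(outdir / "coa_axes.tsv", sep="\t", index=False)
    if report.correlations is not None:
        _fmt(report.correlations.rho).to_csv(
            outdir / "spearman_rho.tsv", sep="\t"
        )
        _fmt(report.correlations.p).to_csv(
            outdir / "spearman_p.tsv", sep="\t"
        )
    if report.ecai:
        pd.DataFrame(
            [
                {
                    "reference_id": k,
                    "mean_cai": v.mean_cai,
                    "sd_cai": v.sd_cai,
                    "e_cai": v.e_cai,
                    "ks_stat": v.ks_stat,
                    "ks_p": v.ks_p,
                    "n_random": v.n_random,
                    "seed": v.seed,
                }
                for k, v in report.ecai.items()
            ]
        ).round(4).to_csv(outdir / "ecai.tsv", sep="\t", index=False)
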