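"""End-to-end per-record analysis and report generation.

``analyze_record`` runs the full BZ workflow on one annotated sequence —
spacer extraction, dispersed-repeat census with masking and family
clustering, hairpin census, tandem arrays with trnY-similarity, promoter
scans upstream of trnD and trnY, and gene-order classification — and
returns a JSON-serialisable report whose tables mirror the repeat-family
and stem-loop summaries of the underlying study.  ``run_pipeline``
orchestrates many records, logging per-record failures and carrying on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import gene_order as go
from . import promoters as pm
from . import repeats as rp
from . import stemloops as sl
from . import tandem as td
from .seq_io import (
    AnnotatedSequence,
    extract_gene_order,
    extract_igs,
    read_fasta,
    read_feature_table,
)

logger = logging.getLogger("fernbz")

__all__ = ["PipelineConfig", "analyze_record", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """All thresholds surfaced in one place; defaults are the study settings."""

    repeat_min_len: int = 20
    repeat_max_hamming: int = 3
    repeat_kinds: tuple[str, ...] = rp.KINDS
    family_max_dissimilarity: float = 0.15
    loop_len: int = 7
    min_stem: int = 3
    aaa_side: str = "loop3"
    coverage_mode: str = "union"
    tandem_period_min: int = 20
    tandem_period_max: int = 40
    tandem_min_copies: int = 3
    tandem_max_divergence: float = 0.2
    promoter_upstream: int = 200
    igs_pairs: tuple[tuple[str, str], ...] = (
        ("trnY-GUA", "trnE-UUC"),
        ("psbM", "petN"),
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read ``key = value`` lines (# comments); unknown keys error."""
        cfg = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (t.strip() for t in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{ln}: unknown setting {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, str):
                setattr(cfg, key, value)
            else:  # tuples (kinds, igs pairs) are not file-configurable
                raise ValueError(f"{path}:{ln}: setting {key!r} is not file-settable")
        return cfg


def _igs_report(aseq: AnnotatedSequence, cfg: PipelineConfig) -> dict:
    out = {}
    for left, right in cfg.igs_pairs:
        key = f"{left}--{right}"
        try:
            igs = extract_igs(aseq, left, right)
        except KeyError as exc:
            logger.warning("%s: %s", aseq.seq_id, exc)
            out[key] = None
            continue
        out[key] = {"start": igs.start, "end": igs.end, "length": igs.length}
    return out


def _repeat_report(seq: str, cfg: PipelineConfig) -> dict:
    matches = rp.find_repeats(
        seq, cfg.repeat_min_len, cfg.repeat_max_hamming, cfg.repeat_kinds
    )
    by_kind = {k: sum(m.kind == k for m in matches) for k in cfg.repeat_kinds}
    masked = rp.mask_overlaps(matches)
    spans = rp.extract_span_seqs(seq, masked)
    families = rp.cluster_families(spans, cfg.family_max_dissimilarity)
    return {
        "total_matches": len(matches),
        "matches_by_kind": by_kind,
        "nonredundant_matches": len(masked),
        "nonredundant_spans": len(spans),
        "n_families": len(families),
        "families": [
            {
                "consensus": f.consensus,
                "size": len(f.consensus),
                "copy_number": f.copy_number,
            }
            for f in families
        ],
    }


def _stemloop_report(seq: str, cfg: PipelineConfig) -> dict:
    hits = sl.scan_stemloops(seq, cfg.loop_len, cfg.min_stem)
    all_census = sl.census(hits, len(seq), require_aaa=False,
                           coverage=cfg.coverage_mode)
    aaa = sl.census(hits, len(seq), require_aaa=True, aaa_side=cfg.aaa_side,
                    coverage=cfg.coverage_mode)
    fam_counts: dict[str, int] = {}
    for h in aaa.hits:
        fam_counts[h.family_key] = fam_counts.get(h.family_key, 0) + 1
    return {
        "total_hits": all_census.total,
        "aaa_hits": aaa.total,
        "aaa_histogram": aaa.histogram,
        "aaa_covered_nt": aaa.covered_nt,
        "aaa_coverage_fraction": round(aaa.fraction, 4),
        "aaa_coverage_percent": round(100 * aaa.fraction, 2),
        "stem_families": dict(sorted(fam_counts.items(), key=lambda kv: -kv[1])),
        "coverage_mode": cfg.coverage_mode,
    }


def _tandem_report(seq: str, aseq: AnnotatedSequence, cfg: PipelineConfig) -> list:
    arrays = td.find_tandem_arrays(
        seq,
        cfg.tandem_period_min,
        cfg.tandem_period_max,
        cfg.tandem_min_copies,
        cfg.tandem_max_divergence,
    )
    out = []
    trny = None
    try:
        f = aseq.feature_by_locus("trnY-GUA")
        gene = aseq.residues[f.start - 1 : f.end]
        trny = gene if f.strand == "+" else None
        if f.strand == "-":
            from .seq_io import reverse_complement

            trny = reverse_complement(gene)
    except KeyError:
        pass
    for arr in arrays:
        entry = {
            "start": arr.start,
            "end": arr.end,
            "period": arr.period,
            "copy_number": arr.copy_number,
            "modules": arr.modules,
            "consensus_unit": arr.consensus_unit,
        }
        if trny is not None:
            sim = td.anticodon_similarity(arr.copies[0], trny)
            entry["trny_anticodon_identity"] = round(sim.identity, 4)
        out.append(entry)
    return out


def _promoter_report(aseq: AnnotatedSequence, cfg: PipelineConfig) -> dict:
    out = {}
    for locus in ("trnD-GUC", "trnY-GUA"):
        try:
            f = aseq.feature_by_locus(locus)
        except KeyError:
            out[locus] = None
            continue
        if f.strand == "+":
            lo = max(1, f.start - cfg.promoter_upstream)
            hi = f.start - 1
            wanted = "+"
        else:
            lo = f.end + 1
            hi = min(len(aseq.residues), f.end + cfg.promoter_upstream)
            wanted = "-"
        if hi < lo:
            out[locus] = {"window": None, "hits": []}
            continue
        hits = pm.scan_promoters(aseq.residues, (lo, hi))
        out[locus] = {
            "window": [lo, hi],
            "gene_strand": f.strand,
            "hits_on_gene_strand": [
                {
                    "minus35": list(h.minus35),
                    "minus10": list(h.minus10),
                    "spacer": h.spacer,
                    "mismatches": h.total_mismatches,
                }
                for h in hits
                if h.strand == wanted
            ],
        }
    return out


def _gene_order_report(aseq: AnnotatedSequence) -> dict | None:
    try:
        order = extract_gene_order(aseq)
    except KeyError as exc:
        logger.warning("%s: gene order skipped (%s)", aseq.seq_id, exc)
        return None
    catalog = go.load_catalog()
    distances = {
        name: go.format_distance(go.inversion_distance(order, ref))
        for name, ref in catalog.items()
        if order.symbols() == ref.symbols()
    }
    return {
        "order": str(order),
        "type": go.classify_order(order, catalog),
        "inversion_distances": distances,
    }


def analyze_record(aseq: AnnotatedSequence, cfg: PipelineConfig | None = None) -> dict:
    """Full analysis of one annotated BZ-like record; deterministic."""
    cfg = cfg or PipelineConfig()
    logger.info("analyzing %s (%d nt, %d features)", aseq.seq_id, len(aseq),
                len(aseq.features))
    report: dict = {"seq_id": aseq.seq_id, "length": len(aseq)}
    report["igs"] = _igs_report(aseq, cfg)

    ye = report["igs"].get("trnY-GUA--trnE-UUC")
    target_seq = aseq.residues
    scope = "record"
    if ye and ye["length"] > 0:
        target_seq = aseq.residues[ye["start"] - 1 : ye["end"]]
        scope = "trnY-GUA--trnE-UUC"
    report["analysis_scope"] = scope
    logger.info("%s: repeat scan over %s (%d nt)", aseq.seq_id, scope, len(target_seq))
    report["repeats"] = _repeat_report(target_seq, cfg)
    report["stemloops"] = _stemloop_report(target_seq, cfg)
    report["tandem_arrays"] = _tandem_report(target_seq, aseq, cfg)
    report["promoters"] = _promoter_report(aseq, cfg)
    report["gene_order"] = _gene_order_report(aseq)
    return report


def run_pipeline(
    fasta: str | Path,
    features: str | Path | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[dict, list[str]]:
    """Analyze every record in a FASTA (+ optional shared feature table).

    Returns (reports keyed by seq_id, list of failed seq_ids); failures
    are logged and do not stop the run.
    """
    cfg = cfg or PipelineConfig()
    records = read_fasta(fasta)
    feats = read_feature_table(features) if features else []
    reports: dict[str, dict] = {}
    failed: list[str] = []
    for rec in records:
        try:
            if feats:
                rec = AnnotatedSequence(rec.seq_id, rec.residues, list(feats))
            reports[rec.seq_id] = analyze_record(rec, cfg)
        except Exception:
            logger.exception("record %s failed", rec.seq_id)
            failed.append(rec.seq_id)
    return reports, failed


def write_report(reports: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")
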