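"""End-to-end case orchestration.

One family at a time — no batching: bin, normalize, segment, call, merge,
filter (gray list, gene proximity, population frequency), screen, phase,
summarize. Every filter stage logs and records its in/out counts so the
interpretation burden of a case is auditable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotate as ann
from . import phase as ph
from . import segment as seg
from .config import default_config
from .core import LOSS, CnvCall, ValidationError, sort_calls
from .depth import DepthProfile, NormalizedProfile, normalize

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

STAGES = ("raw", "post_graylist", "post_gene", "post_frequency")


@dataclass
class CaseSummary:
    """Per-stage accounting for one case."""

    sample_id: str
    stage_counts: dict  # stage name -> call count, in pipeline order
    mosaic_count: int = 0
    inheritance_labels: dict = field(default_factory=dict)  # interval -> label
    n_final: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": self.schema_version,
            "sample_id": self.sample_id,
            "stage_counts": self.stage_counts,
            "mosaic_count": self.mosaic_count,
            "inheritance_labels": self.inheritance_labels,
            "n_final": self.n_final,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CaseSummary":
        d = json.loads(text)
        return cls(
            sample_id=d["sample_id"],
            stage_counts=d["stage_counts"],
            mosaic_count=d["mosaic_count"],
            inheritance_labels=d["inheritance_labels"],
            n_final=d["n_final"],
            schema_version=d["schema_version"],
        )


def run_case(proband: DepthProfile,
             calling_graylist=(),
             full_graylist=(),
             genes=(),
             panel: Optional[ann.PopulationPanel] = None,
             mother: Optional[DepthProfile] = None,
             father: Optional[DepthProfile] = None,
             proband_variants: Optional[pd.DataFrame] = None,
             trio_table: Optional[pd.DataFrame] = None,
             config: Optional[dict] = None,
             seed: int = 0):
    """Run the full calling and interpretation flow for one case.

    Returns (CaseSummary, final call list). Any parental profile may be
    absent (duo/singleton); depth-based inheritance then degrades and the
    SNV-based phasing is used where a trio genotype table is available.
    """
    cfg = default_config()
    if config:
        cfg.update(config)

    def _norm(prof):
        if prof is None:
            return None
        return prof if isinstance(prof, NormalizedProfile) else normalize(prof)

    try:
        nprof = _norm(proband)
        calls = seg.call_cnvs(
            nprof,
            calling_graylist=calling_graylist,
            alpha=cfg["segment.alpha"],
            n_permutations=cfg["segment.n_permutations"],
            min_bins_per_segment=cfg["segment.min_bins_per_segment"],
            min_support_bins=cfg["segment.min_support_bins"],
            merge_gap=cfg["segment.merge_gap_bp"],
            mosaic_gain_threshold=cfg["segment.mosaic_gain_threshold"],
            mosaic_loss_threshold=cfg["segment.mosaic_loss_threshold"],
            seed=seed,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'calling' failed: {exc}") from exc
    counts = {"raw": len(calls)}

    try:
        calls = ann.filter_graylist(calls, full_graylist,
                                    cfg["annotate.graylist_max_fraction"])
    except Exception as exc:
        raise RuntimeError(f"stage 'gray-list filter' failed: {exc}") from exc
    counts["post_graylist"] = len(calls)

    try:
        calls = ann.annotate_genes(calls, genes, cfg["annotate.gene_proximity_bp"])
    except Exception as exc:
        raise RuntimeError(f"stage 'gene filter' failed: {exc}") from exc
    counts["post_gene"] = len(calls)

    if panel is not None:
        try:
            calls = ann.annotate_population(
                calls, panel, proband_sex=proband.sex,
                loss_threshold=cfg["annotate.loss_consistency_threshold"],
                gain_threshold=cfg["annotate.gain_consistency_threshold"],
                min_interval_covered=cfg["annotate.min_interval_covered"],
            )
            calls = ann.filter_population(
                calls, cfg["annotate.population_max_frequency"])
        except Exception as exc:
            raise RuntimeError(
                f"stage 'population-frequency filter' failed: {exc}") from exc
    counts["post_frequency"] = len(calls)

    if proband_variants is not None:
        calls = [
            ann.het_screen(c, proband_variants)
            if (c.type == LOSS and c.copy_number <= 1) else c
            for c in calls
        ]

    nmother, nfather = _norm(mother), _norm(father)
    labels = {}
    phased = []
    for c in calls:
        label = ph.inheritance_by_depth(
            c, nmother, nfather,
            loss_threshold=cfg["segment.mosaic_loss_threshold"],
            gain_threshold=cfg["segment.mosaic_gain_threshold"],
        )
        if (label in (ph.DE_NOVO, ph.NOT_ASSESSABLE)
                and trio_table is not None and c.copy_number in (1, 3)):
            trio = ph.trio_from_dataframe(trio_table, interval=c.interval,
                                          copy_number=c.copy_number)
            if trio.sites:
                res = ph.phase_denovo_cnv(
                    trio, error_rate=cfg["phase.error_rate"],
                    margin=cfg["phase.ambiguity_margin_nats"])
                if res.selected is not None and not res.ambiguous:
                    suffix = "haplotype"
                    label = f"{label} ({res.selected} {suffix})"
        labels[str(c.interval)] = label
        phased.append(c.replace(inheritance=label))
    calls = sort_calls(phased, proband.layout)

    summary = CaseSummary(
        sample_id=proband.sample_id,
        stage_counts=counts,
        mosaic_count=sum(c.mosaic_flag for c in calls),
        inheritance_labels=labels,
        n_final=len(calls),
    )
    return summary, calls


def report(summary: CaseSummary, calls) -> tuple:
    """Human-readable text plus machine-readable JSON for one case."""
    lines = [f"Case {summary.sample_id}"]
    for stage in STAGES:
        if stage in summary.stage_counts:
            lines.append(f"  {stage:>16}: {summary.stage_counts[stage]} calls")
    lines.append(f"  mosaic-flagged: {summary.mosaic_count}")
    for c in calls:
        bits = [f"  {c.interval} {c.type} CN={c.copy_number}"]
        if c.depth_estimate is not None:
            bits.append(f"depth={c.depth_estimate:.2f}")
        if c.mosaic_flag:
            bits.append(f"MOSAIC(purity~{c.purity:.2f})" if c.purity else "MOSAIC")
        if c.inheritance:
            bits.append(c.inheritance)
        if c.genes:
            bits.append("genes=" + ",".join(c.genes))
        lines.append(" ".join(bits))
    return "\n".join(lines) + "\n", summary.to_json()
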