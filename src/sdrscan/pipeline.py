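"""Stage orchestration: ORF annotation -> SDR detection -> classification
-> divergence summaries, over a FASTA of candidate loci.

The pipeline is a pure function of (inputs, config): no hidden state, all
randomness comes from ``config.random_seed`` (and none of the analysis
stages is stochastic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import ElementCopy, GenomeSummary, SourceInfo, classify_copy, n_runs, summarize_genome
from .config import ROLES, RunConfig
from .divergence import mean_pairwise_identity
from .io import (
    FastaFormatError,
    FastaRecord,
    read_fasta,
    source_from_description,
    write_copy_reports,
    write_gff3,
    write_summary_tsv,
)
from .orfs import PanelProtein, annotate_orfs, read_panel, translate
from .repeats import (
    SireTemplate,
    activity_signal,
    call_boundaries,
    classify_architecture,
    detect_sire_like,
    find_repeat_pairs,
    label_terminal_repeats,
    segment_tandem,
)

logger = logging.getLogger("sdrscan")


class PipelineError(RuntimeError):
    def __init__(self, copy_id: str, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for copy {copy_id!r}: {cause}")
        self.copy_id = copy_id
        self.stage = stage


@dataclass
class PipelineResult:
    copies: list[ElementCopy]
    summary: GenomeSummary


def annotate_locus(
    locus_id: str,
    seq: str,
    panel: list[PanelProtein] | None,
    config: RunConfig,
    source: SourceInfo | None = None,
    sire_template: SireTemplate | None = None,
) -> list[ElementCopy]:
    """Annotate one candidate locus, segmenting tandem arrays first.

    Returns one ElementCopy per element-bearing segment (a plain locus
    yields one copy)."""
    try:
        pairs_full = find_repeat_pairs(
            seq, config.seed_len, config.min_repeat_len, config.max_mismatch_frac
        )
        segments = segment_tandem(len(seq), pairs_full, config)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(locus_id, "sdr_detector", exc)
    copies: list[ElementCopy] = []
    multi = len(segments) > 1
    for si, (lo, hi) in enumerate(segments):
        sub = seq[lo:hi]
        copy_id = f"{locus_id}.seg{si}" if multi else locus_id
        sub_source = None
        if source is not None:
            sub_source = SourceInfo(
                source.contig_id, source.start + lo, source.start + hi, source.contig_len
            )
        copy = ElementCopy(copy_id=copy_id, seq=sub, source=sub_source)
        try:
            copy.orfs = annotate_orfs(sub, panel, config)
        except Exception as exc:
            raise PipelineError(copy_id, "orf_annotator", exc)
        try:
            if multi:
                pairs = find_repeat_pairs(
                    sub, config.seed_len, config.min_repeat_len, config.max_mismatch_frac
                )
            else:
                pairs = pairs_full
            copy.repeat_pairs = pairs
            role_orfs = [o for o in copy.orfs if o.role in ROLES]
            anchor = None
            if role_orfs:
                anchor = (
                    min(o.start for o in role_orfs),
                    max(o.end for o in role_orfs),
                )
            copy.units = label_terminal_repeats(
                pairs, len(sub), config.terminal_window_bp, anchor
            )
            copy.architecture = classify_architecture(
                copy.units, copy.orfs, config.gap_warn_bp
            )
            copy.boundaries, copy.boundary_confidence = call_boundaries(
                len(sub), copy.units, copy.orfs
            )
            copy.activity_flag, copy.pair_identities = activity_signal(copy.units)
            copy.sire = detect_sire_like(sub, sire_template)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(copy_id, "sdr_detector", exc)
        for a, b in n_runs(sub, config.n_run_min_len):
            copy.warnings.append(f"N-run at [{a},{b})")
        try:
            classify_copy(copy, config)
        except Exception as exc:
            raise PipelineError(copy_id, "copy_classifier", exc)
        if copy.status == "inconclusive" and copy.source is not None:
            copy.warnings.append("near contig end or missing data region")
        copies.append(copy)
    return copies


def _rank_by_panel_score(copies: list[ElementCopy]) -> list[ElementCopy]:
    """'Most conserved first': rank by summed best panel scores."""

    def total(c: ElementCopy) -> float:
        return sum(
            max((h.score for h in o.panel_hits.values()), default=0.0) for o in c.orfs
        )

    return sorted(copies, key=lambda c: (-total(c), c.copy_id))


def run_pipeline(
    config: RunConfig,
    loci_path: str,
    panel_path: str | None = None,
    dataset_id: str = "dataset",
    gff3_out: str | None = None,
    tsv_out: str | None = None,
    report_out: str | None = None,
) -> PipelineResult:
    """Run all stages over a FASTA of candidate loci.

    Locus headers may carry ``loc=contig:start-end contig_len=N`` metadata
    for contig-end awareness.  Emits GFF3 / TSV / JSON artifacts when
    paths are given.  An empty copies list yields an all-zero summary.
    """
    try:
        records = read_fasta(loci_path)
    except FastaFormatError:
        with open(loci_path) as fh:
            if fh.read().strip():
                raise
        records = []  # a present-but-empty loci file is a valid zero-copy dataset
    panel = read_panel(panel_path) if panel_path else None
    copies: list[ElementCopy] = []
    for rec in records:
        source = source_from_description(rec.description)
        logger.info("annotating locus %s (%d bp)", rec.id, len(rec.seq))
        copies.extend(annotate_locus(rec.id, rec.seq, panel, config, source))
    for copy in copies:
        for w in copy.warnings:
            logger.warning("%s: %s", copy.copy_id, w)
    if config.max_copies_per_dataset is not None:
        copies = _rank_by_panel_score(copies)[: config.max_copies_per_dataset]

    identity_nt = None
    identity_aa: dict[str, tuple[float, int, int]] = {}
    aligned = [
        c.seq for c in copies if c.status in ("putative_autonomous", "potentially_encoding")
    ]
    if len(aligned) >= 2:
        identity_nt = mean_pairwise_identity(
            aligned, "nucleotide", config.mask_window, config.mask_gap_frac
        )
    for role in ROLES:
        prots = []
        for c in copies:
            for o in c.orfs:
                if o.role == role and o.frameshift_partner is None and o.protein:
                    prots.append(o.protein)
                    break
        if len(prots) >= 2:
            res = mean_pairwise_identity(
                prots, "amino_acid", config.mask_window, config.mask_gap_frac
            )
            if res is not None:
                identity_aa[role] = res

    summary = summarize_genome(copies, dataset_id, config, identity_nt, identity_aa)
    if gff3_out:
        write_gff3(copies, gff3_out)
    if tsv_out:
        write_summary_tsv([summary], tsv_out)
    if report_out:
        write_copy_reports(copies, report_out)
    return PipelineResult(copies, summary)
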