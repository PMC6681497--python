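"""FASTA / GFF3 / TSV / JSON input and output.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive.  FASTA records keep their identifiers verbatim and are
normalized to uppercase; ambiguity codes are retained.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ElementCopy, GenomeSummary, SourceInfo


class FastaFormatError(ValueError):
    pass


@dataclass
class FastaRecord:
    id: str
    description: str
    seq: str


_LOC_RE = re.compile(r"loc=(\S+):(\d+)-(\d+)")
_CLEN_RE = re.compile(r"contig_len=(\d+)")


def read_fasta(path: str) -> list[FastaRecord]:
    """Read FASTA records, validating structure with line numbers.

    Lowercase is normalized to uppercase; identifiers and ambiguity codes
    are preserved verbatim.
    """
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    seen_record = False
    expecting_seq_for: int | None = None
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            if len(line[1:].strip()) == 0:
                raise FastaFormatError(f"{path}: empty FASTA header at line {ln}")
            if expecting_seq_for is not None:
                raise FastaFormatError(
                    f"{path}: record starting at line {expecting_seq_for} has no sequence"
                )
            seen_record = True
            expecting_seq_for = ln
        else:
            if not seen_record:
                raise FastaFormatError(
                    f"{path}: sequence data before any header at line {ln}"
                )
            expecting_seq_for = None
    if not seen_record:
        raise FastaFormatError(f"{path}: no FASTA records found (empty file?)")
    if expecting_seq_for is not None:
        raise FastaFormatError(
            f"{path}: record starting at line {expecting_seq_for} has no sequence"
        )
    return [
        FastaRecord(rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(records: list[FastaRecord] | list[tuple[str, str]], path: str) -> None:
    out = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            out.append(
                SeqRecord(Seq(rec.seq), id=rec.id, description=(
                    rec.description[len(rec.id):].strip()
                    if rec.description.startswith(rec.id)
                    else rec.description
                ))
            )
        else:
            name, seq = rec
            out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, path, "fasta")


def source_from_description(description: str) -> SourceInfo | None:
    """Parse ``loc=contig:start-end contig_len=N`` locus metadata from a
    FASTA description (0-based half-open coordinates)."""
    m = _LOC_RE.search(description)
    if not m:
        return None
    c = _CLEN_RE.search(description)
    contig_len = int(c.group(1)) if c else int(m.group(3))
    return SourceInfo(m.group(1), int(m.group(2)), int(m.group(3)), contig_len)


# ---------------------------------------------------------------------------
# GFF3


def _esc(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(copies: list[ElementCopy], path: str, source: str = "sdrscan") -> None:
    """One ``mobile_genetic_element`` feature per copy with ORF and
    repeat-unit children; coordinates 1-based inclusive on the copy."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for copy in copies:
            seqid = copy.copy_id
            lo, hi = copy.boundaries if copy.boundaries is not None else (0, len(copy.seq))
            if hi <= lo:
                lo, hi = 0, max(1, len(copy.seq))
            eid = f"{seqid}.element"
            attrs = [f"ID={_esc(eid)}"]
            if copy.status:
                attrs.append(f"status={_esc(copy.status)}")
            if copy.architecture is not None:
                attrs.append(f"architecture={_esc(copy.architecture.arch_class)}")
                if copy.architecture.layout:
                    attrs.append(f"layout={_esc(copy.architecture.layout)}")
            attrs.append(f"boundary_confidence={_esc(copy.boundary_confidence)}")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        "mobile_genetic_element",
                        str(lo + 1),
                        str(hi),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for k, orf in enumerate(copy.orfs):
                attrs = [
                    f"ID={_esc(f'{seqid}.orf{k}')}",
                    f"Parent={_esc(eid)}",
                    f"role={_esc(orf.role)}",
                    f"evidence={_esc(orf.role_evidence)}",
                    f"protein_len={orf.protein_len_aa}",
                    f"frame={orf.frame}",
                ]
                if orf.frameshift_partner is not None:
                    attrs.append(f"frameshift_partner={_esc(f'{seqid}.orf{orf.frameshift_partner}')}")
                if orf.motifs:
                    attrs.append(
                        "motifs=" + _esc(",".join(m.name for m in orf.motifs))
                    )
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            source,
                            "open_reading_frame",
                            str(orf.start + 1),
                            str(orf.end),
                            ".",
                            orf.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
            for k, u in enumerate(copy.units):
                attrs = [
                    f"ID={_esc(f'{seqid}.rep{k}')}",
                    f"Parent={_esc(eid)}",
                    f"label={_esc(u.label)}",
                ]
                if u.partner:
                    attrs.append(f"partner={_esc(u.partner)}")
                if u.pair_identity_pct is not None:
                    attrs.append(f"pair_identity={u.pair_identity_pct:.2f}")
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            source,
                            "repeat_unit",
                            str(u.start + 1),
                            str(u.end),
                            ".",
                            "+",
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# summary TSV / per-copy JSON


SUMMARY_COLUMNS = [
    "dataset_id",
    "n_analyzed",
    "n_ge1_encoding_orf",
    "n_three_orfs",
    "n_with_domain_support",
    "n_with_sdrs",
    "sdr_modal_class",
    "sdr_sizes_identity",
    "n_autonomous",
    "identity_nt",
    "identity_aa",
    "status_counts",
]


def _fmt_identity(t: tuple[float, int, int] | None) -> str:
    if t is None:
        return "na"
    mean, n, length = t
    return f"{mean:.1f}% (n={n}, len={length})"


def summary_to_row(s: GenomeSummary) -> dict[str, str]:
    return {
        "dataset_id": s.dataset_id,
        "n_analyzed": str(s.n_analyzed),
        "n_ge1_encoding_orf": str(s.n_ge1_encoding_orf),
        "n_three_orfs": str(s.n_three_orfs),
        "n_with_domain_support": str(s.n_with_domain_support),
        "n_with_sdrs": str(s.n_with_sdrs),
        "sdr_modal_class": s.sdr_modal_class,
        "sdr_sizes_identity": " | ".join(s.sdr_sizes_identity) or "na",
        "n_autonomous": str(s.n_autonomous),
        "identity_nt": _fmt_identity(s.identity_nt),
        "identity_aa": "; ".join(
            f"{role}: {_fmt_identity(v)}" for role, v in sorted(s.identity_aa.items())
        )
        or "na",
        "status_counts": ",".join(
            f"{k}:{v}" for k, v in sorted(s.status_counts.items())
        ),
    }


def write_summary_tsv(summaries: list[GenomeSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = summary_to_row(s)
            fh.write("\t".join(row[c] for c in SUMMARY_COLUMNS) + "\n")


def copy_report(copy: ElementCopy) -> dict:
    return {
        "copy_id": copy.copy_id,
        "length": len(copy.seq),
        "status": copy.status,
        "boundaries": list(copy.boundaries) if copy.boundaries else None,
        "boundary_confidence": copy.boundary_confidence,
        "architecture": copy.architecture.arch_class if copy.architecture else None,
        "layout": copy.architecture.layout if copy.architecture else None,
        "distance_flags": copy.architecture.distance_flags if copy.architecture else [],
        "activity_flag": copy.activity_flag,
        "pair_identities": copy.pair_identities,
        "warnings": copy.warnings,
        "orfs": [
            {
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "frame": o.frame,
                "protein_len_aa": o.protein_len_aa,
                "role": o.role,
                "evidence": o.role_evidence,
                "panel_score": o.panel_score,
                "panel_hit": o.panel_hit,
                "motifs": [m.name for m in o.motifs],
                "frameshift_partner": o.frameshift_partner,
                "single_orf_layout": o.single_orf_layout,
            }
            for o in copy.orfs
        ],
        "repeat_units": [
            {
                "label": u.label,
                "start": u.start,
                "end": u.end,
                "partner": u.partner,
                "pair_identity_pct": u.pair_identity_pct,
            }
            for u in copy.units
        ],
    }


def write_copy_reports(copies: list[ElementCopy], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([copy_report(c) for c in copies], fh, indent=1, sort_keys=True)
        fh.write("\n")
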