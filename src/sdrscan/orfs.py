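"""Six-frame ORF discovery, translation, role assignment and motif scanning.

The elements targeted here carry up to three long ORFs: a poorly conserved
gag-like ORF (often bearing a CX2CX4HX4C zinc-knuckle, the "CH-box"), a
tyrosine recombinase (YR), and a reverse transcriptase / RNase H ORF
(RT/RH) that frequently overlaps the YR ORF in a different reading frame.
YR and RT/RH are recognized by similarity to a labeled reference protein
panel; gag-like is recognized primarily by position — immediately upstream
of, or overlapping, the YR ORF.  Copies damaged by a single-base indel
present the two halves of one gene as separate ORFs in different frames;
such fragments are linked into frameshift pairs via their panel hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .config import ROLES, RunConfig

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)

CHBOX_PATTERN = re.compile(r"(?=(C.{2}C.{4}H.{4}C))")

NT_ALPHABET = frozenset("ACGTN")


class AlphabetError(ValueError):
    pass


class PanelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# translation


def translate(dna: str) -> str:
    """Standard-code translation of an in-frame nucleotide string.

    Trailing bases that do not fill a codon are ignored; a terminal stop is
    dropped; internal stops become ``*``.  A codon containing ``N`` becomes
    ``X`` unless every resolution gives the same amino acid (e.g. ``GGN``).
    """
    s = dna.upper()
    bad = set(s) - NT_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            aas.append(_resolve_ambiguous(codon))
        elif codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(_CODON_TO_AA[codon])
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def _resolve_ambiguous(codon: str) -> str:
    opts = {""}
    for base in codon:
        alts = "ACGT" if base == "N" else base
        opts = {p + b for p in opts for b in alts}
    aas = {"*" if c in STOP_CODONS else _CODON_TO_AA[c] for c in opts}
    return aas.pop() if len(aas) == 1 else "X"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# annotations


@dataclass
class MotifHit:
    name: str
    aa_position: int
    matched_span: str


@dataclass
class PanelHit:
    """Best local alignment of an ORF's protein against one panel protein."""

    panel_name: str
    role: str
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    target_len: int

    @property
    def target_coverage(self) -> float:
        return (self.target_span[1] - self.target_span[0]) / self.target_len


@dataclass
class OrfAnnotation:
    """One ORF, with coordinates on the forward strand of its copy."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str
    has_stop: bool = True
    ambiguous: bool = False
    role: str = "unknown"
    role_evidence: str = "none"  # panel_alignment | positional | none
    panel_score: float | None = None
    panel_hit: str | None = None
    panel_hits: dict[str, PanelHit] = field(default_factory=dict)
    motifs: list[MotifHit] = field(default_factory=list)
    frameshift_partner: int | None = None  # index into the copy's ORF list
    single_orf_layout: bool = False

    @property
    def protein_len_aa(self) -> int:
        return len(self.protein)

    @property
    def length(self) -> int:
        return self.end - self.start

    def meets_size(self, min_aa: dict[str, int]) -> bool:
        """Strict size criterion for the assigned role."""
        if self.role not in min_aa:
            return False
        return self.protein_len_aa > min_aa[self.role]


@dataclass
class PanelProtein:
    name: str
    role: str
    seq: str


def read_panel(path: str) -> list[PanelProtein]:
    """Read a reference protein panel whose headers carry ``role=...`` tags."""
    panel = []
    for rec in SeqIO.parse(path, "fasta"):
        m = re.search(r"role=(\w+)", rec.description)
        if not m or m.group(1) not in ROLES:
            raise PanelError(
                f"panel record {rec.id!r} lacks a role=gag_like|yr|rt_rh tag"
            )
        panel.append(PanelProtein(rec.id, m.group(1), str(rec.seq).upper()))
    return panel


# ---------------------------------------------------------------------------
# ORF discovery


def find_orfs(seq: str, min_aa: int) -> list[OrfAnnotation]:
    """All maximal ATG-to-stop ORFs of >= min_aa codons, over six frames.

    Per (frame, stop) the longest ORF (first ATG after the previous stop)
    is reported; an ORF running off the sequence end without a stop is
    reported with ``has_stop=False``.  Coordinates are always given on the
    forward strand; ORFs overlapping an N become ``ambiguous``.
    """
    s = seq.upper()
    bad = set(s) - NT_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    n = len(s)
    out: list[OrfAnnotation] = []
    for strand, text in (("+", s), ("-", revcomp(s))):
        for frame in range(3):
            start_codon: int | None = None
            ncodons = (n - frame) // 3
            for ci in range(ncodons):
                pos = frame + 3 * ci
                codon = text[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_codon is not None:
                        out.extend(
                            _emit_orf(text, n, strand, frame, start_codon, ci, True, min_aa)
                        )
                        start_codon = None
                elif start_codon is None and codon == "ATG":
                    start_codon = ci
            if start_codon is not None:
                out.extend(
                    _emit_orf(text, n, strand, frame, start_codon, ncodons, False, min_aa)
                )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _emit_orf(text, n, strand, frame, start_ci, stop_ci, has_stop, min_aa):
    plen = stop_ci - start_ci
    if plen < min_aa:
        return
    lo = frame + 3 * start_ci
    hi = frame + 3 * (stop_ci + (1 if has_stop else 0))
    nt = text[lo:hi]
    if strand == "+":
        start, end = lo, hi
    else:
        start, end = n - hi, n - lo
    yield OrfAnnotation(
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        protein=translate(nt),
        has_stop=has_stop,
        ambiguous="N" in nt,
    )


# ---------------------------------------------------------------------------
# motif scanning


def scan_chbox(protein: str) -> list[MotifHit]:
    """All (overlapping) CX2CX4HX4C zinc-knuckle matches, 0-based positions."""
    return [
        MotifHit("CH_box", m.start(), m.group(1))
        for m in CHBOX_PATTERN.finditer(protein)
    ]


# ---------------------------------------------------------------------------
# protein similarity


@dataclass
class LocalAlignment:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


def smith_waterman(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal local alignment under affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST
    convention).  Score 0 with empty spans means the best local alignment
    is empty.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    try:
        subst = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    score = aligner.score(query, target)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0))
    aln = aligner.align(query, target)[0]
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return LocalAlignment(float(score), qspan, tspan)


# ---------------------------------------------------------------------------
# role assignment


def _compute_panel_hits(orfs: list[OrfAnnotation], panel: list[PanelProtein]) -> None:
    for orf in orfs:
        if not orf.protein:
            continue
        for prot in panel:
            aln = smith_waterman(orf.protein, prot.seq)
            if aln.score <= 0:
                continue
            best = orf.panel_hits.get(prot.role)
            if best is None or aln.score > best.score:
                orf.panel_hits[prot.role] = PanelHit(
                    prot.name,
                    prot.role,
                    aln.score,
                    aln.query_span,
                    aln.target_span,
                    len(prot.seq),
                )


def assign_roles(
    orfs: list[OrfAnnotation],
    panel: list[PanelProtein] | None,
    config: RunConfig,
) -> list[OrfAnnotation]:
    """Assign gag_like / yr / rt_rh roles to a copy's ORFs, in place.

    YR and RT/RH come from the best panel hit above the score floor; at
    most one ORF per role (the top scorer).  A still-unassigned ORF that
    sits immediately upstream of, or overlaps, the YR ORF and exceeds the
    gag-like size threshold is called gag_like on positional evidence.  A
    single ORF with floor-passing hits in two or more role classes is
    flagged as a single-ORF layout.
    """
    if panel:
        _compute_panel_hits(orfs, panel)
        floor = config.panel_score_floor
        # top scorer per role wins; single-ORF layouts keep all their hits
        for role in ROLES:
            candidates = [
                o for o in orfs if role in o.panel_hits and o.panel_hits[role].score >= floor
            ]
            if not candidates:
                continue
            best = max(candidates, key=lambda o: (o.panel_hits[role].score, -o.start))
            if best.role == "unknown" or o_score(best, role) > o_score(best, best.role):
                best.role = role
                best.role_evidence = "panel_alignment"
                best.panel_score = best.panel_hits[role].score
                best.panel_hit = best.panel_hits[role].panel_name
        for orf in orfs:
            strong = [r for r, h in orf.panel_hits.items() if h.score >= floor]
            if len(strong) >= 2:
                orf.single_orf_layout = True
    # positional gag-like
    yr = next((o for o in orfs if o.role == "yr"), None)
    if yr is not None and not any(o.role == "gag_like" for o in orfs):
        cands = []
        for orf in orfs:
            if orf.role != "unknown" or orf.strand != yr.strand:
                continue
            if orf.protein_len_aa <= config.min_aa["gag_like"]:
                continue
            if yr.strand == "+":
                upstream, gap = orf.start < yr.start, yr.start - orf.end
            else:
                upstream, gap = orf.end > yr.end, orf.start - yr.end
            if upstream and gap <= config.positional_gap_max_bp:
                cands.append((max(gap, 0), orf))
        if cands:
            _, gag = min(cands, key=lambda t: (t[0], t[1].start))
            gag.role = "gag_like"
            gag.role_evidence = "positional"
    return orfs


def o_score(orf: OrfAnnotation, role: str) -> float:
    hit = orf.panel_hits.get(role)
    return hit.score if hit else 0.0


# ---------------------------------------------------------------------------
# frameshift pairing


def detect_frameshift_pairs(
    orfs: list[OrfAnnotation], config: RunConfig
) -> list[tuple[int, int]]:
    """Link two-fragment ORFs produced by a single frameshift.

    Two same-strand ORFs in different frames, separated by at most
    ``frameshift_gap_max_bp`` (small overlaps allowed), whose best hits on
    the same panel protein cover adjacent, minimally overlapping target
    intervals, are linked as one frameshifted gene and both inherit its
    role.  Returns the linked index pairs (upstream, downstream).
    """
    pairs: list[tuple[int, int]] = []
    max_olap_nt = 3 * config.frameshift_max_overlap_aa
    for i, u in enumerate(orfs):
        for j, v in enumerate(orfs):
            if i == j or u.strand != v.strand or u.frame == v.frame:
                continue
            if u.frameshift_partner is not None or v.frameshift_partner is not None:
                continue
            if u.strand == "+":
                if u.start >= v.start:
                    continue
                gap = v.start - u.end
            else:
                if u.end <= v.end:
                    continue
                gap = u.start - v.end
            if gap > config.frameshift_gap_max_bp or gap < -max_olap_nt:
                continue
            for role in ROLES:
                hu, hv = u.panel_hits.get(role), v.panel_hits.get(role)
                if hu is None or hv is None:
                    continue
                if hu.panel_name != hv.panel_name:
                    continue
                # both fragments must be credible hits on this protein
                if hu.score < config.panel_score_floor or hv.score < config.panel_score_floor:
                    continue
                # never hijack an ORF whose assigned role is better supported
                if any(
                    o.role not in ("unknown", role)
                    and o_score(o, o.role) > o_score(o, role)
                    for o in (u, v)
                ):
                    continue
                # u covers the earlier part of the panel protein
                if not (
                    hv.target_span[0] >= hu.target_span[1] - config.frameshift_max_overlap_aa
                    and hv.target_span[1] > hu.target_span[1]
                    and hv.target_span[0] > hu.target_span[0]
                ):
                    continue
                u.frameshift_partner = j
                v.frameshift_partner = i
                for o, h in ((u, hu), (v, hv)):
                    o.role = role
                    o.role_evidence = "panel_alignment"
                    o.panel_score = h.score
                    o.panel_hit = h.panel_name
                pairs.append((i, j))
                break
    return pairs


def annotate_orfs(
    seq: str, panel: list[PanelProtein] | None, config: RunConfig
) -> list[OrfAnnotation]:
    """find_orfs + motif scan + role assignment + frameshift pairing."""
    orfs = find_orfs(seq, config.orf_scan_min_aa)
    for orf in orfs:
        orf.motifs = scan_chbox(orf.protein)
    assign_roles(orfs, panel, config)
    detect_frameshift_pairs(orfs, config)
    return orfs
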