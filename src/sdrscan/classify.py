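"""Copy-status classification and per-dataset summaries.

A copy is *putative autonomous* when it carries the three expected ORFs
above their role size thresholds plus direct repeats; *potentially
encoding* with the three ORFs but no repeats; *SIRE-like remnant* when it
matches only the terminal repeat region of a full element; *inconclusive*
when assembly artifacts (contig-end proximity, N-runs over expected
regions) prevent a verdict; otherwise *degenerate*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import ROLES, RunConfig
from .intervals import intervals_overlap
from .orfs import OrfAnnotation
from .repeats import RepeatPair, RepeatUnit, SdrArchitecture, SireReport

STATUSES = (
    "putative_autonomous",
    "potentially_encoding",
    "degenerate",
    "inconclusive",
    "sire_like_remnant",
)

_STATUS_RANK = {"putative_autonomous": 2, "potentially_encoding": 1, "degenerate": 0}

_N_RUN = re.compile(r"N+")


@dataclass
class SourceInfo:
    """Where a copy's locus sits on its source contig."""

    contig_id: str
    start: int  # locus start on the contig, 0-based
    end: int
    contig_len: int


@dataclass
class ElementCopy:
    copy_id: str
    seq: str
    orfs: list[OrfAnnotation] = field(default_factory=list)
    repeat_pairs: list[RepeatPair] = field(default_factory=list)
    units: list[RepeatUnit] = field(default_factory=list)
    architecture: SdrArchitecture | None = None
    boundaries: tuple[int, int] | None = None
    boundary_confidence: str = "none"
    status: str | None = None
    sire: SireReport | None = None
    activity_flag: bool | None = None
    pair_identities: dict[str, float] = field(default_factory=dict)
    source: SourceInfo | None = None
    warnings: list[str] = field(default_factory=list)

    def role_orfs(self) -> dict[str, list[OrfAnnotation]]:
        out: dict[str, list[OrfAnnotation]] = {r: [] for r in ROLES}
        for o in self.orfs:
            if o.role in out:
                out[o.role].append(o)
        return out

    def encoding_roles(self, min_aa: dict[str, int], n_run_min_len: int | None = None) -> set[str]:
        """Roles with an intact (unframeshifted, fully readable) ORF above
        its size threshold.  An ORF interrupted by a long N-run cannot be
        verified and does not count.  A single-ORF layout with
        floor-passing hits covering several roles contributes each
        well-covered role."""
        roles: set[str] = set()
        long_n: list[tuple[int, int]] = (
            n_runs(self.seq, n_run_min_len) if n_run_min_len else []
        )
        for o in self.orfs:
            if o.frameshift_partner is not None or not o.has_stop:
                continue
            if any(intervals_overlap(a, b, o.start, o.end) for a, b in long_n):
                continue
            if o.single_orf_layout:
                for r, hit in o.panel_hits.items():
                    if hit.target_coverage >= 0.8 and o.protein_len_aa > min_aa[r]:
                        roles.add(r)
            elif o.role in ROLES and o.meets_size(min_aa):
                roles.add(o.role)
        return roles


def n_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in _N_RUN.finditer(seq.upper())
        if m.end() - m.start() >= min_len
    ]


def _near_contig_end(copy: ElementCopy, config: RunConfig) -> bool:
    if copy.source is None:
        return False  # no contig context: cannot claim end proximity
    # a locus abutting a contig end had its flank clipped: part of the
    # copy's evidence may lie off-contig
    if copy.source.start == 0 or copy.source.end >= copy.source.contig_len:
        return True
    lo, hi = copy.boundaries if copy.boundaries is not None else (0, len(copy.seq))
    w = config.contig_end_window_bp
    g_lo = copy.source.start + lo
    g_hi = copy.source.start + hi
    return g_lo < w or copy.source.contig_len - g_hi < w


def _n_run_hits_features(copy: ElementCopy, config: RunConfig) -> bool:
    runs = n_runs(copy.seq, config.n_run_min_len)
    if not runs:
        return False
    feats = [(o.start, o.end) for o in copy.orfs if o.role in ROLES]
    feats += [(u.start, u.end) for u in copy.units]
    if copy.boundaries is not None:
        feats.append(copy.boundaries)
    if not feats:
        return True  # nothing annotated and missing data: cannot conclude
    return any(
        intervals_overlap(a, b, fa, fb) for a, b in runs for fa, fb in feats
    )


def classify_copy(copy: ElementCopy, config: RunConfig) -> str:
    """Assign exactly one status to an annotated copy.

    Requires orfs/units/boundaries to be present (annotation already
    run).  Positive evidence wins: three encoding roles plus labeled
    repeats is autonomous even near a contig end; assembly caveats make a
    copy inconclusive only when they could hide the missing evidence.
    """
    if copy.architecture is None and copy.units is None:
        raise ValueError(f"copy {copy.copy_id} has not been annotated")
    roles = copy.encoding_roles(config.min_aa, config.n_run_min_len)
    has_repeats = any(u.label != "unlabeled" for u in copy.units)
    if roles == set(ROLES) and has_repeats:
        copy.status = "putative_autonomous"
    elif roles == set(ROLES):
        copy.status = "potentially_encoding"
    elif copy.sire is not None and copy.sire.is_sire_like:
        copy.status = "sire_like_remnant"
    elif _n_run_hits_features(copy, config) or _near_contig_end(copy, config):
        copy.status = "inconclusive"
    else:
        copy.status = "degenerate"
    return copy.status


@dataclass
class GenomeSummary:
    dataset_id: str
    n_analyzed: int = 0
    n_ge1_encoding_orf: int = 0
    n_three_orfs: int = 0
    n_with_domain_support: int = 0
    n_with_sdrs: int = 0
    sdr_modal_class: str = "none"
    sdr_structures: list[str] = field(default_factory=list)
    sdr_sizes_identity: list[str] = field(default_factory=list)
    n_autonomous: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)
    identity_nt: tuple[float, int, int] | None = None  # (mean %, n, aln len)
    identity_aa: dict[str, tuple[float, int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        counts = (
            self.n_ge1_encoding_orf,
            self.n_three_orfs,
            self.n_with_domain_support,
            self.n_with_sdrs,
            self.n_autonomous,
        )
        if any(c > self.n_analyzed for c in counts):
            raise ValueError("summary counts exceed n_analyzed")
        if self.n_autonomous > self.n_with_sdrs or self.n_autonomous > self.n_three_orfs:
            raise ValueError("autonomous count exceeds its prerequisites")


def summarize_genome(
    copies: list[ElementCopy],
    dataset_id: str,
    config: RunConfig,
    identity_nt: tuple[float, int, int] | None = None,
    identity_aa: dict[str, tuple[float, int, int]] | None = None,
) -> GenomeSummary:
    """Aggregate classified copies into a per-dataset table row.

    Identity summaries (mean pairwise nucleotide identity, per-role amino
    acid identity with n and alignment length) are computed upstream by
    the divergence toolkit and passed in; counting columns mirror the
    per-genome copy tables:  an ORF counts toward the "encoding" columns
    when it passes its role size threshold, panel/domain support is
    tallied separately.
    """
    s = GenomeSummary(dataset_id=dataset_id, n_analyzed=len(copies))
    arch_sizes: list[str] = []
    for copy in copies:
        roles = copy.encoding_roles(config.min_aa, config.n_run_min_len)
        if roles:
            s.n_ge1_encoding_orf += 1
        if roles == set(ROLES):
            s.n_three_orfs += 1
            support = all(
                any(
                    o.panel_hits.get(r) is not None
                    and o.panel_hits[r].score >= config.panel_score_floor
                    for o in copy.orfs
                )
                for r in ("yr", "rt_rh")
            )
            if support:
                s.n_with_domain_support += 1
        labeled = [u for u in copy.units if u.label != "unlabeled"]
        if labeled:
            s.n_with_sdrs += 1
            if copy.architecture is not None:
                s.sdr_structures.append(copy.architecture.arch_class)
            pairs = {}
            for u in labeled:
                if u.label in ("A1", "B1"):
                    pairs[u.label[0]] = (u.length, u.pair_identity_pct)
            desc = "; ".join(
                f"{k}: {v[0]} bp, {v[1]:.0f}%" for k, v in sorted(pairs.items())
            )
            if desc:
                arch_sizes.append(desc)
        if copy.status == "putative_autonomous":
            s.n_autonomous += 1
        s.status_counts[copy.status or "unclassified"] = (
            s.status_counts.get(copy.status or "unclassified", 0) + 1
        )
    if s.sdr_structures:
        s.sdr_modal_class = max(
            sorted(set(s.sdr_structures)), key=s.sdr_structures.count
        )
    s.sdr_sizes_identity = arch_sizes
    s.identity_nt = identity_nt
    s.identity_aa = identity_aa or {}
    s.validate()
    return s
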