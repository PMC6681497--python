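"""De novo split-direct-repeat (SDR) detection and architecture typing.

VIPER/TATE-like tyrosine-recombinase retrotransposons terminate not in
LTRs but in *split direct repeats*: one repeat unit (A1) at the 5' end and
its partner (A2) at the 3' end, usually interleaved with a second pair
(B1/B2).  The canonical layout is ``A1 ... B1 A2 B2``; a variant
``A1 ... B1 B2 A2`` occurs.  Detection is by self-comparison of the copy
(the sequence aligned against itself), mirroring a blastn query-equals-
subject screen, but with a transparent model: exact k-mer seeding on a
diagonal followed by ungapped extension under a mismatch-fraction budget.

Reported repeats are anchored: each unit must begin and end with
``seed_len`` exact matches, so a repeat planted with clean ends is
recovered with zero-bp boundary error even when chance matches continue
into the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import RunConfig
from .orfs import OrfAnnotation

ARCH_CANONICAL = "canonical_B1A2B2"
ARCH_VARIANT = "variant_B1B2A2"
ARCH_A_ONLY = "A_pair_only"
ARCH_NONE = "none"
ARCH_COMPLEX = "complex"


@dataclass(frozen=True)
class RepeatPair:
    """An ungapped direct repeat: seq[i:i+length] ~ seq[j:j+length], i < j.

    When ``length > diagonal`` the two units overlap — the signature of a
    tandem array (a sequence similar to itself at a period shorter than
    the match).  Such pairs drive tandem segmentation but are not terminal
    repeat units.
    """

    i: int
    j: int
    length: int
    mismatches: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * (1.0 - self.mismatches / self.length)

    @property
    def diagonal(self) -> int:
        return self.j - self.i

    @property
    def units_overlap(self) -> bool:
        return self.length > self.diagonal


@dataclass
class RepeatUnit:
    label: str  # A1 | A2 | B1 | B2 | unlabeled
    start: int
    end: int
    partner: str | None = None
    pair_identity_pct: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SdrArchitecture:
    layout: str
    arch_class: str
    distance_flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# repeat-pair discovery


def find_repeat_pairs(
    seq: str,
    seed_len: int = 12,
    min_repeat_len: int = 50,
    max_mismatch_frac: float = 0.1,
) -> list[RepeatPair]:
    """All maximal anchored direct-repeat pairs of the sequence with itself.

    Matches live on diagonals ``d = j - i`` of the self-comparison.  A
    candidate is an interval that starts and ends with an exact run of
    ``seed_len`` matches (the anchors; exact k-mer seeds by construction)
    and whose overall mismatch fraction is at most ``max_mismatch_frac``.
    Reported pairs are the maximal candidates: those not contained in
    another candidate on the same diagonal.  Anchoring means extension
    between and beyond seeds is bounded by the mismatch budget, and a
    repeat planted with clean ends is recovered exactly.
    """
    s = seq.upper()
    n = len(s)
    if n < 2 * min_repeat_len or n < seed_len:
        return []
    # exact k-mer seeds -> candidate diagonals
    index: dict[str, list[int]] = {}
    for p in range(n - seed_len + 1):
        index.setdefault(s[p : p + seed_len], []).append(p)
    diagonals: set[int] = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                diagonals.add(positions[b] - positions[a])
    pairs: list[RepeatPair] = []
    for d in sorted(diagonals):
        if d < 1:
            continue
        pairs.extend(
            _scan_diagonal(s, n, d, seed_len, min_repeat_len, max_mismatch_frac)
        )
    pairs.sort(key=lambda p: (p.i, p.j, p.length))
    return pairs


def _match_runs(m: list[bool], k: int) -> list[tuple[int, int]]:
    """Maximal runs of >= k consecutive matches in a mismatch vector."""
    runs: list[tuple[int, int]] = []
    start = None
    for p, mm in enumerate(m):
        if not mm:
            if start is None:
                start = p
        else:
            if start is not None and p - start >= k:
                runs.append((start, p))
            start = None
    if start is not None and len(m) - start >= k:
        runs.append((start, len(m)))
    return runs


def _scan_diagonal(s, n, d, seed_len, min_repeat_len, frac):
    """Maximal anchored candidate intervals on one diagonal."""
    m = [s[i] != s[i + d] for i in range(n - d)]
    runs = _match_runs(m, seed_len)
    if not runs:
        return []
    prefix = [0]
    for mm in m:
        prefix.append(prefix[-1] + (1 if mm else 0))
    candidates: list[tuple[int, int]] = []
    for ri, (a, _) in enumerate(runs):
        for rj in range(ri, len(runs)):
            b = runs[rj][1]
            if b - a < min_repeat_len:
                continue
            if prefix[b] - prefix[a] <= frac * (b - a):
                candidates.append((a, b))
    kept = [
        (a, b)
        for a, b in candidates
        if not any(
            a2 <= a and b <= b2 and (a2, b2) != (a, b) for a2, b2 in candidates
        )
    ]
    return [
        RepeatPair(a, a + d, b - a, prefix[b] - prefix[a]) for a, b in sorted(kept)
    ]


# ---------------------------------------------------------------------------
# terminal labeling


def label_terminal_repeats(
    pairs: list[RepeatPair],
    seq_len: int,
    terminal_window_bp: int,
    anchor: tuple[int, int] | None = None,
) -> list[RepeatUnit]:
    """Label terminal repeat pairs as A1/A2 and B1/B2.

    Pairs with at least one unit inside a terminal window are retained.
    Windows are measured from the sequence ends, or — when the copy was
    retrieved with long flanks — from an ``anchor`` interval (normally the
    role-ORF span), since the repeats are terminal with respect to the
    element, not the retrieved locus.  The pair whose 5'-most unit lies
    nearest the 5' terminus is the A pair (ties broken by maximal
    length x identity); among the remaining terminal pairs the one
    reaching nearest the 3' terminus is the B pair.  Units of further
    terminal pairs stay unlabeled.
    """
    w = terminal_window_bp
    if anchor is None:
        lo5, hi5 = 0, w
        lo3, hi3 = seq_len - w, seq_len
    else:
        lo5, hi5 = anchor[0] - w, anchor[0]
        lo3, hi3 = anchor[1], anchor[1] + w

    def in_window(u_start: int, u_end: int) -> bool:
        return (lo5 <= u_start < hi5) or (lo3 < u_end <= hi3)

    terminal = [
        p
        for p in pairs
        if not p.units_overlap
        # a unit longer than the terminal window is not a terminal repeat
        # (it is element-scale similarity, e.g. between neighboring copies)
        and p.length <= w
        and (in_window(p.i, p.i + p.length) or in_window(p.j, p.j + p.length))
    ]
    units: list[RepeatUnit] = []
    if not terminal:
        return units
    a_pair = min(
        terminal, key=lambda p: (p.i, -(p.length * p.identity_pct), p.j)
    )
    ident = a_pair.identity_pct
    units.append(RepeatUnit("A1", a_pair.i, a_pair.i + a_pair.length, "A2", ident))
    units.append(RepeatUnit("A2", a_pair.j, a_pair.j + a_pair.length, "A1", ident))
    rest = [p for p in terminal if p is not a_pair]
    if rest:
        b_pair = max(
            rest, key=lambda p: (p.j + p.length, p.length * p.identity_pct, -p.i)
        )
        ident = b_pair.identity_pct
        units.append(RepeatUnit("B1", b_pair.i, b_pair.i + b_pair.length, "B2", ident))
        units.append(RepeatUnit("B2", b_pair.j, b_pair.j + b_pair.length, "B1", ident))
        for p in rest:
            if p is b_pair:
                continue
            units.append(RepeatUnit("unlabeled", p.i, p.i + p.length))
            units.append(RepeatUnit("unlabeled", p.j, p.j + p.length))
    units.sort(key=lambda u: (u.start, u.end))
    return units


# ---------------------------------------------------------------------------
# architecture


def classify_architecture(
    units: list[RepeatUnit],
    orfs: list[OrfAnnotation],
    gap_warn_bp: int = 1000,
) -> SdrArchitecture:
    """Classify the ordered repeat layout and flag unusual ORF-repeat gaps."""
    labeled = sorted(
        (u for u in units if u.label != "unlabeled"), key=lambda u: u.start
    )
    if not labeled:
        return SdrArchitecture("", ARCH_NONE)
    order = [u.label for u in labeled]
    labels = set(order)
    if labels == {"A1", "A2"}:
        arch = ARCH_A_ONLY
    elif labels == {"A1", "A2", "B1", "B2"} and order[0] == "A1":
        tail = order[1:]
        if tail == ["B1", "A2", "B2"]:
            arch = ARCH_CANONICAL
        elif tail == ["B1", "B2", "A2"]:
            arch = ARCH_VARIANT
        else:
            arch = ARCH_COMPLEX
    else:
        arch = ARCH_COMPLEX

    role_orfs = sorted(
        (o for o in orfs if o.role != "unknown"), key=lambda o: o.start
    )
    if role_orfs:
        first_orf_start = role_orfs[0].start
        last_orf_end = role_orfs[-1].end
        five = [u.label for u in labeled if u.end <= first_orf_start]
        three = [u.label for u in labeled if u.start >= last_orf_end]
        mid = [
            u.label
            for u in labeled
            if u.end > first_orf_start and u.start < last_orf_end
        ]
    else:
        five, mid, three = [labeled[0].label], [], [u.label for u in labeled[1:]]
    parts = [f"5':{','.join(five) or '-'}"]
    if mid:
        parts.append(f"mid:{','.join(mid)}")
    parts.append(f"3':{','.join(three) or '-'}")
    layout = " | ".join(parts)

    flags: list[str] = []
    if role_orfs:
        downstream = [u for u in labeled if u.start >= last_orf_end]
        if downstream and downstream[0].start - last_orf_end > gap_warn_bp:
            flags.append("large_orf_to_repeat_gap")
        upstream = [u for u in labeled if u.end <= first_orf_start]
        if upstream and first_orf_start - upstream[-1].end > gap_warn_bp:
            flags.append("large_repeat_to_orf_gap")
    return SdrArchitecture(layout, arch, flags)


# ---------------------------------------------------------------------------
# boundaries


def call_boundaries(
    seq_len: int, units: list[RepeatUnit], orfs: list[OrfAnnotation]
) -> tuple[tuple[int, int] | None, str]:
    """Element span: labeled-repeat extremes, else role-ORF span."""
    labeled = [u for u in units if u.label != "unlabeled"]
    if labeled:
        return (
            (min(u.start for u in labeled), max(u.end for u in labeled)),
            "sdr",
        )
    role_orfs = [o for o in orfs if o.role != "unknown"]
    if role_orfs:
        return (
            (min(o.start for o in role_orfs), max(o.end for o in role_orfs)),
            "orf_only",
        )
    return None, "none"


# ---------------------------------------------------------------------------
# tandem segmentation


def segment_tandem(
    seq_len: int, pairs: list[RepeatPair], config: RunConfig
) -> list[tuple[int, int]]:
    """Split a locus into segments at tandem-array period boundaries.

    Two signatures mark a tandem junction: a long pair whose units
    overlap (self-similarity at a period shorter than the match; cut at
    every period multiple) and a long pair whose units are nearly
    head-to-tail (cut at the start of the second unit).  The locus is cut
    so each element is labeled on its own.
    """
    cut_set: set[int] = set()
    for p in pairs:
        if p.units_overlap and p.diagonal >= config.tandem_min_len:
            period = p.diagonal
            k = 1
            while k * period <= p.length:
                cut_set.add(p.i + k * period)
                k += 1
        elif (
            p.length >= config.tandem_min_len
            and 0 <= p.j - (p.i + p.length) <= config.tandem_max_gap_bp
        ):
            cut_set.add(p.j)
    cuts = sorted(cut_set)
    bounds = [0] + [c for c in cuts if 0 < c < seq_len] + [seq_len]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# SIRE-like remnants and activity signal


@dataclass
class SireTemplate:
    """Probes from a full-length element: its A2+B2 terminal region and an
    internal (ORF-region) segment."""

    terminal_region: str
    internal_region: str


@dataclass
class SireReport:
    is_sire_like: bool
    terminal_identity: float
    terminal_coverage: float
    internal_coverage: float


def detect_sire_like(
    seq: str,
    template: SireTemplate | None,
    min_identity: float = 70.0,
    min_coverage: float = 0.5,
    max_internal_coverage: float = 0.3,
) -> SireReport | None:
    """Flag loci matching only the terminal A2+B2 region of an element.

    Short non-autonomous derivatives (SIRE-like) retain the terminal
    repeat region but none of the internal coding region.  Returns None
    (detection skipped) when no template is available.
    """
    if template is None:
        return None
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2

    def probe(p: str) -> tuple[float, float]:
        if not p or not seq:
            return 0.0, 0.0
        if aligner.score(seq.upper(), p.upper()) <= 0:
            return 0.0, 0.0
        aln = aligner.align(seq.upper(), p.upper())[0]
        a, b = str(aln[0]), str(aln[1])
        cols = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        tspan = aln.aligned[1]
        covered = sum(int(e - s) for s, e in tspan)
        ident = 100.0 * matches / cols if cols else 0.0
        return ident, covered / len(p)

    t_ident, t_cov = probe(template.terminal_region)
    _, i_cov = probe(template.internal_region)
    flag = (
        t_ident >= min_identity
        and t_cov >= min_coverage
        and i_cov <= max_internal_coverage
    )
    return SireReport(flag, t_ident, t_cov, i_cov)


def activity_signal(units: list[RepeatUnit]) -> tuple[bool | None, dict[str, float]]:
    """Recent-insertion signal: every labeled pair at exactly 100% identity.

    Returns (flag, per-pair identities); flag is None when no labeled
    pairs exist.
    """
    idents: dict[str, float] = {}
    for u in units:
        if u.label in ("A1", "B1") and u.pair_identity_pct is not None:
            idents[u.label[0]] = u.pair_identity_pct
    if not idents:
        return None, {}
    return all(v == 100.0 for v in idents.values()), idents
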