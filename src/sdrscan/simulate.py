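"""Synthetic VIPER/TATE-like elements and genomes with full ground truth.

The generator emulates the structural features the pipeline must
recognize: three long ORFs (gag-like, YR, RT/RH) with the YR and RT/RH
ORFs overlapping in different frames; an optional CH-box zinc-knuckle in
the gag-like protein; split-direct-repeat termini in the canonical
(A1 ... B1 A2 B2), variant (A1 ... B1 B2 A2) or A-pair-only layouts;
degraded copies (substitutions, indels, frameshifts, truncations,
N-runs); tandem arrays; telomeric GGGTTA hexamer context; and
contig-end truncation.  Every planted feature is recorded in a truth
manifest so recovery can be scored exactly.

Default element geometry follows a well-conserved reference copy set:
ORFs of 492/338/948 aa, A repeats of 173 bp and B repeats of 219 bp at
100% pair identity in the canonical layout.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .config import ROLES, RunConfig
from .intervals import intervals_overlap
from .orfs import STOP_CODONS, PanelProtein, translate

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_SYNONYMOUS: dict[str, list[str]] = {}
for _c in _CODONS:
    _SYNONYMOUS.setdefault(translate(_c + "TAA"), []).append(_c)

ARCHITECTURES = ("canonical_B1A2B2", "variant_B1B2A2", "A_pair_only", "none")

TELOMERE_HEXAMER = "GGGTTA"


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specs


@dataclass
class SdrSpec:
    architecture: str = "canonical_B1A2B2"
    len_a: int = 173
    len_b: int = 219
    identity_a: float = 100.0
    identity_b: float = 100.0
    spacer_5: int = 150
    spacer_3: int = 200
    spacer_between: int = 100


@dataclass
class ElementSpec:
    family_label: str = "VIPER_like"
    orf_lengths_aa: tuple[int, int, int] = (492, 338, 948)
    orf_overlap_bp: int = 100
    include_chbox: bool = True
    sdr: SdrSpec = field(default_factory=SdrSpec)
    single_orf_layout: bool = False
    intergenic: int = 60

    def validate(self) -> None:
        if any(x <= 0 for x in self.orf_lengths_aa):
            raise SpecError("ORF lengths must be positive")
        if self.sdr.architecture not in ARCHITECTURES:
            raise SpecError(f"unknown architecture {self.sdr.architecture!r}")
        for ident in (self.sdr.identity_a, self.sdr.identity_b):
            if not (0.0 < ident <= 100.0):
                raise SpecError("repeat identities must lie in (0, 100]")
        if not self.single_orf_layout and self.orf_overlap_bp > 0:
            _, yr_aa, rt_aa = self.orf_lengths_aa
            if self.orf_overlap_bp >= min(3 * yr_aa, 3 * rt_aa):
                raise SpecError("overlap longer than an ORF")
            if self.orf_overlap_bp % 3 == 0:
                raise SpecError(
                    "orf_overlap_bp must shift the frame (not a multiple of 3)"
                )
            if self.orf_overlap_bp < 7:
                raise SpecError("orf_overlap_bp must be 0 or >= 7")


@dataclass
class DegradationSpec:
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    frameshift_positions: tuple[int, ...] = ()
    truncation: str = "none"  # none | 5prime | 3prime | internal
    truncation_len: int = 0
    n_run: tuple[int, int] | None = None  # (position, length)

    def validate(self) -> None:
        for r in (self.sub_rate, self.indel_rate):
            if not (0.0 <= r < 1.0):
                raise SpecError("rates must lie in [0, 1)")
        if self.truncation not in ("none", "5prime", "3prime", "internal"):
            raise SpecError(f"unknown truncation {self.truncation!r}")


# ---------------------------------------------------------------------------
# truth records


@dataclass
class ElementTruth:
    spec: ElementSpec
    length: int
    orf_intervals: dict[str, tuple[int, int]]  # role -> [start, end) incl. stop
    repeat_units: dict[str, tuple[int, int]]  # label -> [start, end)
    pair_identity: dict[str, float]  # "A"/"B" -> planted identity %
    panel: list[PanelProtein]
    expected_status: str = "putative_autonomous"
    damaged_orfs: set[str] = field(default_factory=set)
    frameshifted_orfs: set[str] = field(default_factory=set)
    damaged_pairs: set[str] = field(default_factory=set)
    n_run: tuple[int, int] | None = None
    truncated: bool = False


@dataclass
class PlantedElement:
    element_id: str
    contig_id: str
    start: int  # global, 0-based half-open
    end: int
    truth: ElementTruth


@dataclass
class Genome:
    contigs: dict[str, str]
    planted: list[PlantedElement]


# ---------------------------------------------------------------------------
# element construction


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_nt(rng, n, gc=0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_codons(rng, n_aa) -> str:
    return "".join(rng.choice(_CODONS, size=n_aa))


def _mutate_copy(rng, unit: str, identity_pct: float, protect: int) -> str:
    """Return a copy of ``unit`` with planted mismatches reaching the
    requested pairwise identity; mismatches avoid the first/last
    ``protect`` bases so that anchored detection cannot trivially fail."""
    n_mm = int(round((1.0 - identity_pct / 100.0) * len(unit)))
    if n_mm == 0:
        return unit
    lo, hi = protect, len(unit) - protect
    if hi - lo < n_mm:
        raise SpecError(
            f"repeat of {len(unit)} bp cannot host {n_mm} protected mismatches"
        )
    positions = rng.choice(np.arange(lo, hi), size=n_mm, replace=False)
    out = list(unit)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != unit[p]])
    return "".join(out)


def _encode_protein(rng, protein: str) -> str:
    """Back-translate with codons drawn uniformly from the synonymous set."""
    return "".join(rng.choice(_SYNONYMOUS[aa]) for aa in protein)


CHBOX_AA = "CLRCGSAEHWKDVC"  # matches CX2CX4HX4C


def _fill_overlapped_orfs(rng, yr_aa: int, rt_aa: int, overlap: int) -> tuple[str, int]:
    """Nucleotides for a YR ORF with an RT/RH ORF starting ``overlap`` bp
    before the YR stop, in a shifted frame.

    Returns (sequence, rt_start_offset); the sequence runs from the YR ATG
    to the RT/RH stop.  Within the overlap both frames are stop-free, the
    RT/RH ATG is planted, and a frame-shifted stop immediately precedes it
    so the detected RT/RH ORF starts exactly at the planted position.
    """
    yr_nt = 3 * yr_aa + 3  # incl. stop
    r0 = yr_nt - overlap  # RT start, relative to YR start
    rt_nt = 3 * rt_aa + 3
    total = r0 + rt_nt
    for _attempt in range(200):
        arr: list[str | None] = [None] * total
        # fixed: frame-shifted stop just before the RT ATG, then the ATG
        for k, base in enumerate("TAAATG"):
            arr[r0 - 3 + k] = base
        if not _place_codon(arr, 0, "ATG"):
            continue
        ok = _fill_frame_codons(rng, arr, 0, yr_nt - 3, other_frame_from=r0)
        if not ok:
            continue
        # YR stop
        if not _place_codon(arr, yr_nt - 3, "TAA"):
            continue
        # frame-3 check inside overlap for the YR stop region
        if _creates_fs_stop(arr, yr_nt - 3, r0, total):
            continue
        # RT codons after the YR region
        if not _fill_frame_codons(
            rng, arr, _next_codon_start(r0, yr_nt), total - 3, other_frame_from=None
        ):
            continue
        # straddling RT codon(s) partially fixed by the YR region
        if not _complete_straddle(rng, arr, r0, yr_nt, total):
            continue
        if not _place_codon(arr, total - 3, "TAA"):
            continue
        if any(b is None for b in arr):
            continue
        seq = "".join(arr)  # type: ignore[arg-type]
        # verify both frames
        yr_prot = translate(seq[: yr_nt])
        rt_prot = translate(seq[r0:total])
        if "*" in yr_prot or "*" in rt_prot:
            continue
        if len(yr_prot) != yr_aa or len(rt_prot) != rt_aa:
            continue
        return seq, r0
    raise SpecError("could not realize overlapping ORFs for this spec")


def _place_codon(arr, pos, codon) -> bool:
    for k, b in enumerate(codon):
        cur = arr[pos + k]
        if cur is not None and cur != b:
            return False
        arr[pos + k] = b
    return True


def _next_codon_start(frame_anchor: int, at_or_after: int) -> int:
    off = (at_or_after - frame_anchor) % 3
    return at_or_after if off == 0 else at_or_after + (3 - off)


def _fill_frame_codons(rng, arr, start, end, other_frame_from):
    """Fill codons [start, end) stepping by 3, respecting fixed bases,
    avoiding stops in this frame and (past ``other_frame_from``) in the
    shifted frame."""
    for pos in range(start, end, 3):
        placed = False
        for _try in range(60):
            candidates = [
                c
                for c in _CODONS
                if all(
                    arr[pos + k] is None or arr[pos + k] == c[k] for k in range(3)
                )
            ]
            if not candidates:
                return False
            codon = rng.choice(candidates)
            saved = arr[pos : pos + 3]
            arr[pos : pos + 3] = list(codon)
            if other_frame_from is not None and _creates_fs_stop(
                arr, pos, other_frame_from, len(arr)
            ):
                arr[pos : pos + 3] = saved
                continue
            placed = True
            break
        if not placed:
            return False
    return True


def _creates_fs_stop(arr, changed_pos, fs_start, limit) -> bool:
    """Does any fully-written shifted-frame codon covering ``changed_pos``
    form a stop?  Shifted-frame codons begin at fs_start + 3k; the codon at
    fs_start - 3 (the planted upstream stop) and fs_start (ATG) are exempt."""
    for cstart in range(changed_pos - 2, changed_pos + 3):
        if cstart < fs_start + 3 or cstart + 3 > limit:
            continue
        if (cstart - fs_start) % 3 != 0:
            continue
        tri = arr[cstart : cstart + 3]
        if None in tri:
            continue
        if "".join(tri) in STOP_CODONS:
            return True
    return False


def _complete_straddle(rng, arr, r0, yr_nt, total) -> bool:
    """Fill any RT-frame codon straddling the YR/RT junction."""
    pos = r0 + 3 * ((yr_nt - r0) // 3)
    for cstart in range(pos - 3, yr_nt + 3, 3):
        if cstart < r0 or cstart + 3 > total:
            continue
        if all(arr[cstart + k] is not None for k in range(3)):
            continue
        candidates = [
            c
            for c in _CODONS
            if all(arr[cstart + k] is None or arr[cstart + k] == c[k] for k in range(3))
        ]
        if not candidates:
            return False
        codon = rng.choice(candidates)
        for k in range(3):
            arr[cstart + k] = codon[k]
    return True


def make_element(spec: ElementSpec, seed) -> tuple[str, ElementTruth]:
    """Realize an element spec as a nucleotide sequence plus ground truth.

    The sequence starts at the first repeat unit and ends at the last (or
    spans the ORFs when the architecture is ``none``); translated ORFs are
    emitted as the element's own role-labeled reference panel.
    """
    spec.validate()
    rng = _rng(seed)
    sdr = spec.sdr
    gag_aa, yr_aa, rt_aa = spec.orf_lengths_aa

    parts: list[str] = []
    units: dict[str, tuple[int, int]] = {}
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    def emit_unit(label: str, s: str) -> None:
        units[label] = (pos, pos + len(s))
        emit(s)

    a1 = _random_nt(rng, sdr.len_a)
    b1 = _random_nt(rng, sdr.len_b)
    protect = 12  # matches the default detector seed length
    a2 = _mutate_copy(rng, a1, sdr.identity_a, protect)
    b2 = _mutate_copy(rng, b1, sdr.identity_b, protect)

    has_a = sdr.architecture != "none"
    has_b = sdr.architecture in ("canonical_B1A2B2", "variant_B1B2A2")

    if has_a:
        emit_unit("A1", a1)
        emit(_random_nt(rng, sdr.spacer_5))

    # coding block
    orf_intervals: dict[str, tuple[int, int]] = {}
    if spec.single_orf_layout:
        total_aa = gag_aa + yr_aa + rt_aa
        protein = "".join(translate(_random_codons(rng, n)) for n in (gag_aa, yr_aa, rt_aa))
        if spec.include_chbox:
            at = min(50, gag_aa - len(CHBOX_AA) - 1)
            protein = protein[:at] + CHBOX_AA + protein[at + len(CHBOX_AA) :]
        emit("TAA")
        start = pos
        emit("ATG" + _encode_protein(rng, protein[1:]) + "TAA")
        orf_intervals["single_orf"] = (start, pos)
        protein = "M" + protein[1:]
        panel = [
            PanelProtein(f"{spec.family_label}_gag", "gag_like", protein[:gag_aa]),
            PanelProtein(f"{spec.family_label}_yr", "yr", protein[gag_aa : gag_aa + yr_aa]),
            PanelProtein(f"{spec.family_label}_rt_rh", "rt_rh", protein[gag_aa + yr_aa :]),
        ]
    else:
        gag_prot = "M" + translate(_random_codons(rng, gag_aa - 1))
        if spec.include_chbox:
            at = min(50, gag_aa - len(CHBOX_AA) - 1)
            gag_prot = gag_prot[:at] + CHBOX_AA + gag_prot[at + len(CHBOX_AA) :]
        emit("TAA")
        g0 = pos
        emit(_encode_protein(rng, gag_prot) + "TAA")
        orf_intervals["gag_like"] = (g0, pos)
        emit(_random_nt(rng, spec.intergenic))

        emit("TAA")
        y0 = pos
        if spec.orf_overlap_bp > 0:
            block, r_off = _fill_overlapped_orfs(rng, yr_aa, rt_aa, spec.orf_overlap_bp)
            emit(block)
            orf_intervals["yr"] = (y0, y0 + 3 * yr_aa + 3)
            orf_intervals["rt_rh"] = (y0 + r_off, y0 + len(block))
        else:
            emit("ATG" + _random_codons(rng, yr_aa - 1) + "TAA")
            orf_intervals["yr"] = (y0, pos)
            emit(_random_nt(rng, spec.intergenic))
            emit("TAA")
            r0 = pos
            emit("ATG" + _random_codons(rng, rt_aa - 1) + "TAA")
            orf_intervals["rt_rh"] = (r0, pos)
        panel = None  # assembled below from the full sequence

    if has_a or has_b:
        emit(_random_nt(rng, sdr.spacer_3))
    if sdr.architecture == "canonical_B1A2B2":
        emit_unit("B1", b1)
        emit(_random_nt(rng, sdr.spacer_between))
        emit_unit("A2", a2)
        emit(_random_nt(rng, sdr.spacer_between))
        emit_unit("B2", b2)
    elif sdr.architecture == "variant_B1B2A2":
        emit_unit("B1", b1)
        emit(_random_nt(rng, sdr.spacer_between))
        emit_unit("B2", b2)
        emit(_random_nt(rng, sdr.spacer_between))
        emit_unit("A2", a2)
    elif sdr.architecture == "A_pair_only":
        emit_unit("A2", a2)

    seq = _separate_repeat_flanks(rng, "".join(parts), units, orf_intervals)

    if panel is None:
        panel = [
            PanelProtein(
                f"{spec.family_label}_gag",
                "gag_like",
                translate(seq[orf_intervals["gag_like"][0] : orf_intervals["gag_like"][1]]),
            ),
            PanelProtein(
                f"{spec.family_label}_yr",
                "yr",
                translate(seq[orf_intervals["yr"][0] : orf_intervals["yr"][1]]),
            ),
            PanelProtein(
                f"{spec.family_label}_rt_rh",
                "rt_rh",
                translate(seq[orf_intervals["rt_rh"][0] : orf_intervals["rt_rh"][1]]),
            ),
        ]

    pair_identity = {}
    if has_a:
        pair_identity["A"] = sdr.identity_a
    if has_b:
        pair_identity["B"] = sdr.identity_b

    truth = ElementTruth(
        spec=spec,
        length=len(seq),
        orf_intervals=orf_intervals,
        repeat_units=units,
        pair_identity=pair_identity,
        panel=panel,
        expected_status="putative_autonomous" if has_a else "potentially_encoding",
    )
    return seq, truth


def _separate_repeat_flanks(rng, seq: str, units, orf_intervals) -> str:
    """Force a mismatch at the bases immediately flanking each repeat pair.

    Ungapped self-comparison would otherwise extend a planted repeat by
    chance agreements just outside it; a guaranteed flanking mismatch
    (part of the harness convention, like keeping planted mismatches away
    from the repeat ends) makes boundary recovery exact.  Only spacer
    bases outside every planted feature are edited.
    """
    s = list(seq)
    feats = list(units.values()) + list(orf_intervals.values())

    def editable(p: int) -> bool:
        return 0 <= p < len(s) and not any(a <= p < b for a, b in feats)

    for letter in ("A", "B"):
        u1 = units.get(f"{letter}1")
        u2 = units.get(f"{letter}2")
        if u1 is None or u2 is None:
            continue
        for p1, p2 in ((u1[0] - 1, u2[0] - 1), (u1[1], u2[1])):
            if not (0 <= p1 < len(s) and 0 <= p2 < len(s)):
                continue
            if s[p1] != s[p2]:
                continue
            target = p2 if editable(p2) else p1 if editable(p1) else None
            if target is None:
                continue
            other = p1 if target == p2 else p2
            s[target] = rng.choice([b for b in "ACGT" if b != s[other]])
    return "".join(s)


# ---------------------------------------------------------------------------
# degradation


def degrade(
    seq: str, truth: ElementTruth, dspec: DegradationSpec, seed, config: RunConfig | None = None
) -> tuple[str, ElementTruth]:
    """Apply a degradation spec and update the expected truth.

    Substitutions, indels, explicit frameshift insertions, an N-run and a
    truncation are applied in that order; the expected post-degradation
    status is recomputed by applying the classifier's rules to the planted
    features (e.g. a frameshift inside the third ORF makes the copy
    degenerate; an N-run over an expected region makes it inconclusive).
    """
    dspec.validate()
    config = config or RunConfig()
    rng = _rng(seed)
    truth = _copy.deepcopy(truth)
    s = list(seq)

    sub_positions = []
    if dspec.sub_rate > 0:
        hits = np.nonzero(rng.random(len(s)) < dspec.sub_rate)[0]
        for p in hits:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        sub_positions = list(map(int, hits))

    indel_positions = []
    for p in sorted(dspec.frameshift_positions, reverse=True):
        s.insert(p, rng.choice(list("ACGT")))
        indel_positions.append((p, +1))
    if dspec.indel_rate > 0:
        hits = sorted(
            map(int, np.nonzero(rng.random(len(s)) < dspec.indel_rate)[0]),
            reverse=True,
        )
        for p in hits:
            if rng.random() < 0.5:
                s.insert(p, rng.choice(list("ACGT")))
                indel_positions.append((p, +1))
            else:
                del s[p]
                indel_positions.append((p, -1))

    # shift truth intervals for indels (applied in descending position order)
    def shift(iv: tuple[int, int], p: int, delta: int) -> tuple[int, int]:
        a, b = iv
        if p < a:
            return a + delta, b + delta
        if p < b:
            return a, b + delta
        return a, b

    for p, delta in sorted(indel_positions):
        for role in list(truth.orf_intervals):
            a, b = truth.orf_intervals[role]
            if a <= p < b:
                truth.damaged_orfs.add(role)
                truth.frameshifted_orfs.add(role)
        for label in list(truth.repeat_units):
            a, b = truth.repeat_units[label]
            if a <= p < b:
                truth.damaged_pairs.add(label[0])
    # apply coordinate shifts in ascending order of position
    for p, delta in sorted(indel_positions, reverse=True):
        truth.orf_intervals = {
            r: shift(iv, p, delta) for r, iv in truth.orf_intervals.items()
        }
        truth.repeat_units = {
            l: shift(iv, p, delta) for l, iv in truth.repeat_units.items()
        }

    if dspec.n_run is not None:
        p, ln = dspec.n_run
        p = max(0, min(p, len(s)))
        ln = min(ln, len(s) - p)
        s[p : p + ln] = ["N"] * ln
        truth.n_run = (p, ln)

    if dspec.truncation != "none" and dspec.truncation_len > 0:
        ln = min(dspec.truncation_len, len(s))
        if dspec.truncation == "5prime":
            cut = (0, ln)
        elif dspec.truncation == "3prime":
            cut = (len(s) - ln, len(s))
        else:
            mid = len(s) // 2
            cut = (mid - ln // 2, mid - ln // 2 + ln)
        del s[cut[0] : cut[1]]
        truth.truncated = True

        def clip(iv):
            a, b = iv
            if b <= cut[0]:
                return a, b
            if a >= cut[1]:
                return a - ln, b - ln
            return None  # overlaps the cut

        for role in list(truth.orf_intervals):
            iv = clip(truth.orf_intervals[role])
            if iv is None:
                truth.damaged_orfs.add(role)
                del truth.orf_intervals[role]
            else:
                truth.orf_intervals[role] = iv
        for label in list(truth.repeat_units):
            iv = clip(truth.repeat_units[label])
            if iv is None:
                truth.damaged_pairs.add(label[0])
                del truth.repeat_units[label]
            else:
                truth.repeat_units[label] = iv

    out = "".join(s)
    truth.length = len(out)
    truth.expected_status = _expected_status(out, truth, config)
    return out, truth


def _emulated_orf(seq: str, iv: tuple[int, int]) -> tuple[int, int, int]:
    """The longest ORF the six-frame caller would report for the planted
    frame over the planted interval: every maximal ATG-to-stop reading
    (an ORF starting inside the interval may run past its end, e.g. when
    a guard stop mutated away), longest first.  Returns (length_aa,
    orf_start, orf_end); length 0 when no start survives."""
    a, b = iv
    n = len(seq)
    frags: list[tuple[int, int, int]] = []
    p, start = a, None
    while p + 3 <= n:
        codon = seq[p : p + 3]
        if codon in STOP_CODONS:
            if start is not None:
                frags.append(((p - start) // 3, start, p + 3))
            start = None
            if p >= b:
                break
        elif codon == "ATG" and start is None and p < b:
            start = p
        p += 3
    if start is not None:  # ran off the end without a stop
        frags.append(((p - start) // 3, start, p))
    if not frags:
        return 0, a, a
    return max(frags)


def _orf_encodes(
    seq: str, truth: ElementTruth, role: str, config: RunConfig
) -> bool:
    """Would the classifier count this role as potentially encoding?"""
    iv = truth.orf_intervals.get(role)
    if iv is None:
        return False
    length, start, end = _emulated_orf(seq, iv)
    if length <= config.min_aa.get(role, 0):
        return False
    # a long N-run inside the reading makes it unverifiable
    run = 0
    for p in range(start, min(end, len(seq))):
        run = run + 1 if seq[p] == "N" else 0
        if run >= config.n_run_min_len:
            return False
    return True


def _single_orf_roles(seq: str, truth: ElementTruth, config: RunConfig) -> set[str]:
    iv = truth.orf_intervals.get("single_orf")
    if iv is None:
        return set()
    length, start, end = _emulated_orf(seq, iv)
    gag_aa, yr_aa, rt_aa = truth.spec.orf_lengths_aa
    segs = {
        "gag_like": (0, gag_aa),
        "yr": (gag_aa, gag_aa + yr_aa),
        "rt_rh": (gag_aa + yr_aa, gag_aa + yr_aa + rt_aa),
    }
    roles = set()
    for role, (s0, s1) in segs.items():
        covered = max(0, min(length, s1) - s0)
        if covered >= 0.8 * (s1 - s0) and length > config.min_aa[role]:
            roles.add(role)
    return roles


def _pair_detectable(seq: str, truth: ElementTruth, letter: str, config: RunConfig) -> bool:
    if letter in truth.damaged_pairs:
        return False
    u1, u2 = truth.repeat_units.get(f"{letter}1"), truth.repeat_units.get(f"{letter}2")
    if u1 is None or u2 is None:
        return False
    s1, s2 = seq[u1[0] : u1[1]], seq[u2[0] : u2[1]]
    if len(s1) != len(s2) or "N" in s1 + s2:
        return False
    m = [a != b for a, b in zip(s1, s2)]
    if sum(m) > config.max_mismatch_frac * len(m):
        return False
    # anchored detection needs exact seed_len runs at both ends
    k = config.seed_len
    run = 0
    first = None
    for i, mm in enumerate(m):
        run = 0 if mm else run + 1
        if run >= k:
            first = i - k + 1
            break
    if first is None:
        return False
    run = 0
    last = None
    for i in range(len(m) - 1, -1, -1):
        run = 0 if m[i] else run + 1
        if run >= k:
            last = i + k
            break
    return last is not None and last - first >= config.min_repeat_len


def _expected_status(seq: str, truth: ElementTruth, config: RunConfig) -> str:
    if "single_orf" in truth.orf_intervals or "single_orf" in truth.damaged_orfs:
        three_ok = _single_orf_roles(seq, truth, config) == set(ROLES)
    else:
        three_ok = all(_orf_encodes(seq, truth, r, config) for r in ROLES)
    letters = {l[0] for l in truth.repeat_units} | truth.damaged_pairs
    sdr_ok = any(_pair_detectable(seq, truth, l, config) for l in letters)
    if three_ok and sdr_ok:
        return "putative_autonomous"
    if three_ok:
        return "potentially_encoding"
    if truth.n_run is not None:
        p, ln = truth.n_run
        if ln >= config.n_run_min_len:
            feats = list(truth.orf_intervals.values()) + list(truth.repeat_units.values())
            if any(intervals_overlap(p, p + ln, a, b) for a, b in feats) or not feats:
                return "inconclusive"
    return "degenerate"


# ---------------------------------------------------------------------------
# genome assembly


def plant_genome(
    elements: list[tuple[str, ElementTruth]],
    background_len: int,
    gc: float = 0.5,
    tandem_counts: dict[int, int] | None = None,
    telomeric_context: bool = False,
    contig_breaks: list[int] | None = None,
    seed=0,
) -> Genome:
    """Insert elements into an i.i.d. background and return genome + truth.

    ``tandem_counts`` maps element index -> copy number for head-to-tail
    arrays; ``telomeric_context`` embeds the first element in a GGGTTA
    hexamer array; ``contig_breaks`` are global positions splitting the
    genome into contigs — a break inside an element truncates it at a
    contig end and its expected status becomes inconclusive.
    """
    rng = _rng(seed)
    tandem_counts = tandem_counts or {}
    blocks: list[tuple[str, ElementTruth | None, int]] = []  # (seq, truth, copies)
    total_elem = 0
    for idx, (seq, truth) in enumerate(elements):
        copies = max(1, tandem_counts.get(idx, 1))
        blocks.append((seq, truth, copies))
        total_elem += len(seq) * copies
    if background_len < total_elem + 2 * (len(blocks) + 1):
        raise SpecError("background_len cannot accommodate the elements")

    gap_total = background_len - total_elem
    cuts = sorted(rng.integers(0, gap_total + 1, size=len(blocks)))
    gaps = (
        [cuts[0]]
        + [cuts[k] - cuts[k - 1] for k in range(1, len(blocks))]
        + [gap_total - cuts[-1]]
    )

    out: list[str] = []
    planted: list[PlantedElement] = []
    pos = 0
    eid = 0
    def edge_refs(seq, truth, copies, side) -> list[str]:
        """Element bases that the adjacent background base must differ
        from, so self-comparison cannot extend a terminal repeat (or a
        tandem period) past the true element edge."""
        refs = []
        for label, (a, b) in truth.repeat_units.items():
            partner = label[0] + ("2" if label.endswith("1") else "1")
            piv = truth.repeat_units.get(partner)
            if piv is None:
                continue
            if side == "left" and a == 0 and piv[0] > 0:
                refs.append(seq[piv[0] - 1])
            if side == "right" and b == len(seq) and piv[1] < len(seq):
                refs.append(seq[piv[1]])
        if copies > 1:  # tandem period diagonal
            refs.append(seq[-1] if side == "left" else seq[0])
        return refs

    hexes = TELOMERE_HEXAMER * 40
    pending_refs: list[str] = []
    for k, (seq, truth, copies) in enumerate(blocks):
        gap = _random_nt(rng, gaps[k], gc)
        if telomeric_context and k == 0:
            gap = gap[: max(0, len(gap) - len(hexes))] + hexes[: len(gap)]
        if gap and pending_refs and gap[0] in pending_refs:
            choices = [b for b in "ACGT" if b not in pending_refs]
            if choices:
                gap = rng.choice(choices) + gap[1:]
        left_refs = edge_refs(seq, truth, copies, "left")
        if gap and left_refs and gap[-1] in left_refs:
            choices = [b for b in "ACGT" if b not in left_refs]
            if choices:
                gap = gap[:-1] + rng.choice(choices)
        pending_refs = edge_refs(seq, truth, copies, "right")
        out.append(gap)
        pos += len(gap)
        for c in range(copies):
            planted.append(
                PlantedElement(
                    element_id=f"elem{eid}",
                    contig_id="chr1",
                    start=pos,
                    end=pos + len(seq),
                    truth=_copy.deepcopy(truth),
                )
            )
            out.append(seq)
            pos += len(seq)
            eid += 1
    gap = _random_nt(rng, gaps[-1], gc)
    if telomeric_context and len(blocks) == 1:
        gap = hexes[: len(gap)] + gap[len(hexes):]
    if gap and pending_refs and gap[0] in pending_refs:
        choices = [b for b in "ACGT" if b not in pending_refs]
        if choices:
            gap = rng.choice(choices) + gap[1:]
    out.append(gap)
    genome_seq = "".join(out)

    contigs: dict[str, str] = {}
    if contig_breaks:
        bounds = [0] + sorted(b for b in contig_breaks if 0 < b < len(genome_seq)) + [
            len(genome_seq)
        ]
        remapped: list[PlantedElement] = []
        for ci in range(len(bounds) - 1):
            lo, hi = bounds[ci], bounds[ci + 1]
            name = f"contig{ci + 1}"
            contigs[name] = genome_seq[lo:hi]
            for pe in planted:
                if pe.end <= lo or pe.start >= hi:
                    continue
                t = _copy.deepcopy(pe.truth)
                new_start, new_end = max(pe.start, lo), min(pe.end, hi)
                if new_start > pe.start or new_end < pe.end:
                    t.truncated = True
                    t.expected_status = "inconclusive"
                    # clip per-copy feature intervals
                    off = new_start - pe.start
                    t.orf_intervals = {
                        r: (a - off, b - off)
                        for r, (a, b) in t.orf_intervals.items()
                        if a >= off and b <= new_end - pe.start
                    }
                    t.repeat_units = {
                        l: (a - off, b - off)
                        for l, (a, b) in t.repeat_units.items()
                        if a >= off and b <= new_end - pe.start
                    }
                remapped.append(
                    PlantedElement(pe.element_id, name, new_start - lo, new_end - lo, t)
                )
        planted = remapped
    else:
        contigs["chr1"] = genome_seq
    # placement can itself make a copy unjudgeable: a degenerate copy
    # within the contig-end window is expected inconclusive
    w = RunConfig().contig_end_window_bp
    for pe in planted:
        clen = len(contigs[pe.contig_id])
        if pe.truth.expected_status == "degenerate" and (
            pe.start < w or clen - pe.end < w
        ):
            pe.truth.expected_status = "inconclusive"
    return Genome(contigs, planted)


# ---------------------------------------------------------------------------
# locus extraction (emulates hit retrieval with flanks)


@dataclass
class Locus:
    locus_id: str
    seq: str
    contig_id: str
    start: int  # global on contig
    end: int
    contig_len: int
    planted: list[PlantedElement]  # with copy-local truth coordinates


def extract_loci(genome: Genome, flank_bp: int = 8000) -> list[Locus]:
    """Candidate loci: each planted element plus flanks, merged when the
    flanked windows overlap (so a tandem array yields one locus)."""
    by_contig: dict[str, list[PlantedElement]] = {}
    for pe in genome.planted:
        by_contig.setdefault(pe.contig_id, []).append(pe)
    loci: list[Locus] = []
    li = 0
    for contig_id, pes in by_contig.items():
        contig = genome.contigs[contig_id]
        pes = sorted(pes, key=lambda p: p.start)
        clusters: list[list[PlantedElement]] = []
        for pe in pes:
            if (
                clusters
                and pe.start - flank_bp <= clusters[-1][-1].end + flank_bp
            ):
                clusters[-1].append(pe)
            else:
                clusters.append([pe])
        for cluster in clusters:
            lo = max(0, cluster[0].start - flank_bp)
            hi = min(len(contig), cluster[-1].end + flank_bp)
            local = []
            for pe in cluster:
                truth = pe.truth
                # a locus clipped by a contig end cannot be judged
                # degenerate with confidence (mirrors the classifier)
                if truth.expected_status == "degenerate" and (
                    lo == 0 or hi == len(contig)
                ):
                    truth = _copy.deepcopy(truth)
                    truth.expected_status = "inconclusive"
                local.append(
                    PlantedElement(
                        pe.element_id,
                        contig_id,
                        pe.start - lo,
                        pe.end - lo,
                        truth,
                    )
                )
            loci.append(
                Locus(
                    f"locus{li}",
                    contig[lo:hi],
                    contig_id,
                    lo,
                    hi,
                    len(contig),
                    local,
                )
            )
            li += 1
    return loci


# ---------------------------------------------------------------------------
# derived inputs


def make_copy_set(
    spec: ElementSpec, n: int, mean_pairwise_divergence: float, seed
) -> tuple[list[str], ElementTruth]:
    """A family of n copies of one element, each independently mutated at
    half the requested mean pairwise divergence (so two copies differ at
    about the requested rate)."""
    rng = _rng(seed)
    base, truth = make_element(spec, rng)
    rate = mean_pairwise_divergence / 2.0
    copies = []
    for _ in range(n):
        dseq, _t = degrade(base, truth, DegradationSpec(sub_rate=rate), rng)
        copies.append(dseq)
    return copies, truth


def make_sire_remnant(seq: str, truth: ElementTruth) -> str:
    """The A2..B2 (or last-two-repeat) terminal segment of an element: the
    structure of short non-autonomous SIRE-like derivatives."""
    labels = [l for l in ("A2", "B2", "B1") if l in truth.repeat_units]
    if len(labels) < 2:
        raise SpecError("element has no terminal A2/B2 repeats")
    spans = [truth.repeat_units[l] for l in ("A2", "B2") if l in truth.repeat_units]
    lo = min(a for a, _ in spans)
    hi = max(b for _, b in spans)
    return seq[lo:hi]


def sire_template_from(seq: str, truth: ElementTruth):
    """Build SIRE probes (terminal A2..B2 region + internal ORF region)
    from a full-length copy."""
    from .repeats import SireTemplate

    spans = [truth.repeat_units[l] for l in ("A2", "B2") if l in truth.repeat_units]
    if not spans:
        return None
    lo = min(a for a, _ in spans)
    hi = max(b for _, b in spans)
    ivs = list(truth.orf_intervals.values())
    ilo, ihi = min(a for a, _ in ivs), max(b for _, b in ivs)
    mid = (ilo + ihi) // 2
    internal = seq[max(ilo, mid - 300) : min(ihi, mid + 300)]
    return SireTemplate(terminal_region=seq[lo:hi], internal_region=internal)
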