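"""Split-direct-repeat detection, labeling, architecture and boundaries."""

from itertools import product

import numpy as np
import pytest

from sdrscan.config import RunConfig
from sdrscan.orfs import OrfAnnotation
from sdrscan.repeats import (
    ARCH_A_ONLY,
    ARCH_CANONICAL,
    ARCH_COMPLEX,
    ARCH_NONE,
    ARCH_VARIANT,
    RepeatPair,
    RepeatUnit,
    activity_signal,
    call_boundaries,
    classify_architecture,
    detect_sire_like,
    find_repeat_pairs,
    label_terminal_repeats,
    segment_tandem,
)


def oracle_repeat_pairs(seq, seed_len, min_repeat_len, max_mismatch_frac):
    """Exhaustive anchored-pair enumeration (independent of the k-mer
    seeded scan): every interval on every diagonal that begins and ends
    with seed_len exact matches and respects the mismatch budget, kept
    only if not contained in another such interval on its diagonal."""
    s = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    out = []
    for d in range(1, n):
        nd = n - d
        if nd < min_repeat_len:
            continue
        m = (s[:nd] != s[d : d + nd]).astype(int)
        prefix = np.concatenate([[0], np.cumsum(m)])
        k = seed_len
        cands = []
        for a in range(nd - k + 1):
            if prefix[a + k] - prefix[a] != 0:
                continue
            for b in range(max(a + min_repeat_len, a + k), nd + 1):
                if prefix[b] - prefix[b - k] != 0:
                    continue
                mm = prefix[b] - prefix[a]
                if mm <= max_mismatch_frac * (b - a):
                    cands.append((a, b))
        for a, b in cands:
            if any(
                a2 <= a and b <= b2 and (a2, b2) != (a, b) for a2, b2 in cands
            ):
                continue
            out.append((a, a + d, b - a, int(prefix[b] - prefix[a])))
    return sorted(out)


def _as_tuples(pairs):
    return sorted((p.i, p.j, p.length, p.mismatches) for p in pairs)


def test_simple_adjacent_duplication():
    pairs = find_repeat_pairs("ACGTACGT", seed_len=4, min_repeat_len=4,
                              max_mismatch_frac=0.0)
    assert _as_tuples(pairs) == [(0, 4, 4, 0)]
    assert pairs[0].identity_pct == 100.0


def test_planted_duplicate_in_random_background():
    rng = np.random.default_rng(17)
    for _ in range(20):
        bg = rng.choice(list("ACGT"), size=200)
        unit = bg[30:90].copy()
        bg[130:190] = unit
        # separate the planted copies from their flanks
        for p, q in ((29, 129), (90, 190)):
            if bg[p] == bg[q]:
                bg[q] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bg[q]]
        seq = "".join(bg)
        pairs = find_repeat_pairs(seq, 12, 50, 0.1)
        assert (30, 130, 60, 0) in _as_tuples(pairs)


@pytest.mark.parametrize("frac", [0.0, 0.34])
def test_matches_exhaustive_oracle_small_strings(frac):
    # every string over a reduced alphabet, exhaustively
    for n in range(6, 11):
        for tup in product("AC", repeat=n):
            seq = "".join(tup)
            got = _as_tuples(find_repeat_pairs(seq, 2, 3, frac))
            assert got == oracle_repeat_pairs(seq, 2, 3, frac), seq


def test_matches_oracle_random_200mers_with_planted_repeats():
    rng = np.random.default_rng(23)
    for _ in range(50):
        bg = rng.choice(list("ACGT"), size=200)
        unit = bg[10:75].copy()
        mism = rng.choice(np.arange(12, 53), size=3, replace=False)
        for p in mism:
            unit[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[unit[p]]
        bg[120:185] = unit
        for p, q in ((9, 119), (75, 185)):
            if bg[p] == bg[q]:
                bg[q] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bg[q]]
        seq = "".join(bg)
        got = _as_tuples(find_repeat_pairs(seq, 12, 50, 0.1))
        assert got == oracle_repeat_pairs(seq, 12, 50, 0.1)
        assert any(i == 10 and j == 120 and L == 65 for i, j, L, _ in got)


# ---------------------------------------------------------------------------
# labeling


def _mk_pairs(*ijl):
    return [RepeatPair(i, j, L, 0) for i, j, L in ijl]


def test_canonical_labeling():
    # A1 at 0, B1/A2/B2 at the 3' end of a 7000 bp copy
    pairs = _mk_pairs((0, 6000, 170), (5600, 6400, 200))
    units = label_terminal_repeats(pairs, 6600, 1000)
    got = {u.label: (u.start, u.end) for u in units}
    assert got == {
        "A1": (0, 170),
        "A2": (6000, 6170),
        "B1": (5600, 5800),
        "B2": (6400, 6600),
    }
    assert all(u.pair_identity_pct == 100.0 for u in units)


def test_single_terminal_pair_is_a_pair():
    pairs = _mk_pairs((0, 5500, 100))
    units = label_terminal_repeats(pairs, 5600, 1000)
    assert {u.label for u in units} == {"A1", "A2"}


def test_no_terminal_pairs_is_empty():
    pairs = _mk_pairs((2000, 3000, 100))
    assert label_terminal_repeats(pairs, 8000, 1000) == []


def test_labeling_invariant_to_flank_padding(intact_element, config):
    seq, truth = intact_element
    base = {
        u.label: (u.start, u.end)
        for u in label_terminal_repeats(
            find_repeat_pairs(seq, 12, 50, 0.1), len(seq), 1000
        )
    }
    assert set(base) == {"A1", "A2", "B1", "B2"}
    rng = np.random.default_rng(5)
    pad = 400  # shorter than the terminal window
    left = "".join(rng.choice(list("ACGT"), size=pad))
    right = "".join(rng.choice(list("ACGT"), size=pad))
    padded = left + seq + right
    units = label_terminal_repeats(
        find_repeat_pairs(padded, 12, 50, 0.1), len(padded), 1000
    )
    got = {u.label: (u.start, u.end) for u in units if u.label != "unlabeled"}
    for label, (a, b) in base.items():
        ga, gb = got[label]
        assert abs(ga - (a + pad)) <= 1 and abs(gb - (b + pad)) <= 1


# ---------------------------------------------------------------------------
# architecture


def _units(spec):
    return [RepeatUnit(lab, a, b, None, 100.0) for lab, a, b in spec]


def _orfs():
    return [
        OrfAnnotation(300, 1800, "+", 0, "M" * 499, role="gag_like"),
        OrfAnnotation(1900, 2900, "+", 1, "M" * 332, role="yr"),
        OrfAnnotation(2800, 5600, "+", 2, "M" * 932, role="rt_rh"),
    ]


def test_architecture_classes():
    canonical = _units(
        [("A1", 0, 170), ("B1", 5800, 6000), ("A2", 6100, 6270), ("B2", 6400, 6600)]
    )
    assert classify_architecture(canonical, _orfs()).arch_class == ARCH_CANONICAL
    variant = _units(
        [("A1", 0, 170), ("B1", 5800, 6000), ("B2", 6100, 6300), ("A2", 6400, 6570)]
    )
    assert classify_architecture(variant, _orfs()).arch_class == ARCH_VARIANT
    a_only = _units([("A1", 0, 170), ("A2", 6400, 6570)])
    assert classify_architecture(a_only, _orfs()).arch_class == ARCH_A_ONLY
    assert classify_architecture([], _orfs()).arch_class == ARCH_NONE
    scrambled = _units(
        [("B1", 0, 200), ("A1", 300, 470), ("A2", 6100, 6270), ("B2", 6400, 6600)]
    )
    assert classify_architecture(scrambled, _orfs()).arch_class == ARCH_COMPLEX


def test_large_orf_to_repeat_gap_is_flagged():
    far = _units([("A1", 0, 170), ("B1", 7000, 7200), ("A2", 7300, 7470),
                  ("B2", 7600, 7800)])
    arch = classify_architecture(far, _orfs(), gap_warn_bp=1000)
    assert "large_orf_to_repeat_gap" in arch.distance_flags
    near = _units([("A1", 0, 170), ("B1", 5800, 6000), ("A2", 6100, 6270),
                   ("B2", 6400, 6600)])
    assert classify_architecture(near, _orfs(), gap_warn_bp=1000).distance_flags == []


def test_layout_string_structure():
    canonical = _units(
        [("A1", 0, 170), ("B1", 5800, 6000), ("A2", 6100, 6270), ("B2", 6400, 6600)]
    )
    arch = classify_architecture(canonical, _orfs())
    assert arch.layout == "5':A1 | 3':B1,A2,B2"


# ---------------------------------------------------------------------------
# boundaries / tandem / activity


def test_boundaries_from_units_and_orf_fallback():
    units = _units([("A1", 10, 180), ("A2", 6400, 6570)])
    assert call_boundaries(7000, units, _orfs()) == ((10, 6570), "sdr")
    assert call_boundaries(7000, [], _orfs()) == ((300, 5600), "orf_only")
    assert call_boundaries(7000, [], []) == (None, "none")


def test_tandem_segmentation_from_overlapping_self_similarity(config):
    # three identical 1500 bp copies: self-similarity at period 1500
    pair = RepeatPair(100, 1600, 3000, 0)
    segs = segment_tandem(4700, [pair], config)
    assert segs == [(0, 1600), (1600, 3100), (3100, 4700)]


def test_tandem_segmentation_head_to_tail(config):
    pair = RepeatPair(0, 1550, 1500, 0)  # 50 bp spacer between units
    assert segment_tandem(3100, [pair], config) == [(0, 1550), (1550, 3100)]


def test_activity_signal_rules():
    def units(ia, ib):
        out = [
            RepeatUnit("A1", 0, 100, "A2", ia),
            RepeatUnit("A2", 900, 1000, "A1", ia),
        ]
        if ib is not None:
            out += [
                RepeatUnit("B1", 700, 800, "B2", ib),
                RepeatUnit("B2", 1100, 1200, "B1", ib),
            ]
        return out

    assert activity_signal(units(100.0, 100.0)) == (True, {"A": 100.0, "B": 100.0})
    flag, idents = activity_signal(units(100.0, 99.0))
    assert flag is False and idents == {"A": 100.0, "B": 99.0}
    assert activity_signal([]) == (None, {})


def test_sire_like_detection(intact_element):
    from sdrscan.simulate import make_sire_remnant, sire_template_from

    seq, truth = intact_element
    template = sire_template_from(seq, truth)
    rng = np.random.default_rng(9)
    background = "".join(rng.choice(list("ACGT"), size=800))
    assert detect_sire_like(make_sire_remnant(seq, truth), template).is_sire_like
    assert not detect_sire_like(seq, template).is_sire_like
    assert not detect_sire_like(background, template).is_sire_like
    assert detect_sire_like(seq, None) is None
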