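import itertools
import re

import pytest

from prfscan.genbank_io import CodonUsageTable, GenomeRecord
from prfscan.motif_catalog import (
    BACKWARD,
    FORWARD,
    MOTIF_BY_NAME,
    MOTIF_CLASSES,
    classify_window,
    random_probability,
    scan_overlap,
)
from prfscan.orf_geometry import GenePair, compute_overlap_window, strand_view
from prfscan.genbank_io import CdsFeature

# ---------------------------------------------------------------------------
# independent oracle: regex matcher + enumeration-based precedence
# ---------------------------------------------------------------------------


def _oracle_regex(runs):
    parts = []
    for idx, run in enumerate(runs, start=1):
        neg = f"(?!\\{idx - 1})" if idx > 1 else ""
        parts.append(f"{neg}([ACGT])\\{idx}{{{run - 1}}}")
    return re.compile("".join(parts) + "$")


_ORACLE = {m.name: _oracle_regex(m.runs) for m in MOTIF_CLASSES}


def _enumerated_fraction(motif):
    rx = _ORACLE[motif.name]
    n = sum(
        1
        for tup in itertools.product("ACGT", repeat=motif.span)
        if rx.fullmatch("".join(tup))
    )
    return n / 4**motif.span


_FRACTIONS = {m.name: _enumerated_fraction(m) for m in MOTIF_CLASSES}


def _oracle_classify(window, directions=(BACKWARD, FORWARD)):
    hits = [
        m
        for m in MOTIF_CLASSES
        if m.direction in directions and _ORACLE[m.name].search(window)
    ]
    if not hits:
        return None
    return min(hits, key=lambda m: (_FRACTIONS[m.name], -m.span, m.code))


# ---------------------------------------------------------------------------


class TestCatalogShape:
    def test_eight_backward_two_forward(self):
        assert len(MOTIF_CLASSES) == 10
        assert sum(m.direction == BACKWARD for m in MOTIF_CLASSES) == 8
        assert sum(m.direction == FORWARD for m in MOTIF_CLASSES) == 2
        assert sorted(m.code for m in MOTIF_CLASSES) == list(range(10))

    def test_span_ranges(self):
        for m in MOTIF_CLASSES:
            if m.direction == BACKWARD:
                assert m.span in (5, 6, 7)
            else:
                assert m.span in (3, 4)


class TestClassify:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("GGGGGAA", "fivetwo"),
            ("CCCGGAA", "threetwotwo"),
            ("CAAAAAA", "six"),  # precedence over threethree
            ("AAAAAAG", None),  # the G breaks every right-anchored run
            ("ACGTACG", None),
            ("AAGGGGG", "twofive"),  # beats five by probability
            ("AAGGGGA", None),
            ("CAAGGGG", "twofour"),  # beats forward four by probability
            ("ANAAAAA", "five"),  # N blocks six/threethree, suffix still runs
            ("NNNNAAA", "three"),
        ],
    )
    def test_exemplar_windows(self, window, expected):
        got = classify_window(window)
        assert (got.name if got else None) == expected

    def test_exhaustive_heptamers_match_oracle(self):
        for tup in itertools.product("ACGT", repeat=7):
            w = "".join(tup)
            got = classify_window(w)
            want = _oracle_classify(w)
            assert (got and got.name) == (want and want.name), w

    def test_direction_restricted_classification_matches_oracle(self):
        for tup in itertools.product("ACGT", repeat=7):
            w = "".join(tup)
            for dirs in ((BACKWARD,), (FORWARD,)):
                got = classify_window(w, directions=dirs)
                want = _oracle_classify(w, directions=dirs)
                assert (got and got.name) == (want and want.name), (w, dirs)

    def test_max_span_falls_back_to_shorter_classes(self):
        assert classify_window("CAAAAAA").name == "six"
        assert classify_window("CAAAAAA", max_span=5).name == "five"
        assert classify_window("GGGGGAA", max_span=2) is None


class TestRandomProbability:
    def test_formula_matches_enumeration(self):
        for m in MOTIF_CLASSES:
            assert random_probability(m) == pytest.approx(_FRACTIONS[m.name])

    def test_known_values(self):
        assert random_probability(MOTIF_BY_NAME["six"]) == pytest.approx(4 / 4096)
        assert random_probability(MOTIF_BY_NAME["threethree"]) == pytest.approx(12 / 4096)

    def test_subset_motifs_rank_lower(self):
        p = {m.name: random_probability(m) for m in MOTIF_CLASSES}
        assert p["six"] < p["threethree"]
        assert p["twofive"] < p["twofour"]
        assert p["four"] < p["three"]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _uniform_usage():
    from prfscan.genbank_io import ALL_CODONS

    return CodonUsageTable(freq={c: 1 / 64 for c in ALL_CODONS}, total_codons=64)


def _usage(**overrides):
    from prfscan.genbank_io import ALL_CODONS

    freq = {c: 0.0 for c in ALL_CODONS}
    freq.update(overrides)
    return CodonUsageTable(freq=freq, total_codons=100)


def _mk_pair(seq, a_iv, b_iv):
    record = GenomeRecord("SCAN", seq, [])
    view = strand_view(record, "+")
    got = compute_overlap_window(a_iv, b_iv, view.seq)
    assert got is not None, "test layout must produce a window"
    window, frame_offset, stop_end = got
    gene_a = CdsFeature(segments=[a_iv], strand="+")
    gene_b = CdsFeature(segments=[b_iv], strand="+")
    return GenePair(
        gene_a=gene_a, gene_b=gene_b, strand="+", a_interval=a_iv,
        b_interval=b_iv, window=window, frame_offset=frame_offset,
        a_stop_end=stop_end, view=view,
    )


class TestScanOverlap:
    def test_backward_motif_found_at_codon_boundary(self):
        seq = "ATG" + "CCA" + "CG" + "GGGGGAA" + "CAA" + "TAA" + "CCCCC" + "TAA" + "CC"
        pair = _mk_pair(seq, (0, 21), (17, 29))
        assert pair.frame_offset == -1
        cands = scan_overlap(pair, _uniform_usage())
        # the planted GGGGGAA spans two codon boundaries: its first five Gs
        # end at boundary 12 (a *five* hit), the heptamer itself at 15
        assert [(c.motif.name, c.p_site_end) for c in cands] == [
            ("five", 12), ("fivetwo", 15),
        ]
        c = cands[1]
        assert c.direction == -1
        assert c.position == 8
        assert c.a0_codon == "CAA" and c.a1_codon == "ACA"

    def test_forward_requires_a1_more_abundant(self):
        seq = "ATG" + "CCGCC" + "C" + "AAA" + "CGC" + "TAA" + "CCCCCCC" + "TAA" + "CC"
        pair = _mk_pair(seq, (0, 18), (16, 28))
        assert pair.frame_offset == 1
        # uniform usage: A1 is never strictly more abundant -> nothing
        assert scan_overlap(pair, _uniform_usage()) == []
        # A1 > A0 only for the planted site at p=12 (a0 CGC, a1 GCT)
        cands = scan_overlap(
            pair, _usage(CGC=0.01, GCT=0.05, AAA=0.05, AAC=0.01)
        )
        assert [(c.motif.name, c.p_site_end) for c in cands] == [("three", 12)]

    def test_degenerate_window_yields_nothing(self):
        seq = "ATG" + "CCA" + "CG" + "GGGGGAA" + "CAA" + "TAA" + "CCCCC" + "TAA" + "CC"
        pair = _mk_pair(seq, (0, 21), (17, 29))
        pair.window = (15, 18)  # too small to hold a P-site codon boundary
        assert scan_overlap(pair, _uniform_usage()) == []

    def test_candidates_ordered_and_inside_window(self, corpus_small):
        from prfscan.classifier import candidate_sites

        seen = 0
        for rec in corpus_small.records[:4]:
            for ps in candidate_sites(rec, split_joins=True):
                w_start, w_end = ps.pair.window
                positions = [sc.candidate.position for sc in ps.candidates]
                assert positions == sorted(positions)
                for sc in ps.candidates:
                    c = sc.candidate
                    assert w_start <= c.position
                    assert c.p_site_end <= w_end - 3
                    assert c.p_site_end - c.position == c.motif.span
                    seen += 1
        assert seen > 10
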