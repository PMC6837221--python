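import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caseinevo.reference import BOVINE_GMP, BOVINE_MATURE_KAPPA_CASEIN
from caseinevo.seqio import Alignment, NumericTrack, split_regions
from caseinevo.sites import (
    DisulfideScenario,
    SiteSet,
    classify_disulfide,
    cleavage_density,
    cysteine_positions,
    fam20c_sites,
    glyco_threshold,
    paired_one_tailed_t,
    pepsin_sites,
    plasmin_sites,
    scenario_table,
)

# ---------------------------------------------------------------------------
# independent oracles


def fam20c_closure_oracle(seq: str, n: int) -> set[int]:
    """Fixed-point iteration: an S is predicted if the residue two positions
    away (either side) is E, or is an already-predicted S reachable through
    at most n chained serines. Breadth-first closure with depth tracking,
    structurally unlike the production scan."""
    L = len(seq)
    depth: dict[int, int] = {}
    frontier = []
    for i in range(1, L + 1):
        if seq[i - 1] != "S":
            continue
        for j in (i - 2, i + 2):
            if 1 <= j <= L and seq[j - 1] == "E":
                depth[i] = 0
                frontier.append(i)
                break
    while frontier:
        nxt = []
        for i in frontier:
            for j in (i - 2, i + 2):
                if 1 <= j <= L and seq[j - 1] == "S":
                    d = depth[i] + 1
                    if d <= n and (j not in depth or depth[j] > d):
                        depth[j] = d
                        nxt.append(j)
        frontier = nxt
    return set(depth)


PEPSIN_RE = {
    "pH>2": [
        re.compile(r"(?<=[^HKR][^P])[^R](?=[FLWY][^P])"),
        re.compile(r"(?<=[^HKR][^P])[FLWY](?=.[^P])"),
    ],
    "pH1.3": [
        re.compile(r"(?<=[^HKR][^P])[^R](?=[FL][^P])"),
        re.compile(r"(?<=[^HKR][^P])[FL](?=.[^P])"),
    ],
}


def pepsin_regex_oracle(seq: str, variant: str) -> set[int]:
    """Community regex encoding of the PeptideCutter pepsin rule. The fixed
    lookbehind/lookahead widths restrict it to fully interior bonds, so
    comparisons are made on positions 3..L-2 only."""
    hits = set()
    for pat in PEPSIN_RE[variant]:
        for m in pat.finditer(seq):
            hits.add(m.start() + 1)
    return hits


# ---------------------------------------------------------------------------


class TestFam20c:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("SAE", (1,)),
            ("SASAE", (1, 3)),
            ("EASAS", (3, 5)),
            ("SSE", (1,)),
            ("ESE", ()),  # E adjacent, not two away: no S-x-E context
            ("AAAA", ()),
            ("S", ()),
        ],
    )
    def test_worked_examples(self, seq, expected):
        assert fam20c_sites(seq).positions == expected

    def test_chain_truncation_at_n(self):
        # S (x S)*k x E with k intermediate serines: reachable iff k <= n
        k = 3
        seq = "S" + "AS" * k + "AE"
        assert 1 in fam20c_sites(seq, n=k).positions
        assert 1 not in fam20c_sites(seq, n=k - 1).positions

    @given(st.text(alphabet="SEAX", min_size=1, max_size=60), st.integers(0, 10))
    @settings(derandomize=True, max_examples=300)
    def test_equals_closure_oracle(self, seq, n):
        assert set(fam20c_sites(seq, n=n).positions) == fam20c_closure_oracle(seq, n)

    @given(st.text(alphabet="SEAX", min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_chain_length(self, seq):
        prev: set[int] = set()
        for n in (0, 1, 3, 10):
            cur = set(fam20c_sites(seq, n=n).positions)
            assert prev <= cur
            prev = cur

    def test_bovine_s149_predicted(self):
        sites = fam20c_sites(BOVINE_MATURE_KAPPA_CASEIN)
        assert 149 in sites.positions


class TestPepsin:
    def test_worked_example(self):
        assert pepsin_sites("AAFAAA").positions == (2, 3)

    def test_proline_context_blocks(self):
        # Pro at P2 blocks the P1 branch after the Phe; the bond before Phe
        # is still cleavable through the P1' branch
        assert pepsin_sites("AAPFAA").positions == (3,)

    def test_no_targets_no_sites(self):
        assert pepsin_sites("AAGGSTNQ").positions == ()

    def test_variant_narrowing(self):
        seq = "AAYAAA"
        assert pepsin_sites(seq, variant="pH>2").positions != ()
        assert pepsin_sites(seq, variant="pH1.3").positions == ()

    def test_bovine_gmp_counts(self):
        assert len(pepsin_sites(BOVINE_GMP)) == 2
        assert len(pepsin_sites(BOVINE_GMP.replace("I", "L"))) == 9

    @given(st.text(alphabet="AFLWYPHKRIVST", min_size=5, max_size=60),
           st.sampled_from(["pH>2", "pH1.3"]))
    @settings(derandomize=True, max_examples=300)
    def test_equals_regex_oracle_on_interior(self, seq, variant):
        ours = {
            i for i in pepsin_sites(seq, variant=variant).positions
            if 3 <= i <= len(seq) - 2
        }
        theirs = {
            i for i in pepsin_regex_oracle(seq, variant)
            if 3 <= i <= len(seq) - 2
        }
        assert ours == theirs

    @given(st.text(alphabet="AFLWYPIV", min_size=4, max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_ile_val_swap_invariance_and_ile_to_leu_monotone(self, seq):
        base = set(pepsin_sites(seq).positions)
        swapped = set(pepsin_sites(seq.translate(str.maketrans("IV", "VI"))).positions)
        assert base == swapped
        more = set(pepsin_sites(seq.replace("I", "L")).positions)
        assert base <= more


class TestPlasmin:
    def test_worked_examples(self):
        assert plasmin_sites("AKRA").positions == (2, 3)
        assert plasmin_sites("AAAK").positions == ()
        assert plasmin_sites("AAAA").positions == ()

    @given(st.text(alphabet="AKRGSTE", min_size=2, max_size=80))
    @settings(derandomize=True, max_examples=100)
    def test_count_identity(self, seq):
        count = sum(1 for c in seq[:-1] if c in "KR")
        assert len(plasmin_sites(seq)) == count


class TestGlycoThreshold:
    def test_zero_scores_empty(self):
        t = NumericTrack("x", (0.0, 0.0, 0.0))
        assert glyco_threshold(t, "STT").positions == ()

    def test_cutoff_inclusive_and_residue_filtered(self):
        t = NumericTrack("x", (0.4, 0.9, 0.4))
        assert glyco_threshold(t, "TAS").positions == (1, 3)

    def test_high_score_on_non_st_excluded(self):
        t = NumericTrack("x", (0.9,))
        assert glyco_threshold(t, "A").positions == ()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            glyco_threshold(NumericTrack("x", (0.5,)), "ST")


class TestDisulfide:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ((), (False, False, False)),
            ((10,), (True, False, False)),
            ((10, 11), (True, True, False)),
            ((11, 88), (True, True, True)),
            ((5, 6, 50), (True, True, True)),
        ],
    )
    def test_scenarios(self, positions, expected):
        cys = SiteSet(taxon="x", kind="cysteine", positions=positions)
        sc = classify_disulfide(cys)
        assert (sc.dimer, sc.oligomer, sc.intrachain) == expected
        assert sc.n_cysteines == len(positions)

    @given(st.sets(st.integers(1, 60), max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_flags_monotone_under_cysteine_addition(self, positions):
        pos = tuple(sorted(positions))
        base = classify_disulfide(SiteSet(taxon="x", kind="cysteine", positions=pos))
        for extra in (61, 62):
            bigger = classify_disulfide(
                SiteSet(taxon="x", kind="cysteine", positions=pos + (extra,))
            )
            assert bigger.dimer >= base.dimer
            assert bigger.oligomer >= base.oligomer
            assert bigger.intrachain >= base.intrachain

    def test_bovine_has_both_capabilities(self):
        sc = classify_disulfide(cysteine_positions(BOVINE_MATURE_KAPPA_CASEIN, "cow"))
        assert sc.n_cysteines == 2
        assert sc.dimer and sc.oligomer and sc.intrachain

    def test_scenario_table_columns(self):
        aln = Alignment((("a", "ACCA"), ("b", "AAAA")))
        df = scenario_table(aln).set_index("taxon")
        assert bool(df.loc["a", "oligomer"]) is True
        assert bool(df.loc["a", "intrachain"]) is False  # adjacent cysteines
        assert bool(df.loc["b", "dimer"]) is False


class TestCleavageDensity:
    def test_densities_use_ungapped_region_lengths(self):
        aln = Alignment((("ref", "KFAA-TTTT"), ("oth", "KFAAATTTT")))
        regions = split_regions(aln, "ref", cleavage_pos=4)
        df = cleavage_density(aln, regions).set_index(["taxon", "region"])
        assert df.loc[("ref", "PKC"), "length"] == 4
        assert df.loc[("ref", "GMP"), "length"] == 4
        assert df.loc[("oth", "GMP"), "length"] == 5
        assert df.loc[("ref", "GMP"), "n_sites"] == 0

    def test_t_statistic_matches_closed_form(self):
        pkc = [0.10, 0.12, 0.05]
        gmp = [0.02, 0.03, 0.04]
        d = np.array(pkc) - np.array(gmp)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p = paired_one_tailed_t(pkc, gmp)
        assert t == pytest.approx(t_expected)
        from scipy import stats

        assert p == pytest.approx(float(stats.t.sf(t_expected, df=2)))

    def test_identical_pairs_give_half(self):
        t, p = paired_one_tailed_t([0.1, 0.2], [0.1, 0.2])
        assert t == 0.0 and p == 0.5

    def test_constant_positive_difference_degenerate(self):
        t, p = paired_one_tailed_t([0.2, 0.3], [0.1, 0.2])
        assert p == 0.0 and t == np.inf

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_one_tailed_t([0.1], [0.2])
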