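import numpy as np
import pandas as pd
import pytest

from caseinevo.divergence import (
    EpochFit,
    UndefinedDistanceError,
    distance_time_table,
    epoch_rate_fit,
    estimate_shared_alpha,
    jtt_gamma_ml_distance,
    p_distance,
)
from caseinevo.seqio import Alignment, read_tree
from caseinevo.substmodel import JTT_ORDER, JttModel, discrete_gamma_rates

# 300-residue pair simulated under the package's JTT model at separation
# t = 0.2 (single rate); reference ML distances computed independently with
# phangorn::dist.ml (model="JTT") on this exact pair and frozen here.
ORACLE_A = (
    "KWSCETASSIEQQILLVSKVDNKAALIYKLLQADFDGATNQTLTKPRLLTGKAGENSGVK"
    "KKFNHCGRVDFETMNTVYLNDYLDTKLGGCATILEPAGARVMHLTEKFGLSYNYAPSNHS"
    "AKSLPCDGDGVLEQVIVLLWPLHTGYAHLVQSFPKVEGDADYTRKIKMEVIKKDAGSSPR"
    "YSTLYAAAQQDLAKNFAEVLSMKDLASVTAEERKSETSNSTDLKKRMKSSEPTWNAMDLV"
    "GQIMRGNMTGGLDQEIRPLERSNNNRYQETKDHTGPRPSSFGALPDQLPWRDSKPVVTSG"
)
ORACLE_B = (
    "KLSCETASFIEQQILLVSKVVNKELLEYILLQADFDGATNQTLTRYKLLTGLAGENSGVK"
    "KKFNHCGGVDIETFNTVYLPDYLDTKLGGCATILEPAGLRVFHLFLKFGLSYVYAPSNHS"
    "AKSLNTDGDGVEEQVRVLLQPLHTGYAHLVQSFPKVEGDADYTRKIKMEVRKKDAGSSPR"
    "YSTVYAAAFHDLHKNGEEVLSMKDLASVTAEERKSELSNSTDLKKRMKSSEPTWNAMDLV"
    "GQIMRGNMTGGLDQEIFDLERENNNGYQETKDHTGKRPSSTGALEDLWPWRDTKPVNTSG"
)


def evolve_pair(rng, t, length, alpha=None, n_categories=4, model=None):
    """Simulate two sequences separated by total distance t (cherry of t/2)."""
    model = model or JttModel()
    if alpha is None:
        rates = np.ones(1)
        cat = np.zeros(length, dtype=int)
    else:
        rates = discrete_gamma_rates(alpha, n_categories)
        cat = rng.integers(len(rates), size=length)
    anc = rng.choice(20, size=length, p=model.freqs)

    def step(seq, bl):
        out = seq.copy()
        for k, r in enumerate(rates):
            mask = cat == k
            if not mask.any():
                continue
            p = model.transition_matrix(bl * r)
            cum = p.cumsum(axis=1)
            u = rng.random(mask.sum())
            out[mask] = (u[:, None] > cum[seq[mask]]).sum(axis=1)
        return out

    a = step(anc, t / 2)
    b = step(anc, t / 2)
    to_str = lambda s: "".join(JTT_ORDER[i] for i in s)
    return to_str(a), to_str(b)


class TestPDistance:
    def test_simple_mismatch(self):
        assert p_distance("AAAA", "AAAC") == (0.25, 4)

    def test_pairwise_deletion(self):
        assert p_distance("A-CD", "AB-D") == (0.0, 2)

    def test_identical(self):
        assert p_distance("ACDE", "ACDE") == (0.0, 4)

    def test_no_shared_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("A-", "-A")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("AA", "AAA")


class TestMlDistance:
    def test_identical_sequences_give_zero(self):
        assert jtt_gamma_ml_distance("ACDEF" * 10, "ACDEF" * 10) == 0.0

    def test_matches_phangorn_single_rate(self):
        d = jtt_gamma_ml_distance(ORACLE_A, ORACLE_B, alpha=1.0, n_categories=1)
        assert d == pytest.approx(0.184147012, rel=1e-3)

    def test_matches_phangorn_gamma(self):
        d = jtt_gamma_ml_distance(ORACLE_A, ORACLE_B, alpha=0.5, n_categories=4)
        assert d == pytest.approx(0.2625008709, rel=1e-3)

    def test_symmetric_in_arguments(self):
        d1 = jtt_gamma_ml_distance(ORACLE_A, ORACLE_B, alpha=1.0)
        d2 = jtt_gamma_ml_distance(ORACLE_B, ORACLE_A, alpha=1.0)
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_large_alpha_converges_to_single_rate(self):
        d_inf = jtt_gamma_ml_distance(ORACLE_A, ORACLE_B, alpha=1e6, n_categories=4)
        d_one = jtt_gamma_ml_distance(ORACLE_A, ORACLE_B, alpha=1.0, n_categories=1)
        assert d_inf == pytest.approx(d_one, rel=1e-3)

    def test_parameter_recovery_on_simulated_cherry(self, rng):
        a, b = evolve_pair(rng, 0.3, 5000, alpha=1.0)
        d = jtt_gamma_ml_distance(a, b, alpha=1.0)
        # binomial-scale standard error at p~0.25, n=5000 mapped through the
        # correction is ~0.01; allow 3 SE
        assert d == pytest.approx(0.3, abs=0.03)

    def test_poisson_limit_at_small_distance(self, rng):
        a, b = evolve_pair(rng, 0.015, 8000)
        p, _ = p_distance(a, b)
        d = jtt_gamma_ml_distance(a, b, alpha=1.0, n_categories=1)
        assert p <= 0.02
        assert d == pytest.approx(p, rel=0.05)

    def test_monotone_in_divergence_along_trajectory(self, rng):
        model = JttModel()
        dists = []
        for t in (0.05, 0.2, 0.6, 1.2):
            a, b = evolve_pair(rng, t, 3000, model=model)
            dists.append(jtt_gamma_ml_distance(a, b, alpha=1.0, model=model))
        assert dists == sorted(dists)


class TestDistanceTimeTable:
    def test_three_taxon_table(self, newick_file):
        aln = Alignment(
            (("A", "ACDEFGHIKL"), ("B", "ACDEFGHIKM"), ("C", "ACDEWGHIKM"))
        )
        tree = read_tree(newick_file("((A:10,B:10):10,C:20);"))
        table = distance_time_table(aln, tree, alpha=1.0)
        assert len(table) == 3
        row = table.set_index(["taxon_a", "taxon_b"]).loc[("A", "B")]
        assert row["p_distance"] == pytest.approx(0.1)
        assert row["divergence_time"] == pytest.approx(10.0)
        assert (table["ml_distance"] >= table["p_distance"] - 1e-9).all()

    def test_pair_count(self, newick_file, rng):
        taxa = [f"t{i}" for i in range(5)]
        seqs = ["".join(rng.choice(list("ACDE"), size=8)) for _ in taxa]
        aln = Alignment(tuple(zip(taxa, seqs)))
        tree = read_tree(newick_file("((((t0:1,t1:1):1,t2:2):1,t3:3):1,t4:4);"))
        table = distance_time_table(aln, tree, alpha=1.0)
        assert len(table) == 5 * 4 // 2

    def test_missing_taxon_rejected(self, newick_file, toy_alignment):
        tree = read_tree(newick_file("(cow:1,pig:1);"))
        with pytest.raises(KeyError, match="rat"):
            distance_time_table(toy_alignment, tree, alpha=1.0)

    def test_shared_alpha_grid_detects_strong_heterogeneity(self, rng):
        a, b = evolve_pair(rng, 1.5, 6000, alpha=0.25)
        est = estimate_shared_alpha(Alignment((("pa", a), ("pb", b))))
        assert est <= 0.5


class TestEpochFit:
    def test_noiseless_recovery_exact(self):
        t = np.array([10.0, 30.0, 59.0, 80.0, 120.0, 160.0])
        s_recent, s_old, b = 0.002, 0.006, 60.0
        d = s_recent * np.minimum(t, b) + s_old * np.maximum(t - b, 0)
        table = pd.DataFrame({"divergence_time": t, "ml_distance": d})
        fit = epoch_rate_fit(table, breakpoint=b)
        assert fit.slope_ratio == pytest.approx(3.0, abs=1e-9)

    def test_single_line_gives_ratio_one(self):
        t = np.linspace(5, 150, 20)
        table = pd.DataFrame({"divergence_time": t, "ml_distance": 0.004 * t})
        fit = epoch_rate_fit(table, breakpoint=60.0)
        assert fit.slope_ratio == pytest.approx(1.0, rel=1e-6)

    def test_breakpoint_outside_range_rejected(self):
        table = pd.DataFrame({"divergence_time": [10, 20], "ml_distance": [0.1, 0.2]})
        with pytest.raises(ValueError):
            epoch_rate_fit(table, breakpoint=60.0)

    def test_predict_matches_design(self):
        fit = EpochFit(breakpoint=60.0, slope_recent=0.002, slope_old=0.004)
        assert fit.predict([30.0])[0] == pytest.approx(0.06)
        assert fit.predict([100.0])[0] == pytest.approx(0.12 + 0.16)
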