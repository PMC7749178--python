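"""Stitching, SE calling, subtype tests, target assignment and CRC cliques."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicircuit.superenhancer import (
    assign_se_target,
    call_superenhancers,
    crc_cliques,
    se_gene_score,
    se_signal_tstat,
    stitch_enhancers,
    subtype_se_test,
    subtype_specific_ses,
)


def iv(*triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


class TestStitching:
    def test_gap_rule(self):
        one = stitch_enhancers(iv(("chr1", 0, 500), ("chr1", 10_000, 10_500)))
        assert one[["start", "end"]].values.tolist() == [[0, 10_500]]
        two = stitch_enhancers(iv(("chr1", 0, 500), ("chr1", 13_500, 14_000)))
        assert len(two) == 2  # gap 13,000 > 12,500

    def test_signal_summed_over_constituents(self):
        peaks = iv(("chr1", 0, 500), ("chr1", 5_000, 5_500), ("chr1", 40_000, 40_500))
        sig = pd.DataFrame({"s1": [1.0, 2.0, 7.0], "s2": [0.5, 0.5, 3.0]})
        out = stitch_enhancers(peaks, sig)
        assert out["s1"].tolist() == [3.0, 7.0]
        assert out["s2"].tolist() == [1.0, 3.0]

    def test_matches_chaining_oracle_and_order_invariance(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 20))
            starts = np.sort(rng.integers(0, 200_000, n))
            peaks = pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + rng.integers(100, 2_000, n)}
            )
            got = stitch_enhancers(peaks)
            shuffled = stitch_enhancers(peaks.sample(frac=1, random_state=0))
            assert got.equals(shuffled)
            # union-find oracle: link peaks within 12.5 kb, transitively
            merged = sorted(
                zip(got["start"], got["end"])
            )
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            sp = peaks.sort_values("start").reset_index(drop=True)
            for i, j in itertools.combinations(range(n), 2):
                gap = sp.loc[j, "start"] - sp.loc[i, "end"]
                if gap <= 12_500:
                    parent[find(j)] = find(i)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(i)
            oracle = sorted(
                (int(sp.loc[g, "start"].min()), int(sp.loc[g, "end"].max()))
                for g in groups.values()
            )
            assert merged == oracle


class TestSECall:
    def test_single_outlier_called(self):
        res = call_superenhancers(np.array([1.0, 1, 1, 1, 10]))
        assert res.is_super.tolist() == [False, False, False, False, True]
        assert res.cutoff == 1.0

    def test_flat_curve_yields_none(self):
        res = call_superenhancers(np.full(6, 3.0))
        assert not res.is_super.any()

    def test_scale_invariance(self, rng):
        sig = rng.lognormal(2, 1, 50)
        a = call_superenhancers(sig)
        b = call_superenhancers(sig * 7.3)
        assert np.array_equal(a.is_super, b.is_super)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError, match="at least 3"):
            call_superenhancers(np.array([1.0, 2.0]))

    def test_tangent_point_geometric_oracle(self, rng):
        # on a convex hockey stick the chosen cutoff index minimises y - x
        sig = np.sort(rng.lognormal(0, 1.5, 200))
        res = call_superenhancers(sig)
        x = np.linspace(0, 1, len(sig))
        y = (sig - sig[0]) / (sig[-1] - sig[0])
        assert res.cutoff == sig[int(np.argmin(y - x))]
        assert np.array_equal(res.is_super, sig > res.cutoff)


def make_signal(effect_lfc, n_per=5, n_ses=20, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    subtypes = ["IDH", "MES", "RTK_I", "RTK_II"]
    samples = [f"{st}_{i}" for st in subtypes for i in range(n_per)]
    labels = {s: s.rsplit("_", 1)[0] for s in samples}
    base = np.full((n_ses, len(samples)), 8.0)
    planted = {}
    for i in range(n_ses):
        st = subtypes[i % 4]
        planted[f"SE{i}"] = st
        cols = [j for j, s in enumerate(samples) if labels[s] == st]
        base[i, cols] *= 2.0**effect_lfc
    sig = base * rng.lognormal(0, noise, base.shape)
    return pd.DataFrame(sig, index=[f"SE{i}" for i in range(n_ses)], columns=samples), labels, planted


class TestSubtypeSETest:
    def test_planted_fourfold_assigned(self):
        sig, labels, planted = make_signal(effect_lfc=2.0)
        res = subtype_se_test(sig, labels)
        assert (res["assigned_subtype"] == pd.Series(planted)).all()

    def test_no_difference_no_assignment(self):
        sig, labels, _ = make_signal(effect_lfc=0.0)
        res = subtype_se_test(sig, labels)
        assert res["assigned_subtype"].isna().all()

    def test_logfc_gate_blocks_small_effects(self):
        # clear significance but log2 FC ~= 0.8 < 1
        sig, labels, _ = make_signal(effect_lfc=0.8, noise=0.01)
        res = subtype_se_test(sig, labels)
        assert (res["adj_p"] < 0.01).all()
        assert res["assigned_subtype"].isna().all()

    def test_degenerate_constant_rows_flagged(self):
        sig, labels, _ = make_signal(effect_lfc=0.0, noise=0.0)
        res = subtype_se_test(sig, labels)
        assert res["degenerate"].all()
        assert res["assigned_subtype"].isna().all()

    def test_anova_matches_scipy_on_random_matrix(self, rng):
        sig, labels, _ = make_signal(effect_lfc=0.5, noise=0.3, seed=3)
        res = subtype_se_test(sig, labels)
        groups = {}
        for s, st in labels.items():
            groups.setdefault(st, []).append(s)
        for se_id in sig.index:
            f, p = stats.f_oneway(*[sig.loc[se_id, cols].to_numpy() for cols in groups.values()])
            assert res.loc[se_id, "F"] == pytest.approx(f)
            assert res.loc[se_id, "p"] == pytest.approx(p)


class TestSubtypeSpecific:
    def test_shared_se_excluded_unique_kept(self):
        per_subtype = {
            "MES": iv(("chr1", 0, 10_000), ("chr1", 50_000, 60_000)),
            "RTK_I": iv(("chr1", 0, 10_000)),
        }
        out = subtype_specific_ses(per_subtype)
        assert out["MES"][["start", "end"]].values.tolist() == [[50_000, 60_000]]
        assert len(out["RTK_I"]) == 0

    def test_gene_score_mean_of_constant(self):
        expr = pd.DataFrame(5.0, index=["g1", "g2"], columns=["s1", "s2"])
        assert se_gene_score(expr, ["g1", "g2"]).tolist() == [5.0, 5.0]


def make_target_instance(rng, n_genes=8, n_samples=20):
    tads = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 1_000_000], "end": [1_000_000, 2_000_000],
         "tad_id": ["T0", "T1"]}
    )
    se = pd.Series({"chrom": "chr1", "start": 100_000, "end": 120_000})
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": "chr1",
            "tss": rng.integers(0, 2_000_000, n_genes),
        }
    )
    genes["tad_id"] = np.where(genes["tss"] < 1_000_000, "T0", "T1")
    samples = [f"s{i}" for i in range(n_samples)]
    signal = pd.Series(rng.lognormal(3, 1, n_samples), index=samples)
    expr = pd.DataFrame(
        rng.normal(0, 1, (n_genes, n_samples)), index=genes["gene_id"], columns=samples
    )
    return se, signal, expr, genes, tads


class TestTargetAssignment:
    def test_tad_constraint_beats_higher_rho(self, rng):
        tads = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 500_000], "end": [500_000, 1_000_000],
             "tad_id": ["T0", "T1"]}
        )
        se = pd.Series({"chrom": "chr1", "start": 400_000, "end": 420_000})
        genes = pd.DataFrame(
            {"gene_id": ["G1", "G2"], "chrom": "chr1", "tss": [450_000, 550_000],
             "tad_id": ["T0", "T1"]}
        )
        samples = [f"s{i}" for i in range(10)]
        signal = pd.Series(np.arange(10.0), index=samples)
        expr = pd.DataFrame(
            {
                s: [0.9 * i + rng.normal(0, 0.5), i] for i, s in enumerate(samples)
            }, index=["G1", "G2"]
        )
        res = assign_se_target(se, signal, expr, genes, tads)
        assert res["gene_id"] == "G1"  # G2 correlates perfectly but sits in T1

    def test_single_candidate_wins_regardless_of_sign(self, rng):
        se, signal, expr, genes, tads = make_target_instance(rng, n_genes=1)
        genes.loc[0, ["tss", "tad_id"]] = [200_000, "T0"]
        expr.iloc[0] = -signal.to_numpy()  # perfectly anti-correlated
        res = assign_se_target(se, signal, expr, genes, tads)
        assert res["gene_id"] == "g0" and res["rho"] == pytest.approx(-1.0)

    def test_requires_four_paired_samples(self, rng):
        se, signal, expr, genes, tads = make_target_instance(rng, n_samples=3)
        with pytest.raises(ValueError, match="4 paired samples"):
            assign_se_target(se, signal, expr, genes, tads)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            se, signal, expr, genes, tads = make_target_instance(rng)
            res = assign_se_target(se, signal, expr, genes, tads)
            # oracle: scan every gene, apply constraints, argmax rho with ties
            best = None
            for row in genes.itertuples():
                dist = max(row.tss - 120_000 + 1, 100_000 - row.tss, 0)
                if dist > 500_000 or row.tad_id != "T0":
                    continue
                rho = stats.spearmanr(signal, expr.loc[row.gene_id]).statistic
                key = (-rho, dist, row.gene_id)
                if best is None or key < best[0]:
                    best = (key, row.gene_id, rho)
            if best is None:
                assert res is None
            else:
                assert res["gene_id"] == best[1]
                assert res["rho"] == pytest.approx(best[2])


def brute_force_cliques(tf_to_se, motif):
    """Exhaustive maximal-subset enumeration of the mutual-motif condition."""
    tfs = sorted(tf_to_se)
    qualifying = []
    for r in range(1, len(tfs) + 1):
        for combo in itertools.combinations(tfs, r):
            if all(
                bool(motif.loc[a, tf_to_se[b]]) for a in combo for b in combo
            ):
                qualifying.append(set(combo))
    return sorted(
        (sorted(c) for c in qualifying
         if not any(c < other for other in qualifying)),
        key=lambda c: (-len(c), c),
    )


class TestCRCCliques:
    def test_complete_graph_single_clique(self):
        tf_to_se = {"A": "seA", "B": "seB", "C": "seC"}
        motif = pd.DataFrame(True, index=list("ABC"), columns=["seA", "seB", "seC"])
        out = crc_cliques(tf_to_se, motif)
        assert [c["tfs"] for c in out] == [["A", "B", "C"]]
        assert out[0]["ses"] == ["seA", "seB", "seC"]

    def test_missing_motif_splits_clique(self):
        tf_to_se = {"A": "seA", "B": "seB", "C": "seC"}
        motif = pd.DataFrame(True, index=list("ABC"), columns=["seA", "seB", "seC"])
        motif.loc["C", "seA"] = False  # A's SE lacks C's motif
        out = crc_cliques(tf_to_se, motif)
        assert [c["tfs"] for c in out] == brute_force_cliques(tf_to_se, motif)

    def test_non_autoregulatory_tf_excluded(self):
        tf_to_se = {"A": "seA", "B": "seB"}
        motif = pd.DataFrame(True, index=list("AB"), columns=["seA", "seB"])
        motif.loc["A", "seA"] = False  # A's own SE lacks A's motif
        out = crc_cliques(tf_to_se, motif)
        assert [c["tfs"] for c in out] == [["B"]]

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            tfs = [f"T{i}" for i in range(n)]
            ses = [f"se{i}" for i in range(n)]
            tf_to_se = dict(zip(tfs, ses))
            motif = pd.DataFrame(
                rng.random((n, n)) < 0.6, index=tfs, columns=ses
            )
            got = [c["tfs"] for c in crc_cliques(tf_to_se, motif)]
            auto = {t for t in tfs if motif.loc[t, tf_to_se[t]]}
            expect = brute_force_cliques(
                {t: tf_to_se[t] for t in auto},
                motif,
            )
            assert got == expect


class TestSignalTStat:
    def test_separated_sets_give_large_t(self, rng):
        a = 10 + rng.normal(0, 0.01, 20)
        b = 1 + rng.normal(0, 0.01, 20)
        assert se_signal_tstat(a, b) > 50

    def test_identical_sets_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert se_signal_tstat(x, x) == 0.0

    def test_matches_welch_formula(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 9)
        t = se_signal_tstat(a, b)
        expect = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        )
        assert t == pytest.approx(expect)
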