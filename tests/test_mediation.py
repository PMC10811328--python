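import numpy as np
import pandas as pd
import pytest

from teqtl import mediation as med
from teqtl import synthetic as syn
from teqtl.datatypes import TOPOLOGIES
from teqtl.prep import rank_normalize

from helpers import make_phenotype_table


class TestPairPC1:
    def test_identical_vectors(self, rng):
        v = rng.normal(size=100)
        pq = med.pair_pc1(v, v)
        assert pq.var_explained == pytest.approx(1.0)
        # pc1 is the rank-normalized common vector
        expected = rank_normalize(pd.DataFrame({"x": v}))["x"].to_numpy()
        np.testing.assert_allclose(np.abs(pq.pc1), np.abs(expected), atol=1e-9)

    def test_anticorrelated_sign_tracks_gene(self, rng):
        v = rng.normal(size=100)
        pq = med.pair_pc1(-v, v)
        assert pq.var_explained == pytest.approx(1.0)
        assert pq.loadings[1] >= 0
        # pc1 correlates positively with the gene vector
        assert np.corrcoef(pq.pc1, v)[0, 1] > 0.99

    def test_orthogonal_inputs_split_variance(self, rng):
        pq = med.pair_pc1(rng.normal(size=5000), rng.normal(size=5000))
        assert pq.var_explained == pytest.approx(0.5, abs=0.05)

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            med.pair_pc1(np.ones(50), rng.normal(size=50))


class TestBNLoglik:
    def _node_oracle(self, d, t, g, topology):
        """Independent per-node regression log-likelihood computation."""

        def ll_marginal(x):
            var = x.var()
            return -0.5 * len(x) * (np.log(2 * np.pi * var) + 1)

        def ll_cond(y, x):
            b1, b0 = np.polyfit(x, y, 1)
            resid = y - (b0 + b1 * x)
            var = (resid**2).mean()
            return -0.5 * len(y) * (np.log(2 * np.pi * var) + 1)

        parts = {"causal": [ll_marginal(d), ll_cond(t, d), ll_cond(g, t)],
                 "reactive": [ll_marginal(d), ll_cond(g, d), ll_cond(t, g)],
                 "independent": [ll_marginal(d), ll_cond(t, d), ll_cond(g, d)]}
        return sum(parts[topology])

    def test_matches_node_wise_oracle(self, rng):
        d = rng.binomial(2, 0.3, 200).astype(float)
        t = 0.5 * d + rng.normal(size=200)
        g = 0.4 * t + rng.normal(size=200)
        for topo in TOPOLOGIES:
            assert med.bn_loglik(d, t, g, topo) == pytest.approx(
                self._node_oracle(d, t, g, topo), abs=1e-9
            )

    def test_te_gene_swap_exchanges_causal_reactive(self, rng):
        d = rng.binomial(2, 0.3, 150).astype(float)
        t, g = rng.normal(size=150), rng.normal(size=150)
        assert med.bn_loglik(d, t, g, "causal") == med.bn_loglik(d, g, t, "reactive")
        assert med.bn_loglik(d, t, g, "reactive") == med.bn_loglik(d, g, t, "causal")

    def test_duplicating_samples_doubles_loglik(self, rng):
        d = rng.binomial(2, 0.3, 80).astype(float)
        t = 0.5 * d + rng.normal(size=80)
        g = 0.5 * t + rng.normal(size=80)
        for topo in TOPOLOGIES:
            once = med.bn_loglik(d, t, g, topo)
            twice = med.bn_loglik(np.tile(d, 2), np.tile(t, 2), np.tile(g, 2), topo)
            assert twice == pytest.approx(2 * once, rel=1e-12)

    def test_unknown_topology(self, rng):
        with pytest.raises(ValueError):
            med.bn_loglik(np.ones(5), np.ones(5), np.ones(5), "mediated")


class TestPosteriors:
    def test_simplex_and_tie_order(self, rng):
        d = rng.binomial(2, 0.3, 100).astype(float)
        t = 0.5 * d + rng.normal(size=100)
        g = 0.5 * t + rng.normal(size=100)
        ll, post, assigned = med.bn_posteriors(d, t, g)
        assert post.min() >= 0
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert assigned == TOPOLOGIES[int(np.argmax(ll))]

    def test_variant_marginal_cancels(self, rng):
        # posteriors are unchanged if ll(V) is subtracted from every model
        d = rng.binomial(2, 0.3, 100).astype(float)
        t = 0.5 * d + rng.normal(size=100)
        g = 0.5 * t + rng.normal(size=100)
        ll, post, _ = med.bn_posteriors(d, t, g)
        llv = med._gauss_ll(d)
        shifted = ll - llv
        ref = np.exp(shifted - shifted.max())
        np.testing.assert_allclose(post, ref / ref.sum(), atol=1e-12)

    @pytest.mark.parametrize("topology", TOPOLOGIES)
    def test_topology_recovery(self, topology):
        n_seeds, correct, mean_post = 100, 0, []
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = rng.binomial(2, 0.3, 275).astype(float)
            t, g = syn.simulate_triplet(d, topology, 0.5, 0.5, 1.0, seed=seed + 5000)
            _, post, assigned = med.bn_posteriors(d, t, g)
            correct += assigned == topology
            mean_post.append(post[TOPOLOGIES.index(topology)])
        assert correct / n_seeds >= 0.85
        assert float(np.mean(mean_post)) >= 0.8


class TestLD:
    def test_identical_vectors_r2_one(self, rng):
        d = rng.binomial(2, 0.3, 100).astype(float)
        assert med.ld_r2(d, d) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 275).astype(float)
        b = rng.binomial(2, 0.3, 275).astype(float)
        assert med.ld_r2(a, b) < 0.05

    def test_constant_vector_errors(self, rng):
        with pytest.raises(ValueError):
            med.ld_r2(np.ones(10), rng.binomial(2, 0.3, 10).astype(float))


def _triplet_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "te_id", "gene_id", "assigned_model"])


class TestSwitches:
    @pytest.fixture
    def dosages(self, rng):
        d = pd.DataFrame(
            rng.binomial(2, 0.4, size=(200, 4)).astype(float), columns=["vA", "vB", "vC", "vD"]
        )
        d["vA_proxy"] = d["vA"]  # perfect LD
        noisy = d["vA"].to_numpy().copy()
        flip = rng.random(200) < 0.2
        noisy[flip] = rng.binomial(2, 0.4, flip.sum())
        d["vA_weak"] = noisy  # r^2 well below 0.9
        return d

    def test_identical_data_no_switch(self, dosages):
        tn = _triplet_frame([["vA", "te1", "g1", "causal"]])
        out = med.match_and_classify_switches(tn, tn, dosages)
        assert out["switch_label"].iloc[0] == "no_switch"

    def test_switch_to_causal(self, dosages):
        tn = _triplet_frame([["vA", "te1", "g1", "independent"]])
        tt = _triplet_frame([["vA", "te1", "g1", "causal"]])
        out = med.match_and_classify_switches(tn, tt, dosages)
        assert out["switch_label"].iloc[0] == "switch_to_causal"

    def test_ld_proxy_matches_exact_boundary(self, dosages):
        r2_weak = med.ld_r2(dosages["vA"], dosages["vA_weak"])
        assert r2_weak < 0.9
        tn = _triplet_frame([["vA_weak", "te1", "g1", "causal"]])
        tt = _triplet_frame([["vA", "te1", "g1", "causal"]])
        out = med.match_and_classify_switches(tn, tt, dosages)
        assert out["switch_label"].iloc[0] == "unmatched"
        # a perfect proxy matches
        tn2 = _triplet_frame([["vA_proxy", "te1", "g1", "reactive"]])
        out2 = med.match_and_classify_switches(tn2, tt, dosages)
        assert out2["switch_label"].iloc[0] == "switch_to_causal"

    def test_union_deduplicates(self):
        tn = _triplet_frame([["vA", "te1", "g1", "causal"]])
        tt = _triplet_frame([["vA", "te1", "g1", "independent"], ["vB", "te2", "g2", "causal"]])
        union = med.union_triplets(tn, tt)
        assert len(union) == 2


class TestScans:
    def test_te_gene_scan_recovers_planted_pair(self, rng):
        n = 200
        te_vals = rng.normal(size=(n, 8))
        gene_vals = rng.normal(size=(n, 4))
        gene_vals[:, 1] = 0.6 * te_vals[:, 2] + rng.normal(size=n)
        te_t = make_phenotype_table(
            rank_normalize(pd.DataFrame(te_vals)).to_numpy(), feature_class="TE:L1", stage="ranknorm"
        )
        gene_t = make_phenotype_table(
            rank_normalize(pd.DataFrame(gene_vals)).to_numpy(), stage="ranknorm", spacing=120_000
        )
        pairs = med.te_gene_scan(te_t, gene_t, n_perm=200, fdr=0.05, seed=0)
        assert ("f0002", "f0001") in set(zip(pairs["te_id"], pairs["gene_id"]))

    def test_triplet_qtl_end_to_end(self, rng):
        n = 200
        vs = syn.generate_genotypes(n, 30, maf_low=0.3, maf_high=0.5, seed=3)
        d = vs.dosages["var000010"].to_numpy()
        te, gene = syn.simulate_triplet(d, "causal", 0.5, 0.5, 1.0, seed=4)
        pq = med.pair_pc1(te, gene, "te1", "g1")
        pos = int(vs.variants.loc["var000010", "pos"])
        pair_pos = pd.DataFrame(
            {"chrom": ["chr1"], "te_tss": [pos + 1000], "gene_tss": [pos + 5000]},
            index=["te1|g1"],
        )
        dosages = vs.dosages.set_index(pd.RangeIndex(n))
        with pytest.warns(UserWarning):  # < 100 phenotypes for qvalues
            trip = med.triplet_qtl([pq], pair_pos, vs, vs.dosages, n_perm=200, seed=5)
        assert len(trip) == 1
        assert med.ld_r2(
            vs.dosages[trip["variant_id"].iloc[0]].to_numpy(), d
        ) > 0.8

    def test_window_excluding_variant_yields_nothing(self, rng):
        n = 150
        vs = syn.generate_genotypes(n, 10, chrom_length=1_000_000, seed=6)
        d = vs.dosages["var000005"].to_numpy()
        te, gene = syn.simulate_triplet(d, "causal", 0.6, 0.6, 1.0, seed=7)
        pq = med.pair_pc1(te, gene, "te1", "g1")
        pair_pos = pd.DataFrame(
            {"chrom": ["chr9"], "te_tss": [100], "gene_tss": [200]}, index=["te1|g1"]
        )
        trip = med.triplet_qtl([pq], pair_pos, vs, vs.dosages, n_perm=200, seed=8)
        assert trip.empty


class TestModelInterface:
    def test_triplet_model_summary(self, rng):
        d = rng.binomial(2, 0.3, 275).astype(float)
        te, gene = syn.simulate_triplet(d, "causal", 0.5, 0.5, 1.0, seed=1)
        res = med.TripletModel(d, te, gene).fit()
        assert res.assigned_model == "causal"
        assert "assigned model: causal" in res.summary()
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)
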