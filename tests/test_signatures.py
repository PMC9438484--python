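"""Gene-set scoring, the composite competence index, temporal patterns."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from singleseed.signatures import (
    SignedGeneSet,
    cluster_temporal_patterns,
    composite_signature,
    correlate_signatures,
    module_score,
    signature_from_de,
)


def _residuals(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"s{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes),
    )


class TestSignedGeneSet:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SignedGeneSet("x", up=["a"], down=["a"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SignedGeneSet("x", up=[], down=[])

    def test_duplicates_collapsed(self):
        s = SignedGeneSet("x", up=["a", "a", "b"])
        assert s.up == ["a", "b"]


class TestModuleScore:
    def test_single_gene_set_returns_that_gene(self, rng):
        X = rng.normal(size=(10, 3))
        r = _residuals(X)
        np.testing.assert_allclose(module_score(r, ["g1"]), X[:, 1])

    def test_zero_residuals_zero_score(self):
        r = _residuals(np.zeros((4, 5)))
        assert (module_score(r, [f"g{j}" for j in range(5)]) == 0).all()

    def test_gene_order_and_duplicates_irrelevant(self, rng):
        r = _residuals(rng.normal(size=(10, 4)))
        a = module_score(r, ["g0", "g2", "g3"])
        b = module_score(r, ["g3", "g0", "g2", "g0"])
        pd.testing.assert_series_equal(a, b)

    def test_all_genes_missing_rejected(self, rng):
        r = _residuals(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="none of the listed"):
            module_score(r, ["nope"])

    def test_tracks_latent_competence(self, small_residuals):
        resid, _, truth = small_residuals
        g1 = [g for g in resid.var_names if truth.genes.loc[g, "program"] == "group1"]
        score = module_score(resid, g1)
        rho = stats.spearmanr(
            score, truth.seeds.loc[resid.obs_names, "latent_competence"]
        )[0]
        assert rho >= 0.8


class TestCompositeSignature:
    def test_minmax_scaling_exact(self):
        X = np.array([[-2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        r = _residuals(X)
        s = composite_signature(r, SignedGeneSet("x", up=["g0"], down=["g1"]))
        np.testing.assert_allclose(s.to_numpy(), [-1.0, 0.0, 1.0])

    def test_swapping_sets_negates_raw(self, rng):
        r = _residuals(rng.normal(size=(20, 6)))
        up, down = ["g0", "g1"], ["g4", "g5"]
        _, raw = composite_signature(r, SignedGeneSet("a", up, down), return_raw=True)
        _, raw_swapped = composite_signature(r, SignedGeneSet("b", down, up), return_raw=True)
        np.testing.assert_allclose(raw.to_numpy(), -raw_swapped.to_numpy())

    def test_degenerate_scores_map_to_zero(self):
        r = _residuals(np.ones((5, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            s = composite_signature(r, SignedGeneSet("x", up=["g0"], down=["g1"]))
        assert (s == 0).all()

    def test_bounds_always_attained(self, small_residuals):
        resid, _, truth = small_residuals
        g1 = [g for g in resid.var_names if truth.genes.loc[g, "program"] == "group1"]
        g2 = [g for g in resid.var_names if truth.genes.loc[g, "program"] == "group2"]
        s = composite_signature(resid, SignedGeneSet("c", up=g1, down=g2))
        assert s.min() == -1.0 and s.max() == 1.0

    def test_recovers_latent_competence(self, small_residuals):
        resid, _, truth = small_residuals
        g1 = [g for g in resid.var_names if truth.genes.loc[g, "program"] == "group1"]
        g2 = [g for g in resid.var_names if truth.genes.loc[g, "program"] == "group2"]
        s = composite_signature(resid, SignedGeneSet("c", up=g1, down=g2))
        rho = stats.spearmanr(
            s, truth.seeds.loc[resid.obs_names, "latent_competence"]
        )[0]
        assert rho >= 0.9

    def test_missing_side_rejected(self, rng):
        r = _residuals(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="both up and down"):
            composite_signature(r, SignedGeneSet("x", up=["g0"], down=["absent"]))


class TestSignatureFromDe:
    def _table(self):
        return pd.DataFrame(
            {
                "log2fc": [2.0, 1.5, -1.0, -0.5, 0.1],
                "p_adjusted": [0.01, 0.04, 0.02, 0.03, 0.9],
            },
            index=["u1", "u2", "d1", "d2", "ns"],
        )

    def test_sizes(self):
        s = signature_from_de(self._table())
        assert (len(s.up), len(s.down)) == (2, 2)
        assert set(s.up) == {"u1", "u2"}

    def test_all_nonsignificant_rejected(self):
        t = self._table()
        t["p_adjusted"] = 0.5
        with pytest.raises(ValueError, match="no significant"):
            signature_from_de(t)


class TestMutantContrast:
    def test_dormancy_mutant_degs_enrich_programs(self, small_experiment):
        """A dormancy-deficient (dog1-like) contrast shifts the latent
        competence up, so genes higher in the wild type are enriched for
        the dry-seed program and genes lower for the germination
        program."""
        from singleseed import simulate_experiment, wilcoxon_de
        from singleseed.normalize import sctransform_like
        from singleseed.qc import run_qc
        from conftest import small_config

        _, truth = small_experiment
        cfg = small_config(rng_seed=91, n_timepoints=1,
                           timepoint_labels=("dry",),
                           competence_mean_per_timepoint=(0.0,),
                           competence_sd_per_timepoint=(0.5,),
                           seeds_per_timepoint=96, dog1_fraction=0.5)
        mdata, mtruth = simulate_experiment(cfg, genes=truth.genes)
        filt, _ = run_qc(mdata)
        resid, _ = sctransform_like(filt)
        geno = pd.Series(filt.obs["genotype"].to_numpy(), index=filt.obs_names)
        de = wilcoxon_de(resid, geno, counts=filt, lfc=0.0)
        assert de.attrs["group_a"] == "Col-0"
        sig = signature_from_de(de, name="dog1_like")
        prog = truth.genes["program"]
        up_frac_group2 = (prog.loc[sig.up] == "group2").mean()
        down_frac_group1 = (prog.loc[sig.down] == "group1").mean()
        assert up_frac_group2 > 0.5
        assert down_frac_group1 > 0.5


class TestPoolsplitComposite:
    def test_technical_control_composite_spread_smallest(self):
        """The raw composite spread of pool-split aliquots sits below
        that of every biological time point."""
        from singleseed import simulate_experiment, simulate_poolsplit
        from singleseed.normalize import sctransform_like
        from singleseed.qc import filter_genes_mean, run_qc
        from conftest import small_config

        cfg = small_config(rng_seed=5)
        adata, truth = simulate_experiment(cfg)
        filt, _ = run_qc(adata)
        resid, _ = sctransform_like(filt)
        ps = simulate_poolsplit(cfg, n_aliquots=64)
        ps_resid, _ = sctransform_like(filter_genes_mean(ps, 1.0))

        def raw_composite(r, genes_table):
            g1 = [g for g in r.var_names if genes_table.loc[g, "program"] == "group1"]
            g2 = [g for g in r.var_names if genes_table.loc[g, "program"] == "group2"]
            _, raw = composite_signature(
                r, SignedGeneSet("c", up=g1, down=g2), return_raw=True
            )
            return raw

        ps_var = raw_composite(ps_resid, truth.genes).var()
        for tp in cfg.timepoint_labels:
            sub = resid[resid.obs["timepoint"] == tp]
            assert raw_composite(sub, truth.genes).var() > ps_var


class TestCorrelateSignatures:
    def test_identity_and_negation(self, rng):
        a = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        assert correlate_signatures(a, a) == pytest.approx(1.0)
        assert correlate_signatures(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = pd.Series(np.ones(5), index=list("abcde"))
        b = pd.Series(np.arange(5.0), index=list("abcde"))
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_signatures(a, b)

    def test_requires_shared_seeds(self, rng):
        a = pd.Series(rng.normal(size=3), index=["a", "b", "c"])
        b = pd.Series(rng.normal(size=3), index=["x", "y", "z"])
        with pytest.raises(ValueError, match="shared seeds"):
            correlate_signatures(a, b)


class TestTemporalPatterns:
    def test_increasing_profiles_grouped_as_gradually_up(self, rng):
        base = np.linspace(0, 1, 5)
        up = np.vstack([base * s + rng.normal(0, 0.02, 5) for s in rng.uniform(0.5, 2.0, 11)])
        down = -base[None, :]
        profiles = pd.DataFrame(
            np.vstack([up, down]), index=[f"g{i}" for i in range(12)]
        )
        out = cluster_temporal_patterns(profiles, k=2)
        up_groups = out.iloc[:11]["group"]
        assert up_groups.nunique() == 1
        assert out.iloc[11]["group"] != up_groups.iloc[0]
        assert (out.iloc[:11]["pattern"] == "gradually-up").all()

    def test_k_equal_n_gives_singletons(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(6, 4)))
        out = cluster_temporal_patterns(profiles, k=6)
        assert out["group"].nunique() == 6

    def test_mirrored_profiles_never_share_group(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        profiles = pd.DataFrame([x, -x, x * 2, -x * 3], index=list("abcd"))
        out = cluster_temporal_patterns(profiles, k=2)
        assert out.loc["a", "group"] != out.loc["b", "group"]
        assert out.loc["a", "group"] == out.loc["c", "group"]

    def test_too_few_genes_rejected(self):
        profiles = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="at least k"):
            cluster_temporal_patterns(profiles, k=5)
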