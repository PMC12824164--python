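"""Co-expression network: TOM oracle, module recovery, preservation, hubs."""

import numpy as np
import pandas as pd
import pytest

from radpatho import network, synthdata
from radpatho.network import ModuleSet, NetworkParams


def tom_triple_sum_oracle(a):
    """Direct triple-sum TOM definition, O(n^3)."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            shared += a[i, i] * a[i, j] + a[i, j] * a[j, j]  # zero diagonal: no-op
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestFpkmToTpm:
    def test_single_gene_saturates(self):
        mat = pd.DataFrame([[5.0]], index=["g"], columns=["s"])
        assert network.fpkm_to_tpm(mat).iloc[0, 0] == 1e6

    def test_forced_two_gene_example(self):
        mat = pd.DataFrame({"s": [1.0, 3.0]}, index=["a", "b"])
        out = network.fpkm_to_tpm(mat)
        np.testing.assert_allclose(out["s"], [250000, 750000])

    def test_columns_conserve_one_million(self, rng):
        mat = pd.DataFrame(rng.random((30, 8)) * 100)
        out = network.fpkm_to_tpm(mat)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_sample_rejected(self):
        mat = pd.DataFrame({"s": [0.0, 0.0]})
        with pytest.raises(ValueError):
            network.fpkm_to_tpm(mat)


class TestPreprocess:
    def test_mad_ranking_matches_brute_force(self, rng):
        mat = pd.DataFrame(
            rng.standard_normal((50, 20)) * rng.random((50, 1)) * 5,
            index=[f"g{i}" for i in range(50)],
        )
        out = network.preprocess(mat, top_n=10, log_transform=False)
        logged = mat
        mads = (logged.sub(logged.median(axis=1), axis=0)).abs().median(axis=1)
        expect = set(mads.sort_values(ascending=False).index[:10])
        assert set(out.index) == expect

    def test_planted_batch_shift_removed(self, rng):
        base = rng.standard_normal((40, 60))
        batch = np.repeat(["a", "b"], 30)
        shifted = base.copy()
        shifted[:, 30:] += 3.0
        mat = pd.DataFrame(shifted, columns=[f"s{i}" for i in range(60)])
        out = network.preprocess(mat, batch=batch, top_n=40, log_transform=False)
        gaps = out.T.groupby(batch).mean().diff().iloc[1].abs()
        assert gaps.max() < 0.2

    def test_single_batch_keeps_values_up_to_identity(self, rng):
        mat = pd.DataFrame(rng.random((20, 10)) * 50)
        a = network.preprocess(mat, top_n=20)
        b = network.preprocess(mat, batch=pd.Series(["x"] * 10), top_n=20)
        np.testing.assert_allclose(a.to_numpy(), b.loc[a.index].to_numpy(), atol=1e-9)


class TestTom:
    def test_matches_triple_sum_oracle(self, rng):
        X = rng.standard_normal((20, 40))
        a = np.abs(np.corrcoef(X)) ** 6
        np.fill_diagonal(a, 0.0)
        tom = network.tom_similarity(a)
        oracle = tom_triple_sum_oracle(a)
        np.testing.assert_allclose(tom, oracle, atol=1e-10)

    def test_symmetric_unit_range(self, rng):
        X = rng.standard_normal((25, 30))
        a = np.abs(np.corrcoef(X)) ** 4
        np.fill_diagonal(a, 0.0)
        tom = network.tom_similarity(a)
        np.testing.assert_allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestSoftThreshold:
    def test_low_fit_on_uncorrelated_noise_at_power_one(self, rng):
        mat = pd.DataFrame(rng.standard_normal((200, 60)))
        _, table = network.pick_soft_threshold(mat)
        assert table.loc[table["power"] == 1, "fit"].iloc[0] < 0.5

    def test_permutation_invariance_of_choice(self, rng, expression):
        mat, _ = expression
        beta_a, _ = network.pick_soft_threshold(mat)
        perm = mat.sample(frac=1.0, random_state=1)
        beta_b, _ = network.pick_soft_threshold(perm)
        assert beta_a == beta_b

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            network.pick_soft_threshold(pd.DataFrame(rng.random((10, 5))))


class TestDetectModules:
    def test_noise_free_module_recovered_exactly(self, train_cohort):
        spec = synthdata.SyntheticSpec(
            seed=40, noise_sd=0.05, module_sizes=(60,), module_grade_r=(0.4,)
        )
        mat, truth = synthdata.generate_expression(train_cohort, spec)
        ms = network.detect_modules(mat, beta=6, params=NetworkParams(min_module_size=30))
        planted = {g for g, m in truth["modules"].items()}
        detected = [m for m in ms.modules]
        assert len(detected) == 1
        found = set(ms.genes_in(detected[0]))
        assert planted <= found
        # the static cut may absorb the odd background gene whose chance
        # correlation pattern clears the height threshold
        assert len(found - planted) <= 2

    def test_highly_correlated_modules_merge(self, train_cohort):
        # two planted factors with eigengene correlation ~0.95 merge under
        # the 0.35 dissimilarity rule
        spec = synthdata.SyntheticSpec(
            seed=41, module_sizes=(60, 60), module_grade_r=(0.9, 0.9), noise_sd=0.3
        )
        mat, _ = synthdata.generate_expression(train_cohort, spec)
        ms = network.detect_modules(mat, beta=6)
        assert len(ms.modules) == 1

    def test_eigengene_orientation_and_scale(self, expression):
        mat, _ = expression
        ms = network.detect_modules(mat, beta=6)
        for m in ms.modules:
            members = ms.genes_in(m)
            assert ms.kme.loc[members, m].mean() > 0
            assert ms.eigengenes[m].std(ddof=1) == pytest.approx(1.0)

    def test_min_module_size_respected(self, expression):
        mat, _ = expression
        ms = network.detect_modules(mat, beta=6)
        sizes = ms.labels.value_counts().drop(network.GREY, errors="ignore")
        assert (sizes >= 30).all()


class TestModuleTrait:
    def test_rank_perfect_eigengene(self, train_cohort, expression):
        mat, _ = expression
        ms = network.detect_modules(mat, beta=6)
        trait = train_cohort["grade"].to_numpy()
        # overwrite one eigengene with the trait itself
        ms.eigengenes[ms.modules[0]] = trait.astype(float)
        out = network.module_trait(ms, trait)
        assert out.loc[ms.modules[0], "r"] == pytest.approx(1.0)

    def test_label_permutation_null(self, train_cohort, expression, rng):
        mat, _ = expression
        ms = network.detect_modules(mat, beta=6)
        hits = 0
        for _ in range(40):
            perm = rng.permutation(train_cohort["grade"].to_numpy())
            out = network.module_trait(ms, perm)
            hits += out["significant"].sum()
        assert hits / (40 * len(ms.modules)) < 0.15


class TestPreservation:
    @pytest.fixture(scope="class")
    def two_datasets(self):
        spec = synthdata.SyntheticSpec(seed=42)
        cohort = synthdata.generate_cohort(spec)
        train = cohort[cohort["split"] == "train"].reset_index(drop=True)
        ext = cohort[cohort["split"] == "external"].reset_index(drop=True)
        ref, truth = synthdata.generate_expression(train, spec)
        test, _ = synthdata.generate_expression(ext, spec, noise_seed=999)
        ms = network.detect_modules(ref, beta=6, trait=train["grade"].to_numpy())
        return ref, test, ms, truth

    def test_planted_modules_strongly_preserved(self, two_datasets):
        ref, test, ms, _ = two_datasets
        rep = network.module_preservation(ms, ref, test, n_perm=60, seed=0)
        assert (rep["Zsummary"] > 10).all()

    def test_random_gene_set_not_preserved(self, two_datasets, rng):
        ref, test, _, _ = two_datasets
        zs = []
        for s in range(5):
            fake = rng.choice(ref.index, 40, replace=False)
            labels = pd.Series(network.GREY, index=ref.index)
            labels[fake] = "rand"
            ms = ModuleSet(
                labels=labels,
                eigengenes=pd.DataFrame({"rand": np.zeros(ref.shape[1])}, index=ref.columns),
                kme=pd.DataFrame(index=ref.index),
                beta=6,
            )
            rep = network.module_preservation(ms, ref, test, n_perm=60, seed=s)
            zs.append(rep["Zsummary"].iloc[0])
        assert np.mean(np.abs(zs) < 2) >= 0.8

    def test_self_preservation_is_maximal(self, two_datasets):
        ref, test, ms, _ = two_datasets
        self_rep = network.module_preservation(ms, ref, ref, n_perm=40, seed=1)
        cross_rep = network.module_preservation(ms, ref, test, n_perm=40, seed=1)
        assert (self_rep["Zsummary"] >= cross_rep["Zsummary"] - 1e-9).all()

    def test_median_rank_orders_modules(self, two_datasets):
        ref, test, ms, _ = two_datasets
        rep = network.module_preservation(ms, ref, test, n_perm=40, seed=2)
        assert rep["medianRank"].min() >= 1
        assert rep["medianRank"].max() <= len(rep)


class TestHubGenes:
    def test_threshold_strictness(self):
        genes = ["a", "b", "c"]
        labels = pd.Series(["m", "m", "m"], index=genes)
        kme = pd.DataFrame({"m": [0.9, 0.80, 0.85]}, index=genes)
        gs = pd.Series([0.3, 0.5, 0.20], index=genes)
        ms = ModuleSet(
            labels=labels,
            eigengenes=pd.DataFrame({"m": np.zeros(4)}),
            kme=kme,
            gs=gs,
        )
        hubs = network.hub_genes(ms, modules=["m"])
        # kME must exceed 0.80 and GS must exceed 0.20, both strictly
        assert hubs["m"] == ["a"]

    def test_matches_brute_force_filter(self, rng):
        genes = [f"g{i}" for i in range(50)]
        labels = pd.Series(["m"] * 50, index=genes)
        kme = pd.DataFrame({"m": rng.uniform(-1, 1, 50)}, index=genes)
        gs = pd.Series(rng.uniform(0, 0.5, 50), index=genes)
        ms = ModuleSet(
            labels=labels,
            eigengenes=pd.DataFrame({"m": np.zeros(3)}),
            kme=kme,
            gs=gs,
        )
        hubs = set(network.hub_genes(ms, modules=["m"])["m"])
        expect = {
            g for g in genes if abs(kme.loc[g, "m"]) > 0.80 and gs[g] > 0.20
        }
        assert hubs == expect
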