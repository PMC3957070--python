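import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsmkl.data_io import LabelVector, OmicsBlock, PathwayCollection, encode_clinical
from fsmkl.kernel_bank import (assemble_bank, build_clinical_kernels,
                               build_pathway_kernels,
                               build_statistical_kernels, compute_gram,
                               project_bank, rank_features_ttest,
                               trace_normalize)


def pooled_t(a, b):
    """Independent oracle: two-sample pooled-variance t statistic."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestRankFeatures:
    def test_orders_by_abs_t(self):
        # feature A separates the classes sharply, feature B does not
        A = np.array([0, 0.1, -0.1, 10, 10.1, 9.9])
        B = np.array([0.3, -0.2, 0.1, 0.2, -0.1, -0.3])
        y = np.array([-1, -1, -1, 1, 1, 1])
        block = OmicsBlock("X", [f"s{i}" for i in range(6)], ["A", "B"],
                           np.column_stack([A, B]))
        tA = pooled_t(A[y == 1], A[y == -1])
        tB = pooled_t(B[y == 1], B[y == -1])
        assert abs(tA) > abs(tB)
        order = rank_features_ttest(block, LabelVector(block.samples, y))
        assert list(order) == [0, 1]

    def test_tie_break_keeps_original_order(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        block = OmicsBlock("X", list("abcd"), ["f1", "f2"],
                           np.column_stack([col, col]))
        y = LabelVector(list("abcd"), [-1, -1, 1, 1])
        assert list(rank_features_ttest(block, y)) == [0, 1]

    def test_single_feature(self):
        block = OmicsBlock("X", list("abcd"), ["f"], [[1.], [2.], [3.], [4.]])
        y = LabelVector(list("abcd"), [-1, -1, 1, 1])
        assert list(rank_features_ttest(block, y)) == [0]

    def test_zero_variance_equal_means_ranks_last(self):
        const = np.ones(4)
        good = np.array([0.0, 0.0, 5.0, 5.0])
        block = OmicsBlock("X", list("abcd"), ["const", "good"],
                           np.column_stack([const, good]))
        y = LabelVector(list("abcd"), [-1, -1, 1, 1])
        assert list(rank_features_ttest(block, y)) == [1, 0]

    def test_single_class_errors(self):
        block = OmicsBlock("X", list("abcd"), ["f"], [[1.], [2.], [3.], [4.]])
        with pytest.raises(ValueError, match="two classes"):
            rank_features_ttest(block, LabelVector(list("abcd"), [1, 1, 1, 1]))


class TestComputeGram:
    @pytest.mark.parametrize("func,params,x,z,expected", [
        ("linear", {}, [1, 0], [1, 1], 1.0),
        ("poly", {"degree": 2}, [1, 0], [1, 0], 4.0),   # (x.z + 1)^2 with x.z=1
        ("poly", {"degree": 3}, [1, 1], [0, 0], 1.0),
        ("gaussian", {"bandwidth": 3.7}, [2, 5], [2, 5], 1.0),
    ])
    def test_closed_forms(self, func, params, x, z, expected):
        g = compute_gram(np.array([x], float), np.array([z], float), func, params)
        assert g.shape == (1, 1)
        assert g[0, 0] == pytest.approx(expected)

    def test_column_mismatch(self):
        with pytest.raises(ValueError, match="column mismatch"):
            compute_gram(np.ones((2, 3)), np.ones((2, 2)), "linear")


class TestTraceNormalize:
    def test_identity(self):
        np.testing.assert_allclose(trace_normalize(np.eye(2)),
                                   np.diag([0.5, 0.5]))

    def test_linear_gram_example(self):
        gram = np.array([[1.0, 0.0], [0.0, 4.0]])
        np.testing.assert_allclose(trace_normalize(gram),
                                   [[0.2, 0.0], [0.0, 0.8]])

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            trace_normalize(np.zeros((3, 3)))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_unit_trace_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((5, 3))
        g = trace_normalize(X @ X.T + np.eye(5) * 1e-6)
        assert np.trace(g) == pytest.approx(1.0, abs=1e-12)


def _block_and_labels(seed=0, n=20, p=20):
    rng = np.random.default_rng(seed)
    block = OmicsBlock("EXP", [f"s{i}" for i in range(n)],
                       [f"g{j}" for j in range(p)], rng.standard_normal((n, p)))
    y = np.ones(n, dtype=int)
    y[: n // 2] = -1
    return block, LabelVector(block.samples, y)


class TestStatisticalKernels:
    def test_count_enumeration(self):
        block, labels = _block_and_labels()
        ks = build_statistical_kernels(block, labels, n_max=15,
                                       funcs=("linear", "poly2", "poly3"))
        assert len(ks) == 14 * 3       # k = 2..15, three functions each
        # deterministic order: k outer, function inner
        assert [k.spec.selection_detail["k"] for k in ks[:6]] == [2, 2, 2, 3, 3, 3]

    def test_single_case(self):
        block, labels = _block_and_labels()
        ks = build_statistical_kernels(block, labels, n_max=2, funcs=("linear",))
        assert len(ks) == 1 and len(ks[0].spec.feature_ids) == 2

    def test_cap_at_feature_count_warns(self):
        block, labels = _block_and_labels(p=3)
        with pytest.warns(UserWarning, match="capped"):
            ks = build_statistical_kernels(block, labels, n_max=15,
                                           funcs=("linear",))
        assert [k.spec.selection_detail["k"] for k in ks] == [2, 3]

    def test_all_trace_one_and_psd(self):
        block, labels = _block_and_labels()
        for k in build_statistical_kernels(block, labels, 5):
            k.validate()


class TestPathwayKernels:
    def test_restricts_to_matched_members(self):
        block, labels = _block_and_labels(p=3)
        pc = PathwayCollection([("p1", "d", ["g0", "g1", "gX"])])
        ks = build_pathway_kernels(block, pc, funcs=("linear",))
        assert len(ks) == 1
        assert ks[0].spec.feature_ids == ("g0", "g1")
        assert ks[0].spec.selection_detail["pathway_id"] == "p1"

    def test_unmatched_pathway_skipped(self):
        block, _ = _block_and_labels(p=3)
        pc = PathwayCollection([("p1", "d", ["nope"])])
        with pytest.warns(UserWarning, match="skipped"):
            assert build_pathway_kernels(block, pc, funcs=("linear",)) == []

    def test_count_enumeration(self):
        block, _ = _block_and_labels(p=30)
        pc = PathwayCollection([(f"p{i}", "d", [f"g{3*i}", f"g{3*i+1}", f"g{3*i+2}"])
                                for i in range(10)])
        ks = build_pathway_kernels(block, pc, funcs=("linear", "poly2", "poly3"))
        assert len(ks) == 30

    def test_topk_requires_labels(self):
        block, _ = _block_and_labels(p=3)
        pc = PathwayCollection([("p1", "d", ["g0", "g1"])])
        with pytest.raises(ValueError, match="labels"):
            build_pathway_kernels(block, pc, within_pathway_top_k=2)


class TestClinicalKernels:
    def test_one_kernel_per_covariate(self):
        import pandas as pd
        from fsmkl.data_io import ClinicalTable
        samples = [f"s{i}" for i in range(6)]
        df = pd.DataFrame({"ER": ["+", "-", "+", "-", "+", "-"],
                           "age": ["40", "50", "60", "45", "55", "65"],
                           "hist": ["a", "b", "c", "a", "b", "c"]},
                          index=samples, dtype=str)
        clin = encode_clinical(ClinicalTable(
            samples, df, {"ER": "binary", "age": "numeric",
                          "hist": "categorical"}))
        ks = build_clinical_kernels(clin, funcs=("linear",))
        assert [k.spec.selection_detail["covariate"] for k in ks] == \
            ["ER", "age", "hist"]

    def test_boolean_dot_product(self):
        # two ER+ samples share indicator 1 -> pre-normalization gram entry 1
        g = compute_gram(np.array([[1.0]]), np.array([[1.0]]), "linear")
        assert g[0, 0] == 1.0

    def test_constant_covariate_dropped(self):
        import pandas as pd
        from fsmkl.data_io import ClinicalTable
        samples = ["s0", "s1", "s2"]
        df = pd.DataFrame({"age": ["50", "50", "50"],
                           "ER": ["+", "-", "+"]}, index=samples, dtype=str)
        clin = encode_clinical(ClinicalTable(
            samples, df, {"age": "numeric", "ER": "binary"}))
        with pytest.warns(UserWarning, match="constant"):
            ks = build_clinical_kernels(clin, funcs=("linear",))
        assert [k.spec.selection_detail["covariate"] for k in ks] == ["ER"]


class TestProjection:
    def test_projecting_training_set_reproduces_gram(self, tiny_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank = assemble_bank(tiny_ds.blocks, tiny_ds.labels,
                                 pathways=tiny_ds.pathways)
        blocks = {b.name: b for b in tiny_ds.blocks}
        proj = project_bank(bank, blocks, blocks)
        np.testing.assert_allclose(proj, bank.stack(), atol=1e-10)

    def test_single_point_matches_gram_row(self, tiny_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank = assemble_bank(tiny_ds.blocks, tiny_ds.labels,
                                 pathways=tiny_ds.pathways)
        blocks = {b.name: b for b in tiny_ds.blocks}
        test = {n: b.subset_samples([b.samples[3]]) for n, b in blocks.items()}
        proj = project_bank(bank, blocks, test)
        np.testing.assert_allclose(proj[:, 0, :], bank.stack()[:, 3, :],
                                   atol=1e-10)

    def test_missing_test_feature_named(self, tiny_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank = assemble_bank(tiny_ds.blocks, tiny_ds.labels,
                                 pathways=tiny_ds.pathways)
        blocks = {b.name: b for b in tiny_ds.blocks}
        # drop a feature that some kernel actually selects
        used = next(k.spec for k in bank if k.spec.source_block == "EXP")
        victim = used.feature_ids[0]
        exp = blocks["EXP"]
        keep = [j for j, f in enumerate(exp.features) if f != victim]
        crippled = dict(blocks)
        crippled["EXP"] = OmicsBlock("EXP", exp.samples,
                                     [exp.features[j] for j in keep],
                                     exp.values[:, keep])
        with pytest.raises(KeyError, match=victim):
            project_bank(bank, blocks, crippled)


class TestBankProperties:
    def test_deterministic_construction(self, tiny_ds):
        kwargs = dict(pathways=tiny_ds.pathways, use_statistical=True,
                      n_max=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = assemble_bank(tiny_ds.blocks, tiny_ds.labels, **kwargs)
            b2 = assemble_bank(tiny_ds.blocks, tiny_ds.labels, **kwargs)
        assert [k.spec.label() for k in b1] == [k.spec.label() for k in b2]
        np.testing.assert_array_equal(b1.stack(), b2.stack())

    def test_all_kernels_valid(self, tiny_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank = assemble_bank(tiny_ds.blocks, tiny_ds.labels,
                                 pathways=tiny_ds.pathways,
                                 use_statistical=True, n_max=4)
        bank.validate()

    def test_training_kernels_blind_to_heldout_rows(self, tiny_ds):
        """Changing held-out rows never changes a training-restricted bank."""
        train_ids = tiny_ds.labels.samples[:60]
        lab = tiny_ds.labels.subset_samples(train_ids)

        def bank_from(blocks):
            restricted = [b.subset_samples(train_ids) for b in blocks]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return assemble_bank(restricted, lab,
                                     pathways=tiny_ds.pathways,
                                     use_statistical=True, n_max=4)
        b_ref = bank_from(tiny_ds.blocks)
        corrupted = []
        for b in tiny_ds.blocks:
            vals = b.values.copy()
            vals[60:, :] = 1e6        # scramble the held-out rows only
            corrupted.append(OmicsBlock(b.name, b.samples, b.features, vals))
        b_cor = bank_from(corrupted)
        np.testing.assert_array_equal(b_ref.stack(), b_cor.stack())

    def test_duplicate_column_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6, 1))
        X2 = np.hstack([x, x])
        g_first = compute_gram(X2[:, :1], X2[:, :1], "linear")
        g_second = compute_gram(X2[:, 1:], X2[:, 1:], "linear")
        np.testing.assert_allclose(g_first, g_second)
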