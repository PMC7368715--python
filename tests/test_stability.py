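import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from refstab import (
    CtMatrix,
    StudyDesign,
    bestkeeper,
    ct_to_quantity,
    delta_ct,
    genorm,
    normfinder,
    run_all,
)
from refstab.errors import DesignMismatchError, DomainError, ShapeError
from refstab.stability import RelativeQuantityMatrix
from refstab.synthetic_data import GeneCtSpec, CtSimSpec, FactorSpec, simulate_ct
from conftest import random_ct


def _qm(df: pd.DataFrame) -> RelativeQuantityMatrix:
    return RelativeQuantityMatrix(df, pd.Series(2.0, index=df.index))


class TestQuantityTransform:
    def test_anchor_and_power(self, toy_ct):
        q = ct_to_quantity(toy_ct)
        # each gene's minimum-Ct sample maps to Q = 1
        assert np.allclose(q.q.max(axis=1), 1.0)
        # g1: Ct (20,21,22) with min 20 -> Q (1, .5, .25)
        assert q.q.loc["g1"].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_explicit_power_example(self):
        ct = CtMatrix(pd.DataFrame({"s1": [20.0], "s2": [23.0]}, index=["g"]))
        q = ct_to_quantity(ct, 2.0)
        assert q.q.loc["g", "s2"] == pytest.approx(0.125)

    def test_log_q_differences_equal_negated_ct_differences(self):
        ct = random_ct(np.random.default_rng(0), 4, 6)
        q = ct_to_quantity(ct, 2.0)
        lq = np.log2(q.q.to_numpy())
        dct = ct.ct.to_numpy()
        assert np.allclose(
            lq[:, 1:] - lq[:, :-1], -(dct[:, 1:] - dct[:, :-1])
        )

    def test_implausible_base_rejected(self, toy_ct):
        with pytest.raises(DomainError):
            ct_to_quantity(toy_ct, 1.2)
        with pytest.raises(DomainError):
            ct_to_quantity(toy_ct, {"g1": 2.0, "g2": 2.0, "g3": 3.0})


class TestGenorm:
    def test_hand_worked_m_values(self, toy_quantities):
        res = genorm(toy_quantities)
        assert res.m_values["g1"] == pytest.approx(0.5)
        assert res.m_values["g2"] == pytest.approx(0.5)
        assert res.m_values["g3"] == pytest.approx(1.0)
        assert res.exclusion_order[0] == "g3"

    def test_m_matches_naive_oracle(self):
        rng = np.random.default_rng(4)
        ct = random_ct(rng, 6, 8)
        q = ct_to_quantity(ct)
        res = genorm(q)
        naive = oracle.genorm_m({g: q.q.loc[g].tolist() for g in q.gene_ids})
        for g in q.gene_ids:
            assert res.m_values[g] == pytest.approx(naive[g], abs=1e-9)

    def test_v_sequence_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        ct = random_ct(rng, 5, 8)
        q = ct_to_quantity(ct)
        res = genorm(q)
        naive = oracle.genorm_v(
            {g: q.q.loc[g].tolist() for g in q.gene_ids}, res.ranking.to_dict()
        )
        for n in naive:
            assert res.pairwise_variation[f"V{n}/V{n + 1}"] == pytest.approx(
                naive[n], abs=1e-9
            )

    def test_gene_tracking_nf_gives_zero_pairwise_variation(self):
        # 3 base genes + one gene exactly proportional to their NF_3:
        # log2 NF_3 - log2 NF_4 is then constant, so V3/V4 = 0
        rng = np.random.default_rng(6)
        base = rng.uniform(0.1, 1.0, size=(3, 6))
        nf3 = np.exp(np.log(base).mean(axis=0))
        q = np.vstack([base, nf3 * 0.5])
        qm = _qm(
            pd.DataFrame(
                q, index=pd.Index(["a", "b", "c", "track"], name="gene"),
                columns=[f"s{j}" for j in range(6)],
            )
        )
        res = genorm(qm)
        # force 'track' into 4th rank position? not needed: wherever it ranks,
        # the V at the stage where it joins the NF must vanish only if it joins
        # last; instead check via explicit NF construction:
        ordered = list(res.ranking.sort_values().index)
        if ordered[3] == "track":
            assert res.pairwise_variation["V3/V4"] == pytest.approx(0.0, abs=1e-9)
        naive = oracle.genorm_v(
            {g: qm.q.loc[g].tolist() for g in qm.gene_ids}, res.ranking.to_dict()
        )
        for n in naive:
            assert res.pairwise_variation[f"V{n}/V{n + 1}"] == pytest.approx(
                naive[n], abs=1e-9
            )

    def test_invariant_to_per_gene_ct_offsets(self):
        rng = np.random.default_rng(7)
        ct = random_ct(rng, 5, 7)
        shifted = CtMatrix(ct.ct.add(pd.Series(
            rng.uniform(-3, 3, size=5), index=ct.ct.index), axis=0))
        a, b = genorm(ct_to_quantity(ct)), genorm(ct_to_quantity(shifted))
        assert np.allclose(a.m_values, b.m_values)
        assert a.ranking.to_dict() == b.ranking.to_dict()

    def test_two_gene_m_equals_log_ratio_sd(self):
        # with exactly 3 genes the check runs at the first stage instead
        rng = np.random.default_rng(8)
        ct = random_ct(rng, 3, 6)
        q = ct_to_quantity(ct)
        res = genorm(q)
        lq = np.log2(q.q.to_numpy())
        for i, g in enumerate(q.gene_ids):
            partners = [j for j in range(3) if j != i]
            expect = np.mean(
                [np.std(lq[i] - lq[j], ddof=1) for j in partners]
            )
            assert res.m_values[g] == pytest.approx(expect)

    def test_fewer_than_three_genes_rejected(self):
        q = _qm(pd.DataFrame({"s1": [1.0, 1.0], "s2": [0.5, 1.0]}, index=["a", "b"]))
        with pytest.raises(ShapeError):
            genorm(q)


class TestNormFinder:
    def test_identical_genes_have_zero_stability(self, two_group_design):
        df = pd.DataFrame(
            np.tile([1.0, 0.5, 0.25, 1.0, 0.5, 0.25], (3, 1)),
            index=pd.Index(["a", "b", "c"], name="gene"),
            columns=[f"s{i}" for i in range(1, 7)],
        )
        s = normfinder(_qm(df), two_group_design, "grp")
        assert np.allclose(s.values, 0.0)
        s0 = normfinder(_qm(df))
        assert np.allclose(s0.values, 0.0)

    def test_grouped_matches_naive_oracle(self, two_group_design):
        rng = np.random.default_rng(9)
        ct = random_ct(rng, 5, 6)
        ct = CtMatrix(
            ct.ct.set_axis([f"s{i}" for i in range(1, 7)], axis=1)
        )
        q = ct_to_quantity(ct)
        s = normfinder(q, two_group_design, "grp")
        y = {g: np.log2(q.q.loc[g].to_numpy()).tolist() for g in q.gene_ids}
        naive = oracle.normfinder(y, groups={"A": [0, 1, 2], "B": [3, 4, 5]})
        for g in q.gene_ids:
            assert s.values[g] == pytest.approx(naive[g], abs=1e-9)

    def test_ungrouped_matches_naive_oracle(self):
        rng = np.random.default_rng(10)
        ct = random_ct(rng, 6, 8)
        q = ct_to_quantity(ct)
        s = normfinder(q)
        y = {g: np.log2(q.q.loc[g].to_numpy()).tolist() for g in q.gene_ids}
        naive = oracle.normfinder(y)
        for g in q.gene_ids:
            assert s.values[g] == pytest.approx(naive[g], abs=1e-9)

    def test_group_of_one_rejected(self):
        design = StudyDesign.from_mapping("grp", {"s0": "A", "s1": "B", "s2": "B"})
        ct = random_ct(np.random.default_rng(11), 3, 3)
        with pytest.raises(DesignMismatchError):
            normfinder(ct_to_quantity(ct), design, "grp")

    def test_noisier_gene_scores_worse_ungrouped(self):
        rng = np.random.default_rng(12)
        n = 60
        quiet = 25 + rng.normal(0, 0.1, size=(4, n))
        loud = 25 + rng.normal(0, 1.0, size=(1, n))
        ct = CtMatrix(pd.DataFrame(
            np.vstack([quiet, loud]),
            index=pd.Index([f"q{i}" for i in range(4)] + ["loud"], name="gene"),
            columns=[f"s{j}" for j in range(n)],
        ))
        s = normfinder(ct_to_quantity(ct))
        assert s.values["loud"] == s.values.max()


class TestBestKeeper:
    def test_constant_gene(self):
        ct = CtMatrix(pd.DataFrame(
            {"s1": [25.0, 20.0], "s2": [25.0, 21.0], "s3": [25.0, 22.0]},
            index=pd.Index(["flat", "g"], name="gene"),
        ))
        bk = bestkeeper(ct)
        assert bk.per_gene.loc["flat", "std_value"] == 0.0
        assert bk.per_gene.loc["flat", "cv_pct"] == 0.0

    def test_hand_worked_both_centerings(self):
        ct = CtMatrix(pd.DataFrame(
            {"s1": [20.0, 24.0], "s2": [21.0, 24.0], "s3": [22.0, 24.0]},
            index=pd.Index(["g", "flat"], name="gene"),
        ))
        arith = bestkeeper(ct, center="arith").per_gene.loc["g"]
        assert arith["arith_mean"] == pytest.approx(21.0)
        assert arith["std_value"] == pytest.approx(2.0 / 3.0)
        geo = bestkeeper(ct, center="geo").per_gene.loc["g"]
        assert geo["geo_mean"] == pytest.approx(20.9839, abs=1e-3)
        assert geo["std_value"] == pytest.approx(0.672, abs=1e-3)

    def test_matches_naive_oracle_and_ordering_invariants(self):
        ct = random_ct(np.random.default_rng(13), 6, 8)
        bk = bestkeeper(ct)
        data = {g: ct.ct.loc[g].tolist() for g in ct.gene_ids}
        naive_std = oracle.bestkeeper_std(data)
        naive_idx = oracle.bestkeeper_index(data)
        for g in ct.gene_ids:
            assert bk.per_gene.loc[g, "std_value"] == pytest.approx(
                naive_std[g], abs=1e-9
            )
            r = oracle.pearson_r(data[g], naive_idx)
            assert bk.correlation.loc[g, "r"] == pytest.approx(r, abs=1e-9)
        assert np.allclose(bk.index.to_numpy(), naive_idx)
        pg = bk.per_gene
        assert (pg["min"] <= pg["geo_mean"] + 1e-12).all()
        assert (pg["geo_mean"] <= pg["arith_mean"] + 1e-12).all()
        assert (pg["arith_mean"] <= pg["max"] + 1e-12).all()

    def test_mad_never_exceeds_sample_sd(self):
        ct = random_ct(np.random.default_rng(14), 8, 10)
        bk = bestkeeper(ct)
        sds = ct.ct.std(axis=1, ddof=1)
        assert (bk.per_gene["std_value"] <= sds + 1e-12).all()


class TestDeltaCt:
    def test_constant_offset_pair_scores_zero(self):
        ct = CtMatrix(pd.DataFrame(
            {"s1": [20.0, 23.0], "s2": [21.0, 24.0], "s3": [22.0, 25.0]},
            index=pd.Index(["a", "b"], name="gene"),
        ))
        s = delta_ct(ct)
        assert np.allclose(s.values, 0.0)

    def test_hand_worked_three_genes(self, toy_ct):
        s = delta_ct(toy_ct)
        assert s.values["g1"] == pytest.approx(1.07735, abs=1e-4)
        assert s.values["g2"] == pytest.approx(0.78868, abs=1e-4)
        assert s.values["g3"] == pytest.approx(0.86603, abs=1e-4)

    def test_matches_naive_oracle(self):
        ct = random_ct(np.random.default_rng(15), 6, 8)
        s = delta_ct(ct)
        naive = oracle.delta_ct({g: ct.ct.loc[g].tolist() for g in ct.gene_ids})
        for g in ct.gene_ids:
            assert s.values[g] == pytest.approx(naive[g], abs=1e-9)

    def test_invariant_to_per_sample_offsets(self):
        ct = random_ct(np.random.default_rng(16), 5, 7)
        shift = np.random.default_rng(17).uniform(-2, 2, size=7)
        shifted = CtMatrix(ct.ct.add(pd.Series(shift, index=ct.ct.columns), axis=1))
        assert np.allclose(delta_ct(ct).values, delta_ct(shifted).values)

    def test_two_gene_stability_equals_pair_sd(self):
        ct = random_ct(np.random.default_rng(18), 2, 9)
        s = delta_ct(ct)
        pair = np.std(ct.ct.iloc[0] - ct.ct.iloc[1], ddof=1)
        assert s.values.iloc[0] == pytest.approx(pair)
        assert s.values.iloc[1] == pytest.approx(pair)

    def test_single_gene_rejected(self):
        ct = CtMatrix(pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=["g"]))
        with pytest.raises(ShapeError):
            delta_ct(ct)


class TestRunAll:
    def test_four_series_over_identical_gene_set(self, default_sim):
        series = run_all(default_sim.ct, default_sim.design, "cohort")
        assert [s.algorithm for s in series] == [
            "geNorm", "NormFinder", "BestKeeper", "deltaCt"
        ]
        genes = set(default_sim.ct.gene_ids)
        for s in series:
            assert set(s.gene_ids) == genes
            assert s.lower_is_stable

    def test_planted_noisy_gene_ranks_last_in_every_series(self):
        spec = CtSimSpec(
            genes=[GeneCtSpec(f"g{i}", 24.0 + i, 0.1) for i in range(5)]
            + [GeneCtSpec("noisy", 27.0, 1.0)],
            factors=[FactorSpec("grp", ("A", "B"), samples_per_level=10)],
            seed=42,
        )
        res = simulate_ct(spec)
        for s in run_all(res.ct, res.design, "grp"):
            assert s.ranking()["noisy"] == 6, s.algorithm

    def test_near_degenerate_samples_give_near_zero_values(self):
        spec = CtSimSpec(
            genes=[GeneCtSpec(f"g{i}", 22.0 + i, 0.0) for i in range(4)],
            factors=[FactorSpec("grp", ("A", "B"), samples_per_level=4)],
            replicate_sd=0.0,
            seed=1,
        )
        res = simulate_ct(spec)
        for s in run_all(res.ct):
            assert np.allclose(s.values, 0.0, atol=1e-9), s.algorithm
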