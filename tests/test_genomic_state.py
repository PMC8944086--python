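import numpy as np
import pandas as pd
import pytest

from methage.genomic_state import (
    IntensityPair,
    MGMT_CUTOFF,
    cbs_segment,
    cdkn2a_hd_call,
    copy_number_logratio,
    estimate_purity,
    gcimp_cluster,
    mgmt_stp27,
    nearest_centroid_subtype,
    segment_genome,
    segments_to_bed,
)
from methage.preprocess import MethylationMatrix

from conftest import toy_matrix


def _intensity(total, betas=0.5):
    total = np.asarray(total, dtype=float)
    meth = pd.DataFrame(
        total * betas,
        index=[f"cg{i}" for i in range(total.shape[0])],
        columns=[f"s{j}" for j in range(total.shape[1])],
    )
    unmeth = pd.DataFrame(
        total * (1 - betas), index=meth.index, columns=meth.columns
    )
    return IntensityPair(meth, unmeth)


class TestLogRatio:
    def test_identical_to_reference_is_zero(self):
        pair = _intensity(np.full((10, 3), 2000.0))
        ref = pd.Series(2000.0, index=pair.meth.index)
        lr = copy_number_logratio(pair, ref)
        assert np.allclose(lr.to_numpy(), 0.0)

    def test_doubled_region_near_one(self):
        total = np.full((20, 1), 1000.0)
        total[5:10] = 2000.0
        lr = copy_number_logratio(_intensity(total), pd.Series(1000.0, index=[f"cg{i}" for i in range(20)]))
        assert lr.iloc[6, 0] == pytest.approx(1.0, abs=1e-9)

    def test_homozygous_deletion_ratio(self):
        total = np.full((100, 1), 1000.0)
        total[40:45] = 100.0
        ref = pd.Series(1000.0, index=[f"cg{i}" for i in range(100)])
        lr = copy_number_logratio(_intensity(total), ref)
        assert lr.iloc[41, 0] == pytest.approx(np.log2(0.1), abs=1e-9)

    def test_zero_total_masked(self):
        total = np.full((5, 1), 1000.0)
        total[2] = 0.0
        ref = pd.Series(1000.0, index=[f"cg{i}" for i in range(5)])
        lr = copy_number_logratio(_intensity(total), ref)
        assert np.isnan(lr.iloc[2, 0])


class TestCbs:
    def test_flat_signal_mostly_single_segment(self):
        rng = np.random.default_rng(0)
        single = 0
        runs = 100
        for k in range(runs):
            x = rng.normal(0, 0.2, 60)
            segs = cbs_segment(x, alpha=0.01, n_perm=199, seed=k)
            single += len(segs) == 1
        assert single >= 0.95 * runs

    def test_single_step_breakpoint_localized(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.2, 200)
        segs = cbs_segment(x, alpha=0.01, n_perm=500, seed=1)
        assert len(segs) == 2
        # breakpoint at position 101 (1-based start of the second segment)
        assert abs(segs[1].start - 101) <= 3

    def test_nested_steps_recovered(self):
        rng = np.random.default_rng(3)
        x = np.zeros(240)
        x[80:160] += 1.0
        x += rng.normal(0, 0.2, 240)
        segs = cbs_segment(x, alpha=0.01, n_perm=500, seed=2)
        assert len(segs) == 3
        means = [s.mean for s in segs]
        assert abs(means[0] - 0.0) < 0.1
        assert abs(means[1] - 1.0) < 0.1
        assert abs(means[2] - 0.0) < 0.1

    def test_segments_tile_probes(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.zeros(50), np.full(50, 1.5)]) + rng.normal(0, 0.1, 100)
        segs = cbs_segment(x, n_perm=200, seed=0)
        assert sum(s.n_probes for s in segs) == 100
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.start > a.end

    def test_genome_wrapper_and_bed(self, tmp_path):
        rng = np.random.default_rng(2)
        ann = pd.DataFrame(
            {
                "chromosome": ["1"] * 60 + ["2"] * 60,
                "position": list(range(1, 61)) * 2,
            },
            index=[f"cg{i}" for i in range(120)],
        )
        vals = rng.normal(0, 0.1, 120)
        vals[60:] += 1.0  # chr2 uniformly shifted: still one segment there
        lr = pd.Series(vals, index=ann.index)
        segs = segment_genome(lr, ann, n_perm=100, seed=0)
        assert {s.chromosome for s in segs} == {"1", "2"}
        bed = tmp_path / "segs.bed"
        segments_to_bed(segs, bed)
        first = bed.read_text().splitlines()[0].split("\t")
        assert int(first[1]) == int(first[2]) - 60  # 0-based half-open span


class TestCdkn2aMixture:
    def test_bimodal_assignment(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(-3, 0.3, 50)])
        s = pd.Series(x, index=[f"s{i}" for i in range(100)])
        calls = cdkn2a_hd_call(s)
        truth = np.array([False] * 50 + [True] * 50)
        assert (calls["hd"].to_numpy() == truth).mean() >= 0.98

    def test_unimodal_no_calls(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(0, 0.3, 60), index=[f"s{i}" for i in range(60)])
        assert not cdkn2a_hd_call(s)["hd"].any()

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(-3, 0.3, 30)])
        s = pd.Series(x, index=[f"s{i}" for i in range(60)])
        calls = cdkn2a_hd_call(s)
        # posterior of HD and its complement sum to 1 by construction
        assert ((calls["posterior_hd"] >= 0) & (calls["posterior_hd"] <= 1)).all()

    def test_identical_input_warns_no_hd(self):
        s = pd.Series(0.0, index=[f"s{i}" for i in range(25)])
        with pytest.warns(UserWarning):
            calls = cdkn2a_hd_call(s)
        assert not calls["hd"].any()


class TestPurity:
    @staticmethod
    def _refs(p=120, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"cg{i}" for i in range(p)]
        t = pd.Series(np.r_[rng.uniform(0.8, 0.95, p // 2), rng.uniform(0.05, 0.2, p - p // 2)], index=idx)
        nrm = pd.Series(np.r_[rng.uniform(0.05, 0.2, p // 2), rng.uniform(0.8, 0.95, p - p // 2)], index=idx)
        return t, nrm

    def _mix(self, w):
        t, nrm = self._refs()
        obs = w * t + (1 - w) * nrm
        return MethylationMatrix(obs.to_frame("s0")), t, nrm

    @pytest.mark.parametrize("w,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5)])
    def test_constructed_mixture(self, w, expected):
        m, t, nrm = self._mix(w)
        est = estimate_purity(m, t, nrm)
        assert est.iloc[0] == pytest.approx(expected, abs=0.02)

    def test_monotone_in_mixing_weight(self):
        t, nrm = self._refs()
        obs = pd.DataFrame({f"s{k}": w * t + (1 - w) * nrm
                            for k, w in enumerate(np.linspace(0, 1, 11))})
        est = estimate_purity(MethylationMatrix(obs), t, nrm)
        assert (np.diff(est.to_numpy()) > -1e-12).all()

    def test_no_informative_probes_raises(self):
        idx = [f"cg{i}" for i in range(60)]
        flat = pd.Series(0.5, index=idx)
        m = MethylationMatrix(pd.DataFrame({"s0": flat}))
        with pytest.raises(ValueError, match="informative"):
            estimate_purity(m, flat, flat)


class TestMgmt:
    def _mvals(self, m1, m2):
        return pd.DataFrame(
            {"s0": [m1, m2]}, index=["cg12434587", "cg12981137"]
        )

    def test_zero_predictor_is_methylated(self):
        calls = mgmt_stp27(self._mvals(0.0, 0.0), (0.0, 1.0, 1.0))
        assert calls["probability"].iloc[0] == pytest.approx(0.5)
        assert calls["status"].iloc[0] == "M"  # 0.5 >= 0.358

    def test_boundary_probability_is_methylated(self):
        from scipy.special import logit

        b0 = float(logit(MGMT_CUTOFF))
        calls = mgmt_stp27(self._mvals(0.0, 0.0), (b0, 1.0, 1.0))
        assert calls["probability"].iloc[0] == pytest.approx(MGMT_CUTOFF, abs=1e-12)
        assert calls["status"].iloc[0] == "M"

    def test_monotone_in_m_values(self):
        grid = np.linspace(-6, 6, 25)
        probs = [
            mgmt_stp27(self._mvals(v, 1.0), (0.2, 0.8, 0.5))["probability"].iloc[0]
            for v in grid
        ]
        assert (np.diff(probs) > 0).all()

    def test_missing_probe_raises_by_name(self):
        bad = pd.DataFrame({"s0": [0.0]}, index=["cg12434587"])
        with pytest.raises(KeyError, match="cg12981137"):
            mgmt_stp27(bad, (0, 1, 1))


class TestClusteringAndSubtypes:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(0)
        low = rng.uniform(0.1, 0.3, (50, 10))
        high = rng.uniform(0.7, 0.9, (50, 10))
        m = toy_matrix(np.hstack([low, high]))
        out = gcimp_cluster(m)
        labels = out["cluster"].to_numpy()
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:10])) == 1 and len(np.unique(labels[10:])) == 1
        # the hypermethylated blob carries the G-CIMP flag
        assert out["gcimp"].iloc[10:].all() and not out["gcimp"].iloc[:10].any()

    def test_duplicate_samples_same_label(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 0.9, (30, 6))
        X[:, 5] = X[:, 0]
        out = gcimp_cluster(toy_matrix(X))
        assert out["cluster"].iloc[5] == out["cluster"].iloc[0]

    def test_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(2)
        X = np.hstack(
            [rng.uniform(0.1, 0.3, (40, 8)), rng.uniform(0.7, 0.9, (40, 8))]
        )
        m1 = toy_matrix(X)
        perm = rng.permutation(16)
        m2 = MethylationMatrix(m1.values.iloc[:, perm])
        l1 = gcimp_cluster(m1)["gcimp"]
        l2 = gcimp_cluster(m2)["gcimp"]
        assert (l2.reindex(l1.index) == l1).all()

    def test_centroid_sample_gets_its_label(self):
        rng = np.random.default_rng(3)
        centroids = pd.DataFrame(
            rng.uniform(0.2, 0.8, (40, 3)),
            index=[f"cg{i}" for i in range(40)],
            columns=["MES", "RTK_I", "RTK_II"],
        )
        m = MethylationMatrix(centroids[["RTK_I"]].rename(columns={"RTK_I": "s0"}))
        assert nearest_centroid_subtype(m, centroids).iloc[0] == "RTK_I"

    def test_equidistant_tie_prefers_first_column(self):
        centroids = pd.DataFrame(
            {"MES": [0.2, 0.2], "RTK_I": [0.8, 0.8], "RTK_II": [0.1, 0.1]},
            index=["cg0", "cg1"],
        )
        m = toy_matrix([[0.5], [0.5]])
        assert nearest_centroid_subtype(m, centroids).iloc[0] == "MES"

    def test_synthetic_subtype_accuracy(self, default_cohort):
        calls = nearest_centroid_subtype(
            default_cohort.betas, default_cohort.truth.subtype_centroids
        )
        truth = default_cohort.truth.samples["subtype"]
        assert (calls == truth).mean() >= 0.95
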