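"""Preprocessing tests: TMM (with brute-force and edgeR oracles), gene
filter, multi-criterion sample QC, sex check, residualization."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pmlsubtypes import (filter_genes, qc_outlier_filter, residualize, sex_check,
                        tmm_normalize)

from conftest import make_dataset


# -- independent brute-force TMM oracle ---------------------------------------

def _avg_ranks(values):
    """Average ranks computed by explicit pair counting."""
    out = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        out.append(smaller + (ties + 1) / 2.0)
    return out


def oracle_pair_factor(obs, ref):
    """TMM factor of obs against ref by explicit trim-set enumeration."""
    n_obs, n_ref = float(sum(obs)), float(sum(ref))
    m, a, w = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m.append(math.log2((o / n_obs) / (r / n_ref)))
            a.append(0.5 * math.log2((o / n_obs) * (r / n_ref)))
            w.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = len(m)
    if n == 0 or max(abs(v) for v in m) < 1e-6:
        return 1.0
    lo_m, lo_a = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
    hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
    rm, ra = _avg_ranks(m), _avg_ranks(a)
    num = den = 0.0
    kept = 0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += m[i] / w[i]
            den += 1.0 / w[i]
            kept += 1
    if kept == 0:
        return 1.0
    return 2.0 ** (num / den)


class TestTmm:
    def test_identical_samples_all_factors_one(self):
        col = np.array([5, 9, 2, 40, 11, 3, 7, 25])
        ds = make_dataset(np.tile(col[:, None], (1, 4)), scale="counts")
        res, _ = tmm_normalize(ds)
        assert np.allclose(res.factors, 1.0)

    def test_pure_depth_difference_factors_one(self):
        col = np.array([5, 9, 2, 40, 11, 3, 7, 25])
        ds = make_dataset(np.column_stack([col, 3 * col]), scale="counts")
        res, _ = tmm_normalize(ds)
        assert np.allclose(res.factors, 1.0, atol=1e-12)

    def test_brute_force_oracle_on_asymmetric_toy(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 0.01, size=(100, 2)).astype(int) + 1
        counts[:10, 1] *= 8                     # 10 genes 8-fold up in sample B
        ds = make_dataset(counts, scale="counts")
        res, _ = tmm_normalize(ds)
        ref_col = ds.sample_ids.index(res.reference_sample)
        raw = [oracle_pair_factor(counts[:, j], counts[:, ref_col]) for j in (0, 1)]
        geo = math.exp(sum(math.log(f) for f in raw) / 2)
        expected = [f / geo for f in raw]
        assert np.allclose(res.factors.to_numpy(), expected, atol=1e-10)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check factors and log2-CPM against edgeR on a small toy."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; edgeR cross-check cannot run")
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(4, 0.02, size=(150, 5)).astype(int)
        counts[:12, 2] *= 6
        ds = make_dataset(counts, scale="counts")
        res, logcpm = tmm_normalize(ds)
        tsv = tmp_path / "counts.tsv"
        ds.values.to_csv(tsv, sep="\t")
        out = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'x<-as.matrix(read.delim("{tsv}",row.names=1));'
             'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n");'
             'y<-calcNormFactors(DGEList(counts=x));'
             'cat(sprintf("%.12f", cpm(y, log=TRUE, prior.count=2)[1,]), sep="\\n")'],
            capture_output=True, text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_factors, r_logcpm_row0 = vals[:5], vals[5:]
        assert np.allclose(res.factors.to_numpy(), r_factors, atol=1e-6)
        assert np.allclose(logcpm.values.iloc[0].to_numpy(), r_logcpm_row0, atol=1e-6)

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(5, 0.01, size=(200, 4)).astype(int) + 1
        ds = make_dataset(counts, scale="counts")
        f1 = tmm_normalize(ds)[0].factors
        # rescaling every library jointly leaves M, A, trims and the
        # (uniformly rescaled) precision weights unchanged -> exact invariance
        f2 = tmm_normalize(make_dataset(counts * 5, scale="counts"))[0].factors
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-12)
        # rescaling a single library changes only that library's precision
        # weights, so factors move slightly but stay within 2%
        scaled = counts.copy()
        scaled[:, 1] *= 7
        f3 = tmm_normalize(make_dataset(scaled, scale="counts"))[0].factors
        assert np.allclose(f1.to_numpy(), f3.to_numpy(), rtol=0.02)

    def test_geometric_mean_one_and_all_zero_sample_error(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=(50, 6))
        res, _ = tmm_normalize(make_dataset(counts, scale="counts"))
        assert np.exp(np.mean(np.log(res.factors))) == pytest.approx(1.0, abs=1e-12)
        bad = counts.copy()
        bad[:, 2] = 0
        with pytest.raises(ValueError, match="s3"):
            tmm_normalize(make_dataset(bad, scale="counts"))


class TestFilterGenes:
    def test_hand_checked_toy(self):
        # 6 genes: 2 constant (IQR 0), 1 with row sum 0.5, 3 good
        vals = np.array([
            [5.0, 5.0, 5.0, 5.0],     # constant -> out
            [1.0, 2.0, 3.0, 4.0],     # keep
            [0.1, 0.2, 0.1, 0.1],     # sum 0.5 -> out
            [2.0, 2.0, 2.0, 2.0],     # constant -> out
            [0.0, 1.0, 0.0, 1.5],     # keep (sum 2.5, IQR > 0)
            [9.0, 1.0, 4.0, 2.0],     # keep
        ])
        kept = filter_genes(make_dataset(vals))
        assert kept.gene_ids == ["g2", "g5", "g6"]

    def test_row_sum_exactly_one_removed(self):
        vals = np.array([[0.25, 0.25, 0.25, 0.25], [1.0, 2.0, 3.0, 4.0]])
        vals[0, 0] = 0.1
        vals[0, 1] = 0.4   # sum exactly 1.0, IQR > 0
        assert vals[0].sum() == 1.0
        kept = filter_genes(make_dataset(vals))
        assert kept.gene_ids == ["g2"]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(5, 2, size=(40, 8))
        vals[3] = 1.0
        once = filter_genes(make_dataset(vals))
        twice = filter_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="every gene"):
            filter_genes(make_dataset(np.ones((3, 4))))


class TestQcOutlierFilter:
    @staticmethod
    def _with_tin(values, tin):
        md = pd.DataFrame({"tin": tin})
        return make_dataset(values, metadata=md)

    def test_homogeneous_samples_none_excluded(self):
        # shared gene-level structure so samples resemble real replicates
        rng = np.random.default_rng(16)
        mu = rng.normal(0, 3, size=(300, 1))
        ds = self._with_tin(mu + rng.normal(0, 1, size=(300, 25)),
                            rng.normal(75, 1, size=25))
        report = qc_outlier_filter(ds)
        assert not report.excluded.any()

    def test_single_criterion_failure_retained(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(300, 25))
        tin = np.full(25, 75.0) + rng.normal(0, 0.5, 25)
        tin[0] = 40.0                           # massive TIN outlier only
        report = qc_outlier_filter(self._with_tin(vals, tin))
        assert report.criteria_failed["s1"] == ["tin"]
        assert not report.excluded["s1"]

    def test_double_criterion_failure_excluded(self):
        rng = np.random.default_rng(7)
        mu = rng.normal(0, 3, size=(300, 1))          # samples correlate ~0.9
        vals = mu + rng.normal(0, 1, size=(300, 25))
        vals[:, 0] = rng.normal(0, 3, size=300)       # decorrelated outlier
        ds = self._with_tin(vals, np.full(25, 75.0) + rng.normal(0, 0.5, 25))
        report = qc_outlier_filter(ds)
        # verify by direct recomputation that both z-scores exceed 2
        corr = np.corrcoef(vals.T)
        mc = (corr.sum(axis=1) - 1) / 24
        zc = (mc - mc.mean()) / mc.std(ddof=1)
        assert abs(zc[0]) > 2
        centered = (vals - vals.mean(axis=1, keepdims=True)).T
        cov = centered @ centered.T
        evals, evecs = np.linalg.eigh(cov)
        pc1 = evecs[:, -1] * np.sqrt(evals[-1])
        z1 = (pc1 - pc1.mean()) / pc1.std(ddof=1)
        assert abs(z1[0]) > 2
        assert set(report.criteria_failed["s1"]) >= {"correlation", "principal_components"}
        assert report.excluded["s1"]

    def test_exclusion_iff_more_than_one_criterion(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, size=(200, 30))
        vals[:, 3] += rng.normal(0, 6, size=200)
        tin = np.full(30, 75.0) + rng.normal(0, 1, 30)
        tin[5] = 30.0
        report = qc_outlier_filter(self._with_tin(vals, tin))
        for sid in report.excluded.index:
            assert report.excluded[sid] == (len(report.criteria_failed[sid]) > 1)

    def test_missing_tin_warns_and_skips_criterion(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng.normal(0, 1, size=(100, 12)))
        report = qc_outlier_filter(ds)
        assert any("TIN" in w for w in report.warnings)
        assert all("tin" not in v for v in report.criteria_failed.values())


class TestSexCheck:
    @staticmethod
    def _dataset(y_expr, annotated):
        vals = np.vstack([np.random.default_rng(0).normal(5, 1, size=(10, len(y_expr))),
                          y_expr[None, :].repeat(2, axis=0)])
        ds = make_dataset(vals, metadata=pd.DataFrame({"sex": annotated}))
        y_genes = [f"g{len(vals) - 1}", f"g{len(vals)}"]
        return ds, y_genes

    def test_aligned_bimodal_no_mismatch(self):
        y = np.array([8.0] * 5 + [1.0] * 5)
        annotated = ["male"] * 5 + ["female"] * 5
        ds, y_genes = self._dataset(y, annotated)
        assert not sex_check(ds, y_genes).any()

    def test_swapped_annotation_flagged(self):
        y = np.array([8.0] * 5 + [1.0] * 5)
        annotated = ["male"] * 4 + ["female"] + ["female"] * 4 + ["male"]
        ds, y_genes = self._dataset(y, annotated)
        flags = sex_check(ds, y_genes)
        assert flags["s5"] and flags["s10"]
        assert flags.sum() == 2

    def test_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(10)
        y = np.concatenate([rng.normal(2, 1, 11), rng.normal(7, 1, 9)])
        annotated = ["female"] * 11 + ["male"] * 9
        ds, y_genes = self._dataset(y, annotated)
        flags = sex_check(ds, y_genes)
        # oracle: scan every split of the sorted scores, minimize within-SS
        score = ds.values.loc[y_genes].mean(axis=0).to_numpy()
        order = np.argsort(score)
        best, best_ss = None, np.inf
        for cut in range(1, 20):
            lo, hi = score[order[:cut]], score[order[cut:]]
            ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if ss < best_ss:
                best_ss, best = ss, cut
        predicted = np.empty(20, dtype=object)
        predicted[order[:best]] = "female"
        predicted[order[best:]] = "male"
        expected = predicted != np.array(annotated)
        assert (flags.to_numpy() == expected).all()

    def test_no_y_genes_undetermined(self):
        ds, _ = self._dataset(np.ones(6), ["male"] * 6)
        with pytest.warns(UserWarning, match="no Y genes"):
            flags = sex_check(ds, ["absent1"])
        assert flags.isna().all()


class TestResidualize:
    def test_orthogonal_covariate_equals_centering(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, size=(30, 40))
        cov = rng.normal(0, 1, 40)
        # orthogonalize the covariate against every centered gene
        centered = vals - vals.mean(axis=1, keepdims=True)
        cov = cov - cov.mean()
        cov = cov - centered.T @ np.linalg.lstsq(centered.T, cov, rcond=None)[0]
        md = pd.DataFrame({"c": cov})
        res = residualize(make_dataset(vals, metadata=md), ["c"])
        assert np.abs(res.matrix() - centered).max() < 1e-10

    def test_gene_linear_in_tin_zeroed(self):
        rng = np.random.default_rng(12)
        tin = rng.normal(75, 5, 25)
        vals = rng.normal(0, 1, size=(10, 25))
        vals[0] = 3.0 + 0.4 * tin
        md = pd.DataFrame({"tin": tin})
        res = residualize(make_dataset(vals, metadata=md), ["tin"])
        assert np.abs(res.values.iloc[0].to_numpy()).max() < 1e-10

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        n = 40
        md = pd.DataFrame({
            "tin": rng.normal(75, 5, n),
            "batch": rng.choice(["A", "B", "C"], n),
            "x": rng.normal(0, 1, n),
        })
        vals = rng.normal(0, 1, size=(15, n))
        res = residualize(make_dataset(vals, metadata=md), ["tin", "batch", "x"])
        # explicit normal-equations solve
        dummies = pd.get_dummies(md["batch"], prefix="batch", drop_first=True, dtype=float)
        x = np.column_stack([np.ones(n), md["tin"], dummies.to_numpy(), md["x"]])
        beta = np.linalg.solve(x.T @ x, x.T @ vals.T)
        expected = (vals.T - x @ beta).T
        assert np.abs(res.matrix() - expected).max() < 1e-10

    def test_projection_idempotence(self):
        rng = np.random.default_rng(14)
        md = pd.DataFrame({"tin": rng.normal(75, 5, 30),
                           "batch": rng.choice(["A", "B"], 30)})
        ds = make_dataset(rng.normal(0, 1, size=(20, 30)), metadata=md)
        once = residualize(ds, ["tin", "batch"])
        twice = residualize(once, ["tin", "batch"])
        assert np.abs(once.matrix() - twice.matrix()).max() < 1e-10

    def test_rank_deficient_design_named(self):
        rng = np.random.default_rng(15)
        md = pd.DataFrame({"tin": rng.normal(75, 5, 20)})
        md["tin_copy"] = md["tin"]
        ds = make_dataset(rng.normal(0, 1, size=(5, 20)), metadata=md)
        with pytest.raises(ValueError, match="collinear"):
            residualize(ds, ["tin", "tin_copy"])
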