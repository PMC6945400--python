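"""Normalization, dispersion estimation and the moderated QL F test."""

import subprocess

import numpy as np
import pytest
from scipy import stats as st

from dosage_de.de_testing import (
    bonferroni_adjust,
    estimate_dispersions,
    estimate_size_factors,
)
from dosage_de.de_testing import test_pairwise as run_pairwise
from dosage_de.errors import DesignError, ParameterError, ValidationError
from dosage_de.spike_calibration import detection_filter
from dosage_de.synthetic_data import GeneParams, make_default_design, simulate_counts

from conftest import build_matrix


def _simulated_6lib(n_genes=400, phi=0.05, lfc=0.0, depth=5e5, seed=0,
                    base=200.0, planted=0):
    """Het+WT 6-library simulation; first `planted` genes carry `lfc` per allele."""
    design = make_default_design(seed=seed, depth_mean=depth, depth_cv=0.1)
    from dosage_de.synthetic_data import make_spike_reference

    spikes = make_spike_reference(seed=seed + 1)
    genes = []
    for i in range(n_genes):
        if i < planted:
            cls = "linear_up" if lfc > 0 else "linear_down"
            genes.append(GeneParams(f"g{i}", base, phi, lfc, cls))
        else:
            genes.append(GeneParams(f"g{i}", base, phi))
    m, _ = simulate_counts(design, genes, spikes, seed=seed + 2)
    het = design.libraries_for("Het")
    wt = design.libraries_for("CorrWT")
    sub = m.subset(het + wt)
    return sub, het, wt


def _de_setup(sub, het, wt, threshold=5):
    filt = detection_filter(sub, het + wt, threshold, comparison_id="HetVsWT")
    norm = estimate_size_factors(sub)
    groups = {l: "mut" for l in het} | {l: "wt" for l in wt}
    disp = estimate_dispersions(sub, groups, norm,
                                gene_ids=sorted(filt.analyzable_genes))
    return filt, norm, disp


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        m = build_matrix(np.tile([[10], [20], [30]], (1, 6)))
        for method in ("median_of_ratios", "tmm"):
            f = estimate_size_factors(m, method).series(m.library_ids)
            assert np.allclose(f, 1.0)

    def test_doubled_library_scales_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 200, size=(50, 1))
        counts = np.hstack([base, 2 * base, base, base, base, base])
        f = estimate_size_factors(build_matrix(counts)).series(None)
        ratio = f.iloc[1] / f.iloc[0]
        assert ratio == pytest.approx(2.0, rel=1e-10)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-10)

    def test_median_of_ratios_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(200, 6)) + 1
        m = build_matrix(counts)
        f = estimate_size_factors(m, "median_of_ratios").series(m.library_ids)
        logc = np.log(counts)
        oracle = np.exp(np.median(logc - logc.mean(axis=1, keepdims=True), axis=0))
        oracle = oracle / np.exp(np.log(oracle).mean())
        assert np.allclose(f.to_numpy(), oracle, atol=1e-10)

    def test_tmm_matches_edger(self, tmp_path):
        """Cross-check TMM effective sizes against edgeR's calcNormFactors."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(5, 0.05, size=(300, 6))
        counts[:30, :3] *= 4  # composition difference
        m = build_matrix(counts)
        ours = estimate_size_factors(m, "tmm").series(m.library_ids).to_numpy()
        np.savetxt(tmp_path / "counts.txt", counts, fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.table("{tmp_path}/counts.txt"))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'eff <- colSums(x) * f\n'
            'cat(eff / exp(mean(log(eff))), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        theirs = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(ours, theirs, rtol=1e-6)

    def test_fallback_to_totals_with_warning(self, caplog):
        counts = np.array([[10, 0, 10, 10, 10, 10], [0, 20, 20, 20, 20, 20]])
        m = build_matrix(counts)
        with caplog.at_level("WARNING"):
            f = estimate_size_factors(m).series(m.library_ids)
        assert (f > 0).all()
        assert any("total-count" in r.message for r in caplog.records)


class TestBonferroni:
    def test_direct_formula(self):
        assert bonferroni_adjust([0.01], 10)[0] == pytest.approx(0.1)
        assert bonferroni_adjust([0.5], 10)[0] == 1.0
        out = bonferroni_adjust([1e-6, 0.004, 0.2], 100)
        assert np.allclose(out, [1e-4, 0.4, 1.0])

    def test_validation(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([1.2], 5)
        with pytest.raises(ParameterError):
            bonferroni_adjust([0.1, 0.2], 1)


class TestDispersions:
    def test_poisson_data_gives_near_zero_dispersion(self):
        sub, het, wt = _simulated_6lib(n_genes=2000, phi=0.0, base=500.0, seed=3)
        _, norm, disp = _de_setup(sub, het, wt)
        assert disp.per_gene["shrunk"].median() < 0.01

    def test_recovers_planted_dispersion(self):
        sub, het, wt = _simulated_6lib(n_genes=2000, phi=0.2, base=300.0, seed=4)
        _, norm, disp = _de_setup(sub, het, wt)
        med = disp.per_gene["shrunk"].median()
        assert 0.1 <= med <= 0.4
        assert 0.1 <= disp.common <= 0.4

    def test_constant_gene_has_zero_raw_dispersion(self):
        counts = np.vstack([np.full(6, 100), np.array([80, 120, 90, 110, 100, 100])])
        m = build_matrix(counts)
        norm = estimate_size_factors(m)
        groups = {l: ("mut" if i < 3 else "wt") for i, l in enumerate(m.library_ids)}
        disp = estimate_dispersions(m, groups, norm)
        assert disp.per_gene.loc["g0", "raw"] <= 1e-4

    def test_single_replicate_group_rejected(self):
        m = build_matrix(np.full((5, 6), 50))
        norm = estimate_size_factors(m)
        groups = {l: "wt" for l in m.library_ids}
        groups[m.library_ids[0]] = "mut"
        with pytest.raises(DesignError, match="mut"):
            estimate_dispersions(m, groups, norm)


class TestPairwise:
    def test_identical_groups_null_result(self):
        counts = np.tile([[50], [200], [9]], (1, 6))
        m = build_matrix(counts)
        filt, norm, disp = _de_setup(m, m.library_ids[:3], m.library_ids[3:])
        res = run_pairwise(m, m.library_ids[:3], m.library_ids[3:], norm, disp, filt)
        assert np.allclose(res.table["log2fc"], 0.0, atol=1e-9)
        assert np.allclose(res.table["p_raw"], 1.0, atol=1e-6)

    def test_group_swap_negates_log2fc_keeps_p(self):
        sub, het, wt = _simulated_6lib(n_genes=300, phi=0.05, lfc=1.0,
                                       planted=30, seed=6)
        filt, norm, disp = _de_setup(sub, het, wt)
        fwd = run_pairwise(sub, het, wt, norm, disp, filt)
        rev = run_pairwise(sub, wt, het, norm, disp, filt)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-9)
        assert np.allclose(fwd.table["p_raw"], rev.table["p_raw"], rtol=1e-9)

    def test_recovers_planted_log2fc(self):
        sub, het, wt = _simulated_6lib(n_genes=500, phi=0.05, lfc=1.0,
                                       planted=40, base=300.0, seed=7)
        filt, norm, disp = _de_setup(sub, het, wt)
        res = run_pairwise(sub, het, wt, norm, disp, filt)
        planted = [f"g{i}" for i in range(40) if f"g{i}" in res.table.index]
        est = res.table.loc[planted, "log2fc"]
        assert np.abs(est - 1.0).median() < 0.3
        assert (np.abs(est - 1.0) < 0.3).mean() > 0.6

    def test_scaling_invariance_on_noiseless_counts(self):
        base = np.array([[100], [250], [60], [900], [30]])
        counts = np.tile(base, (1, 6))
        counts[:, 1] *= 5  # one library scaled by integer k
        m = build_matrix(counts)
        filt, norm, disp = _de_setup(m, m.library_ids[:3], m.library_ids[3:])
        res = run_pairwise(m, m.library_ids[:3], m.library_ids[3:], norm, disp, filt)
        assert np.allclose(res.table["log2fc"], 0.0, atol=1e-6)

    def test_monotone_power_in_effect_size(self):
        powers = []
        for lfc in (1.0, 2.0):
            hits = 0
            tot = 0
            for seed in range(2):
                sub, het, wt = _simulated_6lib(
                    n_genes=400, phi=0.05, lfc=lfc, planted=80,
                    base=200.0, seed=100 + seed,
                )
                filt, norm, disp = _de_setup(sub, het, wt)
                res = run_pairwise(sub, het, wt, norm, disp, filt)
                planted = [f"g{i}" for i in range(80) if f"g{i}" in res.table.index]
                hits += int(res.table.loc[planted, "significant"].sum())
                tot += len(planted)
            powers.append(hits / tot)
        assert powers[1] >= powers[0] - 3 * np.sqrt(0.25 / tot)

    def test_poisson_limit_ranks_match_lrt(self):
        """With phi ~ 0 the QL F p-values rank like a Poisson LRT."""
        sub, het, wt = _simulated_6lib(n_genes=500, phi=0.0, base=150.0, seed=8,
                                       depth=2e5)
        filt, norm, disp = _de_setup(sub, het, wt)
        res = run_pairwise(sub, het, wt, norm, disp, filt)
        libs = het + wt
        y = sub.endogenous().loc[res.table.index, libs].to_numpy(float)
        s = norm.series(libs).to_numpy()

        def pois_ll(y, mu_scalar, sv):
            mu = np.maximum(mu_scalar[:, None] * sv[None, :], 1e-12)
            return (y * np.log(mu) - mu).sum(axis=1)

        muA = y[:, :3].sum(1) / s[:3].sum()
        muB = y[:, 3:].sum(1) / s[3:].sum()
        mu0 = y.sum(1) / s.sum()
        lrt = 2 * (pois_ll(y[:, :3], muA, s[:3]) + pois_ll(y[:, 3:], muB, s[3:])
                   - pois_ll(y, mu0, s))
        p_lrt = st.chi2.sf(lrt, 1)
        rho = st.spearmanr(res.table["p_raw"], p_lrt).statistic
        assert rho > 0.99

    def test_exact_mode_agrees_in_direction(self):
        counts = np.hstack([np.full((1, 3), 200), np.full((1, 3), 50)])
        counts = np.vstack([counts, np.full((3, 6), 100)])
        m = build_matrix(counts)
        filt, norm, disp = _de_setup(m, m.library_ids[:3], m.library_ids[3:])
        res = run_pairwise(m, m.library_ids[:3], m.library_ids[3:], norm, disp,
                            filt, test="exact")
        assert res.table.loc["g0", "p_raw"] < 0.01
        assert np.all(res.table.loc[["g1", "g2", "g3"], "p_raw"] > 0.5)

    def test_design_errors(self):
        m = build_matrix(np.full((2, 6), 50))
        filt, norm, disp = _de_setup(m, m.library_ids[:3], m.library_ids[3:])
        with pytest.raises(DesignError):
            run_pairwise(m, m.library_ids[:3], m.library_ids[2:], norm, disp, filt)
        with pytest.raises(ParameterError):
            run_pairwise(m, m.library_ids[:3], m.library_ids[3:], norm, disp,
                          filt, alpha=1.5)
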