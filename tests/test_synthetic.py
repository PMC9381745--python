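import dataclasses

import numpy as np
import pytest
from scipy import stats

from atpskit.binodal import evaluate_merchuk, fit_merchuk, fit_zm
from atpskit.core import KOH, PEG600, validate_composition
from atpskit.partitioning import fit_diamond_hsu
from atpskit.refractometry import calibrate, invert_to_polymer_fraction
from atpskit.synthetic import (
    GeneratorConfig,
    generate_binodal,
    generate_partition,
    generate_refractometry,
    generate_tielines,
    write_dataset,
)
from atpskit.tielines import fit_othmer_tobias, fit_setschenow, lever_rule_check


class TestDeterminism:
    def test_same_seed_same_points(self):
        cfg = GeneratorConfig(seed=3)
        a = generate_binodal(cfg)
        b = generate_binodal(cfg)
        assert a == b

    def test_streams_independent(self):
        # changing the number of binodal points must not perturb tie-lines
        c1, c2 = GeneratorConfig(seed=3), GeneratorConfig(seed=3, n_binodal_points=100)
        assert generate_tielines(c1) == generate_tielines(c2)

    def test_bundle_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(cfg, d1)
        p2 = write_dataset(cfg, d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestBinodalGeneration:
    def test_noiseless_points_on_curve(self, noiseless_config):
        for p in generate_binodal(noiseless_config):
            assert p.w_p == pytest.approx(
                evaluate_merchuk(noiseless_config.binodal_truth, p.w_s), rel=1e-12
            )

    def test_noise_sd_within_chi_square_interval(self):
        """Sample residual sd over n=200 draws lies in the 99% chi-square band."""
        cfg = GeneratorConfig(seed=21, n_binodal_points=200, binodal_noise_sd=0.3)
        pts = generate_binodal(cfg)
        resid = np.array(
            [p.w_p - evaluate_merchuk(cfg.binodal_truth, p.w_s) for p in pts]
        )
        n, sd = resid.size, 0.3
        lo = sd * np.sqrt(stats.chi2.ppf(0.005, n) / n)
        hi = sd * np.sqrt(stats.chi2.ppf(0.995, n) / n)
        assert lo <= resid.std() <= hi

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(binodal_noise_sd=-0.1)


class TestTielineGeneration:
    def test_compositions_validate_and_lever_exact(self, noiseless_config):
        for t in generate_tielines(noiseless_config):
            for c in (t.overall, t.top, t.bottom):
                validate_composition(c)
            rep = lever_rule_check(t)
            assert rep.max_deviation == pytest.approx(0.0, abs=1e-10)
            assert 0.3 <= rep.phase_fraction_top <= 0.7

    def test_exact_othmer_tobias_mode(self, noiseless_config):
        fit = fit_othmer_tobias(generate_tielines(noiseless_config, mode="othmer_tobias"))
        k, n = noiseless_config.othmer_tobias_truth
        assert fit.k == pytest.approx(k, rel=1e-10)
        assert fit.n == pytest.approx(n, rel=1e-10)

    def test_exact_setschenow_mode(self, noiseless_config):
        fit = fit_setschenow(
            generate_tielines(noiseless_config, mode="setschenow"), PEG600, KOH
        )
        k_p, k_s = noiseless_config.setschenow_truth
        assert fit.k_p == pytest.approx(k_p, rel=1e-10)
        assert fit.k_s == pytest.approx(k_s, rel=1e-10)

    def test_unknown_mode_rejected(self, noiseless_config):
        with pytest.raises(ValueError, match="mode"):
            generate_tielines(noiseless_config, mode="nope")


class TestPartitionGeneration:
    def test_noiseless_truth_recovered(self, noiseless_config):
        tls = generate_tielines(noiseless_config)
        recs = generate_partition(noiseless_config, tls)
        for drug, (A, B) in noiseless_config.partition_truth.items():
            fit = fit_diamond_hsu([r for r in recs if r.drug == drug])
            assert fit.A == pytest.approx(A, rel=1e-9)
            assert fit.B == pytest.approx(B, rel=1e-9)

    def test_drug_mass_balance_exact(self, noiseless_config):
        tls = generate_tielines(noiseless_config)
        recs = generate_partition(noiseless_config, tls)
        by_overall = {(t.overall.w_s, t.overall.w_p): t for t in tls}
        for r in recs:
            t = by_overall[(r.overall.w_s, r.overall.w_p)]
            f = lever_rule_check(t).phase_fraction_top
            total = r.w_top_drug * f + r.w_bot_drug * (1 - f)
            assert total == pytest.approx(noiseless_config.total_drug_fraction, rel=1e-12)

    def test_requires_tielines(self, noiseless_config):
        with pytest.raises(ValueError):
            generate_partition(noiseless_config, [])


class TestRefractometryGeneration:
    def test_noiseless_inversion_exact(self, noiseless_config):
        tls = generate_tielines(noiseless_config)
        comps = [t.top for t in tls]
        readings, sp, ss = generate_refractometry(noiseless_config, comps)
        cal = calibrate(sp, ss)
        for reading, c in zip(readings, comps):
            with pytest.warns(UserWarning):  # phase compositions exceed dilute range
                got = invert_to_polymer_fraction(reading, cal)
            assert got == pytest.approx(c.w_p / 100.0, abs=1e-10)

    def test_inversion_error_matches_propagation(self):
        """Over many draws the inversion error sd approaches sigma_n / a_p."""
        cfg = GeneratorConfig(seed=17)
        comps = [t.top for t in generate_tielines(cfg)]
        errs = []
        for rep in range(200):
            rep_cfg = dataclasses.replace(cfg, seed=rep)
            readings, sp, ss = generate_refractometry(rep_cfg, comps)
            truth_cal = cfg.refractometry_truth
            for reading, c in zip(readings, comps):
                w_p = (reading.n_d - truth_cal.n0 - truth_cal.a_s * reading.w_s_known) / truth_cal.a_p
                errs.append(w_p - c.w_p / 100.0)
        expected = cfg.refractometry_noise_sd / cfg.refractometry_truth.a_p
        assert np.std(errs) == pytest.approx(expected, rel=0.1)


def test_end_to_end_noiseless_recovery(noiseless_config, tmp_path):
    """The pipeline run on noiseless synthetic data reproduces every truth
    parameter to <= 1e-8 relative error."""
    from atpskit.io import read_binodal_csv, read_partition_csv, read_tielines_csv
    from atpskit.partitioning import match_records_to_tielines

    paths = write_dataset(noiseless_config, tmp_path)
    pts = read_binodal_csv(paths["binodal"])
    mk = fit_merchuk(pts)
    truth = noiseless_config.binodal_truth
    assert mk.a == pytest.approx(truth.a, rel=1e-8)
    assert mk.b == pytest.approx(truth.b, rel=1e-8)
    assert mk.c == pytest.approx(truth.c, rel=1e-8)
    tls = read_tielines_csv(paths["tielines"])
    recs = match_records_to_tielines(read_partition_csv(paths["partition"]), tls)
    for drug, (A, B) in noiseless_config.partition_truth.items():
        fit = fit_diamond_hsu([r for r in recs if r.drug == drug])
        assert fit.A == pytest.approx(A, rel=1e-8)
        assert fit.B == pytest.approx(B, rel=1e-8)
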