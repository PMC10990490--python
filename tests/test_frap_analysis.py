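import numpy as np
import pytest

from neuritemito.frap_analysis import (
    PRE_T,
    FrapSeries,
    GeometryError,
    NormalizationError,
    ScheduleError,
    compare_recovery_curves,
    extract_frap_series,
    fit_recovery,
    normalize_frap,
    prebleach_puncta_areas,
)
from neuritemito.imaging_io import ImageStack, NeuritePath, Roi
from neuritemito.synthetic_data import frap_curve, gen_frap_experiment


def series_from(t_post, y_post, f_pre=100.0, f0=None, animal="a"):
    """Build a raw series: pre point + post-bleach samples."""
    t = np.concatenate([[PRE_T], t_post])
    f = np.concatenate([[f_pre], y_post])
    return FrapSeries(animal_id=animal, t_min=t, f=f)


def noisy_group(rng, plateau, k, n=8, sd=5.0, t=None):
    t = np.arange(0, 16.1, 2.0) if t is None else t
    out = []
    for a in range(n):
        y = plateau * (1 - np.exp(-k * t)) + rng.normal(0, sd, len(t))
        out.append(FrapSeries(animal_id=f"a{a}", t_min=t, f=y,
                              norm_mode="percent", f_norm=y))
    return out


class TestExtract:
    def test_static_sample_constant_series(self):
        pages = np.full((3, 64, 120), 100.0)
        pages[:, 28:36, :] = 900.0
        stack = ImageStack(pages=pages, axis_kind="z", px_um=0.1, dz_um=0.25)
        region = Roi(id="r", kind="rectangle", vertices=[(40, 30), (80, 34)])
        bg = Roi(id="b", kind="rectangle", vertices=[(40, 2), (80, 8)])
        series = extract_frap_series([stack] * 5, region, bg,
                                     t_min=[PRE_T, 0, 2, 4, 6])
        assert np.ptp(series.f) == pytest.approx(0.0)

    def test_noiseless_generator_identity(self):
        stacks, region, bg, truth = gen_frap_experiment(
            k_per_min=0.3, plateau_pct=70.0, seed=0, noise=False)
        t_min = [PRE_T] + [r["t_min"] for r in truth.records[1:]]
        series = extract_frap_series(stacks, region, bg, t_min=t_min)
        levels = np.array([r["level"] for r in truth.records])
        ratio = series.f / levels  # proportional: constant optical gain
        assert np.ptp(ratio) / ratio.mean() < 1e-9

    def test_region_outside_image(self):
        stack = ImageStack(pages=np.zeros((2, 20, 20)), axis_kind="z",
                           px_um=0.1, dz_um=0.25)
        region = Roi(id="r", kind="rectangle", vertices=[(10, 10), (30, 15)])
        with pytest.raises(GeometryError):
            extract_frap_series([stack, stack], region, None, t_min=[PRE_T, 0])

    def test_missing_timepoint(self):
        stack = ImageStack(pages=np.zeros((2, 20, 20)), axis_kind="z",
                           px_um=0.1, dz_um=0.25)
        region = Roi(id="r", kind="rectangle", vertices=[(2, 2), (8, 8)])
        with pytest.raises(ScheduleError):
            extract_frap_series([stack] * 3, region, None,
                                t_min=[PRE_T, 0, 2, 4])


class TestNormalize:
    def test_full_recovery_is_100(self):
        s = series_from(np.arange(0, 16.1, 2.0),
                        [20.0] + [100.0] * 8, f_pre=100.0)
        out = normalize_frap(s, "percent")
        t, y = out.post_bleach()
        assert y[0] == 0.0
        np.testing.assert_allclose(y[1:], 100.0)

    def test_no_recovery_is_0(self):
        s = series_from(np.arange(0, 16.1, 2.0), [20.0] * 9, f_pre=100.0)
        p = normalize_frap(s, "percent")
        np.testing.assert_allclose(p.post_bleach()[1], 0.0)
        sub = normalize_frap(s, "subtract")
        np.testing.assert_allclose(sub.f_norm, 0.0)

    def test_percent_endpoints_exact(self):
        s = series_from(np.arange(0, 16.1, 2.0),
                        20.0 + 5 * np.arange(9), f_pre=120.0)
        out = normalize_frap(s, "percent")
        assert out.f_norm[0] == pytest.approx(100.0)  # pre
        assert out.f_norm[1] == 0.0  # 0 min, by construction

    def test_subtract_drops_pre(self):
        s = series_from(np.arange(0, 16.1, 2.0), 20.0 + np.arange(9))
        out = normalize_frap(s, "subtract")
        assert not out.has_pre
        assert out.f_norm[0] == 0.0

    def test_failed_bleach_rejected(self):
        s = series_from(np.array([0.0, 2.0, 4.0]), [100.0, 100.0, 100.0],
                        f_pre=90.0)
        with pytest.raises(NormalizationError):
            normalize_frap(s, "percent")


class TestFitRecovery:
    def test_exact_inversion(self):
        t = np.arange(0, 16.1, 2.0)
        y = 80.0 * (1 - np.exp(-0.2 * t))
        s = FrapSeries(animal_id="a", t_min=t, f=y, norm_mode="percent", f_norm=y)
        fit = fit_recovery([s])
        assert fit.plateau == pytest.approx(80.0, abs=1e-6)
        assert fit.k_per_min == pytest.approx(0.2, abs=1e-6)

    def test_zero_data_flagged(self):
        t = np.arange(0, 16.1, 2.0)
        s = FrapSeries(animal_id="a", t_min=t, f=np.zeros_like(t),
                       norm_mode="percent", f_norm=np.zeros_like(t))
        fit = fit_recovery([s])
        assert fit.flagged
        assert fit.plateau == pytest.approx(0.0, abs=1e-9)

    def test_noisy_k_recovery_rate(self, rng):
        hits = 0
        for _ in range(100):
            fit = fit_recovery(noisy_group(rng, 80.0, 0.2))
            hits += abs(fit.k_per_min - 0.2) / 0.2 <= 0.2
        assert hits >= 90

    def test_monotone_on_noiseless_truth(self):
        t = np.arange(0, 16.1, 2.0)
        y = 60.0 * (1 - np.exp(-0.35 * t))
        s = FrapSeries(animal_id="a", t_min=t, f=y, norm_mode="percent", f_norm=y)
        fit = fit_recovery([s])
        grid = np.linspace(0, 16, 200)
        assert np.all(np.diff(fit.predict(grid)) >= -1e-12)


class TestCompareCurves:
    def test_identical_groups_null_identity(self):
        t = np.arange(0, 16.1, 2.0)
        y = 80.0 * (1 - np.exp(-0.2 * t)) + np.sin(t)  # any fixed data
        g = [FrapSeries(animal_id="a", t_min=t, f=y, norm_mode="percent", f_norm=y)]
        comps = compare_recovery_curves({"a": g, "b": g})
        assert comps[0].F == pytest.approx(0.0, abs=1e-9)
        assert comps[0].p_raw == pytest.approx(1.0)

    def test_ss_shared_never_below_separate(self, rng):
        for _ in range(20):
            groups = {"a": noisy_group(rng, 80, 0.2, n=4),
                      "b": noisy_group(rng, 60, 0.3, n=4)}
            c = compare_recovery_curves(groups)[0]
            assert c.F >= 0.0

    def test_power_plateau_80_vs_40(self, rng):
        hits = 0
        for _ in range(50):
            comps = compare_recovery_curves({"a": noisy_group(rng, 80, 0.2),
                                             "b": noisy_group(rng, 40, 0.2)})
            hits += comps[0].p_adj < 0.01
        assert hits >= 48

    def test_bonferroni_family_size(self, rng):
        groups = {"ctl": noisy_group(rng, 80, 0.2), "a": noisy_group(rng, 70, 0.2),
                  "b": noisy_group(rng, 60, 0.2)}
        comps = compare_recovery_curves(groups, control="ctl")
        assert len(comps) == 2
        for c in comps:
            assert c.p_adj == pytest.approx(min(c.p_raw * 2, 1.0))
        allp = compare_recovery_curves(groups, all_pairs=True)
        assert len(allp) == 3


class TestPunctaProfile:
    def make_triangle_image(self, centers_px, height, half_width_px=10,
                            baseline=100.0, shape=(40, 300)):
        h, w = shape
        profile = np.full(w, baseline)
        x = np.arange(w)
        for c in centers_px:
            tri = height * np.clip(1 - np.abs(x - c) / half_width_px, 0, None)
            profile += tri
        pages = np.tile(profile, (h, 1))[None]
        return ImageStack(pages=pages, axis_kind="z", px_um=0.1, dz_um=0.25)

    def test_flat_profile_no_peaks(self):
        stack = self.make_triangle_image([], 0.0)
        path = NeuritePath(points=[(5, 20), (290, 20)], width_px=20)
        prof = prebleach_puncta_areas(stack, path)
        assert prof.no_peaks
        assert prof.mean_area == 0.0

    def test_two_triangles_analytic_area(self):
        # triangle area = height * half_width (in um): 200 * 1.0 um = 200
        stack = self.make_triangle_image([100, 200], 200.0, half_width_px=10)
        path = NeuritePath(points=[(5, 20), (290, 20)], width_px=20)
        prof = prebleach_puncta_areas(stack, path)
        assert len(prof.peaks) == 2
        for _, area in prof.peaks:
            assert area == pytest.approx(200.0 * 1.0, rel=0.05)

    def test_linearity_under_doubled_illumination(self, rng):
        base = self.make_triangle_image([100, 200], 150.0)
        noise = rng.normal(0, 2.0, base.pages.shape)
        noisy = ImageStack(pages=(base.pages + noise).clip(0), axis_kind="z",
                           px_um=0.1, dz_um=0.25)
        doubled = ImageStack(pages=2 * noisy.pages, axis_kind="z",
                             px_um=0.1, dz_um=0.25)
        path = NeuritePath(points=[(5, 20), (290, 20)], width_px=20)
        p1 = prebleach_puncta_areas(noisy, path)
        p2 = prebleach_puncta_areas(doubled, path)
        assert len(p1.peaks) == len(p2.peaks)
        for (_, a1), (_, a2) in zip(p1.peaks, p2.peaks):
            assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_short_path_rejected(self):
        stack = self.make_triangle_image([], 0.0)
        path = NeuritePath(points=[(5, 20), (6, 20)], width_px=20)
        with pytest.raises(GeometryError):
            prebleach_puncta_areas(stack, path)
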