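import numpy as np
import pytest
from scipy.optimize import curve_fit

from renaldwi import fit_adc, fit_dki, fit_ivim_segmented, fit_volume
from renaldwi.errors import FitError
from renaldwi.protocol import B_SCALE, make_protocol
from renaldwi.signal import ImageSeries, add_rician_noise, forward_ivim_kurtosis


# ------------------------------------------------------------------ ADC

def test_adc_two_point_examples():
    assert fit_adc(1000.0, 1000 * np.exp(-1.6)).adc == pytest.approx(2.0, rel=1e-12)
    assert fit_adc(500.0, 500.0).adc == 0.0
    assert not fit_adc(1000.0, 0.0).valid
    assert not fit_adc(-5.0, 100.0).valid


def test_adc_inverts_monoexponential_forward(multi_b):
    for d in np.linspace(0.3, 3.5, 15):
        sig = forward_ivim_kurtosis(multi_b.b, 1000.0, 0.0, d, 50.0, 0.0)
        est = fit_adc(sig[multi_b.b == 0][0], sig[multi_b.b == 800][0])
        assert est.adc == pytest.approx(d, rel=1e-12)


# ------------------------------------------------------------------ DKI

def test_dki_exact_on_noiseless_kurtosis_signal():
    b = np.array([200, 400, 800, 1000, 1500, 2000, 2500], float)
    md, mk = 2.5, 0.5
    x = b * md * B_SCALE
    sig = 900.0 * np.exp(-x + mk * x**2 / 6)
    res = fit_dki(b, sig)
    assert res.md == pytest.approx(md, abs=1e-6)
    assert res.mk == pytest.approx(mk, abs=1e-6)
    assert res.fit_flags == ()


def test_dki_zero_kurtosis_gives_monoexponential():
    b = np.array([200, 500, 1200, 2500], float)
    sig = 1000 * np.exp(-b * 1.8 * B_SCALE)
    res = fit_dki(b, sig)
    assert res.md == pytest.approx(1.8, abs=1e-9)
    assert res.mk == pytest.approx(0.0, abs=1e-9)


def test_dki_needs_three_distinct_b_and_positive_signal():
    with pytest.raises(FitError, match="distinct b"):
        fit_dki(np.array([300.0, 300.0, 900.0]), np.array([10.0, 10.0, 5.0]))
    res = fit_dki(np.array([200.0, 800.0, 2000.0]), np.array([10.0, -1.0, 5.0]))
    assert not res.valid and "invalid_signal" in res.fit_flags


def test_dki_median_md_recovery_under_noise(multi_b, rng):
    """Severe-group-like truth at SNR 50, 500 voxels: the median fitted MD
    stays within 0.1 of the generating 2.74 um^2/ms despite the noise
    floor at the highest b values."""
    sig = forward_ivim_kurtosis(multi_b.b, 1000.0, 0.0, 2.74, 70.0, 0.502)
    noisy = add_rician_noise(np.tile(sig, (500, 1)), 20.0, multi_b.n_avg, seed=rng)
    mds = [fit_dki(multi_b.b, noisy[i]).md for i in range(500)]
    assert abs(np.median(mds) - 2.74) < 0.1


# ----------------------------------------------------------------- IVIM

def _ivim_signal(b, s0, f, d, d_star):
    return s0 * (f * np.exp(-b * d_star * B_SCALE) + (1 - f) * np.exp(-b * d * B_SCALE))


def test_ivim_segmented_matches_full_nonlinear_oracle(multi_b):
    """On a noiseless bi-exponential the segmented estimates agree with a
    full joint 3-parameter nonlinear fit of the same series."""
    b = multi_b.b[multi_b.b <= 800]
    sig = _ivim_signal(b, 1000.0, 0.20, 1.5, 50.0)
    seg = fit_ivim_segmented(b, sig)

    def model(bb, f, d, d_star):
        return _ivim_signal(bb, 1000.0, f, d, d_star)

    (f_o, d_o, ds_o), _ = curve_fit(
        model, b, sig, p0=[0.1, 1.0, 30.0], bounds=([0, 0.1, 4], [0.6, 4, 300])
    )
    assert seg.f == pytest.approx(f_o, rel=0.01) and seg.f == pytest.approx(0.20, rel=0.01)
    assert seg.d == pytest.approx(d_o, rel=0.01) and seg.d == pytest.approx(1.5, rel=0.01)
    assert seg.d_star == pytest.approx(ds_o, rel=0.05)
    assert seg.d_star == pytest.approx(50.0, rel=0.05)


def test_ivim_degenerate_monoexponential():
    b = np.array([0, 10, 30, 50, 70, 100, 200, 400, 800], float)
    sig = 1000 * np.exp(-b * 1.7 * B_SCALE)
    res = fit_ivim_segmented(b, sig)
    assert res.f <= 0.005
    assert res.d == pytest.approx(1.7, rel=1e-3)


def test_ivim_f_monotone_in_true_f(multi_b):
    b = multi_b.b[multi_b.b <= 800]
    estimates = [
        fit_ivim_segmented(b, _ivim_signal(b, 1000.0, f, 1.5, 60.0)).f
        for f in np.linspace(0.0, 0.5, 8)
    ]
    assert np.all(np.diff(estimates) > 0)


def test_ivim_needs_points_on_both_sides_of_threshold():
    b = np.array([0, 300, 500, 800], float)
    with pytest.raises(FitError, match="threshold"):
        fit_ivim_segmented(b, np.full(4, 100.0))


def test_ivim_median_f_recovery_under_noise(multi_b, rng):
    """Mild-group cortical truth (f = 0.226, D = 1.65, D* = 73) at SNR 50:
    the median |f error| over 500 voxels stays within 0.03."""
    sig = _ivim_signal(multi_b.b, 1000.0, 0.226, 1.65, 73.0)
    noisy = add_rician_noise(np.tile(sig, (500, 1)), 20.0, multi_b.n_avg, seed=rng)
    fs = np.array([
        fit_ivim_segmented(multi_b.b, noisy[i], n_avg=multi_b.n_avg).f
        for i in range(500)
    ])
    assert abs(np.median(fs) - 0.226) < 0.03


# ----------------------------------------------------------- fit_volume

def _toy_image(multi_b, truth_by_region, labels):
    data = np.zeros(labels.labels.shape + (len(multi_b),))
    for region, (f, d, d_star, mk) in truth_by_region.items():
        sig = forward_ivim_kurtosis(multi_b.b, 1000.0, f, d, d_star, mk)
        data[labels.mask(region), :] = sig
    return ImageSeries(data=data, protocol=multi_b)


def test_fit_volume_adc_on_toy_volume(multi_b):
    data = np.tile(
        forward_ivim_kurtosis(multi_b.b, 1000.0, 0.0, 2.0, 50.0, 0.0), (10, 1, 1, 1)
    )
    image = ImageSeries(data=data, protocol=multi_b)
    mask = np.ones((10, 1, 1), bool)
    maps = fit_volume(image, mask, "adc")
    assert np.isfinite(maps["adc"].data).sum() == 10
    assert maps["adc"].data[mask] == pytest.approx(np.full(10, 2.0), rel=1e-9)


def test_fit_volume_empty_mask_warns_and_returns_nan(multi_b):
    image = ImageSeries(data=np.ones((4, 4, 1, 13)), protocol=multi_b)
    with pytest.warns(UserWarning, match="empty mask"):
        maps = fit_volume(image, np.zeros((4, 4, 1), bool), "adc")
    assert np.all(np.isnan(maps["adc"].data))


def test_fit_volume_region_contrast_matches_truth_sign(multi_b):
    from renaldwi import PhantomGeometry, build_phantom
    from renaldwi.cmd import summarize_region

    labels = build_phantom(PhantomGeometry(nx=36, ny=36, outer_semiaxes=(14, 10)))
    truth = {"cortex": (0.0, 2.4, 60.0, 0.0), "medulla": (0.0, 1.6, 60.0, 0.0)}
    image = _toy_image(multi_b, truth, labels)
    maps = fit_volume(image, labels.kidney_mask, "adc")
    cort = summarize_region(maps["adc"], labels, "cortex")
    med = summarize_region(maps["adc"], labels, "medulla")
    assert cort.mean == pytest.approx(2.4, rel=1e-9)
    assert med.mean == pytest.approx(1.6, rel=1e-9)


def test_fit_volume_flagged_fraction_small_at_snr50(multi_b, rng):
    """On SNR-50 cortex-like voxels, fewer than 5% of IVIM fits hit a bound
    or fail to converge."""
    sig = _ivim_signal(multi_b.b, 1000.0, 0.226, 1.65, 73.0)
    noisy = add_rician_noise(np.tile(sig, (200, 1)), 20.0, multi_b.n_avg, seed=rng)
    image = ImageSeries(data=noisy.reshape(200, 1, 1, 13), protocol=multi_b)
    maps = fit_volume(image, np.ones((200, 1, 1), bool), "ivim")
    flagged = maps["ivim_f"].provenance["n_flagged"]
    assert flagged / 200 < 0.05


def test_fit_volume_mask_grid_mismatch(multi_b):
    image = ImageSeries(data=np.ones((4, 4, 1, 13)), protocol=multi_b)
    with pytest.raises(FitError, match="mask shape"):
        fit_volume(image, np.ones((5, 4, 1), bool), "adc")
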