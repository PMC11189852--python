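import warnings

import numpy as np
import pytest

from renaldwi import (
    DT2Mesh,
    DT2Spectrum,
    build_kernel,
    choose_boundaries,
    compartment_fractions,
    invert_spectrum,
    make_protocol,
)
from renaldwi.errors import GridMismatchError, ProtocolError, RenalDwiError
from renaldwi.spectrum import CompartmentPartition, default_lambda


def test_mesh_is_30x30_log_spaced_with_exact_endpoints(mesh):
    assert mesh.size == 900
    assert mesh.d[0] == 0.3 and mesh.d[-1] == 30.0
    assert mesh.t2[0] == 5.0 and mesh.t2[-1] == 200.0
    assert np.all(np.diff(mesh.d) > 0) and np.all(np.diff(mesh.t2) > 0)
    # geometric spacing: constant ratio
    assert np.allclose(np.diff(np.log(mesh.d)), np.log(mesh.d[1] / mesh.d[0]))


def test_kernel_shape_and_range(kernel):
    assert kernel.shape == (36, 900)
    assert np.all(kernel > 0) and np.all(kernel <= 1)


def test_kernel_b0_rows_independent_of_d(drcsi, mesh, kernel):
    row = kernel[drcsi.b == 0][0].reshape(mesh.shape)
    te = drcsi.te[drcsi.b == 0][0]
    assert np.allclose(row, np.exp(-te / mesh.t2)[None, :])


def test_kernel_rows_dominated_by_heavier_weighting(drcsi, kernel):
    """A point with both larger b and larger TE decays every mesh component
    at least as much."""
    i_light = int(np.argmin(drcsi.b + drcsi.te))
    i_heavy = int(np.argmax(drcsi.b + drcsi.te))
    assert np.all(kernel[i_heavy] <= kernel[i_light])


def test_single_te_protocol_rejected(multi_b, mesh):
    with pytest.raises(ProtocolError, match="distinct echo times"):
        build_kernel(multi_b, mesh)


def test_single_component_inversion_concentrates_mass(mesh, kernel):
    """A noiseless on-mesh component is recovered with >= 99% of the mass
    inside the 3x3 neighborhood of the generating mesh point."""
    j, k = mesh.nearest(1.0, 60.0)
    truth = np.zeros(mesh.shape)
    truth[j, k] = 1.0
    signal = 1000.0 * kernel @ truth.ravel()
    spec = invert_spectrum(signal, kernel, lambda_reg=1e-4, mesh=mesh)
    total = spec.total_mass
    window = spec.intensity[max(j - 1, 0): j + 2, max(k - 1, 0): k + 2].sum()
    assert window / total >= 0.99


def test_zero_signal_gives_zero_spectrum_with_warning(mesh, kernel):
    with pytest.warns(UserWarning, match="all-zero"):
        spec = invert_spectrum(np.zeros(36), kernel, 1e-4, mesh)
    assert spec.total_mass == 0.0


def test_inversion_nonnegative_and_deterministic(mesh, kernel, rng):
    signal = np.abs(rng.normal(100, 30, 36))
    a = invert_spectrum(signal, kernel, mesh=mesh)
    b = invert_spectrum(signal, kernel, mesh=mesh)
    assert np.all(a.intensity >= 0)
    assert np.array_equal(a.intensity, b.intensity)


def test_roundtrip_signal_error_below_0p1_percent(mesh, kernel, rng):
    """Representability round-trip: forward -> invert (lambda 1e-4) ->
    forward reproduces the signal to < 0.1% of S0 RMS."""
    truth = np.zeros(mesh.shape)
    for _ in range(4):
        j, k = rng.integers(0, 30, 2)
        truth[j, k] += rng.uniform(0.1, 1.0)
    truth /= truth.sum()
    s0 = 1000.0
    signal = s0 * kernel @ truth.ravel()
    spec = invert_spectrum(signal, kernel, lambda_reg=1e-4, mesh=mesh)
    refor = kernel @ spec.intensity.ravel()
    rms = np.sqrt(np.mean((refor - signal) ** 2))
    assert rms < 1e-3 * s0


def test_residual_nonincreasing_as_lambda_decreases(mesh, kernel):
    j, k = mesh.nearest(2.0, 80.0)
    truth = np.zeros(mesh.shape)
    truth[j, k] = 1.0
    signal = 500.0 * kernel @ truth.ravel()
    residuals = []
    for lam in (10.0, 1.0, 0.1, 1e-3):
        spec = invert_spectrum(signal, kernel, lam, mesh)
        residuals.append(np.linalg.norm(kernel @ spec.intensity.ravel() - signal))
    assert np.all(np.diff(residuals) <= 1e-9)


def test_boundaries_found_at_marginal_trough(mesh):
    """A spectrum with a clean T2 gap at ~38 ms puts the T2 boundary on the
    gridline nearest 38 ms."""
    intensity = np.zeros(mesh.shape)
    ja, ka = mesh.nearest(1.0, 20.0)
    jb, kb = mesh.nearest(1.5, 90.0)
    jc, kc = mesh.nearest(15.0, 70.0)
    intensity[ja, ka] = intensity[jb, kb] = intensity[jc, kc] = 1.0
    part = choose_boundaries(DT2Spectrum(intensity, mesh))
    expected_t2 = mesh.t2[np.argmin(np.abs(mesh.t2 - 38.0))]
    assert part.t2_boundary == pytest.approx(expected_t2)
    assert 6.0 <= part.d_boundary <= 9.0
    assert part.d_boundary < 15.0 and part.d_boundary > 1.5


def test_flat_spectrum_ties_break_to_window_midpoints(mesh):
    part = choose_boundaries(DT2Spectrum(np.ones(mesh.shape), mesh))
    in_t2_window = mesh.t2[(mesh.t2 >= 30) & (mesh.t2 <= 50)]
    in_d_window = mesh.d[(mesh.d >= 6) & (mesh.d <= 9)]
    assert part.t2_boundary == in_t2_window[np.argmin(np.abs(in_t2_window - 40.0))]
    assert part.d_boundary == in_d_window[np.argmin(np.abs(in_d_window - 7.5))]


def test_partition_masks_cover_mesh_exactly_once(mesh):
    part = CompartmentPartition(mesh=mesh, d_boundary=7.0, t2_boundary=40.0)
    masks = part.masks()
    total = sum(m.astype(int) for m in masks.values())
    assert np.all(total == 1)


def test_fractions_examples(mesh):
    part = CompartmentPartition(mesh=mesh, d_boundary=7.0, t2_boundary=40.0)
    masks = part.masks()
    # all mass at a single point inside B
    jb, kb = mesh.nearest(1.0, 100.0)
    assert masks["B"][jb, kb]
    one_point = np.zeros(mesh.shape)
    one_point[jb, kb] = 3.7
    fr = compartment_fractions(DT2Spectrum(one_point, mesh), part)
    assert (fr.v_a, fr.v_b, fr.v_c) == (0.0, 1.0, 0.0)
    # uniform spectrum: fractions proportional to mask sizes
    fr_u = compartment_fractions(DT2Spectrum(np.ones(mesh.shape), mesh), part)
    for comp, v in zip("ABC", (fr_u.v_a, fr_u.v_b, fr_u.v_c)):
        assert v == pytest.approx(masks[comp].sum() / 900, abs=1e-12)


def test_fractions_sum_to_one_for_random_spectra(mesh, rng):
    part = CompartmentPartition(mesh=mesh, d_boundary=7.0, t2_boundary=40.0)
    for _ in range(20):
        spec = DT2Spectrum(rng.uniform(0, 1, mesh.shape), mesh)
        fr = compartment_fractions(spec, part)
        assert abs(fr.v_a + fr.v_b + fr.v_c - 1.0) <= 1e-9


def test_fraction_recovery_degrades_with_noise(mesh, kernel):
    """Median absolute fraction error at SNR 30 is at least that at SNR 100
    (fixed-seed ensembles of ROI-mean inversions)."""
    from renaldwi.signal import rician_debias

    truth = np.zeros(mesh.shape)
    weights = {"A": 0.26, "B": 0.43, "C": 0.31}
    for comp, (d, t2) in {"A": (1.2, 26.0), "B": (1.5, 90.0), "C": (15.0, 70.0)}.items():
        j, k = mesh.nearest(d, t2)
        truth[j, k] = weights[comp]
    signal = 1000.0 * kernel @ truth.ravel()
    lam = default_lambda(kernel)

    def ensemble_error(sigma, seed):
        rng = np.random.default_rng(seed)
        errs = []
        for _ in range(6):
            g1 = rng.normal(0, sigma, (150, 36))
            g2 = rng.normal(0, sigma, (150, 36))
            roi = np.sqrt((signal[None, :] + g1) ** 2 + g2**2).mean(axis=0)
            spec = invert_spectrum(rician_debias(roi, sigma), kernel, lam, mesh)
            fr = compartment_fractions(spec, choose_boundaries(spec)).as_dict()
            errs.append(np.mean([abs(fr[c] - weights[c]) for c in "ABC"]))
        return np.median(errs)

    assert ensemble_error(1000 / 30, seed=101) >= ensemble_error(1000 / 100, seed=101)


def test_spectrum_zero_mass_errors(mesh):
    part = CompartmentPartition(mesh=mesh, d_boundary=7.0, t2_boundary=40.0)
    zero = DT2Spectrum(np.zeros(mesh.shape), mesh)
    with pytest.raises(RenalDwiError):
        compartment_fractions(zero, part)
    with pytest.raises(RenalDwiError):
        choose_boundaries(zero)


def test_dimension_mismatch_rejected(mesh, kernel):
    with pytest.raises(GridMismatchError):
        invert_spectrum(np.ones(35), kernel, 1e-4, mesh)
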