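import numpy as np
import pytest

from phagosim.free_energy import (UmbrellaWindow, autocorr_biexp_fit,
                                  autocorrelation, integrated_autocorr_time,
                                  kramers_escape_time, wham)


def _exact_window_samples(U, center, k, n, rng, grid=(-2.0, 2.0, 4001)):
    """Exact samples from exp(-(U(x) + 0.5 k (x-c)^2)) on a fine grid."""
    xs = np.linspace(*grid)
    w = np.exp(-(U(xs) + 0.5 * k * (xs - center) ** 2))
    w /= w.sum()
    jitter = 0.5 * (xs[1] - xs[0])
    return rng.choice(xs, size=n, p=w) + rng.uniform(-jitter, jitter, n)


def _ar1(tau, n, rng):
    a = np.exp(-1.0 / tau)
    x = np.zeros(n)
    e = rng.normal(size=n) * np.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + e[i]
    return x


def test_wham_single_unbiased_window(rng):
    # degenerate case: PMF = -ln(histogram) + const
    samples = rng.normal(0.0, 1.0, 20000)
    win = UmbrellaWindow(da_0=0.0, k=0.0, samples=samples, sweeps=0, seed=0)
    res = wham([win], n_bins=40, n_bootstrap=10, thin=False)
    sel = np.abs(res.centers) < 1.5
    expect = 0.5 * res.centers[sel] ** 2
    expect -= expect.min()
    assert np.sqrt(np.nanmean((res.pmf[sel] - expect) ** 2)) < 0.1


def test_wham_disconnected_windows(rng):
    w1 = UmbrellaWindow(0.0, 50.0,
                        rng.normal(0.0, 0.1, 4000), 0, 0)
    w2 = UmbrellaWindow(5.0, 50.0,
                        rng.normal(5.0, 0.1, 4000), 0, 1)
    res = wham([w1, w2], n_bins=100, n_bootstrap=0, thin=False)
    assert res.disconnected
    assert len(res.segments) >= 2


def test_wham_requires_windows():
    with pytest.raises(ValueError):
        wham([])


def test_autocorrelation_white_noise(rng):
    acf = autocorrelation(rng.normal(size=50000))
    assert acf[0] == pytest.approx(1.0)
    assert np.all(np.abs(acf[1:50]) < 0.05)
    assert integrated_autocorr_time(rng.normal(size=50000)) < 1.5


def test_biexp_recovery(rng):
    n = 200000
    s = np.sqrt(0.5) * _ar1(3.0, n, rng) + np.sqrt(0.5) * _ar1(25.0, n, rng)
    w, t1, t2, info = autocorr_biexp_fit(s)
    assert t2 >= t1
    assert w == pytest.approx(0.5, abs=0.1)
    assert t1 == pytest.approx(3.0, rel=0.25)
    assert t2 == pytest.approx(25.0, rel=0.25)
    assert not info["degenerate"]


def test_biexp_single_exponential_degenerate(rng):
    s = _ar1(8.0, 200000, rng)
    w, t1, t2, info = autocorr_biexp_fit(s)
    assert info["degenerate"]
    # the dominant recovered timescale is the true one
    dom = t2 if w < 0.5 else t1
    assert dom == pytest.approx(8.0, rel=0.3)


def test_kramers():
    assert kramers_escape_time(1.0, 0.0) == pytest.approx(2 * np.pi)
    assert kramers_escape_time(2.0, 1.0) > kramers_escape_time(2.0, 0.5)
    with pytest.raises(ValueError):
        kramers_escape_time(-1.0, 1.0)
    with pytest.raises(ValueError):
        kramers_escape_time(1.0, -1.0)


def test_umbrella_window_on_sphere(icosphere3):
    """Moderate bias at da_0 = 1 on a sphere: unimodal histogram centered
    near 1, no drift flag."""
    from phagosim.free_energy import run_umbrella_window

    w = run_umbrella_window(icosphere3, 1.0, k=2e5, n_sweeps=400,
                            sample_stride=2, equil_sweeps=150, seed=3)
    assert len(w.samples) == 200
    assert abs(w.samples.mean() - 1.0) < 0.01
    counts, _ = np.histogram(w.samples, 20)
    peak = np.argmax(counts)
    assert 0 < peak < 19  # interior mode
    # a center the sphere cannot reach against its constraints is flagged
    w2 = run_umbrella_window(icosphere3, 0.90, k=2e5, n_sweeps=200,
                             sample_stride=2, equil_sweeps=100, seed=4)
    assert w2.drift_flag
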