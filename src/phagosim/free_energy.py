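"""Umbrella sampling along the area difference, WHAM, and rate estimates.

The potential of mean force F(da) is reconstructed from overlapping
umbrella windows, each biased by 0.5*k*(da - da_0)^2 added to the membrane
energy (the stiff area-difference *constraint* is switched off during
umbrella runs so that only one restraint acts on the reaction coordinate).
WHAM is solved by direct self-consistent iteration of the standard
equations; samples are thinned by the integrated autocorrelation time and
uncertainties come from bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import EnergyModel
from .engine import MembraneState, _child_seeds
from .mesh import TriMesh

__all__ = [
    "UmbrellaWindow",
    "run_umbrella_window",
    "umbrella_scan",
    "wham",
    "WhamResult",
    "autocorrelation",
    "integrated_autocorr_time",
    "autocorr_biexp_fit",
    "barrier_to_kT",
    "kramers_escape_time",
]


@dataclass
class UmbrellaWindow:
    """Biased time series of the area difference in one umbrella window."""
    da_0: float
    k: float
    samples: np.ndarray
    sweeps: int
    seed: int
    drift_flag: bool = False      # mean further than 3 sigma from da_0
    meta: dict = field(default_factory=dict)

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(x) - self.da_0) ** 2


def run_umbrella_window(mesh: TriMesh, da_0: float, k: float = 2e5,
                        model: EnergyModel | None = None,
                        n_sweeps: int = 4000, sample_stride: int = 2,
                        equil_sweeps: int = 500, seed: int = 0,
                        T: float = 1.0) -> UmbrellaWindow:
    """Sample da under a harmonic bias centered at ``da_0``.

    Starts from a relaxed mesh near the window center (anneal or quench
    output), equilibrates, then records da every ``sample_stride`` sweeps.
    The hard area-difference constraint is off (K_da = 0); only the bias
    acts on da.
    """
    model = model or EnergyModel(kappa=20.0, K_A=1e6, K_V=1e6)
    m = replace(model, K_da=0.0, k_umb=float(k), da_umb=float(da_0))
    if m.A_ref is None or m.V_ref is None:
        from .energetics import shape_state

        st0 = shape_state(mesh)
        m = m.with_refs(m.A_ref or mesh.area(), m.V_ref or st0.volume)
    state = MembraneState(mesh, model=m)
    s1, s2 = _child_seeds(seed, 2)
    stats, _ = state.run(equil_sweeps, m, T=T, tune=True, seed=s1)
    _, obs = state.run(n_sweeps, m, T=T, seed=s2,
                       vertex_width=stats["vertex_width"],
                       sample_stride=sample_stride)
    da = obs[:, 5].copy()
    sigma = float(da.std()) or 1.0
    drift = abs(float(da.mean()) - da_0) > 3.0 * sigma
    return UmbrellaWindow(da_0=float(da_0), k=float(k), samples=da,
                          sweeps=n_sweeps, seed=seed, drift_flag=drift,
                          meta={"stride": sample_stride, "T": T,
                                "final_mesh": state.mesh()})


def umbrella_scan(mesh: TriMesh, centers, k: float = 5e4,
                  model: EnergyModel | None = None, n_sweeps: int = 1500,
                  sample_stride: int = 2, equil_sweeps: int = 500,
                  seed: int = 0, T: float = 1.0) -> list[UmbrellaWindow]:
    """Sequential umbrella windows along ``centers``.

    Each window is seeded from the final configuration of the previous
    one, so the membrane deforms gradually along the reaction coordinate
    instead of being dragged from the first anchor every time.
    """
    centers = [float(c) for c in centers]
    seeds = _child_seeds(seed, len(centers))
    windows = []
    cur = mesh
    for c, sd in zip(centers, seeds):
        w = run_umbrella_window(cur, c, k=k, model=model,
                                n_sweeps=n_sweeps,
                                sample_stride=sample_stride,
                                equil_sweeps=equil_sweeps, seed=sd, T=T)
        cur = w.meta.pop("final_mesh")
        windows.append(w)
    return windows


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, max_lag: int | None = None):
    """Normalized autocorrelation function via FFT."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 2 or not np.any(x):
        return np.ones(1)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    if max_lag is not None:
        acf = acf[:max_lag + 1]
    return acf


def integrated_autocorr_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time (sum to the first zero crossing)."""
    acf = autocorrelation(series)
    tau = 0.5
    for lag in range(1, len(acf)):
        if acf[lag] <= 0:
            break
        tau += acf[lag]
    return max(1.0, tau)


def autocorr_biexp_fit(series: np.ndarray, dt: float = 1.0,
                       max_lag: int | None = None):
    """Fit w*exp(-t/t1) + (1-w)*exp(-t/t2) to the autocorrelation.

    Returns ``(w, t1, t2, info)`` with ``t2 >= t1``; ``info['degenerate']``
    is True when a single exponential suffices (w ~ 0 or 1, or t1 ~ t2).
    """
    from scipy.optimize import curve_fit

    acf = autocorrelation(series, max_lag)
    # fit over lags down to acf ~ 0.01 (beyond that it is noise)
    good = np.nonzero(acf < 0.01)[0]
    stop = int(good[0]) if len(good) else len(acf)
    stop = max(stop, 8)
    t = np.arange(stop) * dt
    y = acf[:stop]

    def f(t, w, t1, t2):
        return w * np.exp(-t / t1) + (1 - w) * np.exp(-t / t2)

    tau0 = max(integrated_autocorr_time(series) * dt, dt)
    p0 = (0.5, 0.3 * tau0, 3.0 * tau0)
    popt, pcov = curve_fit(
        f, t, y, p0=p0,
        bounds=([0.0, dt * 1e-3, dt * 1e-3], [1.0, np.inf, np.inf]),
        maxfev=20000)
    w, t1, t2 = popt
    if t1 > t2:
        t1, t2 = t2, t1
        w = 1.0 - w
    degenerate = bool(w < 0.05 or w > 0.95 or abs(t2 - t1) < 0.05 * t2)
    perr = np.sqrt(np.diag(pcov))
    return float(w), float(t1), float(t2), {
        "degenerate": degenerate, "perr": perr, "n_lags": stop}


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

@dataclass
class WhamResult:
    centers: np.ndarray        # bin centers (da grid)
    pmf: np.ndarray            # F/k_B T, min-shifted; NaN in empty bins
    error: np.ndarray          # bootstrap standard error
    f_shifts: np.ndarray       # per-window free-energy shifts
    segments: list             # list of slice index pairs of connected parts
    n_iter: int
    meta: dict = field(default_factory=dict)

    @property
    def disconnected(self) -> bool:
        return len(self.segments) > 1


def _wham_solve(counts, n_eff, bias_mat, tol, max_iter, T):
    """Self-consistent WHAM iteration; returns (P_bins, f_windows, iters)."""
    n_win, n_bin = bias_mat.shape
    f = np.zeros(n_win)
    total = counts.sum(axis=0)
    expb = np.exp(-bias_mat / T)
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_eff[:, None] * np.exp(f)[:, None] * expb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        z = expb @ p
        f_new = np.where(z > 0, -np.log(z), f)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    s = p.sum()
    if s > 0:
        p = p / s
    return p, f, it


def wham(windows, n_bins: int = 200, tol: float = 1e-8,
         max_iter: int = 100000, n_bootstrap: int = 100,
         thin: bool = True, T: float = 1.0, seed: int = 0) -> WhamResult:
    """Potential of mean force from umbrella windows (up to a constant).

    Histograms the (autocorrelation-thinned) samples of every window on a
    common grid, iterates the WHAM equations until the window free-energy
    shifts move by less than ``tol``, and estimates errors by bootstrap
    over samples.  Non-overlapping groups of windows are reported as
    disconnected segments (bins between them stay NaN) rather than being
    silently joined.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one umbrella window")
    thinned = []
    for w in windows:
        x = np.asarray(w.samples, dtype=float)
        if thin and len(x) > 10:
            step = max(1, int(np.ceil(integrated_autocorr_time(x))))
            x = x[::step]
        thinned.append(x)
    allx = np.concatenate(thinned)
    lo, hi = float(allx.min()), float(allx.max())
    if hi <= lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bias_mat = np.stack([w.bias(centers) for w in windows])

    def solve(samples):
        counts = np.stack([np.histogram(x, edges)[0] for x in samples])
        n_eff = counts.sum(axis=1).astype(float)
        p, f, it = _wham_solve(counts, n_eff, bias_mat, tol, max_iter, T)
        with np.errstate(divide="ignore"):
            pmf = np.where(p > 0, -T * np.log(p), np.nan)
        return pmf, f, it, counts

    pmf, f, n_iter, counts = solve(thinned)
    if np.any(np.isfinite(pmf)):
        pmf = pmf - np.nanmin(pmf)
    # connected segments = maximal runs of occupied bins
    occupied = counts.sum(axis=0) > 0
    segments = []
    start = None
    for i, o in enumerate(occupied):
        if o and start is None:
            start = i
        elif not o and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(occupied)))

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        res = [x[rng.integers(0, len(x), len(x))] for x in thinned]
        b_pmf, _, _, _ = solve(res)
        if np.any(np.isfinite(b_pmf)):
            b_pmf = b_pmf - np.nanmin(b_pmf)
        boots.append(b_pmf)
    err = (np.nanstd(np.stack(boots), axis=0) if boots
           else np.full_like(pmf, np.nan))
    return WhamResult(centers=centers, pmf=pmf, error=err, f_shifts=f,
                      segments=segments, n_iter=n_iter,
                      meta={"n_bins": n_bins, "tol": tol,
                            "n_bootstrap": n_bootstrap, "thin": thin})


def barrier_to_kT(height_8pik: float, kappa: float) -> float:
    """Convert a barrier from 8*pi*kappa units to k_B T (kappa in k_B T)."""
    return float(height_8pik) * 8.0 * np.pi * float(kappa)


def kramers_escape_time(tau: float, barrier: float) -> float:
    """Kramers estimate 2*pi*tau*exp(H) of the escape time from a
    metastable state over a barrier of H k_B T (tau in any time unit)."""
    if tau <= 0:
        raise ValueError("relaxation time must be positive")
    if barrier < 0:
        raise ValueError("barrier must be non-negative")
    return 2.0 * np.pi * tau * float(np.exp(barrier))
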