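"""Normalized photon autocorrelation and the 1-D flow+diffusion fit.

The correlator works on binned counts with the symmetric normalization
``g(tau) = <n(t) n(t+tau)> / (<n(t)> <n(t+tau)>)`` so an uncorrelated
stream gives ``g ~ 1``.  Lags are either a user grid (direct estimator) or
the standard multi-tau pseudologarithmic ladder with 16 lags per octave and
pairwise rebinning between octaves.

The model fitted to the curve is

    g(tau) = a0 + a1 / (1 + a3 tau) * exp(-a2 tau**2 / (1 + a3 tau))

with ``a1 = F**2/(F+B)**2`` the amplitude, ``a2 = (v/omega0)**2`` the
squared reciprocal flow time constant and ``a3 = 4 D / omega0**2`` the
reciprocal diffusion time constant.  The fitted transit constant
``sigma_t = omega0/(2 v) = 1/(2 sqrt(a2))`` calibrates the translation
speed via :func:`speed_from_transit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ACFModel",
    "AcfFitError",
    "acf_model_g",
    "compute_acf",
    "fit_acf",
    "speed_from_transit",
]

PARAM_NAMES = ("a0", "a1", "a2", "a3")


class AcfFitError(RuntimeError):
    """Raised when the nonlinear ACF fit fails to converge."""


@dataclass
class ACFModel:
    """Normalized autocorrelation curve and (optionally) fit parameters.

    ``level`` and ``k`` record, for each lag, the multi-tau octave and the
    integer lag in rebinned samples (both -1 for direct-grid lags), which
    makes the estimator auditable against a brute-force correlator on the
    identically rebinned stream.
    """

    lags: np.ndarray
    g: np.ndarray
    bin_width: float
    level: np.ndarray | None = None
    k: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)


def acf_model_g(tau, a0, a1, a2, a3):
    """Model curve ``a0 + a1/(1+a3 tau) * exp(-a2 tau**2/(1+a3 tau))``."""
    tau = np.asarray(tau, dtype=float)
    den = 1.0 + a3 * tau
    return a0 + a1 / den * np.exp(-a2 * tau**2 / den)


def _direct_g(counts: np.ndarray, k: int) -> float:
    """Symmetrically normalized correlation at integer lag ``k``."""
    if k == 0:
        m = counts.mean()
        return float(np.mean(counts * counts) / (m * m))
    left = counts[:-k]
    right = counts[k:]
    return float(np.mean(left * right) / (left.mean() * right.mean()))


def _rebin2(counts: np.ndarray) -> np.ndarray:
    n = (len(counts) // 2) * 2
    return counts[:n].reshape(-1, 2).sum(axis=1)


def compute_acf(
    photons,
    lag_grid: np.ndarray | None = None,
    *,
    max_lag: float | None = None,
    n_per_octave: int = 16,
    rebin: int = 1,
    include_zero_lag: bool = False,
) -> ACFModel:
    """Normalized ACF of a photon stream (or a raw count array).

    Parameters
    ----------
    photons
        A :class:`~smrkit.simulate.PhotonData` or a 1-D count array (in
        which case ``rebin`` refers to its native binning and the bin width
        is taken as 10 us unless the array carries one).
    lag_grid
        Optional lag times (s); when given, the direct estimator is
        evaluated at each (rounded to the count grid) instead of multi-tau.
    max_lag
        Largest lag for the multi-tau ladder; defaults to a quarter of the
        record and must stay below half of it.
    rebin
        Integer pre-binning factor applied to the counts before
        correlating.
    """
    counts, bw = _coerce_counts(photons)
    if rebin > 1:
        n = (len(counts) // rebin) * rebin
        counts = counts[:n].reshape(-1, rebin).sum(axis=1)
        bw *= rebin
    counts = counts.astype(float)
    if counts.sum() < 2:
        raise ValueError("need at least two photons to correlate")
    record = len(counts) * bw
    if max_lag is None:
        max_lag = record / 4.0
    if max_lag >= record / 2.0:
        raise ValueError("max_lag must be below half the record length")

    if lag_grid is not None:
        ks = np.asarray(np.rint(np.asarray(lag_grid, float) / bw), dtype=int)
        if np.any(ks < 0) or np.any(ks >= len(counts) // 2):
            raise ValueError("lag_grid entries must lie in [0, record/2)")
        g = np.array([_direct_g(counts, int(k)) for k in ks])
        return ACFModel(
            lags=ks * bw,
            g=g,
            bin_width=bw,
            level=np.full(len(ks), -1),
            k=np.full(len(ks), -1),
        )

    m = n_per_octave
    lags, g, levels, kk = [], [], [], []
    cur = counts
    bw_l = bw
    level = 0
    if include_zero_lag:
        lags.append(0.0)
        g.append(_direct_g(cur, 0))
        levels.append(0)
        kk.append(0)
    done = False
    while not done:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            tau = k * bw_l
            if tau > max_lag or k >= len(cur) // 2:
                done = True
                break
            lags.append(tau)
            g.append(_direct_g(cur, k))
            levels.append(level)
            kk.append(k)
        cur = _rebin2(cur)
        bw_l *= 2.0
        level += 1
        if len(cur) < 2 * m:
            done = True
    return ACFModel(
        lags=np.asarray(lags),
        g=np.asarray(g),
        bin_width=bw,
        level=np.asarray(levels),
        k=np.asarray(kk),
    )


def _coerce_counts(photons) -> tuple[np.ndarray, float]:
    if hasattr(photons, "bin_counts"):
        counts = np.asarray(photons.bin_counts)
        if counts.size == 0:
            raise ValueError("empty photon stream")
        return counts, float(photons.bin_width)
    counts = np.asarray(photons)
    if counts.size == 0:
        raise ValueError("empty count stream")
    return counts, 1.0e-5


def fit_acf(
    curve: ACFModel,
    fix: dict | None = None,
    p0: dict | None = None,
    max_fit_lag: float | None = None,
) -> ACFModel:
    """Least-squares fit of the flow+diffusion model to an ACF curve.

    ``fix`` pins parameters (e.g. ``{"a3": 0.0}`` for an immobilized bead);
    ``max_fit_lag`` restricts the fitted window so that recycle-period
    echoes beyond the first decay are excluded.  Returns a copy of the
    curve with ``params`` and asymptotic ``stderr`` filled in.

    Raises
    ------
    AcfFitError
        If the optimizer fails to converge; the message carries the
        optimizer diagnostics.
    """
    fix = dict(fix or {})
    for name in fix:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    sel = np.ones(len(curve.lags), dtype=bool)
    if max_fit_lag is not None:
        sel &= curve.lags <= max_fit_lag
    tau = np.asarray(curve.lags, float)[sel]
    y = np.asarray(curve.g, float)[sel]
    if len(tau) < 8:
        raise ValueError("need at least 8 lag points spanning the decay")

    guess = _initial_guess(tau, y)
    guess.update(p0 or {})
    free = [n for n in PARAM_NAMES if n not in fix]
    if not free:
        raise ValueError("at least one parameter must be free")
    lower = {"a0": -np.inf, "a1": 0.0, "a2": 0.0, "a3": 0.0}

    def model(t, *theta):
        kw = dict(zip(free, theta))
        kw.update(fix)
        return acf_model_g(t, kw["a0"], kw["a1"], kw["a2"], kw["a3"])

    x0 = [max(guess[n], lower[n]) if np.isfinite(lower[n]) else guess[n] for n in free]
    bounds = ([lower[n] for n in free], [np.inf] * len(free))
    try:
        popt, pcov = curve_fit(model, tau, y, p0=x0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # non-convergence
        raise AcfFitError(
            f"ACF fit did not converge (free={free}, p0={x0}): {exc}"
        ) from exc
    params = dict(zip(free, (float(v) for v in popt)))
    params.update({k: float(v) for k, v in fix.items()})
    perr = np.sqrt(np.abs(np.diag(pcov)))
    stderr = dict(zip(free, (float(v) for v in perr)))
    stderr.update({k: 0.0 for k in fix})
    return ACFModel(
        lags=curve.lags,
        g=curve.g,
        bin_width=curve.bin_width,
        level=curve.level,
        k=curve.k,
        params=params,
        stderr=stderr,
    )


def _initial_guess(tau: np.ndarray, y: np.ndarray) -> dict:
    n_tail = max(1, len(y) // 10)
    a0 = float(np.median(y[-n_tail:]))
    a1 = max(float(np.max(y) - a0), 1e-12)
    half = a0 + 0.5 * a1
    below = np.nonzero(y <= half)[0]
    tau_half = float(tau[below[0]]) if len(below) and tau[below[0]] > 0 else float(
        tau[len(tau) // 2]
    )
    a2 = np.log(2.0) / tau_half**2
    return {"a0": a0, "a1": a1, "a2": a2, "a3": 0.0}


def speed_from_transit(
    sigma_t: float | None = None,
    omega0: float = 1.0e-6,
    a2: float | None = None,
) -> float:
    """Translation speed from the fitted transit constant.

    Either ``v = omega0 / (2 sigma_t)`` from the transit width
    ``sigma_t = omega0/(2v)``, or equivalently ``v = omega0 * sqrt(a2)``
    from the fitted flow parameter.
    """
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    if (sigma_t is None) == (a2 is None):
        raise ValueError("give exactly one of sigma_t or a2")
    if sigma_t is not None:
        if sigma_t <= 0:
            raise ValueError("sigma_t must be positive")
        return omega0 / (2.0 * sigma_t)
    if a2 < 0:
        raise ValueError("a2 must be non-negative")
    return omega0 * float(np.sqrt(a2))
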