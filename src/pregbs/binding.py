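"""One-site saturation binding: simulation, least-squares fit, bootstrap CI.

Fluorescence polarization titrations (trace-labeled DNA probe, increasing
protein) are modeled with the simple hyperbola

    F(c) = f0 + (fmax - f0) * c / (Kd + c)

where c is the total protein concentration in nM.  Ligand depletion is
ignored by default (probe at ~10 nM trace concentration); an optional
quadratic tight-binding form is available for cases where Kd approaches
the probe concentration.  95% confidence intervals come from a seeded
nonparametric bootstrap over titration points (percentile method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: The titration design used in the assays: 1 nM to 50 uM, log-spaced.
DEFAULT_CONCENTRATIONS_NM = tuple(np.geomspace(1.0, 50_000.0, 12))


class DegenerateFitError(RuntimeError):
    """The titration carries no signal variation; Kd is unidentifiable."""


@dataclass(frozen=True)
class BindingCurve:
    """A concentration–signal titration, possibly with replicates."""

    concentrations: np.ndarray  # nM, > 0
    signals: np.ndarray         # polarization, arbitrary units
    replicates: np.ndarray      # replicate id per point

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        r = np.asarray(self.replicates)
        if not (c.shape == s.shape == r.shape):
            raise ValueError("concentrations, signals, replicates must align")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        for rep in np.unique(r):
            cc = c[r == rep]
            if np.any(np.diff(cc) <= 0):
                raise ValueError(f"concentrations not strictly increasing in replicate {rep}")
        if len(np.unique(c)) < 5:
            raise ValueError("need at least 5 distinct concentrations to fit")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "replicates", r)


@dataclass(frozen=True)
class BindingFitResult:
    kd: float                    # nM
    kd_ci: tuple[float, float]   # 95% bootstrap percentile interval, nM
    f0: float
    fmax: float
    converged: bool

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if not self.kd_ci[0] <= self.kd <= self.kd_ci[1]:
            raise ValueError("Kd must lie inside its confidence interval")


def one_site_model(c, kd: float, f0: float, fmax: float):
    """Hyperbolic one-site binding signal at concentration(s) ``c`` (nM)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    c = np.asarray(c, dtype=float)
    out = f0 + (fmax - f0) * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def quadratic_model(c, kd: float, f0: float, fmax: float, probe_nm: float = 10.0):
    """Tight-binding (ligand depletion) form with fixed probe concentration."""
    c = np.asarray(c, dtype=float)
    s = kd + c + probe_nm
    bound = (s - np.sqrt(s * s - 4.0 * c * probe_nm)) / (2.0 * probe_nm)
    out = f0 + (fmax - f0) * bound
    return float(out) if out.ndim == 0 else out


_KD_BOUNDS = (1e-6, 1e9)


def _fit_once(c: np.ndarray, s: np.ndarray, quadratic: bool) -> tuple[float, float, float, bool]:
    f0_guess, fmax_guess = float(s[np.argmin(c)]), float(s[np.argmax(c)])
    half = f0_guess + 0.5 * (fmax_guess - f0_guess)
    # concentration nearest half-saturation as the Kd seed
    kd_guess = float(c[np.argmin(np.abs(s - half))])
    kd_guess = min(max(kd_guess, _KD_BOUNDS[0] * 10), _KD_BOUNDS[1] / 10)
    model = quadratic_model if quadratic else one_site_model
    lo_sig, hi_sig = float(np.min(s)), float(np.max(s))
    span = hi_sig - lo_sig
    bounds = (
        [_KD_BOUNDS[0], lo_sig - 10 * span - 1.0, lo_sig - 10 * span - 1.0],
        [_KD_BOUNDS[1], hi_sig + 10 * span + 1.0, hi_sig + 10 * span + 1.0],
    )
    popt, _ = curve_fit(
        model, c, s, p0=[kd_guess, f0_guess, fmax_guess], bounds=bounds, maxfev=20_000
    )
    kd, f0, fmax = (float(v) for v in popt)
    at_bounds = any(
        np.isclose(v, b, rtol=1e-6) for v, b in zip(popt, bounds[0])
    ) or any(np.isclose(v, b, rtol=1e-6) for v, b in zip(popt, bounds[1]))
    return kd, f0, fmax, not at_bounds


def fit_one_site(
    curve: BindingCurve,
    n_boot: int = 1000,
    seed: int = 0,
    quadratic: bool = False,
) -> BindingFitResult:
    """Least-squares one-site fit with a percentile bootstrap 95% CI.

    The bootstrap resamples titration points with replacement (``n_boot``
    refits, seeded); set ``n_boot=0`` to skip the CI (it is then the point
    estimate on both ends).  Raises :class:`DegenerateFitError` when the
    signal is flat across concentrations.
    """
    c, s = curve.concentrations, curve.signals
    if np.ptp(s) == 0:
        raise DegenerateFitError("flat signal: no binding transition to fit")
    kd, f0, fmax, converged = _fit_once(c, s, quadratic)

    if n_boot <= 0:
        return BindingFitResult(kd, (kd, kd), f0, fmax, converged)

    rng = np.random.default_rng(seed)
    n = len(c)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cb, sb = c[idx], s[idx]
        if np.ptp(sb) == 0 or len(np.unique(cb)) < 3:
            continue
        try:
            kd_b, *_ = _fit_once(cb, sb, quadratic)
        except RuntimeError:
            continue
        draws.append(kd_b)
    if len(draws) < max(10, n_boot // 10):
        return BindingFitResult(kd, (kd, kd), f0, fmax, False)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo, hi = min(float(lo), kd), max(float(hi), kd)
    return BindingFitResult(kd, (lo, hi), f0, fmax, converged)


def simulate_curve(
    kd: float,
    f0: float,
    fmax: float,
    concentrations=DEFAULT_CONCENTRATIONS_NM,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> BindingCurve:
    """Generate a titration from the one-site model plus i.i.d. Gaussian noise."""
    c1 = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    cs, ss, rs = [], [], []
    for rep in range(n_replicates):
        signal = one_site_model(c1, kd, f0, fmax)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=c1.shape)
        cs.append(c1)
        ss.append(signal)
        rs.append(np.full(c1.shape, rep, dtype=int))
    return BindingCurve(np.concatenate(cs), np.concatenate(ss), np.concatenate(rs))
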