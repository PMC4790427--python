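"""Flux estimation: weighted nonlinear regression, Monte-Carlo uncertainty,
distribution summaries, flux correlations and sensitivity scans.

The fit minimizes sum_points [(model - data)/sd]^2 over the seven free
fluxes with nonnegativity (and an upper physical bound) enforced by a
trust-region-reflective least-squares solver; each residual is weighted by
1/sd, i.e. the square root of the inverse variance.  Model variants select
the fitted curve set: 6 positional totals, the full 17-curve bonded set, or
the 11 individual multiplets alone.

Monte-Carlo uncertainty follows the parametric-bootstrap procedure: noise
with the data's variance is added to the best-fit model curves, each
replicate is refitted, and the spread, gamma-density summaries (with FWHM)
and the Pearson correlation matrix of the replicate estimates quantify
precision and parameter interdependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cumomer import CumomerSystem, build_rhs, enumerate_bonded_cumomers, integrate
from .multiplets import curves_from_trajectories, variant_curves
from .network import FREE_FLUXES, FluxSet, Network, build_default_network
from .synth import SyntheticDataset, input_function

__all__ = [
    "FitResult",
    "MCResult",
    "ScanResult",
    "MonteCarloError",
    "DEFAULT_BOUNDS",
    "fit",
    "monte_carlo",
    "summarize_distribution",
    "correlation_matrix",
    "sensitivity_scan",
    "DEFAULT_SCAN_GRIDS",
]


class MonteCarloError(RuntimeError):
    """Too many Monte-Carlo replicates failed to converge."""


#: optimizer bounds on every free flux, µmol/g/min
DEFAULT_BOUNDS = (0.0, 5.0)

#: neutral starting point when no init is given
DEFAULT_INIT = FluxSet(vpdh_n=0.5, vg=0.2, vpc=0.1, vx=0.5,
                       vnt=0.2, vdil=0.2, vout=0.2)

#: constrained-value grids of the sensitivity analysis, µmol/g/min
DEFAULT_SCAN_GRIDS = {"vnt": (0.07, 0.10, 0.20), "vdil": (0.20, 0.30, 0.60)}

#: curves stored by the sensitivity scan: GluC4/GlnC4 totals and multiplets
SCAN_CURVES = tuple((met, 4, pat) for met in ("glu", "gln")
                    for pat in ("total", "S", "D43", "D45", "Q"))


@dataclass(frozen=True)
class FitResult:
    """Point estimates with convergence diagnostics."""

    estimates: FluxSet
    residual: float  # weighted SSE at the optimum
    n_curves: int
    variant: str
    success: bool
    message: str
    nfev: int
    init: FluxSet
    fixed: Mapping[str, float] | None = None


@dataclass(frozen=True)
class MCResult:
    """Monte-Carlo flux samples and their summaries."""

    samples: pd.DataFrame  # n_mc x 7, columns = free flux names
    base: FitResult
    mean: pd.Series
    sd: pd.Series
    gamma_params: Mapping[str, tuple[float, float]] | None  # (shape, scale)
    fwhm: Mapping[str, float] | None
    correlation: pd.DataFrame | None  # None below 50 usable replicates
    n_failed: int

    @property
    def n_mc(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ScanResult:
    """One constrained flux scanned over a grid, the rest refitted."""

    flux_name: str
    grid: tuple[float, ...]
    fits: tuple[FitResult, ...]
    curves: tuple[Mapping[tuple, np.ndarray], ...]  # SCAN_CURVES per grid point
    converged: tuple[bool, ...]


class _Objective:
    """Weighted-residual evaluator for one dataset/variant pair.

    Precompiles the cumomer system (order 1 for the positional variant,
    order 3 otherwise) and caches the data and weight matrices.
    """

    def __init__(self, dataset: SyntheticDataset, variant: str,
                 network: Network | None = None, rtol: float = 1e-6):
        self.net = network or build_default_network()
        self.variant = variant
        self.keys = variant_curves(variant)
        missing = [k for k in self.keys if k not in dataset.keys()]
        if missing:
            raise ValueError(f"dataset lacks curves required by variant "
                             f"{variant!r}: {missing}")
        order = 1 if variant == "positional" else 3
        self.sys = build_rhs(self.net, enumerate_bonded_cumomers(self.net, order))
        self.t_grid = dataset.times
        self.input_fn = input_function(dataset.spec)
        self.nat = dataset.spec.natural_abundance
        self.rtol = rtol
        self.data = np.stack([dataset.curve(*k).values for k in self.keys])
        self.sd = np.stack([dataset.curve(*k).sd for k in self.keys])

    def model_matrix(self, f: FluxSet) -> np.ndarray:
        traj = integrate(self.sys, f, self.input_fn, self.t_grid,
                         rtol=self.rtol, atol=self.rtol * 1e-2,
                         natural_abundance=self.nat)
        curves = curves_from_trajectories(traj, self.net, self.keys, tol=1e-4)
        return np.stack([curves[k] for k in self.keys])

    def residuals(self, f: FluxSet) -> np.ndarray:
        return ((self.model_matrix(f) - self.data) / self.sd).ravel()


def _fluxset_from(free_names: Sequence[str], x: np.ndarray,
                  fixed: Mapping[str, float]) -> FluxSet:
    values = dict(fixed)
    values.update(dict(zip(free_names, x)))
    return FluxSet(**{name: values[name] for name in FREE_FLUXES})


def fit(
    dataset: SyntheticDataset,
    variant: str | None = None,
    init: FluxSet | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    network: Network | None = None,
    fixed: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    objective: "_Objective | None" = None,
    ftol: float = 1e-8,
    max_nfev: int = 400,
) -> FitResult:
    """Weighted least-squares fit of a model variant to labeling curves.

    ``fixed`` pins named fluxes (used by the sensitivity scan); the remaining
    free fluxes are optimized within ``bounds``.  Non-convergence is flagged
    on the result, not raised.
    """
    variant = variant or dataset.variant
    init = init or DEFAULT_INIT
    fixed = dict(fixed or {})
    obj = objective or _Objective(dataset, variant, network, rtol)
    free_names = [n for n in FREE_FLUXES if n not in fixed]
    lo, hi = bounds
    x0 = np.clip([getattr(init, n) for n in free_names], lo, hi)
    for name, value in fixed.items():
        if not lo <= value <= hi:
            raise ValueError(f"fixed flux {name}={value} outside bounds {bounds}")

    def fun(x: np.ndarray) -> np.ndarray:
        return obj.residuals(_fluxset_from(free_names, x, fixed))

    # finite-difference steps must stay well above the ODE solver noise floor
    res = optimize.least_squares(
        fun, x0, bounds=(lo, hi), method="trf", diff_step=1e-3,
        ftol=ftol, xtol=ftol, gtol=ftol, max_nfev=max_nfev)
    estimates = _fluxset_from(free_names, res.x, fixed)
    return FitResult(
        estimates=estimates,
        residual=float(2 * res.cost),
        n_curves=len(obj.keys),
        variant=variant,
        success=bool(res.success),
        message=str(res.message),
        nfev=int(res.nfev),
        init=init,
        fixed=fixed or None,
    )


def monte_carlo(
    dataset: SyntheticDataset,
    variant: str | None = None,
    n_mc: int = 500,
    seed: int = 0,
    base: FitResult | None = None,
    network: Network | None = None,
    rtol: float = 1e-6,
    max_failure_fraction: float = 0.1,
    ftol: float = 1e-8,
) -> MCResult:
    """Parametric-bootstrap uncertainty of the fitted fluxes.

    Artificial datasets are generated by adding Gaussian noise with the
    data's per-point SD to the best-fit model curves; each is refitted from
    the base estimates.  Errors out if more than ``max_failure_fraction`` of
    replicates fail to converge.
    """
    variant = variant or dataset.variant
    obj = _Objective(dataset, variant, network, rtol)
    if base is None:
        base = fit(dataset, variant, objective=obj, ftol=ftol)
    model = obj.model_matrix(base.estimates)
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    for _ in range(n_mc):
        noisy = model + rng.normal(0.0, 1.0, size=model.shape) * obj.sd
        replicate = dataset.with_values(
            {k: noisy[i] for i, k in enumerate(obj.keys)})
        rep_obj = _replace_data(obj, replicate)
        r = fit(replicate, variant, init=base.estimates, objective=rep_obj, ftol=ftol)
        if not r.success:
            n_failed += 1
            continue
        rows.append(r.estimates.free_values())
    if n_failed > max_failure_fraction * n_mc:
        raise MonteCarloError(
            f"{n_failed}/{n_mc} Monte-Carlo replicates failed to converge")
    samples = pd.DataFrame(rows, columns=list(FREE_FLUXES))
    mean, sd = samples.mean(), samples.std(ddof=1)
    gamma_params = fwhm = None
    if len(samples) >= 50:
        gamma_params, fwhm = {}, {}
        for name in FREE_FLUXES:
            summ = summarize_distribution(samples[name].to_numpy())
            gamma_params[name] = (summ["shape"], summ["scale"])
            fwhm[name] = summ["fwhm"]
    corr = correlation_matrix(samples) if len(samples) >= 50 else None
    return MCResult(samples=samples, base=base, mean=mean, sd=sd,
                    gamma_params=gamma_params, fwhm=fwhm,
                    correlation=corr, n_failed=n_failed)


def _replace_data(obj: _Objective, dataset: SyntheticDataset) -> _Objective:
    """Clone an objective with new data values (same compiled system)."""
    new = _Objective.__new__(_Objective)
    new.__dict__.update(obj.__dict__)
    new.data = np.stack([dataset.curve(*k).values for k in obj.keys])
    return new


def summarize_distribution(samples: np.ndarray) -> dict[str, float]:
    """Maximum-likelihood gamma summary of positive flux samples.

    Returns shape k, scale theta, sample mean/sd and the FWHM of the fitted
    density, located by bisection on the half-maximum crossings around the
    mode (requires k > 1, i.e. an interior mode).
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 50:
        raise ValueError("need at least 50 samples for a distribution summary")
    if np.any(samples <= 0):
        raise ValueError("gamma summary requires strictly positive samples")
    if np.ptp(samples) == 0:
        raise ValueError("degenerate (constant) samples")
    shape, _, scale = stats.gamma.fit(samples, floc=0)
    if shape <= 1:
        raise ValueError("fitted gamma has no interior mode; FWHM undefined")
    mode = (shape - 1) * scale
    pdf = lambda x: stats.gamma.pdf(x, shape, scale=scale)
    half = pdf(mode) / 2
    left = optimize.brentq(lambda x: pdf(x) - half, mode * 1e-12, mode)
    upper = mode * 2
    while pdf(upper) > half:
        upper *= 2
    right = optimize.brentq(lambda x: pdf(x) - half, mode, upper)
    return {
        "shape": float(shape),
        "scale": float(scale),
        "mean": float(samples.mean()),
        "sd": float(samples.std(ddof=1)),
        "fwhm": float(right - left),
    }


def correlation_matrix(samples: "pd.DataFrame | np.ndarray") -> pd.DataFrame:
    """Pearson correlations between Monte-Carlo flux samples."""
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(np.asarray(samples), columns=list(FREE_FLUXES))
    if len(samples) < 50:
        raise ValueError("need at least 50 samples for a correlation matrix")
    values = samples.to_numpy(dtype=float)
    if np.any(values.std(axis=0) == 0):
        bad = [c for c, s in zip(samples.columns, values.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance flux samples: {bad}")
    corr = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(corr, index=samples.columns, columns=samples.columns)


def sensitivity_scan(
    dataset: SyntheticDataset,
    variant: str | None = None,
    flux_name: str = "vnt",
    grid: Sequence[float] | None = None,
    network: Network | None = None,
    init: FluxSet | None = None,
    rtol: float = 1e-6,
    ftol: float = 1e-8,
) -> ScanResult:
    """Constrain one flux to each grid value and refit the remaining six.

    For every grid point the refitted model's GluC4 and GlnC4 total and
    multiplet curves are stored (simulated from the order-3 system even for
    the positional variant, to expose the multiplet sensitivity that the
    positional cost function does not see).  Non-convergence at a grid point
    is flagged per point.
    """
    variant = variant or dataset.variant
    if flux_name not in FREE_FLUXES:
        raise ValueError(f"unknown free flux {flux_name!r}")
    if grid is None:
        if flux_name not in DEFAULT_SCAN_GRIDS:
            raise ValueError(f"no default grid for {flux_name!r}; pass one")
        grid = DEFAULT_SCAN_GRIDS[flux_name]
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid values must be strictly increasing")

    obj = _Objective(dataset, variant, network, rtol)
    net = obj.net
    full_sys = (obj.sys if obj.sys.max_order == 3
                else build_rhs(net, enumerate_bonded_cumomers(net, 3)))
    fits, curve_sets, converged = [], [], []
    warm = init or DEFAULT_INIT
    for value in grid:
        r = fit(dataset, variant, init=warm, fixed={flux_name: value},
                objective=obj, ftol=ftol)
        fits.append(r)
        converged.append(r.success)
        if r.success:
            warm = r.estimates
        traj = integrate(full_sys, r.estimates, obj.input_fn, obj.t_grid,
                         rtol=rtol, atol=rtol * 1e-2, natural_abundance=obj.nat)
        curve_sets.append(curves_from_trajectories(traj, net, SCAN_CURVES, tol=1e-4))
    return ScanResult(flux_name, grid, tuple(fits), tuple(curve_sets),
                      tuple(converged))
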