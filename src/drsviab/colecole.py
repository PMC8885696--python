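"""Double Cole-Cole dielectric relaxation model: forward evaluation and fitting.

The model

    eps*(w) = eps_inf + d_eps1 / (1 + (j w tau1)^(1-alpha1))
                      + d_eps2 / (1 + (j w tau2)^(1-alpha2))

describes two dispersion processes (here the slow delta-dispersion of bound
water/proteins and the fast gamma-dispersion of bulk water).  ``ColeColeModel``
follows the Model/Results convention: build the model from a spectrum, call
``fit()``, and read estimates, goodness of fit and a ``summary()`` table off
the returned ``ColeColeResults``.

Fitting minimises the unweighted stacked residual over [eps'; eps''] with a
bounded trust-region least-squares solver, relaxation times parameterised in
log space, and a multi-start strategy (one data-driven initialisation plus
seeded jitters).  Dispersions are relabelled after fitting so tau1 > tau2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import FrequencyGrid, PermittivitySpectrum, SpectrumError

__all__ = [
    "ColeColeParams",
    "ColeColeModel",
    "ColeColeResults",
    "FitResult",
    "evaluate_model",
    "fit_model",
    "goodness_of_fit",
    "r_squared_stacked",
    "compare_dispersion_orders",
    "DispersionComparison",
    "PARAM_BOUNDS",
]

#: Default high-frequency permittivity and broadening exponents used when a
#: parameter set is anchored on the printed relaxation strengths/times alone.
DEFAULT_EPS_INF = 7.0
DEFAULT_ALPHA1 = 0.10
DEFAULT_ALPHA2 = 0.02

#: Box bounds for fitting: eps_inf, d_eps (per dispersion), tau (s), alpha.
PARAM_BOUNDS = {
    "eps_inf": (1.0, 20.0),
    "d_eps": (1e-6, 200.0),
    "tau": (0.05e-12, 50e-9),
    "alpha": (0.0, 0.5),
}

#: Relative improvement in R^2 below which an extra dispersion is flagged
#: as a minimal improvement.
MIN_R2_IMPROVEMENT = 1e-3


@dataclass(frozen=True)
class ColeColeParams:
    """Parameters of a double Cole-Cole dispersion (tau in seconds).

    Convention: dispersion 1 is the slower process, tau1 > tau2.
    """

    eps_inf: float
    delta_eps1: float
    delta_eps2: float
    tau1: float
    tau2: float
    alpha1: float = DEFAULT_ALPHA1
    alpha2: float = DEFAULT_ALPHA2

    def __post_init__(self):
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if self.delta_eps1 <= 0 or self.delta_eps2 <= 0:
            raise ValueError("relaxation strengths must be positive")
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError("need tau1 > tau2 > 0")
        for a in (self.alpha1, self.alpha2):
            if not (0 <= a < 1):
                raise ValueError("alpha must lie in [0, 1)")

    @property
    def eps_static(self) -> float:
        """Low-frequency limit eps_s = eps_inf + d_eps1 + d_eps2."""
        return self.eps_inf + self.delta_eps1 + self.delta_eps2

    def replace(self, **kw) -> "ColeColeParams":
        return dataclasses.replace(self, **kw)

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.eps_inf,
                self.delta_eps1,
                self.delta_eps2,
                self.tau1,
                self.tau2,
                self.alpha1,
                self.alpha2,
            ]
        )


def evaluate_model(p: ColeColeParams, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate eps*(w) on a grid; returns complex eps' - j eps''."""
    return _evaluate_terms(
        grid.omega,
        p.eps_inf,
        [(p.delta_eps1, p.tau1, p.alpha1), (p.delta_eps2, p.tau2, p.alpha2)],
    )


def _evaluate_terms(omega, eps_inf, terms):
    w = np.asarray(omega, dtype=float)
    out = np.full(w.shape, eps_inf, dtype=complex)
    for d_eps, tau, alpha in terms:
        out = out + d_eps / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    return out


def r_squared_stacked(
    eps_pred: np.ndarray, spectrum: PermittivitySpectrum
) -> float:
    """Coefficient of determination on the stacked [eps'; eps''] vector.

    SS_tot is taken about the mean of the concatenated data vector.
    """
    data = np.concatenate([spectrum.eps_real, spectrum.eps_imag])
    pred = np.concatenate([eps_pred.real, -eps_pred.imag])
    ss_tot = np.sum((data - data.mean()) ** 2)
    if ss_tot == 0:
        raise SpectrumError("R^2 undefined: constant spectrum (SS_tot = 0)")
    ss_res = np.sum((data - pred) ** 2)
    return float(1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one Cole-Cole fit (any dispersion order)."""

    params: ColeColeParams | None
    r_squared: float
    residual_norm: float
    converged: bool
    n_restarts_used: int
    n_dispersions: int = 2
    #: raw per-dispersion terms (d_eps, tau, alpha) for orders != 2
    terms: tuple = ()
    eps_inf: float = np.nan


# ---------------------------------------------------------------------------
# internal parameter packing: theta = [eps_inf, d_eps_i..., log10(tau_i)...,
# alpha_i...] for n dispersions


def _pack(eps_inf, terms):
    d = [t[0] for t in terms]
    lt = [np.log10(t[1]) for t in terms]
    a = [t[2] for t in terms]
    return np.array([eps_inf, *d, *lt, *a])


def _unpack(theta, n):
    eps_inf = theta[0]
    d = theta[1 : 1 + n]
    tau = 10.0 ** theta[1 + n : 1 + 2 * n]
    alpha = theta[1 + 2 * n : 1 + 3 * n]
    return eps_inf, list(zip(d, tau, alpha))


def _bounds(n):
    lo = [PARAM_BOUNDS["eps_inf"][0]]
    hi = [PARAM_BOUNDS["eps_inf"][1]]
    lo += [PARAM_BOUNDS["d_eps"][0]] * n
    hi += [PARAM_BOUNDS["d_eps"][1]] * n
    lo += [np.log10(PARAM_BOUNDS["tau"][0])] * n
    hi += [np.log10(PARAM_BOUNDS["tau"][1])] * n
    lo += [PARAM_BOUNDS["alpha"][0]] * n
    hi += [PARAM_BOUNDS["alpha"][1]] * n
    return np.array(lo), np.array(hi)


def _residuals(theta, omega, data, n):
    eps_inf, terms = _unpack(theta, n)
    pred = _evaluate_terms(omega, eps_inf, terms)
    return np.concatenate([pred.real, -pred.imag]) - data


def _heuristic_init(s: PermittivitySpectrum, n: int) -> np.ndarray:
    """Data-driven starting point: eps_inf from the top of the band, strengths
    from the eps' drop split across dispersions, tau from the loss peak."""
    f = s.grid.points
    w = s.grid.omega
    eps_inf = np.clip(s.eps_real[-1] * 0.8, *PARAM_BOUNDS["eps_inf"])
    total_drop = max(s.eps_real[0] - eps_inf, 10 * n * PARAM_BOUNDS["d_eps"][0])
    # loss peak locates the dominant (fast) dispersion: tau ~ 1/w_peak
    i_peak = int(np.argmax(s.eps_imag))
    tau_fast = 1.0 / w[min(i_peak, len(w) - 1)]
    taus = [tau_fast * (100.0 ** k) for k in range(n)][::-1]  # slow ... fast
    if n == 1:
        strengths = [total_drop]
    else:
        strengths = [0.3 * total_drop] + [0.7 * total_drop / (n - 1)] * (n - 1)
    terms = [
        (
            np.clip(st, *PARAM_BOUNDS["d_eps"]),
            np.clip(t, *PARAM_BOUNDS["tau"]),
            0.05,
        )
        for st, t in zip(strengths, taus)
    ]
    return _pack(eps_inf, terms)


def fit_model(
    s: PermittivitySpectrum,
    n_dispersions: int = 2,
    init: ColeColeParams | None = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> FitResult:
    """Fit an n-dispersion Cole-Cole model by bounded nonlinear least squares.

    The residual is the unweighted stacked vector [eps'; eps''] (both parts
    are of comparable magnitude over this band).  ``n_restarts`` starts are
    tried: one heuristic initialisation (or the user-supplied ``init``) plus
    seeded log-uniform jitters; the best residual wins, ties broken by first
    occurrence.  Deterministic for fixed seed and input.
    """
    if n_dispersions not in (1, 2, 3):
        raise ValueError("n_dispersions must be 1, 2 or 3")
    if len(s.grid) < 10:
        raise SpectrumError("need at least 10 spectral points to fit")
    if not (np.all(np.isfinite(s.eps_real)) and np.all(np.isfinite(s.eps_imag))):
        raise SpectrumError("non-finite values in spectrum")

    n = n_dispersions
    omega = s.grid.omega
    data = np.concatenate([s.eps_real, s.eps_imag])
    lo, hi = _bounds(n)

    if init is not None:
        theta0 = _pack(
            init.eps_inf,
            [
                (init.delta_eps1, init.tau1, init.alpha1),
                (init.delta_eps2, init.tau2, init.alpha2),
            ][:n]
            if n <= 2
            else [
                (init.delta_eps1, init.tau1, init.alpha1),
                (init.delta_eps2, init.tau2, init.alpha2),
                (init.delta_eps2 / 2, init.tau2 / 10, init.alpha2),
            ],
        )
        theta0 = np.clip(theta0, lo, hi)
    else:
        theta0 = _heuristic_init(s, n)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.uniform(-1.0, 1.0, size=theta0.shape)
        # tau entries are already log10; jitter them by up to one decade,
        # linear entries by up to 30 %
        th = theta0.copy()
        th[0] *= 1 + 0.3 * jitter[0]
        th[1 : 1 + n] *= 1 + 0.3 * jitter[1 : 1 + n]
        th[1 + n : 1 + 2 * n] += jitter[1 + n : 1 + 2 * n]
        th[1 + 2 * n :] = np.clip(
            th[1 + 2 * n :] + 0.1 * jitter[1 + 2 * n :], lo[1 + 2 * n :], hi[1 + 2 * n :]
        )
        starts.append(np.clip(th, lo, hi))

    best = None
    best_cost = np.inf
    n_used = 0
    any_converged = False
    for k, th in enumerate(starts):
        n_used = k + 1
        try:
            sol = least_squares(
                _residuals,
                th,
                bounds=(lo, hi),
                args=(omega, data, n),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        any_converged = any_converged or sol.status > 0
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol

    if best is None:
        return FitResult(
            params=None,
            r_squared=-np.inf,
            residual_norm=np.inf,
            converged=False,
            n_restarts_used=n_used,
            n_dispersions=n,
        )

    eps_inf, terms = _unpack(best.x, n)
    # relabel so dispersion 1 is the slowest (largest tau)
    terms = sorted(terms, key=lambda t: -t[1])
    pred = _evaluate_terms(omega, eps_inf, terms)
    r2 = r_squared_stacked(pred, s)
    resid_norm = float(np.sqrt(2 * best.cost))

    params = None
    if n == 2:
        params = ColeColeParams(
            eps_inf=float(eps_inf),
            delta_eps1=float(terms[0][0]),
            delta_eps2=float(terms[1][0]),
            tau1=float(terms[0][1]),
            tau2=float(terms[1][1]),
            alpha1=float(terms[0][2]),
            alpha2=float(terms[1][2]),
        )
    return FitResult(
        params=params,
        r_squared=r2,
        residual_norm=resid_norm,
        converged=bool(any_converged and np.isfinite(resid_norm)),
        n_restarts_used=n_used,
        n_dispersions=n,
        terms=tuple((float(d), float(t), float(a)) for d, t, a in terms),
        eps_inf=float(eps_inf),
    )


def goodness_of_fit(fit: FitResult, s: PermittivitySpectrum) -> float:
    """R^2 of a fit against a spectrum, on the stacked [eps'; eps''] vector."""
    pred = _evaluate_terms(s.grid.omega, fit.eps_inf, list(fit.terms))
    return r_squared_stacked(pred, s)


@dataclass(frozen=True)
class DispersionComparison:
    """Fits of orders 1..3 with successive R^2 improvements."""

    fits: tuple[FitResult, ...]
    delta_r2: tuple[float, ...]
    selected_order: int
    flags: tuple[str, ...]


def compare_dispersion_orders(
    s: PermittivitySpectrum, seed: int = 0, min_improvement: float = MIN_R2_IMPROVEMENT
) -> DispersionComparison:
    """Fit 1-, 2- and 3-dispersion models and flag minimal improvements.

    The selected order is the smallest whose successor improves R^2 by less
    than ``min_improvement`` (an extra dispersion that buys less than this is
    judged not worth its three parameters).
    """
    fits = tuple(fit_model(s, n_dispersions=n, seed=seed) for n in (1, 2, 3))
    r2 = [f.r_squared for f in fits]
    deltas = tuple(r2[i + 1] - r2[i] for i in range(2))
    flags = []
    for i, f in enumerate(fits):
        if i == 0:
            flags.append("baseline")
        elif deltas[i - 1] < min_improvement:
            flags.append("minimal improvement")
        else:
            flags.append("adequate gain")
    selected = 3
    for i, d in enumerate(deltas):
        if d < min_improvement:
            selected = i + 1
            break
    return DispersionComparison(fits, deltas, selected, tuple(flags))


# ---------------------------------------------------------------------------
# Model/Results interface


class ColeColeModel:
    """Cole-Cole relaxation model bound to one permittivity spectrum.

    Parameters
    ----------
    spectrum : PermittivitySpectrum
        The measured (or simulated) spectrum to describe.
    n_dispersions : int
        Number of Cole-Cole terms (default 2, the double model).

    Examples
    --------
    >>> res = ColeColeModel(spec).fit(seed=0)
    >>> res.params.tau1, res.rsquared
    """

    def __init__(self, spectrum: PermittivitySpectrum, n_dispersions: int = 2):
        if n_dispersions not in (1, 2, 3):
            raise ValueError("n_dispersions must be 1, 2 or 3")
        self.spectrum = spectrum
        self.n_dispersions = n_dispersions

    @classmethod
    def from_dataframe(cls, df, n_dispersions: int = 2) -> "ColeColeModel":
        """Build from a DataFrame with columns frequency_hz, eps_real, eps_imag."""
        f = np.asarray(df["frequency_hz"], dtype=float)
        s = PermittivitySpectrum(
            FrequencyGrid(f),
            np.asarray(df["eps_real"], dtype=float),
            np.asarray(df["eps_imag"], dtype=float),
        )
        return cls(s, n_dispersions=n_dispersions)

    def evaluate(self, params: ColeColeParams) -> np.ndarray:
        return evaluate_model(params, self.spectrum.grid)

    def fit(
        self,
        init: ColeColeParams | None = None,
        seed: int = 0,
        n_restarts: int = 5,
    ) -> "ColeColeResults":
        fit = fit_model(
            self.spectrum,
            n_dispersions=self.n_dispersions,
            init=init,
            seed=seed,
            n_restarts=n_restarts,
        )
        return ColeColeResults(self, fit)

    def compare_orders(self, seed: int = 0) -> DispersionComparison:
        return compare_dispersion_orders(self.spectrum, seed=seed)


class ColeColeResults:
    """Fitted Cole-Cole model: estimates, fit quality and summary table."""

    def __init__(self, model: ColeColeModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> ColeColeParams | None:
        return self.fit_result.params

    @property
    def rsquared(self) -> float:
        return self.fit_result.r_squared

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def fittedvalues(self) -> np.ndarray:
        """Model eps* on the data grid."""
        f = self.fit_result
        return _evaluate_terms(self.model.spectrum.grid.omega, f.eps_inf, list(f.terms))

    @property
    def resid(self) -> np.ndarray:
        """Stacked [eps'; eps''] residuals (data minus fit)."""
        s = self.model.spectrum
        pred = self.fittedvalues
        return np.concatenate(
            [s.eps_real - pred.real, s.eps_imag - (-pred.imag)]
        )

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            f"Cole-Cole fit ({f.n_dispersions} dispersion(s))",
            "=" * 44,
            f"{'eps_inf':<12}{f.eps_inf:>12.4f}",
        ]
        for i, (d, t, a) in enumerate(f.terms, start=1):
            lines.append(f"{f'delta_eps{i}':<12}{d:>12.4f}")
            lines.append(f"{f'tau{i} [ps]':<12}{t * 1e12:>12.4f}")
            lines.append(f"{f'alpha{i}':<12}{a:>12.4f}")
        lines += [
            "-" * 44,
            f"{'R^2':<12}{f.r_squared:>12.6f}",
            f"{'resid norm':<12}{f.residual_norm:>12.4e}",
            f"{'converged':<12}{str(f.converged):>12}",
            f"{'restarts':<12}{f.n_restarts_used:>12d}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ColeColeResults n_disp={self.fit_result.n_dispersions} "
            f"R2={self.rsquared:.6f} converged={self.converged}>"
        )
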