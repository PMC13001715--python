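"""RIDME dipolar traces: simulation, background, and Tikhonov inversion.

A RIDME (relaxation-induced dipolar modulation enhancement) trace from a
pair of coupled electron spins is modelled in the usual pulsed-dipolar
form-factor convention:

    V(t) = [(1 - lambda) + lambda * (K P)(t)] * exp(-k t^d)

where K is the powder-averaged dipolar kernel, P(r) the distance
distribution, lambda the modulation depth and the stretched exponential the
intermolecular background.  The dipolar frequency scale is
nu_dd = 52.04 MHz / (r/nm)^3 for a g ~ 2 pair.

Inversion alternates a bounded nonlinear background fit with a
non-negative Tikhonov solve (2nd-derivative penalty); the regularization
parameter comes from generalized cross-validation by default.  Confidence
bands are estimated by residual-resampling bootstrap.

Relaxation-time fits used to set up the experiment are also provided:
stretched-exponential phase-memory (Tm) decay and biexponential inversion
recovery with the mixing-time recommendation T_mix = 0.7 * T1 (amplitude-
weighted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit, least_squares, nnls
from scipy.special import fresnel

from cuepr.constants import DIPOLAR_MHZ_NM3
from cuepr.occupancy import DistanceDistribution

__all__ = [
    "RidmeTrace",
    "KernelMatrix",
    "BackgroundModel",
    "RelaxationFit",
    "dipolar_frequency",
    "dipolar_kernel",
    "dipolar_kernel_fresnel",
    "simulate_ridme",
    "invert_tikhonov",
    "combine_field_positions",
    "uncertainty_band",
    "fit_stretched_exp",
    "fit_inversion_recovery",
    "default_t_grid",
    "default_r_grid",
]


def default_t_grid(t_max: float = 2.1, dt: float = 0.008) -> np.ndarray:
    """Uniform time grid in microseconds (tau2 = 2.5 us minus dead time)."""
    n = int(round(t_max / dt)) + 1
    return np.linspace(0.0, t_max, n)


def default_r_grid(r_min: float = 1.5, r_max: float = 8.0, step: float = 0.02) -> np.ndarray:
    """Distance grid spanning the detectability window, in nm."""
    n = int(round((r_max - r_min) / step)) + 1
    return np.linspace(r_min, r_max, n)


@dataclass
class RidmeTrace:
    """Normalized dipolar time trace, V(0) = 1."""

    t_axis: np.ndarray  # us, uniform, t >= 0
    signal: np.ndarray
    field_offset: float = 0.0  # G
    mixing_time: float = 0.0  # us
    tau1: float = 0.4  # us
    tau2: float = 2.5  # us

    def __post_init__(self) -> None:
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t_axis.shape != self.signal.shape or self.t_axis.ndim != 1:
            raise ValueError("t_axis and signal must be 1-D, equal length")
        if self.t_axis[0] < 0:
            raise ValueError("t_axis must start at >= 0")
        dt = np.diff(self.t_axis)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("t_axis must be uniform")
        if self.signal[0] == 0:
            raise ValueError("V(0) must be nonzero for normalization")
        self.signal = self.signal / self.signal[0]

    def to_text(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t_axis, self.signal]),
            header=(
                f"t_us V | field_offset_G={self.field_offset} "
                f"mixing_time_us={self.mixing_time}"
            ),
        )

    @classmethod
    def from_text(cls, path: str | Path) -> "RidmeTrace":
        offset = 0.0
        t_mix = 0.0
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first.split():
                if token.startswith("field_offset_G="):
                    offset = float(token.split("=", 1)[1])
                elif token.startswith("mixing_time_us="):
                    t_mix = float(token.split("=", 1)[1])
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], field_offset=offset, mixing_time=t_mix)


@dataclass
class KernelMatrix:
    """Powder-averaged dipolar kernel K(t, r); first row (t = 0) is all 1."""

    t_grid: np.ndarray  # us
    r_grid: np.ndarray  # nm
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.t_grid), len(self.r_grid)):
            raise ValueError("kernel shape must be (len(t), len(r))")
        if np.any(np.abs(self.matrix) > 1.0 + 1e-9):
            raise ValueError("kernel entries must be bounded by 1 in magnitude")


@dataclass(frozen=True)
class BackgroundModel:
    """Stretched-exponential intermolecular background with modulation depth."""

    k: float = 0.05  # us^-d
    d: float = 1.5  # stretch dimension
    lam: float = 0.3  # modulation depth

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("decay rate k must be >= 0")
        if not 0.0 < self.d < 6.0:
            raise ValueError("stretch d must lie in (0, 6)")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("modulation depth must lie in (0, 1]")

    def decay(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-self.k * np.power(np.abs(t), self.d))


@dataclass
class RelaxationFit:
    """Relaxation-time fit results (phase memory and/or T1 recovery)."""

    tm: float | None = None  # us
    beta: float | None = None
    t1_fast: float | None = None  # us
    t1_slow: float | None = None  # us
    amp_fast: float | None = None
    amp_slow: float | None = None
    mixing_time: float | None = None  # us, recommended

    def __post_init__(self) -> None:
        for v in (self.tm, self.t1_fast, self.t1_slow):
            if v is not None and v <= 0:
                raise ValueError("relaxation times must be positive")
        for v in (self.amp_fast, self.amp_slow):
            if v is not None and v < 0:
                raise ValueError("amplitudes must be >= 0")


def dipolar_frequency(r_nm: np.ndarray | float) -> np.ndarray | float:
    """Perpendicular dipolar frequency in MHz for a g ~ 2 pair at r (nm)."""
    r = np.asarray(r_nm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    out = DIPOLAR_MHZ_NM3 / r**3
    return float(out) if np.isscalar(r_nm) else out


def dipolar_kernel(
    t_grid: np.ndarray, r_grid: np.ndarray, quadrature_n: int = 401
) -> KernelMatrix:
    """Powder dipolar kernel by Gauss-Legendre orientation quadrature.

    K(t, r) = integral_0^1 cos(2 pi nu_dd(r) (1 - 3 x^2) t) dx with
    x = cos(theta) between the spin-spin vector and the field.
    """
    t = np.asarray(t_grid, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_grid must be positive")
    nodes, weights = np.polynomial.legendre.leggauss(quadrature_n)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    nu = dipolar_frequency(r)  # MHz
    # phase[t, r, x] = 2 pi nu (1 - 3 x^2) t ; MHz * us is dimensionless cycles
    angular = 2.0 * np.pi * nu[None, :, None] * (1.0 - 3.0 * x[None, None, :] ** 2)
    k = np.einsum("trx,x->tr", np.cos(angular * t[:, None, None]), w)
    return KernelMatrix(t_grid=t, r_grid=r, matrix=k)


def dipolar_kernel_fresnel(t_grid: np.ndarray, r_grid: np.ndarray) -> KernelMatrix:
    """Closed-form powder kernel via Fresnel integrals (cross-check route)."""
    t = np.asarray(t_grid, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_grid must be positive")
    nu = dipolar_frequency(r)
    # K = [cos(ph) C(z) + sin(ph) S(z)] / z with ph = 2 pi nu t and
    # z = sqrt(6 ph / pi) (standard DEER/RIDME closed form)
    ph = 2.0 * np.pi * nu[None, :] * t[:, None]
    z = np.sqrt(6.0 * np.abs(ph) / np.pi)
    s, c = fresnel(np.sqrt(2.0 / np.pi) * np.sqrt(np.abs(ph) * 3.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (np.cos(ph) * c + np.sin(ph) * s) / (
            np.sqrt(2.0 / np.pi) * np.sqrt(np.abs(ph) * 3.0)
        )
    k = np.where(np.abs(ph) < 1e-12, 1.0, k)
    return KernelMatrix(t_grid=t, r_grid=r, matrix=k)


def simulate_ridme(
    distribution: DistanceDistribution,
    background: BackgroundModel,
    t_grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    field_offset: float = 0.0,
    mixing_time: float = 0.0,
    quadrature_n: int = 401,
) -> RidmeTrace:
    """Simulate a RIDME trace from a distance distribution + background."""
    if t_grid is None:
        t_grid = default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    p = distribution.normalize()
    kernel = dipolar_kernel(t_grid, p.r_grid, quadrature_n=quadrature_n)
    dr = p.r_grid[1] - p.r_grid[0]
    form_factor = kernel.matrix @ (p.density * dr)
    form_factor = form_factor / form_factor[0]
    signal = ((1.0 - background.lam) + background.lam * form_factor) * background.decay(
        t_grid
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=t_grid.shape)
    return RidmeTrace(
        t_axis=t_grid,
        signal=signal,
        field_offset=field_offset,
        mixing_time=mixing_time,
    )


# ---------------------------------------------------------------------------
# inversion


def _second_derivative_operator(n: int) -> np.ndarray:
    """Second-difference penalty with Dirichlet boundaries (P = 0 just
    outside the grid), so mass cannot pile up at the grid edges where the
    kernel is degenerate with the background."""
    l2 = np.zeros((n, n))
    for i in range(n):
        l2[i, i] = -2.0
        if i > 0:
            l2[i, i - 1] = 1.0
        if i < n - 1:
            l2[i, i + 1] = 1.0
    return l2


def _tikhonov_nnls(
    kernel: np.ndarray, y: np.ndarray, alpha: float, l2: np.ndarray
) -> np.ndarray:
    a = np.vstack([kernel, alpha * l2])
    b = np.concatenate([y, np.zeros(l2.shape[0])])
    p, _ = nnls(a, b, maxiter=10 * a.shape[1])
    return p


def _gcv_alpha(
    kernel: np.ndarray, y: np.ndarray, alphas: np.ndarray, l2: np.ndarray
) -> float:
    """Generalized cross-validation on the unconstrained Tikhonov problem.

    The seminorm penalty ||alpha L2 P||^2 is brought to standard form with
    the (invertible, Dirichlet-boundary) operator: K~ = K L2^-1, after which
    the usual SVD filter-factor expressions apply.
    """
    k_std = np.linalg.solve(l2.T, kernel.T).T  # K @ inv(L2)
    u, s, _vt = np.linalg.svd(k_std, full_matrices=False)
    uty = u.T @ y
    n = len(y)
    best = (np.inf, float(alphas[0]))
    for alpha in alphas:
        f = s**2 / (s**2 + alpha**2)
        resid = np.sum(((1 - f) * uty) ** 2) + (y @ y - uty @ uty)
        denom = (n - np.sum(f)) ** 2
        g = n * resid / denom
        if g < best[0]:
            best = (g, float(alpha))
    return best[1]


def _lcurve_alpha(
    kernel: np.ndarray, y: np.ndarray, l2: np.ndarray, alphas: np.ndarray
) -> float:
    """Maximum-curvature corner of the (log residual, log seminorm) curve."""
    rho = []
    eta = []
    for alpha in alphas:
        p = _tikhonov_nnls(kernel, y, alpha, l2)
        rho.append(np.log(np.linalg.norm(kernel @ p - y) + 1e-15))
        eta.append(np.log(np.linalg.norm(l2 @ p) + 1e-15))
    rho = np.array(rho)
    eta = np.array(eta)
    drho = np.gradient(rho)
    deta = np.gradient(eta)
    d2rho = np.gradient(drho)
    d2eta = np.gradient(deta)
    curvature = (drho * d2eta - d2rho * deta) / np.power(
        drho**2 + deta**2, 1.5
    )
    return float(alphas[int(np.nanargmax(curvature))])


def _invert_core(
    trace: RidmeTrace,
    r_grid: np.ndarray,
    alpha: float | str,
    max_outer: int,
    tol: float,
    quadrature_n: int,
    bg_init: BackgroundModel | None = None,
) -> tuple[np.ndarray, BackgroundModel, np.ndarray, float]:
    """Shared inversion engine; returns the raw (unnormalized) density, the
    fitted background model, the model's fitted time trace, and the
    regularization parameter used.

    ``bg_init`` skips the tail-fit initialisation (used to warm-start
    bootstrap refits from the point estimate)."""
    if not np.any(trace.signal):
        raise ValueError("cannot invert an all-zero trace")
    r_grid = np.asarray(r_grid, dtype=float)
    t = trace.t_axis
    v = trace.signal
    kernel = dipolar_kernel(t, r_grid, quadrature_n=quadrature_n).matrix
    dr = r_grid[1] - r_grid[0]
    k_int = kernel * dr  # maps a density to a form factor
    l2 = _second_derivative_operator(len(r_grid))

    if bg_init is not None:
        bg = bg_init
    else:
        # -- initial background from the trace tail ------------------------
        tail = t >= 0.4 * t[-1]

        def tail_model(params: np.ndarray) -> np.ndarray:
            a_, k_, d_ = params
            return a_ * np.exp(-k_ * np.power(t[tail], d_)) - v[tail]

        res0 = least_squares(
            tail_model,
            x0=[max(float(np.mean(v[tail])), 0.1), 0.05, 1.5],
            bounds=([1e-3, 0.0, 1.0], [1.0, 10.0, 4.0]),
            max_nfev=400,
        )
        a0, k0, d0 = res0.x
        lam0 = float(np.clip(1.0 - a0, 0.05, 0.95))
        bg = BackgroundModel(k=float(k0), d=float(d0), lam=lam0)

    # -- regularization parameter at the initial background ----------------
    def reduced_signal(bgm: BackgroundModel) -> np.ndarray:
        return (v / bgm.decay(t) - (1.0 - bgm.lam)) / bgm.lam

    if isinstance(alpha, str):
        alphas = np.logspace(-5, 2, 36)
        y0 = reduced_signal(bg)
        try:
            if alpha == "gcv":
                alpha_val = _gcv_alpha(k_int, y0, alphas, l2)
            elif alpha == "lcurve":
                alpha_val = _lcurve_alpha(k_int, y0, l2, alphas)
            else:
                raise ValueError(f"unknown alpha selection {alpha!r}")
        except np.linalg.LinAlgError:
            warnings.warn("alpha selection failed; using alpha = 1",
                          stacklevel=2)
            alpha_val = 1.0
    else:
        alpha_val = float(alpha)

    # -- variable projection: refine (k, d, lambda) with P solved inside ---
    # The stacked Tikhonov matrix [K; alpha L2] is fixed across the varpro
    # iterations; its QR factorisation compresses every NNLS solve to an
    # equivalent square problem min ||R p - Q^T b||.
    a_stack = np.vstack([k_int, alpha_val * l2])
    q_fac, r_fac = np.linalg.qr(a_stack)
    qt_kernel = q_fac[: len(t)].T  # maps y to Q^T [y; 0]

    def solve_p(bgm: BackgroundModel) -> np.ndarray:
        b = qt_kernel @ reduced_signal(bgm)
        p, _ = nnls(r_fac, b, maxiter=10 * r_fac.shape[1])
        return p

    def full_residual(params: np.ndarray) -> np.ndarray:
        k_, d_, lam_ = params
        bgm = BackgroundModel(k=float(k_), d=float(d_), lam=float(lam_))
        p = solve_p(bgm)
        fitted = ((1 - lam_) + lam_ * (k_int @ p)) * bgm.decay(t)
        return fitted - v

    # the (k, d) valley is shallow; start from the tail fit and from low/high
    # stretch dimensions, keep the best converged fit
    if bg_init is not None:
        starts = [[bg.k, bg.d, bg.lam]]
    else:
        starts = [[bg.k, bg.d, bg.lam],
                  [bg.k, 1.25, bg.lam],
                  [bg.k, 2.5, bg.lam]]
    res = None
    for x0 in starts:
        cand = least_squares(
            full_residual,
            x0=x0,
            bounds=([0.0, 1.0, 0.01], [10.0, 4.0, 1.0]),
            diff_step=1e-4,
            x_scale=[0.1, 1.0, 0.3],
            max_nfev=max_outer,
            xtol=tol,
            ftol=tol,
            gtol=tol,
        )
        if res is None or cand.cost < res.cost:
            res = cand
    k_, d_, lam_ = res.x
    bg = BackgroundModel(k=float(k_), d=float(d_), lam=float(lam_))
    p_density = solve_p(bg)
    if not np.any(p_density):
        raise RuntimeError("inversion produced an all-zero distribution")
    fitted = ((1 - bg.lam) + bg.lam * (k_int @ p_density)) * bg.decay(t)
    return p_density, bg, fitted, float(alpha_val)


def invert_tikhonov(
    trace: RidmeTrace,
    r_grid: np.ndarray | None = None,
    alpha: float | str = "gcv",
    max_outer: int = 80,
    tol: float = 1e-12,
    quadrature_n: int = 401,
) -> tuple[DistanceDistribution, BackgroundModel, float]:
    """Invert a RIDME trace to a non-negative distance distribution.

    Procedure: the background is first estimated from the tail of the trace
    (where the dipolar oscillation has decayed) by fitting A exp(-k t^d);
    the regularization parameter is then selected at that background
    (generalized cross-validation by default, ``"lcurve"`` or a fixed
    number otherwise) and the three background parameters (k, d, lambda)
    are refined by bounded nonlinear least squares with the non-negative
    Tikhonov solve for P(r) nested inside (variable projection).
    ``max_outer`` caps the refinement function evaluations; ``tol`` is the
    termination tolerance.

    Returns ``(P, background, modulation_depth)``; P integrates to 1.
    """
    if r_grid is None:
        r_grid = default_r_grid()
    p_density, bg, _fitted, _alpha = _invert_core(
        trace, r_grid, alpha, max_outer, tol, quadrature_n
    )
    dist = DistanceDistribution(
        np.asarray(r_grid, dtype=float), p_density, source="inverted"
    ).normalize()
    return dist, bg, bg.lam


def combine_field_positions(traces: list[RidmeTrace]) -> RidmeTrace:
    """Average traces recorded at different field offsets (orientation
    averaging); the result is renormalized to V(0) = 1."""
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0].t_axis
    signals = []
    for tr in traces:
        if tr.t_axis.shape == ref.shape and np.allclose(tr.t_axis, ref):
            signals.append(tr.signal)
        else:
            signals.append(np.interp(ref, tr.t_axis, tr.signal))
    mean = np.mean(signals, axis=0)
    return RidmeTrace(
        t_axis=ref.copy(),
        signal=mean,
        field_offset=float(np.mean([tr.field_offset for tr in traces])),
        mixing_time=traces[0].mixing_time,
    )


def uncertainty_band(
    trace: RidmeTrace,
    r_grid: np.ndarray | None = None,
    alpha: float | str = "gcv",
    n_boot: int = 100,
    seed: int | None = None,
    quadrature_n: int = 401,
) -> tuple[DistanceDistribution, np.ndarray, np.ndarray]:
    """Residual-resampling bootstrap 95% band for the inverted P(r).

    Returns ``(P_hat, lower, upper)`` where lower/upper are the 2.5th and
    97.5th percentiles of the bootstrap distributions at each r.
    """
    if n_boot < 20:
        warnings.warn("n_boot < 20 gives unstable percentiles", stacklevel=2)
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(r_grid, dtype=float)
    p_raw, bg, fitted, alpha_used = _invert_core(
        trace, r_grid, alpha, 80, 1e-12, quadrature_n
    )
    p_hat = DistanceDistribution(r_grid, p_raw, source="inverted").normalize()
    residuals = trace.signal - fitted

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(r_grid)))
    for b in range(n_boot):
        resampled = fitted + rng.choice(residuals, size=len(residuals), replace=True)
        resampled[0] = max(resampled[0], 1e-6)
        boot_trace = RidmeTrace(
            t_axis=trace.t_axis.copy(),
            signal=resampled,
            field_offset=trace.field_offset,
            mixing_time=trace.mixing_time,
        )
        p_b, _bg_b, _fit_b, _a = _invert_core(
            boot_trace, r_grid, alpha_used, 80, 1e-12, quadrature_n,
            bg_init=bg,
        )
        boots[b] = DistanceDistribution(
            r_grid, p_b, source="inverted"
        ).normalize().density
    lower = np.percentile(boots, 2.5, axis=0)
    upper = np.percentile(boots, 97.5, axis=0)
    lower = np.minimum(lower, p_hat.density)
    upper = np.maximum(upper, p_hat.density)
    return p_hat, lower, upper


# ---------------------------------------------------------------------------
# relaxation fits


def fit_stretched_exp(t: np.ndarray, y: np.ndarray) -> RelaxationFit:
    """Fit y = y0 exp(-(t/Tm)^beta) to a 2-pulse echo decay."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y[0] <= 0:
        raise ValueError("y(0) must be positive")
    if np.ptp(y) < 1e-9 * abs(y[0]):
        raise ValueError("decay is constant; stretched-exponential fit is degenerate")

    def model(tt, y0, tm, beta):
        return y0 * np.exp(-np.power(tt / tm, beta))

    t_scale = max(t[-1], 1e-6)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=(y[0], 0.5 * t_scale, 1.0),
            bounds=([1e-12, 1e-9, 0.05], [np.inf, np.inf, 6.0]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"stretched-exponential fit failed: {exc}") from exc
    _y0, tm, beta = popt
    if beta <= 0.051:
        raise RuntimeError(
            "stretched-exponential fit collapsed to the beta -> 0 boundary "
            "(constant data?)"
        )
    return RelaxationFit(tm=float(tm), beta=float(beta))


def fit_inversion_recovery(t: np.ndarray, y: np.ndarray) -> RelaxationFit:
    """Biexponential inversion-recovery fit with mixing-time recommendation.

    Model: y = y_inf - a_f exp(-t/T1_fast) - a_s exp(-t/T1_slow).  The
    recommended RIDME mixing time is 0.7 x the amplitude-weighted mean T1.
    Falls back to a single exponential if the biexponential fit fails.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 recovery points")

    def biexp(tt, yinf, af, t1f, as_, t1s):
        return yinf - af * np.exp(-tt / t1f) - as_ * np.exp(-tt / t1s)

    t_scale = max(t[-1], 1e-6)
    try:
        popt, _ = curve_fit(
            biexp, t, y,
            p0=(y[-1], 0.5 * np.ptp(y), 0.1 * t_scale, 0.5 * np.ptp(y), 0.5 * t_scale),
            bounds=(
                [-np.inf, 0.0, 1e-9, 0.0, 1e-9],
                [np.inf, np.inf, np.inf, np.inf, np.inf],
            ),
            maxfev=40000,
        )
        _yinf, af, t1f, as_, t1s = popt
        if t1f > t1s:  # keep fast/slow ordering
            t1f, t1s = t1s, t1f
            af, as_ = as_, af
    except RuntimeError:
        warnings.warn(
            "biexponential fit failed; falling back to a single exponential",
            stacklevel=2,
        )

        def monoexp(tt, yinf, a, t1):
            return yinf - a * np.exp(-tt / t1)

        popt, _ = curve_fit(
            monoexp, t, y, p0=(y[-1], np.ptp(y), 0.3 * t_scale),
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        _yinf, a, t1 = popt
        t1f = t1s = t1
        af = as_ = 0.5 * a

    total = af + as_
    weighted_t1 = (af * t1f + as_ * t1s) / total if total > 0 else 0.5 * (t1f + t1s)
    return RelaxationFit(
        t1_fast=float(t1f),
        t1_slow=float(t1s),
        amp_fast=float(af),
        amp_slow=float(as_),
        mixing_time=float(0.7 * weighted_t1),
    )
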