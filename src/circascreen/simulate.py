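"""Labelled-rhythm simulator for supervised phase estimation.

Mouse activity and feeding under a 12:12 LD cycle are bimodal: a strong
evening (E) peak shortly after lights-off and a weaker morning (M) peak.
Real screen data contain too few abnormal chronotypes to train a phase
regressor, so training curves are synthesized from a generative template
with known onset and peak labels:

* the rest-to-active transition (recording start t1 up to the evening peak
  t3) follows the relaxation ODE dx/dt = eps * (F - x), where the switch
  input F ramps linearly from u1*h1 at t1 to u2*h2 at t2 (the hour before
  onset) and then sits at u3*h3 until t3 (u1 = u2 = u3 = 1.1);
* everything after the evening peak is a superposition of three Gaussian
  bumps (evening peak, late-night/morning peak, and a small early-morning
  bump near the recording start) on a shared baseline.

A per-centre, per-modality *template* is fitted once to the mean wild-type
curve; labelled curves are then drawn by randomizing the template
parameters (uniform multipliers on heights, widths, phases and the
relaxation rate) and adding white measurement noise.  Each curve is 25
hourly samples on ZT6..ZT30 with onset label t2 + 1 (the first point
inside the transition) and peak label t3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import EmptyInputError, FitFailureError
from .ic_data import CANONICAL_ZT, N_GRID

DEFAULT_DT = 0.05       # RK4 step, hours
SWITCH_GAIN = 1.1       # u1 = u2 = u3
MIN_WIDTH = 1e-3        # Gaussian widths are bounded away from zero


# ---------------------------------------------------------------------------
# ODE machinery
# ---------------------------------------------------------------------------

def switch_input(t, t1, t2, t3, h1, h2, h3, u=SWITCH_GAIN):
    """Piecewise endogenous switch F(t): linear ramp on [t1, t2], then u*h3."""
    t = np.asarray(t, dtype=float)
    ramp = (u * h2 - u * h1) / (t2 - t1) * t + (u * h1 * t2 - u * h2 * t1) / (t2 - t1)
    return np.where(t <= t2, ramp, u * h3)


def _rk4_relax(eps, f_full, f_half, x0, dt):
    """Integrate dx/dt = eps*(F - x) with classical RK4 on a fixed grid.

    f_full[j] = F at node j (j = 0..n); f_half[j] = F at midpoint j+1/2.
    """
    n = f_half.size
    x = np.empty(n + 1)
    x[0] = x0
    half = 0.5 * dt
    for j in range(n):
        xj = x[j]
        k1 = eps * (f_full[j] - xj)
        k2 = eps * (f_half[j] - (xj + half * k1))
        k3 = eps * (f_half[j] - (xj + half * k2))
        k4 = eps * (f_full[j + 1] - (xj + dt * k3))
        x[j + 1] = xj + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return x


def integrate_relaxation(eps, forcing, t0, t_end, x0=0.0, dt=DEFAULT_DT):
    """Integrate dx/dt = eps*(F(t) - x) from t0 to t_end (fixed-step RK4).

    `forcing` may be a scalar or a vectorized callable of t.  Returns
    (times, x) including both endpoints.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    n = max(1, int(round((t_end - t0) / dt)))
    step = (t_end - t0) / n
    times = t0 + step * np.arange(n + 1)
    mids = times[:-1] + 0.5 * step
    if callable(forcing):
        f_full = np.broadcast_to(np.asarray(forcing(times), dtype=float), times.shape).copy()
        f_half = np.broadcast_to(np.asarray(forcing(mids), dtype=float), mids.shape).copy()
    else:
        f_full = np.full(times.shape, float(forcing))
        f_half = np.full(mids.shape, float(forcing))
    x = _rk4_relax(float(eps), f_full, f_half, float(x0), step)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("ODE integration produced non-finite values")
    return times, x


def integrate_switch(eps, t1, t2, t3, h1, h2, h3, x0=None, dt=DEFAULT_DT):
    """Transition segment: relaxation towards the piecewise switch on [t1, t3]."""
    if x0 is None:
        x0 = h1
    forcing = lambda t: switch_input(t, t1, t2, t3, h1, h2, h3)
    return integrate_relaxation(eps, forcing, t1, t3, x0=x0, dt=dt)


def gaussian_component(amplitude, width, center, offset, t):
    """One fitted peak: amplitude * exp(-(t-center)^2 / (2 width^2)) + offset."""
    t = np.asarray(t, dtype=float)
    w = max(float(width), MIN_WIDTH)
    return amplitude * np.exp(-((t - center) ** 2) / (2.0 * w * w)) + offset


def _bump(amplitude, width, center, t):
    return gaussian_component(amplitude, width, center, 0.0, t)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TemplateParams:
    """Standard (fitted) parameters of one centre x modality template.

    `gauss` holds the twelve Gaussian parameters a1..a12 in order:
    amplitudes a1, a5, a9 at indices 0, 4, 8; widths a2, a6, a10 at
    1, 5, 9; peak phases a3, a7, a11 at 2, 6, 10; offsets a4, a8, a12 at
    3, 7, 11.  `m3` is the measured third-peak value (0 when the mean
    curve has only two peaks).
    """

    centre: str
    modality: str
    t1: float
    t2: float
    t3: float
    h1: float
    h2: float
    h3: float
    eps: float
    gauss: np.ndarray
    m3: float = 0.0
    u: float = SWITCH_GAIN

    def __post_init__(self):
        self.gauss = np.asarray(self.gauss, dtype=float)
        if self.gauss.shape != (12,):
            raise ValueError("gauss must hold the twelve parameters a1..a12")
        if not (self.t1 < self.t2 < self.t3):
            raise ValueError("need t1 < t2 < t3")
        if self.eps <= 0:
            raise ValueError("relaxation rate eps must be positive")
        if min(self.gauss[1], self.gauss[5], self.gauss[9]) <= 0:
            raise ValueError("Gaussian widths must be positive")
        if min(self.gauss[0], self.gauss[4], self.gauss[8]) < 0:
            raise ValueError("Gaussian amplitudes must be non-negative")


@dataclass
class SimParams:
    """One randomized draw of the template parameters plus its ODE solution."""

    t1: float
    t2: float
    t3: float
    h1: float
    h2: float
    h3: float
    eps: float
    a: np.ndarray            # a1..a12 of the drawn curve (a11 = a8, offsets)
    t_peak3: float           # third-bump centre, near the recording start
    noise_scale: float = 0.05
    u: float = SWITCH_GAIN
    ode_times: np.ndarray | None = field(default=None, repr=False)
    ode_values: np.ndarray | None = field(default=None, repr=False)


@dataclass
class LabelledCurve:
    """A 25-point synthetic rhythm with its known phase labels (ZT hours)."""

    values: np.ndarray
    onset_label: float
    peak_label: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GRID,):
            raise ValueError(f"curve must have {N_GRID} points")
        if self.onset_label > self.peak_label:
            raise ValueError("onset label cannot exceed peak label")


@dataclass
class FitInit:
    """Initial values and box bounds for the Gaussian remainder fit."""

    zt_peak1: float
    zt_peak2: float | None
    zt_peak3: float | None
    m2: float
    m3: float
    a1_fixed: float
    x0: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...]


# ---------------------------------------------------------------------------
# Template construction and fitting
# ---------------------------------------------------------------------------

def average_profile(curves) -> np.ndarray:
    """Pointwise mean over non-missing values on the canonical grid.

    Accepts a sequence of 25-vectors (NaN = missing) or of profile objects
    exposing `.values` on the canonical grid.
    """
    if len(curves) == 0:
        raise EmptyInputError("cannot average an empty profile list")
    rows = []
    for c in curves:
        v = getattr(c, "values", c)
        v = np.asarray(v, dtype=float)
        if v.shape != (N_GRID,):
            raise ValueError("profiles must be on the canonical 25-point grid")
        rows.append(v)
    stack = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def find_local_maxima(curve: np.ndarray) -> list[int]:
    """Indices strictly exceeding the four surrounding points (i±1, i±2).

    The comparison window is truncated at the curve edges; ties never
    qualify.
    """
    y = np.asarray(curve, dtype=float)
    n = y.size
    out = []
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        neighbours = np.concatenate([y[lo:i], y[i + 1:hi]])
        if neighbours.size and np.all(y[i] > neighbours):
            out.append(i)
    return out


def _grid_value(curve: np.ndarray, zt: float) -> float:
    return float(np.interp(zt, CANONICAL_ZT, curve))


def prepare_fit_init(
    y_ave: np.ndarray, onset_hint: float, peak_hint: float, modality: str
) -> FitInit:
    """Derive Gaussian-fit initial values and bounds from the mean curve.

    Local maxima (4-neighbour rule) seed the peak phases; the evening peak
    is the first maximum at or after the onset hint, the second peak the
    next one after it, and a maximum before onset (early morning) counts as
    the third peak.  When the curve has only two peaks the third-peak value
    m3 is zero and its amplitude is pinned at zero.
    """
    y = np.asarray(y_ave, dtype=float)
    maxima_zt = [float(CANONICAL_ZT[i]) for i in find_local_maxima(y)]
    y_min = float(y.min())

    peak1 = float(peak_hint)
    after = [z for z in maxima_zt if z > peak1 + 0.5]
    before = [z for z in maxima_zt if z < onset_hint - 0.5]
    peak2 = after[0] if after else None
    peak3 = before[0] if before else None

    if peak2 is None:
        m2 = 0.0
        peak2_init = min(peak1 + 6.0, float(CANONICAL_ZT[-1]))
    else:
        m2 = _grid_value(y, peak2)
        peak2_init = peak2
    if peak3 is None:
        m3 = 0.0
        peak3_init = float(CANONICAL_ZT[0])
    else:
        m3 = _grid_value(y, peak3)
        peak3_init = peak3

    # transition segment values fix the first-peak amplitude
    onset_seg = y[(CANONICAL_ZT >= CANONICAL_ZT[0]) & (CANONICAL_ZT <= peak1)]
    a1_fixed = float(onset_seg.max() - onset_seg.min())

    if modality == "food_intake":
        off_init, off_lo, off_hi = 0.05, 0.0, 0.15
    else:
        off_init, off_lo, off_hi = 750.0, 0.0, max(float(y.max()), 1.0)
    off_init = float(np.clip(off_init, off_lo, off_hi))

    a5_hi = max(10.0 * (m2 - y_min), 0.0)
    a9_hi = max(10.0 * (m3 - y_min), 0.0) if m3 > 0 else 0.0

    # parameter vector: a2, a4(offset), a5, a6, a7, a9, a10, a11(centre)
    x0 = np.array([
        2.0,
        off_init,
        min(max(m2 - y_min, 0.0), a5_hi) if a5_hi > 0 else 0.0,
        2.0,
        peak2_init,
        min(max(m3 - y_min, 0.0), a9_hi) if a9_hi > 0 else 0.0,
        2.0,
        peak3_init,
    ])
    lower = np.array([
        MIN_WIDTH, off_lo, 0.0, MIN_WIDTH, peak2_init - 3.0,
        0.0, MIN_WIDTH, peak3_init - 3.0,
    ])
    upper = np.array([
        4.0, off_hi, max(a5_hi, MIN_WIDTH), 4.0, peak2_init + 3.0,
        max(a9_hi, 1e-12), 4.0, peak3_init + 3.0,
    ])
    x0 = np.clip(x0, lower, upper)
    return FitInit(
        zt_peak1=peak1, zt_peak2=peak2, zt_peak3=peak3, m2=m2, m3=m3,
        a1_fixed=a1_fixed, x0=x0, lower=lower, upper=upper,
        names=("a2", "a4", "a5", "a6", "a7", "a9", "a10", "a11"),
    )


def _gauss_superposition(t, a):
    """Baseline a4 plus the three bumps (offsets a8 = a12 = a4 shared)."""
    return (
        a[3]
        + _bump(a[0], a[1], a[2], t)
        + _bump(a[4], a[5], a[6], t)
        + _bump(a[8], a[9], a[10], t)
    )


def fit_template(
    y_ave: np.ndarray,
    onset_hint: float,
    peak_hint: float,
    modality: str = "activity",
    centre: str = "SIM",
    dt: float = DEFAULT_DT,
) -> TemplateParams:
    """Fit the standard template to a complete 25-point mean curve.

    The transition segment [t1, t3] is fitted by least squares over the
    relaxation rate eps (heights h1, h2, h3 are read off the data at t1,
    t2 = onset_hint - 1 and t3 = peak_hint); the remainder (t > t3) is
    fitted by bounded least squares over the Gaussian parameters with the
    first-peak amplitude and phase pinned to the data.
    """
    y = np.asarray(y_ave, dtype=float)
    if y.shape != (N_GRID,) or np.any(np.isnan(y)):
        raise ValueError("y_ave must be a complete 25-point curve")
    t1 = float(CANONICAL_ZT[0])
    t2 = float(onset_hint) - 1.0
    t3 = float(peak_hint)
    if not (t1 < t2 < t3):
        raise ValueError("hints must satisfy t1 < onset-1 < peak")

    h1 = _grid_value(y, t1)
    h2 = _grid_value(y, t2)
    h3 = _grid_value(y, t3)

    trans_mask = CANONICAL_ZT <= t3 + 1e-9
    t_trans = CANONICAL_ZT[trans_mask]
    y_trans = y[trans_mask]

    def sse(eps):
        times, x = integrate_switch(eps, t1, t2, t3, h1, h2, h3, dt=dt)
        pred = np.interp(t_trans, times, x)
        return float(np.sum((pred - y_trans) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-3, 20.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise FitFailureError("transition fit diverged", residual=float(res.fun))
    eps = float(res.x)

    init = prepare_fit_init(y, onset_hint, peak_hint, modality)
    rem_mask = CANONICAL_ZT > t3 + 1e-9
    t_rem = CANONICAL_ZT[rem_mask]
    y_rem = y[rem_mask]

    def unpack(theta):
        a2, a4, a5, a6, a7, a9, a10, a11 = theta
        return np.array([
            init.a1_fixed, a2, init.zt_peak1, a4,
            a5, a6, a7, a4,
            a9, a10, a11, a4,
        ])

    def residuals(theta):
        return _gauss_superposition(t_rem, unpack(theta)) - y_rem

    ls = optimize.least_squares(
        residuals, init.x0, bounds=(init.lower, init.upper),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not ls.success or not np.all(np.isfinite(ls.x)):
        raise FitFailureError(
            "Gaussian remainder fit failed", residual=float(np.sum(ls.fun ** 2))
        )
    gauss = unpack(ls.x)
    return TemplateParams(
        centre=centre, modality=modality,
        t1=t1, t2=t2, t3=t3, h1=h1, h2=h2, h3=h3, eps=eps,
        gauss=gauss, m3=init.m3,
    )


def template_curve(template: TemplateParams, dt: float = DEFAULT_DT) -> np.ndarray:
    """Noiseless standard curve implied by a template (25 points)."""
    times, x = integrate_switch(
        template.eps, template.t1, template.t2, template.t3,
        template.h1, template.h2, template.h3, dt=dt,
    )
    pre = CANONICAL_ZT <= template.t3 + 1e-9
    out = np.empty(N_GRID)
    out[pre] = np.interp(CANONICAL_ZT[pre], times, x)
    out[~pre] = _gauss_superposition(CANONICAL_ZT[~pre], template.gauss)
    return out


def canonical_template(modality: str = "activity", centre: str = "SIM") -> TemplateParams:
    """A built-in wild-type-like template for simulation without raw data.

    Heights are made self-consistent with the transition ODE (h2 and h3
    equal the integrated solution at t2 and t3, as they would when read
    off a real mean curve), so that a template fitted back to its own
    noiseless curve recovers the same parameters.  Scales are typical of
    group-housed male mice in metabolic cages: activity peaks near
    2000 counts/hr, food intake near 0.45 g/hr.
    """
    if modality == "activity":
        h1, h2, h3 = 1000.0, 1500.0, 2600.0
        eps = 0.8
        a5, a6, a7 = 400.0, 2.0, 22.0
        a9, a10 = 120.0, 1.5
    elif modality == "food_intake":
        h1, h2, h3 = 0.15, 0.22, 0.45
        eps = 0.7
        a5, a6, a7 = 0.10, 2.0, 22.0
        a9, a10 = 0.03, 1.5
    else:
        raise ValueError(f"unknown modality {modality!r}")
    t1, t2, t3 = 6.0, 11.0, 13.0

    # fixed point (damped): heights read off the curve equal those driving
    # it, so a template refitted to its own noiseless curve round-trips
    for _ in range(500):
        times, x = integrate_switch(eps, t1, t2, t3, h1, h2, h3)
        h2_new = float(np.interp(t2, times, x))
        h3_new = float(x[-1])
        if abs(h2_new - h2) < 1e-10 * max(h2, 1e-9) and \
                abs(h3_new - h3) < 1e-10 * max(h3, 1e-9):
            break
        h2 += 0.5 * (h2_new - h2)
        h3 += 0.5 * (h3_new - h3)
    times, x = integrate_switch(eps, t1, t2, t3, h1, h2, h3)
    a4 = float(x[0])                 # baseline = first transition value
    a1 = float(x.max() - x[0])       # evening-peak amplitude
    gauss = np.array([a1, 2.5, t3, a4, a5, a6, a7, a4, a9, a10, t1 + 0.5, a4])
    return TemplateParams(
        centre=centre, modality=modality,
        t1=t1, t2=t2, t3=t3, h1=h1, h2=h2, h3=h3, eps=eps,
        gauss=gauss, m3=a9 + a4,
    )


# ---------------------------------------------------------------------------
# Randomized curve generation
# ---------------------------------------------------------------------------

def sample_sim_params(
    template: TemplateParams,
    rng: np.random.Generator,
    noise_scale: float = 0.05,
    t2: float | None = None,
    delta_t: float | None = None,
    dt: float = DEFAULT_DT,
) -> SimParams:
    """Draw one randomized parameter set from a template.

    Distributions (all uniform): t2 ~ U(9, 13); delta_t = t3 - t2 ~ U(0, 3)
    resampled until >= 1 h so the onset label (t2 + 1) never exceeds the
    peak label; height multipliers zeta_h3 ~ U(0.5, 1.5),
    zeta_h2 ~ U(0.2, 0.9), zeta_h1 ~ U(1, 1.2) (h1 = h2 / zeta_h1);
    zeta_eps ~ U(0.8, 1.2).  Gaussian parameters follow the transition
    solution y1: a4 = y1 at t1, a1 = max(y1) - y1 at t1; the first-peak
    width is the larger of U(2, 3) and U(0, 3) x (t3 - t_mid) where t_mid
    is when y1 first crosses (h2 + h3)/2; a5 = U(0.8, 1.2) x a1;
    a6, a10 = U(0.8, 1.2) x template widths; a7 = template phase + U(-1, 2);
    a9 = max(0, U(0.5, 1.5) x (a4 + a1) - a4); the third bump sits at
    t1 + U(0, 1).  `t2`/`delta_t` overrides replace the corresponding draw
    (used for engineered phase-shift fixtures); the random stream is
    consumed identically either way.
    """
    d_t2 = rng.uniform(9.0, 13.0)
    d_dt = rng.uniform(0.0, 3.0)
    while d_dt < 1.0:
        d_dt = rng.uniform(0.0, 3.0)
    t2v = d_t2 if t2 is None else float(t2)
    dtv = d_dt if delta_t is None else float(delta_t)
    if dtv < 1.0:
        raise ValueError("delta_t override must be >= 1 h")
    t3v = t2v + dtv

    h3 = rng.uniform(0.5, 1.5) * template.h3
    h2 = rng.uniform(0.2, 0.9) * h3
    h1 = h2 / rng.uniform(1.0, 1.2)
    eps = rng.uniform(0.8, 1.2) * template.eps

    times, y1 = integrate_switch(eps, template.t1, t2v, t3v, h1, h2, h3, dt=dt)
    a4 = float(y1[0])
    a1 = float(y1.max() - y1[0])

    y_mid = 0.5 * (h2 + h3)
    crossed = np.flatnonzero(y1 >= y_mid)
    t_width0 = t3v - float(times[crossed[0]]) if crossed.size else 0.0
    tw1 = rng.uniform(0.0, 3.0) * t_width0
    tw2 = rng.uniform(2.0, 3.0)
    a2 = max(tw1, tw2)

    a5 = rng.uniform(0.8, 1.2) * a1
    a6 = rng.uniform(0.8, 1.2) * template.gauss[5]
    a7 = template.gauss[6] + rng.uniform(-1.0, 2.0)
    a9 = max(0.0, rng.uniform(0.5, 1.5) * (a4 + a1) - a4)
    a10 = rng.uniform(0.8, 1.2) * template.gauss[9]
    t_peak3 = template.t1 + rng.uniform(0.0, 1.0)

    a = np.array([a1, a2, t3v, a4, a5, a6, a7, a4, a9, a10, t_peak3, a4])
    return SimParams(
        t1=template.t1, t2=t2v, t3=t3v, h1=h1, h2=h2, h3=h3, eps=eps,
        a=a, t_peak3=t_peak3, noise_scale=noise_scale,
        ode_times=times, ode_values=y1,
    )


def synthesize_curve(
    params: SimParams, rng: np.random.Generator | None = None, dt: float = DEFAULT_DT
) -> LabelledCurve:
    """Render a 25-point labelled curve from one parameter draw.

    Values at ZT <= t3 come from the transition ODE, values after t3 from
    the Gaussian superposition; white noise with s.d.
    noise_scale x max(curve) is added on top.  Labels: onset = t2 + 1,
    peak = t3.
    """
    if params.ode_times is not None:
        times, y1 = params.ode_times, params.ode_values
    else:
        times, y1 = integrate_switch(
            params.eps, params.t1, params.t2, params.t3,
            params.h1, params.h2, params.h3, dt=dt,
        )
    pre = CANONICAL_ZT <= params.t3 + 1e-9
    values = np.empty(N_GRID)
    values[pre] = np.interp(CANONICAL_ZT[pre], times, y1)
    values[~pre] = _gauss_superposition(CANONICAL_ZT[~pre], params.a)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("curve synthesis produced non-finite values")

    if params.noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, params.noise_scale * values.max(), N_GRID)

    return LabelledCurve(
        values=values,
        onset_label=params.t2 + 1.0,
        peak_label=params.t3,
    )


def generate_training_set(
    template: TemplateParams,
    n: int,
    seed: int,
    noise_scale: float = 0.05,
) -> list[LabelledCurve]:
    """Draw `n` independent labelled curves (reproducible under `seed`)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = sample_sim_params(template, rng, noise_scale=noise_scale)
        out.append(synthesize_curve(p, rng))
    return out


def curves_to_arrays(curves, normalize: bool = True):
    """Stack labelled curves into (X, y): X is n x 25, y is n x 2 (onset, peak).

    With `normalize`, each row of X is min-max scaled to [0, 1] — the same
    convention the QC pipeline applies to measured curves.
    """
    from .ic_data import minmax_scale

    X = np.vstack([c.values for c in curves])
    y = np.array([[c.onset_label, c.peak_label] for c in curves])
    if normalize:
        X = minmax_scale(X)
    return X.astype(np.float32), y.astype(np.float32)


def save_training_set(path, curves, template: TemplateParams | None = None, **meta):
    """Serialize curves + labels (and generator metadata) to one .npz file."""
    import json

    X = np.vstack([c.values for c in curves])
    y = np.array([[c.onset_label, c.peak_label] for c in curves])
    info = dict(meta)
    if template is not None:
        info["template"] = {
            "centre": template.centre, "modality": template.modality,
            "t1": template.t1, "t2": template.t2, "t3": template.t3,
            "h1": template.h1, "h2": template.h2, "h3": template.h3,
            "eps": template.eps, "gauss": list(map(float, template.gauss)),
            "m3": template.m3,
        }
    np.savez_compressed(path, curves=X, labels=y, meta=json.dumps(info))


def load_training_set(path):
    """Inverse of `save_training_set`: returns (curves, labels, meta dict)."""
    import json

    with np.load(path, allow_pickle=False) as z:
        X = z["curves"]
        y = z["labels"]
        meta = json.loads(str(z["meta"]))
    return X, y, meta
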