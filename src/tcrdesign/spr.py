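"""Surface plasmon resonance binding analysis.

Two fitting modes cover the standard workflows:

* Steady-state 1:1 Langmuir equilibrium: R(C) = Rmax C / (KD + C), fit by
  nonlinear least squares to plateau responses over a concentration series.
* Single-cycle kinetic titration: sequential analyte injections without
  surface regeneration, fit globally to the 1:1 association model with a
  linear baseline drift. Within each constant-concentration segment the
  model dR/dt = kon C (Rmax - R) - koff R is linear, so the simulator uses
  the exact piecewise-exponential solution; no numerical integrator is
  involved.

The simulator doubles as the synthetic-data generator for parameter
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares


@dataclass(frozen=True)
class Injection:
    start: float        # s
    stop: float         # s
    concentration: float  # M

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError("injection stop must follow start")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")


@dataclass(frozen=True)
class InjectionSchedule:
    injections: tuple[Injection, ...]
    end_time: float     # end of the final dissociation phase, s

    def __post_init__(self):
        prev = -np.inf
        for inj in self.injections:
            if inj.start < prev:
                raise ValueError("injections must be ordered and non-overlapping")
            prev = inj.stop
        if self.end_time < prev:
            raise ValueError("end_time precedes the final injection")

    @classmethod
    def titration(cls, concentrations, contact_time: float = 120.0,
                  final_dissociation: float = 600.0) -> "InjectionSchedule":
        """Back-to-back titration series (single-cycle kinetics layout)."""
        injections = []
        t = 0.0
        for c in concentrations:
            injections.append(Injection(t, t + contact_time, float(c)))
            t += contact_time
        return cls(tuple(injections), end_time=t + final_dissociation)


@dataclass(frozen=True)
class KineticParams:
    kon: float          # 1/(M s)
    koff: float         # 1/s
    rmax: float         # RU
    drift: float = 0.0  # RU/s
    r0: float = 0.0     # RU

    def __post_init__(self):
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise ValueError("kon, koff and rmax must be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class Sensorgram:
    time: np.ndarray        # s, strictly increasing
    response: np.ndarray    # RU
    schedule: InjectionSchedule

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")


# ---------------------------------------------------------------------------
# Steady-state equilibrium fit
# ---------------------------------------------------------------------------

def langmuir(c, kd, rmax):
    """1:1 Langmuir equilibrium response."""
    c = np.asarray(c, dtype=float)
    return rmax * c / (kd + c)


def steady_state_fit(concentrations, responses) -> dict:
    """Fit R(C) = Rmax C / (KD + C) by nonlinear least squares.

    Returns {"kd", "rmax", "kd_se", "rmax_se"}; concentrations in the input
    units (KD comes back in the same units).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    p0 = (np.median(c), max(r.max(), 1e-9) * 1.5)
    try:
        popt, pcov = curve_fit(langmuir, c, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"steady-state fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    return {"kd": float(popt[0]), "rmax": float(popt[1]),
            "kd_se": float(se[0]), "rmax_se": float(se[1])}


# ---------------------------------------------------------------------------
# Kinetic simulation (piecewise-analytic 1:1 model)
# ---------------------------------------------------------------------------

def _binding_response(t: np.ndarray, params: KineticParams,
                      schedule: InjectionSchedule) -> np.ndarray:
    """Exact solution of dR/dt = kon C(t) (Rmax - R) - koff R, R(0)=0."""
    edges: list[tuple[float, float]] = []       # (segment start, concentration)
    t_cursor = 0.0
    for inj in schedule.injections:
        if inj.start > t_cursor:
            edges.append((t_cursor, 0.0))
        edges.append((inj.start, inj.concentration))
        t_cursor = inj.stop
    edges.append((t_cursor, 0.0))

    out = np.empty_like(t)
    r_seg = 0.0
    for k, (t0, conc) in enumerate(edges):
        t1 = edges[k + 1][0] if k + 1 < len(edges) else np.inf
        rate = params.kon * conc + params.koff
        req = params.kon * conc * params.rmax / rate if rate > 0 else 0.0
        mask = (t >= t0) & (t < t1)
        out[mask] = req + (r_seg - req) * np.exp(-rate * (t[mask] - t0))
        if np.isfinite(t1):
            r_seg = req + (r_seg - req) * np.exp(-rate * (t1 - t0))
    return out


def simulate_sensorgram(params: KineticParams, schedule: InjectionSchedule,
                        noise_sd: float = 0.0, seed: int | None = None,
                        dt: float = 1.0) -> Sensorgram:
    """Simulate a single-cycle sensorgram: binding + baseline + drift + noise.

    Deterministic for a fixed seed; the binding signal is the exact
    piecewise-exponential solution of the 1:1 model.
    """
    t = np.arange(0.0, schedule.end_time + dt / 2, dt)
    r = _binding_response(t, params, schedule)
    r = r + params.r0 + params.drift * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=t.shape)
    return Sensorgram(time=t, response=r, schedule=schedule)


# ---------------------------------------------------------------------------
# Kinetic titration fit
# ---------------------------------------------------------------------------

def _initial_estimates(gram: Sensorgram) -> KineticParams:
    """Deterministic starting point: koff from the terminal dissociation
    log-slope, kon from the first-injection initial slope."""
    t, r = gram.time, gram.response
    last_stop = gram.schedule.injections[-1].stop
    tail = (t > last_stop + 5.0)
    koff = 1e-3
    if tail.sum() >= 5:
        rt = r[tail] - r[tail].min() + 1e-6
        slope = np.polyfit(t[tail], np.log(np.clip(rt, 1e-9, None)), 1)[0]
        koff = float(np.clip(-slope, 1e-5, 10.0))
    first = gram.schedule.injections[0]
    inj_mask = (t >= first.start) & (t <= first.stop)
    rmax0 = max(float(r.max() - r.min()), 1.0) * 1.5
    kon = 1e5
    if inj_mask.sum() >= 3:
        dr = np.gradient(r[inj_mask], t[inj_mask])
        kon = float(np.clip(dr[: max(3, len(dr) // 4)].mean() /
                            (first.concentration * rmax0), 1e2, 1e9))
    return KineticParams(kon=kon, koff=koff, rmax=rmax0,
                         drift=0.0, r0=float(r[0]))


def kinetic_titration_fit(gram: Sensorgram,
                          p0: KineticParams | None = None) -> dict:
    """Global fit of the 1:1 kinetic titration model with drift.

    Optimizes (log kon, log koff, log Rmax, drift, r0) by least squares over
    the whole single-cycle trace. Returns the fitted KineticParams plus
    KD = koff/kon, residual RMS, and asymptotic standard errors.
    """
    if len(gram.schedule.injections) < 2:
        raise ValueError("kinetic titration needs at least 2 injections")
    p0 = p0 or _initial_estimates(gram)
    x0 = np.array([np.log(p0.kon), np.log(p0.koff), np.log(p0.rmax),
                   p0.drift, p0.r0])

    def model(x):
        params = KineticParams(kon=np.exp(x[0]), koff=np.exp(x[1]),
                               rmax=np.exp(x[2]), drift=x[3], r0=x[4])
        return (_binding_response(gram.time, params, gram.schedule)
                + params.r0 + params.drift * gram.time)

    def resid(x):
        return model(x) - gram.response

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"kinetic fit did not converge: {sol.message}")
    jac = sol.jac
    jtj = jac.T @ jac
    if np.linalg.cond(jtj) > 1e14:
        raise RuntimeError("kinetic fit is non-identifiable (flat gradient)")
    dof = max(len(gram.time) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.diag(cov))
    params = KineticParams(kon=float(np.exp(sol.x[0])),
                           koff=float(np.exp(sol.x[1])),
                           rmax=float(np.exp(sol.x[2])),
                           drift=float(sol.x[3]), r0=float(sol.x[4]))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return {"params": params, "kd": params.kd, "residual_rms": rms,
            "se_log_kon": float(se[0]), "se_log_koff": float(se[1]),
            "se_log_rmax": float(se[2]), "se_drift": float(se[3]),
            "se_r0": float(se[4])}
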