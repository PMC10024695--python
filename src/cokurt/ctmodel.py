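"""Coupled corticothalamic mean-field model with state-dependent noise.

Two identical mean-field models, each comprising cortical excitatory (e) and
inhibitory (i) populations and thalamic relay (s) and reticular (r)
populations.  Dendritic potentials follow second-order synaptic dynamics

    (1/(alpha beta) d2/dt2 + (1/alpha + 1/beta) d/dt + 1) V_a = sum nu φ,

potentials convert to firing rates through the sigmoid
Q(V) = Qmax / (1 + exp(-(V - theta)/sigma)), and the cortical rate is
additionally damped by a second-order wave operator with rate gamma_e
(φ_a = Q_a for the i, r, s populations, whose damping rate is effectively
infinite).  Corticothalamic propagation is delayed by tau in each direction.

The thalamic relay population receives the external drive

    φ_n(t) = φ_n0 + ξ_m(t) + chi · ξ_j(t) · φ_e(t - tau),

with ξ_m, ξ_j i.i.d. Gaussian per integration step (SD ``noise_sd``).  The
multiplicative term (weight ``chi``) makes the noise state-dependent: near the
subcritical Hopf bifurcation of the thalamocortical loop it drives switching
between low-amplitude linear fluctuations and high-amplitude limit-cycle
oscillations — alpha-band bursts.  Coupling two models through their
excitatory populations (additive, delayed) synchronizes these bursts, which
is what the cokurtosis statistic detects.

Integration is Euler-Maruyama at dt = 1e-4 s (smaller than the delay), with
the inner loop compiled by numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize

__all__ = [
    "CTParams",
    "SimOutput",
    "PARAMETER_SETS",
    "default_params",
    "sigmoid",
    "fixed_point",
    "simulate_pair",
    "sweep",
    "sweep_with_null",
    "decimate_traces",
    "analytic_pair",
]


@dataclass
class CTParams:
    """Corticothalamic model parameters (SI units; potentials in mV)."""

    alpha: float = 50.0       # synaptic decay rate (1/s)
    beta: float = 200.0       # synaptic rise rate (1/s)
    gamma_e: float = 100.0    # cortical damping rate (1/s)
    qmax: float = 250.0       # maximum firing rate (1/s)
    theta: float = 15.0       # firing threshold (mV)
    sigma: float = 3.3        # threshold spread (mV)
    tau: float = 0.04         # one-way corticothalamic delay (s)
    nu_ee: float = 1.2        # connection strengths (mV s)
    nu_ei: float = -1.8
    nu_es: float = 1.35       # thalamocortical gain: working point near the Hopf onset (~1.5)
    nu_se: float = 1.2
    nu_sr: float = -0.8
    nu_re: float = 0.4
    nu_rs: float = 0.2
    nu_sn: float = 0.5
    phi_n0: float = 0.5       # mean external drive (1/s)
    noise_sd: float = 0.1     # SD of the additive/multiplicative noise draws
    noise_scaling: str = "sqrt_dt"  # "sqrt_dt": per-step SD = noise_sd/sqrt(dt) (white-noise
                                    # Euler-Maruyama convention); "per_step": SD used as-is
    chi: float = 0.0          # state-dependent noise balance
    dt: float = 1e-4          # integration step (s)
    wave_damping: float = 1.0 # first-order coefficient of the wave operator, in 1/gamma units

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma_e", "qmax", "sigma", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.noise_scaling not in ("sqrt_dt", "per_step"):
            raise ValueError("noise_scaling must be 'sqrt_dt' or 'per_step'")
        steps = self.tau / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("tau must be an integer multiple of dt")

    @property
    def delay_steps(self) -> int:
        return int(round(self.tau / self.dt))


#: named, version-controlled parameter registry; "corticothalamic-eyes-closed"
#: is the standard eyes-closed mean-field set with the thalamocortical gain
#: nu_es raised to place the model near its subcritical Hopf bifurcation.
PARAMETER_SETS: dict[str, CTParams] = {
    "corticothalamic-eyes-closed": CTParams(),
}


def default_params(name: str = "corticothalamic-eyes-closed", **overrides) -> CTParams:
    """Fetch a registry parameter set, optionally overriding fields."""
    base = PARAMETER_SETS[name]
    return replace(base, **overrides) if overrides else replace(base)


def sigmoid(v, qmax: float = 250.0, theta: float = 15.0, sigma: float = 3.3):
    """Firing-rate sigmoid Q(V) = Qmax / (1 + exp(-(V - theta)/sigma))."""
    v = np.asarray(v, dtype=float)
    out = qmax / (1.0 + np.exp(-(v - theta) / sigma))
    return float(out) if out.ndim == 0 else out


def fixed_point(params: CTParams, coupling: float = 0.0) -> dict[str, float]:
    """Noise-free steady state of the symmetric coupled system.

    Solves the algebraic equations obtained by dropping all time derivatives,
    with both models at the same state (symmetric fixed point).  Returns the
    steady potentials and the cortical firing rate.
    """
    p = params

    def q(v):
        return sigmoid(v, p.qmax, p.theta, p.sigma)

    def residual(v):
        ve, vr, vs = v
        phie = q(ve)
        r_e = (p.nu_ee + coupling) * phie + p.nu_ei * q(ve) + p.nu_es * q(vs) - ve
        r_r = p.nu_re * phie + p.nu_rs * q(vs) - vr
        r_s = p.nu_se * phie + p.nu_sr * q(vr) + p.nu_sn * p.phi_n0 - vs
        return [r_e, r_r, r_s]

    sol = optimize.fsolve(residual, x0=[0.0, 0.0, 0.0], full_output=True)
    x, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"fixed-point solve failed: {msg}")
    ve, vr, vs = x
    return {"ve": float(ve), "vr": float(vr), "vs": float(vs), "phi_e": q(float(ve))}


@njit(cache=True)
def _simulate_kernel(
    n_steps, dt, d,
    alpha, beta, gamma, qmax, theta, sigma,
    nu_ee, nu_ei, nu_es, nu_se, nu_sr, nu_re, nu_rs, nu_sn,
    phi_n0, chi, coupling, wave_damping,
    ve0, vr0, vs0, phie0,
    noise_m, noise_j,
    out_phie,
):  # pragma: no cover - compiled
    ab = alpha * beta
    apb = alpha + beta
    g2 = gamma * gamma

    ve = np.array([ve0, ve0])
    vr = np.array([vr0, vr0])
    vs = np.array([vs0, vs0])
    dve = np.zeros(2)
    dvr = np.zeros(2)
    dvs = np.zeros(2)
    phie = np.array([phie0, phie0])
    dphie = np.zeros(2)

    # circular delay buffers for phi_e and phi_s per model
    buf_e = np.empty((2, d))
    buf_s = np.empty((2, d))
    qs0 = qmax / (1.0 + np.exp(-(vs0 - theta) / sigma))
    for m in range(2):
        for k in range(d):
            buf_e[m, k] = phie0
            buf_s[m, k] = qs0
    head = 0

    for t in range(n_steps):
        # delayed rates (d steps ago); head currently points at the oldest entry
        e_del0 = buf_e[0, head]
        e_del1 = buf_e[1, head]
        s_del0 = buf_s[0, head]
        s_del1 = buf_s[1, head]
        e_del = (e_del0, e_del1)
        s_del = (s_del0, s_del1)

        for m in range(2):
            other = 1 - m
            qe = qmax / (1.0 + np.exp(-(ve[m] - theta) / sigma))
            qr = qmax / (1.0 + np.exp(-(vr[m] - theta) / sigma))
            qs = qmax / (1.0 + np.exp(-(vs[m] - theta) / sigma))

            phi_n = phi_n0 + noise_m[m, t] + chi * noise_j[m, t] * e_del[m]

            ie = nu_ee * phie[m] + nu_ei * qe + nu_es * s_del[m] + coupling * e_del[other]
            ir = nu_re * e_del[m] + nu_rs * qs
            is_ = nu_se * e_del[m] + nu_sr * qr + nu_sn * phi_n

            d2ve = ab * (ie - ve[m]) - apb * dve[m]
            d2vr = ab * (ir - vr[m]) - apb * dvr[m]
            d2vs = ab * (is_ - vs[m]) - apb * dvs[m]
            d2phie = g2 * (qe - phie[m]) - wave_damping * gamma * dphie[m]

            ve[m] += dt * dve[m]
            dve[m] += dt * d2ve
            vr[m] += dt * dvr[m]
            dvr[m] += dt * d2vr
            vs[m] += dt * dvs[m]
            dvs[m] += dt * d2vs
            phie[m] += dt * dphie[m]
            dphie[m] += dt * d2phie

            # write the NEW rates into the slot we just consumed
            buf_e[m, head] = phie[m]
            qs_new = qmax / (1.0 + np.exp(-(vs[m] - theta) / sigma))
            buf_s[m, head] = qs_new

            out_phie[m, t] = phie[m]
            # physical phi_e is bounded by Qmax (~250/s); far larger values
            # mean the discretization has gone unstable
            if not np.isfinite(phie[m]) or abs(phie[m]) > 1e6:
                return t
        head += 1
        if head == d:
            head = 0
    return n_steps


@dataclass
class SimOutput:
    """Simulated firing-rate traces of the two coupled models."""

    phi_e: np.ndarray        # (2, samples) at dt resolution, burn-in removed
    fs: float
    duration: float
    burn_in: float
    seed: int
    params: CTParams = field(repr=False, default=None)


def simulate_pair(
    params: CTParams | None = None,
    coupling: float = 0.0,
    chi: float | None = None,
    duration: float = 60.0,
    burn_in: float = 5.0,
    seed: int = 0,
) -> SimOutput:
    """Integrate the two coupled models and return their phi_e traces.

    ``coupling`` is the additive, tau-delayed inter-model gain (mV s) feeding
    each model's excitatory population with the other model's phi_e.  ``chi``
    overrides ``params.chi`` when given.  Burn-in is discarded.
    """
    p = params if params is not None else default_params()
    if chi is not None:
        p = replace(p, chi=chi)
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    n_steps = int(round((duration) / p.dt))
    n_burn = int(round(burn_in / p.dt))
    d = max(p.delay_steps, 1)

    rng = np.random.default_rng(seed)
    step_sd = p.noise_sd / np.sqrt(p.dt) if p.noise_scaling == "sqrt_dt" else p.noise_sd
    noise_m = rng.normal(0.0, step_sd, size=(2, n_steps))
    noise_j = rng.normal(0.0, step_sd, size=(2, n_steps))

    fp = fixed_point(p, coupling=coupling)
    out = np.empty((2, n_steps))
    done = _simulate_kernel(
        n_steps, p.dt, d,
        p.alpha, p.beta, p.gamma_e, p.qmax, p.theta, p.sigma,
        p.nu_ee, p.nu_ei, p.nu_es, p.nu_se, p.nu_sr, p.nu_re, p.nu_rs, p.nu_sn,
        p.phi_n0, p.chi, coupling, p.wave_damping,
        fp["ve"], fp["vr"], fp["vs"], fp["phi_e"],
        noise_m, noise_j,
        out,
    )
    if done < n_steps:
        raise RuntimeError(
            f"integration diverged at t={done * p.dt:.3f}s "
            f"(chi={p.chi}, coupling={coupling}, nu_es={p.nu_es})"
        )
    return SimOutput(
        phi_e=out[:, n_burn:],
        fs=1.0 / p.dt,
        duration=duration - burn_in,
        burn_in=burn_in,
        seed=seed,
        params=p,
    )


def decimate_traces(data: np.ndarray, fs: float, target_fs: float = 200.0):
    """Stage-wise FIR decimation of raw phi_e traces to ~target_fs.

    Returns ``(data, fs)``; decimation factors are kept <= 10 per stage.
    """
    from scipy import signal as sps

    data = np.atleast_2d(np.asarray(data, dtype=float))
    q_left = int(round(fs / target_fs))
    while q_left > 1:
        q = 10 if q_left % 10 == 0 else (5 if q_left % 5 == 0 else q_left)
        q = min(q, q_left)
        data = sps.decimate(data, q, ftype="fir", axis=-1)
        fs /= q
        q_left //= q
    return data, fs


def analytic_pair(
    data: np.ndarray,
    fs: float,
    center: float = 10.0,
    edge_trim_s: float = 2.0,
) -> np.ndarray:
    """Band-limited analytic signals of decimated traces, edges trimmed.

    ``edge_trim_s`` seconds are dropped at both ends after filtering: the
    forward-backward filter and Hilbert transform leave edge transients that
    are shared across channels and would otherwise inflate envelope
    correlations of weak signals.
    """
    from .spectral import TimeSeriesSet, analytic_band

    tf = analytic_band(TimeSeriesSet(data=data, fs=fs), center=center, decimate_by=5)
    n_trim = int(round(edge_trim_s * tf.fs))
    return tf.coeffs[:, n_trim : tf.coeffs.shape[1] - n_trim or None]


def _alpha_band_pair(sim: SimOutput, center: float = 10.0, target_fs: float = 200.0):
    data, fs = decimate_traces(sim.phi_e, sim.fs, target_fs)
    return analytic_pair(data, fs, center=center)


def sweep(
    chi_grid,
    coupling_grid,
    params: CTParams | None = None,
    duration: float = 60.0,
    burn_in: float = 5.0,
    reps: int = 1,
    seed: int = 0,
    center: float = 10.0,
) -> dict[str, np.ndarray]:
    """Power correlation, |coherence|^2 and cokurtosis over a (chi, coupling) grid.

    Per cell, ``reps`` independent simulations; statistics are computed on the
    alpha-band analytic signals of the two phi_e traces and averaged over
    repetitions.  Returns arrays of shape (len(chi_grid), len(coupling_grid)).
    """
    from . import hos

    p = params if params is not None else default_params()
    chi_grid = np.asarray(chi_grid, dtype=float)
    coupling_grid = np.asarray(coupling_grid, dtype=float)
    shape = (chi_grid.size, coupling_grid.size)
    r = np.zeros(shape)
    coh2 = np.zeros(shape)
    kxy = np.zeros(shape)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(shape[0] * shape[1] * reps).reshape(*shape, reps)
    for i, chi in enumerate(chi_grid):
        for j, c in enumerate(coupling_grid):
            acc = np.zeros(3)
            for k in range(reps):
                sim = simulate_pair(
                    p, coupling=float(c), chi=float(chi),
                    duration=duration, burn_in=burn_in,
                    seed=int(cell_seeds[i, j, k]) % (2**31),
                )
                x, y = _alpha_band_pair(sim, center=center)
                acc[0] += hos.power_correlation(x, y)
                acc[1] += abs(hos.coherence(x, y)) ** 2
                acc[2] += hos.cokurtosis(x, y)
            r[i, j], coh2[i, j], kxy[i, j] = acc / reps
    return {"power_corr": r, "coh_sq": coh2, "cokurtosis": kxy,
            "chi": chi_grid, "coupling": coupling_grid}


def sweep_with_null(
    chi_grid=(0.0, 0.15, 0.3),
    coupling_grid=(0.0, 0.025, 0.05),
    params: CTParams | None = None,
    duration: float = 65.0,
    burn_in: float = 5.0,
    reps: int = 3,
    n_surrogates: int = 5,
    seed: int = 0,
    center: float = 10.0,
) -> dict:
    """Rep-averaged (chi, coupling) sweep plus a Gaussian null for the chi=0 row.

    Per grid cell, ``reps`` independent simulations are analysed in the alpha
    band and the power correlation, |coherence|^2, cokurtosis and the
    decomposition terms are averaged.  For chi = 0 cells, each realization
    additionally yields ``n_surrogates`` jointly phase-randomized surrogates
    of the decimated traces — Gaussian processes with identical auto- and
    cross-spectra — whose cokurtosis estimates form the Monte-Carlo null band
    against which the observed chi = 0 cokurtosis is judged.
    """
    from . import hos
    from .networks import phase_randomize

    p = params if params is not None else default_params()
    chi_grid = np.asarray(chi_grid, dtype=float)
    coupling_grid = np.asarray(coupling_grid, dtype=float)
    shape = (chi_grid.size, coupling_grid.size)
    out = {k: np.zeros(shape) for k in
           ("power_corr", "coh_sq", "cokurtosis", "term_coh", "term_kur")}
    null_mean = np.full(shape, np.nan)
    null_sd = np.full(shape, np.nan)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(shape[0] * shape[1] * reps).reshape(*shape, reps)
    surr_rng = np.random.default_rng(ss.spawn(1)[0])
    for i, chi in enumerate(chi_grid):
        for j, c in enumerate(coupling_grid):
            acc = {k: 0.0 for k in out}
            null_vals = []
            for k in range(reps):
                sim = simulate_pair(
                    p, coupling=float(c), chi=float(chi),
                    duration=duration, burn_in=burn_in,
                    seed=int(cell_seeds[i, j, k]) % (2**31),
                )
                dec, fs = decimate_traces(sim.phi_e, sim.fs)
                x, y = analytic_pair(dec, fs, center=center)
                d = hos.decompose(x, y)
                acc["power_corr"] += hos.power_correlation(x, y)
                acc["coh_sq"] += abs(hos.coherence(x, y)) ** 2
                acc["cokurtosis"] += hos.cokurtosis(x, y)
                acc["term_coh"] += d.term_coherence
                acc["term_kur"] += d.term_cokurtosis
                if chi == 0.0:
                    for _ in range(n_surrogates):
                        xs, ys = analytic_pair(phase_randomize(dec, surr_rng), fs, center=center)
                        null_vals.append(hos.cokurtosis(xs, ys))
            for key in out:
                out[key][i, j] = acc[key] / reps
            if null_vals:
                null_mean[i, j] = np.mean(null_vals)
                null_sd[i, j] = np.std(null_vals, ddof=1)
    return {**out, "chi": chi_grid, "coupling": coupling_grid,
            "null_mean": null_mean, "null_sd": null_sd, "reps": reps}
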