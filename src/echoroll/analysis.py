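"""Post-hoc analysis battery for the echolocation model.

Covers: exponential step-response fitting of head trajectories (time
constants), steady-state mean squared error at the final iteration,
characterization of learned basis vectors by fitting Gaussian-windowed
linear FM sweeps (ILD, ITD, center frequency, sweep rate), pure-tone
probing of binaural units (best frequency, ILD and ITD tuning curves)
with monotonic / peaked / cyclic / flat classification, histogram
comparison (KL divergence, Bhattacharyya coefficient) and one-way ANOVA
with Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "StepFit",
    "BasisCharacterization",
    "TuningCurve",
    "ClassifyConfig",
    "fit_step_response",
    "steady_state_mse",
    "characterize_basis",
    "probe_pure_tones",
    "classify_tuning_curve",
    "compare_distributions",
    "effect_stats",
    "basis_cue_distributions",
]


# ---------------------------------------------------------------------------
# Step-response fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepFit:
    """Parameters of s(t) = A exp(-t / tau) + B fitted to a trajectory."""

    A: float
    B: float
    tau: float
    residual: float
    tau_at_bound: bool = False


_TAU_BOUNDS = (1e-3, 1e3)


def fit_step_response(trajectory, t=None) -> StepFit:
    """Fit s(t) = A exp(-t/tau) + B to an angle trajectory.

    ``t`` defaults to iterations 1..len(trajectory).  Nonlinear least
    squares with multi-start over initial time constants; the
    best-residual fit is returned.  The time constant tau measures the
    number of iterations to reduce the initial error by 63%.
    """
    y = np.asarray(trajectory, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 points to fit a step response")
    if np.ptp(y) == 0.0:
        raise ValueError("constant trajectory: step-response fit ill-posed")
    if t is None:
        t = np.arange(1, len(y) + 1, dtype=float)
    else:
        t = np.asarray(t, dtype=float)

    def model(tt, A, B, tau):
        return A * np.exp(-tt / tau) + B

    best = None
    for tau0 in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
        e = np.exp(-t / tau0)
        # linear pre-solve for A, B at fixed tau keeps starts cheap
        M = np.column_stack([e, np.ones_like(t)])
        (A0, B0), *_ = np.linalg.lstsq(M, y, rcond=None)
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=[A0, B0, tau0],
                bounds=([-np.inf, -np.inf, _TAU_BOUNDS[0]],
                        [np.inf, np.inf, _TAU_BOUNDS[1]]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        res = float(np.linalg.norm(y - model(t, *popt)))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError("step-response fit did not converge from any start")
    (A, B, tau), res = best
    at_bound = bool(tau > 0.99 * _TAU_BOUNDS[1] or tau < 1.01 * _TAU_BOUNDS[0])
    return StepFit(float(A), float(B), float(tau), res, at_bound)


def steady_state_mse(final_directions, reference_mse: float | None = None):
    """Mean squared error of the final target directions.

    ``final_directions`` is an (N, 2) array-like of (horizontal,
    elevation) at the final iteration; MSE = mean(h^2 + e^2).  If a
    reference MSE (the sigma = 0 condition) is given, the normalized MSE
    is returned as well.
    """
    d = np.asarray(final_directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("final_directions must be (N, 2)")
    mse = float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
    if reference_mse is None:
        return mse
    return mse, mse / reference_mse


# ---------------------------------------------------------------------------
# Basis characterization: Gaussian-windowed linear-FM template fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisCharacterization:
    """Binaural cue summary of one basis vector (left/right pair).

    ILD in dB (positive = left louder); ITD in us (positive = left
    leads); center frequency f_c in kHz; sweep rate m in kHz/ms.
    """

    ild_db: float
    itd_us: float
    f_c_khz: float
    sweep_rate_khz_ms: float
    residual: float
    converged: bool = True


def _chirp_design(t, t0, w, fc, m):
    """Quadrature pair of Gaussian-windowed linear chirps (fc Hz, m Hz/s)."""
    env = np.exp(-0.5 * ((t - t0) / w) ** 2)
    psi = 2 * np.pi * (fc * (t - t0) + 0.5 * m * (t - t0) ** 2)
    return np.column_stack([env * np.cos(psi), env * np.sin(psi)])


def _linear_fit(component, t, t0, w, fc, m):
    """Best amplitude/phase for fixed envelope and sweep; returns
    (amplitude, phase, residual_vector)."""
    M = _chirp_design(t, t0, w, fc, m)
    coef, *_ = np.linalg.lstsq(M, component, rcond=None)
    resid = component - M @ coef
    amp = float(np.hypot(*coef))
    phase = float(np.arctan2(-coef[1], coef[0]))  # cos(psi + phase) form
    return amp, phase, resid


def characterize_basis(left, right, sample_rate: float) -> BasisCharacterization:
    """Fit windowed linear FM sweeps to the two components of a basis vector.

    The template is g(t) = A exp(-(t-t0)^2 / 2w^2) cos(psi(t) + phi) with
    psi a linear chirp of center frequency f_c and sweep rate m; both
    components share (t0, w, f_c, m) and have their own amplitude and
    phase.  ILD = 20 log10(A_left / A_right); ITD is the carrier phase
    difference over 2 pi f_c, wrapped to half a cycle, positive when the
    left component leads.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("components must have the same length")
    n = len(left)
    t = np.arange(n) / float(sample_rate)
    T = t[-1]
    scale = max(np.linalg.norm(left), np.linalg.norm(right), 1e-30)

    def residuals(params):
        t0, logw, fc, m = params
        w = np.exp(logw)
        _, _, rl = _linear_fit(left, t, t0, w, fc, m)
        _, _, rr = _linear_fit(right, t, t0, w, fc, m)
        return np.concatenate([rl, rr]) / scale

    best = None
    for fc0 in np.arange(15e3, 70e3, 10e3):
        for m0 in (-20e6, 0.0, 20e6):  # Hz/s
            x0 = np.array([T / 2, np.log(T / 4), fc0, m0])
            sol = optimize.least_squares(
                residuals, x0, method="trf",
                bounds=([0.0, np.log(T / 20), 5e3, -1e8],
                        [T, np.log(2 * T), 120e3, 1e8]),
                max_nfev=200,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost < 1e-10:
                break
        if best.cost < 1e-10:
            break
    t0, logw, fc, m = best.x
    w = np.exp(logw)
    al, pl, _ = _linear_fit(left, t, t0, w, fc, m)
    ar, pr, _ = _linear_fit(right, t, t0, w, fc, m)
    ild = 20.0 * np.log10(max(al, 1e-30) / max(ar, 1e-30))
    # a right component delayed by ITD carries phase phi_l - 2 pi f ITD,
    # so ITD = (phi_l - phi_r) / (2 pi f); positive = left leads
    dphi = np.angle(np.exp(1j * (pl - pr)))  # wrap to (-pi, pi]
    itd = dphi / (2 * np.pi * fc)
    resid = float(np.sqrt(2 * best.cost))
    converged = bool(best.success and resid < 0.9)
    return BasisCharacterization(
        float(ild), float(itd * 1e6), float(fc / 1e3), float(m / 1e9 * 1e3),
        resid, converged,
    )


def basis_cue_distributions(
    dictionary, sample_rate: float,
    ild_bins=np.arange(-21.0, 22.0, 2.0),
    itd_bins=np.arange(-52.5, 53.0, 5.0),
):
    """ILD/ITD histograms over every basis vector of a binaural dictionary.

    Returns (ild_hist, itd_hist, characterizations); histograms use 2 dB
    and 5 us bins and are normalized to sum to 1 over in-range values.
    """
    chars = []
    half = dictionary.config.dim // 2
    for j in range(dictionary.config.n_units):
        for col in range(2):
            vec = dictionary.bases[j, :, col]
            chars.append(characterize_basis(vec[:half], vec[half:], sample_rate))
    ilds = np.array([c.ild_db for c in chars])
    itds = np.array([c.itd_us for c in chars])
    ild_hist, _ = np.histogram(ilds, bins=ild_bins)
    itd_hist, _ = np.histogram(itds, bins=itd_bins)
    ild_hist = ild_hist / max(ild_hist.sum(), 1)
    itd_hist = itd_hist / max(itd_hist.sum(), 1)
    return ild_hist, itd_hist, chars


# ---------------------------------------------------------------------------
# Pure-tone probing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningCurve:
    """Max-normalized response along a stimulus axis."""

    axis: np.ndarray
    values: np.ndarray
    kind: str  # "frequency" | "ild" | "itd"

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(a) <= 0):
            raise ValueError("stimulus axis must be strictly increasing")


def _tone_pair(freq_hz, n, dt, amp_l=1.0, amp_r=1.0, itd_s=0.0, phases=8):
    """Unit-norm binaural windows of a pure tone at several carrier phases."""
    t = np.arange(n) * dt
    out = np.empty((phases, 2 * n))
    for k in range(phases):
        ph = 2 * np.pi * k / phases
        l = amp_l * np.cos(2 * np.pi * freq_hz * t + ph)
        r = amp_r * np.cos(2 * np.pi * freq_hz * (t - itd_s) + ph)
        x = np.concatenate([l, r])
        out[k] = x / np.linalg.norm(x)
    return out


def probe_pure_tones(
    dictionary, sample_rate: float,
    freqs_khz=np.arange(10.0, 71.0, 1.0),
    ild_db=np.arange(-40.0, 41.0, 1.0),
    itd_us=np.arange(-80.0, 81.0, 1.0),
) -> list[dict]:
    """Probe every unit of a binaural dictionary with pure tones.

    Protocol: (1) best frequency (BF) from a 10-70 kHz sweep in 1 kHz
    steps at zero ILD/ITD; (2) ILD sweep -40..40 dB in 1 dB steps at BF;
    (3) ITD (phase-delay) sweep -80..80 us in 1 us steps at BF.
    Responses are squared projection lengths, averaged over carrier
    phases and max-normalized per curve.

    Returns one dict per unit with keys "bf_khz", "frequency", "ild",
    "itd" (the last three :class:`TuningCurve`).
    """
    dt = 1.0 / sample_rate
    n = dictionary.config.dim // 2

    def responses(stims):
        # mean over carrier phases of squared projection lengths
        proj = np.einsum("pd,udk->puk", stims, dictionary.bases)
        return np.einsum("puk,puk->u", proj, proj) / stims.shape[0]

    freq_resp = np.array([
        responses(_tone_pair(f * 1e3, n, dt)) for f in freqs_khz
    ])  # (nf, units)
    out = []
    for j in range(dictionary.config.n_units):
        fr = freq_resp[:, j]
        peak = fr.max()
        bf = float(freqs_khz[int(np.argmax(fr))])
        ild_resp = np.array([
            responses(_tone_pair(bf * 1e3, n, dt,
                                 amp_l=10 ** (x / 40.0),
                                 amp_r=10 ** (-x / 40.0)))[j]
            for x in ild_db
        ])
        itd_resp = np.array([
            responses(_tone_pair(bf * 1e3, n, dt, itd_s=x * 1e-6))[j]
            for x in itd_us
        ])
        def norm(v):
            m = v.max()
            return v / m if m > 0 else v
        out.append({
            "bf_khz": bf,
            "frequency": TuningCurve(freqs_khz, norm(fr), "frequency"),
            "ild": TuningCurve(ild_db, norm(ild_resp), "ild"),
            "itd": TuningCurve(itd_us, norm(itd_resp), "itd"),
            "peak_response": float(peak),
        })
    return out


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for tuning-curve classification (explicit stand-ins)."""

    monotonic_spearman: float = 0.9
    cyclic_variance_fraction: float = 0.5
    peak_prominence: float = 0.3
    flat_range: float = 1e-6


def classify_tuning_curve(curve: TuningCurve,
                          config: ClassifyConfig | None = None) -> str:
    """Label a tuning curve monotonic, peaked, cyclic or flat.

    monotonic: |Spearman rho| >= 0.9 against the stimulus axis;
    peaked: a single interior maximum with prominence >= 0.3 (on the
    max-normalized curve) and no second comparable peak;
    cyclic: the dominant nonzero Fourier component explains >= 50% of
    the variance with at least one full period in range;
    otherwise flat.
    """
    cfg = config or ClassifyConfig()
    y = np.asarray(curve.values, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 points to classify")
    if np.ptp(y) < cfg.flat_range:
        return "flat"
    rho = stats.spearmanr(curve.axis, y).statistic
    if np.abs(rho) >= cfg.monotonic_spearman:
        return "monotonic"
    peaks, props = signal.find_peaks(y, prominence=cfg.peak_prominence)
    if len(peaks) == 1:
        return "peaked"
    yc = y - y.mean()
    spec = np.abs(np.fft.rfft(yc)) ** 2
    if len(spec) > 1:
        k = 1 + int(np.argmax(spec[1:]))
        frac = spec[k] / spec[1:].sum() if spec[1:].sum() > 0 else 0.0
        if k >= 1 and frac >= cfg.cyclic_variance_fraction:
            return "cyclic"
    return "flat"


# ---------------------------------------------------------------------------
# Distribution comparison and group statistics
# ---------------------------------------------------------------------------

def compare_distributions(p, q, smoothing: float = 0.0) -> tuple[float, float]:
    """KL divergence KL(p||q) and Bhattacharyya coefficient of histograms.

    ``p`` and ``q`` must share the same binning.  With ``smoothing`` > 0
    an additive constant is applied before normalization (needed for KL
    when q has empty bins where p does not).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share binning")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histogram masses must be non-negative")
    if smoothing > 0:
        p = p + smoothing
        q = q + smoothing
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q vanishes where p does not; use smoothing")
    kl = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    bc = float(np.sum(np.sqrt(p * q)))
    return kl, bc


def effect_stats(groups) -> dict:
    """One-way ANOVA plus pairwise Cohen's d with pooled std.

    ``groups`` is a sequence of 1-D value arrays.  Returns a dict with
    keys F, df (between, within), p, and cohens_d mapping (i, j) index
    pairs to effect sizes.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    N = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        if ss_between == 0:
            f_stat = 0.0
        else:
            raise ZeroDivisionError("zero within-group variance in all groups")
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w)) if ss_within > 0 else 0.0
    d = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            pooled = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            d[(i, j)] = float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.inf
    return {"F": float(f_stat), "df": (df_b, df_w), "p": p, "cohens_d": d}
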