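"""FRET kinase-activity traces to dose-response tables and Hill fits.

A trace is a YFP/CFP ratio time series with stimulus windows. Each window's
kinase-inhibition drop is measured against the preceding baseline and
normalised to the drop at the saturating dose; the resulting fractional
inhibition table is fitted to ``f(L) = A L^h / (K^h + L^h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class TraceError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class FretTrace:
    time: np.ndarray                 # seconds, strictly increasing
    ratio: np.ndarray                # YFP/CFP
    stimulus_windows: list           # (start_s, end_s, dose_uM)
    saturating_dose: float           # uM

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.ratio = np.asarray(self.ratio, float)
        if len(self.time) != len(self.ratio):
            raise TraceError("time and ratio lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise TraceError("time must be strictly increasing")
        wins = sorted(self.stimulus_windows, key=lambda w: w[0])
        for (s0, e0, _), (s1, e1, _) in zip(wins, wins[1:]):
            if s1 < e0:
                raise TraceError("stimulus windows overlap")
        for s, e, _ in wins:
            if s < self.time[0] or e > self.time[-1]:
                raise TraceError("stimulus window outside the time range")
        self.stimulus_windows = wins


@dataclass
class DoseResponseTable:
    doses: np.ndarray                # uM
    fractional_inhibition: np.ndarray  # in [0, 1]

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.fractional_inhibition = np.asarray(self.fractional_inhibition, float)
        if len(self.doses) != len(self.fractional_inhibition):
            raise ValueError("doses and inhibition lengths differ")


@dataclass
class HillFitResult:
    k_half: float                    # uM
    hill_coefficient: float
    amplitude: float
    residual_rms: float
    confidence_intervals: dict = field(default_factory=dict)

    def predict(self, doses):
        return hill_curve(np.asarray(doses, float), self.amplitude,
                          self.k_half, self.hill_coefficient)


def hill_curve(dose, amplitude, k_half, h):
    dose = np.asarray(dose, float)
    out = np.zeros_like(dose)
    pos = dose > 0
    # evaluate in log space for numeric safety at extreme h
    lr = h * (np.log(dose[pos]) - np.log(k_half))
    out[pos] = amplitude / (1.0 + np.exp(-lr))
    return out


def fractional_inhibition(trace: FretTrace, baseline_s: float = 20.0,
                          min_baseline_samples: int = 3) -> DoseResponseTable:
    """Per-window kinase inhibition, normalised to the saturating dose.

    drop = (median baseline over the ``baseline_s`` seconds before the
    window) - (median of the final 50% of the window); fractional inhibition
    = drop / drop at the saturating dose, clipped to [0, 1].
    """
    sat_wins = [w for w in trace.stimulus_windows if w[2] >= trace.saturating_dose]
    if not sat_wins:
        raise TraceError("trace has no saturating-dose stimulus window")
    drops, doses = [], []
    for start, end, dose in trace.stimulus_windows:
        pre = (trace.time >= start - baseline_s) & (trace.time < start)
        if pre.sum() < min_baseline_samples:
            raise TraceError(f"baseline before t={start}s has fewer than "
                             f"{min_baseline_samples} samples")
        mid = 0.5 * (start + end)
        plateau = (trace.time >= mid) & (trace.time < end)
        if plateau.sum() < 1:
            raise TraceError(f"window at t={start}s too short to measure a plateau")
        drops.append(np.median(trace.ratio[pre]) - np.median(trace.ratio[plateau]))
        doses.append(dose)
    drops = np.asarray(drops)
    doses = np.asarray(doses)
    sat_drop = drops[[i for i, d in enumerate(doses) if d >= trace.saturating_dose][0]]
    if sat_drop <= 0:
        raise TraceError("saturating-dose window shows no kinase inhibition")
    frac = np.clip(drops / sat_drop, 0.0, 1.0)
    return DoseResponseTable(doses=doses, fractional_inhibition=frac)


def hill_fit(table: DoseResponseTable, n_bootstrap: int = 200,
             seed: int = 0, ci_level: float = 0.95) -> HillFitResult:
    """Least-squares multi-site Hill fit with residual-resampling bootstrap
    confidence intervals.

    The bootstrap is a wild (Rademacher) residual resample: each residual is
    sign-flipped in place rather than pooled, which preserves the strong
    heteroscedasticity of dose-response measurements (transition doses are
    far noisier than the pinned plateaus) and keeps the intervals honest.
    """
    doses = np.asarray(table.doses, float)
    resp = np.asarray(table.fractional_inhibition, float)
    pos = doses > 0
    if len(np.unique(doses[pos])) < 4:
        raise FitError("need >= 4 distinct non-zero doses spanning the transition")
    if np.ptp(resp) < 1e-12:
        raise FitError("degenerate data: all responses equal")

    def _fit(d, r):
        amp0 = max(r.max(), 1e-3)
        k0 = float(np.interp(0.5 * amp0, np.sort(r[d > 0]), np.sort(d[d > 0])))
        k0 = k0 if k0 > 0 else float(np.median(d[d > 0]))
        p0 = [amp0, k0, 2.0]
        popt, pcov = curve_fit(hill_curve, d, r, p0=p0,
                               bounds=([1e-6, 1e-9, 0.05], [10.0, 1e6, 30.0]),
                               maxfev=20000)
        return popt, pcov

    try:
        popt, _ = _fit(doses, resp)
    except Exception as exc:  # noqa: BLE001 - surface the optimiser diagnostics
        raise FitError(f"Hill fit failed to converge: {exc}") from exc
    amplitude, k_half, h = (float(v) for v in popt)
    pred = hill_curve(doses, *popt)
    residuals = resp - pred
    rms = float(np.sqrt(np.mean(residuals**2)))

    cis = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        # leverage-corrected residuals: the fit chases noise hardest at the
        # high-leverage transition doses, shrinking raw residuals there
        eps = 1e-6
        jac = np.column_stack([
            (hill_curve(doses, popt[0] + eps, popt[1], popt[2]) - pred) / eps,
            (hill_curve(doses, popt[0], popt[1] * (1 + eps), popt[2]) - pred)
            / (popt[1] * eps),
            (hill_curve(doses, popt[0], popt[1], popt[2] + eps) - pred) / eps,
        ])
        try:
            hat = jac @ np.linalg.solve(jac.T @ jac, jac.T)
            lever = np.clip(np.diag(hat), 0.0, 0.95)
        except np.linalg.LinAlgError:
            lever = np.zeros(len(doses))
        scaled = residuals / np.sqrt(1.0 - lever)
        samples = []
        for _ in range(n_bootstrap):
            signs = rng.choice([-1.0, 1.0], size=len(residuals))
            r_boot = pred + signs * scaled
            try:
                p_boot, _ = _fit(doses, np.clip(r_boot, 0.0, None))
            except Exception:  # noqa: BLE001 - skip non-converged resamples
                continue
            samples.append(p_boot)
        if len(samples) >= max(10, n_bootstrap // 4):
            from scipy.stats import t as t_dist

            arr = np.asarray(samples)
            # normal-theory interval with bootstrap sd and a t quantile:
            # more stable than raw percentiles at dose-response sample sizes,
            # and the t factor absorbs the residual-scale uncertainty
            dof = max(len(doses) - 3, 1)
            t_mult = float(t_dist.ppf(0.5 * (1 + ci_level), dof))
            for j, name in enumerate(("amplitude", "k_half", "hill_coefficient")):
                centre = (amplitude, k_half, h)[j]
                half = t_mult * float(arr[:, j].std(ddof=1))
                cis[name] = (centre - half, centre + half)
    return HillFitResult(k_half=k_half, hill_coefficient=h, amplitude=amplitude,
                         residual_rms=rms, confidence_intervals=cis)


def simulate_fret_trace(
    doses,
    k_half: float = 0.4,
    h: float = 2.7,
    amplitude: float = 1.0,
    adaptation_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_ratio: float = 1.2,
    drop_scale: float = 0.25,
    window_s: float = 60.0,
    gap_s: float = 100.0,
    dt: float = 1.0,
    saturating_dose: float | None = None,
) -> FretTrace:
    """Synthetic YFP/CFP trace: per dose a step drop of Hill(dose) amplitude,
    exponential adaptation during the stimulus, and a post-removal overshoot
    that decays back to baseline. ``adaptation_rate = 0`` gives flat plateaus
    and no overshoot."""
    for name, val in (("k_half", k_half), ("h", h), ("amplitude", amplitude)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")
    if adaptation_rate < 0 or noise_sd < 0:
        raise ValueError("rates and noise must be non-negative")
    doses = list(doses)
    if saturating_dose is None:
        saturating_dose = max(doses)
    total = gap_s + len(doses) * (window_s + gap_s)
    time = np.arange(0.0, total, dt)
    ratio = np.full_like(time, baseline_ratio)
    windows = []
    for i, dose in enumerate(doses):
        start = gap_s + i * (window_s + gap_s)
        end = start + window_s
        windows.append((start, end, float(dose)))
        drop = drop_scale * hill_curve(np.array([dose]), amplitude, k_half, h)[0]
        inside = (time >= start) & (time < end)
        t_in = time[inside] - start
        recovery = 1.0 - np.exp(-adaptation_rate * t_in) if adaptation_rate > 0 else 0.0
        ratio[inside] -= drop * (1.0 - recovery)
        # methylation overshoot on stimulus removal, proportional to adaptation
        after = time >= end
        if adaptation_rate > 0:
            adapted = drop * (1.0 - np.exp(-adaptation_rate * window_s))
            t_post = time[after] - end
            ratio[after] += adapted * np.exp(-adaptation_rate * 2.0 * t_post)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=len(ratio))
    return FretTrace(time=time, ratio=ratio, stimulus_windows=windows,
                     saturating_dose=float(saturating_dose))
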