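"""Force-ramp single-molecule analysis: FJC elasticity and step detection.

Unfolding events release contour length that extends under force according
to the freely jointed chain (FJC) model

    x(F) = dLc [coth(beta) - 1/beta],   beta = F l_K / kT

with Kuhn length l_K = 1.1 nm and thermal energy kT = 4.11 pN nm by
default.  Step sizes measured on a trajectory are converted back to
contour-length increments dLc by inverting the same expression at the
unfolding force.  Under a linear force ramp F = r t the force coordinate is
deterministic in time, so the unfolding force of a detected change point is
simply r * t_U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FJCConstants",
    "RampTrajectory",
    "UnfoldingEvent",
    "fjc_extension",
    "contour_from_step",
    "detect_steps",
    "event_summary",
]


@dataclass(frozen=True)
class FJCConstants:
    """Freely-jointed-chain constants: Kuhn length (nm), kT (pN nm)."""

    l_K: float = 1.1
    kT: float = 4.11

    def __post_init__(self):
        if self.l_K <= 0 or self.kT <= 0:
            raise ValueError("l_K and kT must be positive")


DEFAULT_FJC = FJCConstants()


@dataclass
class RampTrajectory:
    """Extension record under a linear force ramp."""

    time: np.ndarray  # s
    force: np.ndarray  # pN, = loading_rate * time
    extension: np.ndarray  # nm
    loading_rate: float  # pN/s
    sample_rate: float  # Hz

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.extension)):
            raise ValueError("time/force/extension must have equal length")
        if np.any(np.diff(self.force) < 0):
            raise ValueError("force must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "force_pN": self.force, "extension_nm": self.extension}
        )

    @classmethod
    def from_frame(cls, df, loading_rate=None, sample_rate=None) -> "RampTrajectory":
        t = df["time_s"].to_numpy(dtype=float)
        f = df["force_pN"].to_numpy(dtype=float)
        if loading_rate is None:
            loading_rate = float(np.polyfit(t, f, 1)[0])
        if sample_rate is None:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, f, df["extension_nm"].to_numpy(dtype=float), loading_rate, sample_rate)


@dataclass
class UnfoldingEvent:
    """A detected (or ground-truth) rupture: time, force, step and dLc."""

    t_U: float  # s
    F_U: float  # pN
    step: float  # nm, instantaneous extension jump
    dLc: float  # nm, FJC contour-length increment

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.dLc < self.step - 1e-9:
            raise ValueError("dLc must be >= step (FJC extension <= contour)")


def _fjc_factor(F, c: FJCConstants):
    """coth(beta) - 1/beta, series-stabilized near beta -> 0."""
    beta = np.asarray(F, dtype=float) * c.l_K / c.kT
    out = np.empty_like(beta, dtype=float)
    small = beta < 1e-3
    bs = beta[small]
    out[small] = bs / 3.0 - bs**3 / 45.0
    bl = beta[~small]
    # coth(b) = 1 + 2/(e^{2b} - 1); exp overflow-safe via clipping
    out[~small] = 1.0 + 2.0 / np.expm1(np.clip(2.0 * bl, None, 700.0)) - 1.0 / bl
    return out


def fjc_extension(F, dLc, c: FJCConstants = DEFAULT_FJC):
    """FJC extension (nm) of a contour increment dLc (nm) at force F (pN).

    Saturates to dLc as F -> inf and vanishes linearly (x ~ dLc*beta/3) as
    F -> 0+.  Negative forces are rejected.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    if np.any(np.asarray(dLc, dtype=float) < 0):
        raise ValueError("dLc must be >= 0")
    out = np.asarray(dLc, dtype=float) * _fjc_factor(F, c)
    return float(out) if out.ndim == 0 else out


def contour_from_step(step, F, c: FJCConstants = DEFAULT_FJC):
    """Invert the FJC: contour-length increment from a step at force F."""
    step = np.asarray(step, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(step <= 0) and step.ndim:
        raise ValueError("step must be positive")
    if step.ndim == 0 and step <= 0:
        raise ValueError("step must be positive")
    if np.any(F <= 0):
        raise ValueError("force must be positive")
    out = step / _fjc_factor(F, c)
    return float(out) if out.ndim == 0 else out


def detect_steps(
    traj: RampTrajectory,
    min_step: float = 5.0,
    window: float = 0.5,
    fp_rate: float = 0.05,
    c: FJCConstants = DEFAULT_FJC,
) -> list:
    """Detect abrupt upward extension jumps on a force-ramp trajectory.

    The smooth elastic baseline varies slowly on the ``window`` timescale,
    so each sample is scored by the contrast between the medians of the
    leading and trailing windows.  The detection threshold is the larger of
    ``min_step`` and a noise floor calibrated so that a pure-noise trace
    yields a false event with probability <= ``fp_rate``: with w samples
    per window the median contrast has standard deviation
    ~ sigma*sqrt(pi/w), sigma estimated robustly from first differences,
    and the threshold is the Bonferroni-corrected normal quantile over the
    ~n/w effectively independent window positions.

    Events are local score maxima above threshold separated by at least one
    window.  Each event records t_U at the change point, F_U = r*t_U, step
    as the difference of flanking window medians, and dLc via the FJC
    inverse at F_U.
    """
    w = max(int(round(window * traj.sample_rate)), 3)
    x = traj.extension
    n = len(x)
    if n < 2 * w + 1:
        raise ValueError("trajectory too short for the chosen window")

    # robust noise scale from first differences (steps are sparse)
    d = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0)

    # rolling medians via pandas (O(n log w))
    s = pd.Series(x)
    med_trail = s.rolling(w).median().to_numpy()  # median of x[i-w+1 .. i]
    med_lead = s[::-1].rolling(w).median().to_numpy()[::-1]  # x[i .. i+w-1]
    score = np.full(n, -np.inf)
    valid = slice(w, n - w)
    score[valid] = med_lead[w : n - w] - med_trail[w - 1 : n - w - 1]

    n_tests = max(n / w, 1.0)
    z = stats.norm.ppf(max(1.0 - fp_rate / n_tests, 0.5))
    noise_floor = z * sigma * math.sqrt(math.pi / w) if sigma > 0 else 0.0
    threshold = max(min_step, noise_floor)

    events = []
    above = score >= threshold
    i = w
    while i < n - w:
        if above[i]:
            j = i
            while j < n - w and above[j]:
                j += 1
            k = i + int(np.argmax(score[i:j]))
            pre = float(np.median(x[max(k - w, 0) : k]))
            post = float(np.median(x[k + 1 : k + 1 + w]))
            step = post - pre
            t_u = float(traj.time[k])
            f_u = float(traj.loading_rate * t_u)
            if step > 0 and f_u > 0:
                events.append(
                    UnfoldingEvent(
                        t_U=t_u, F_U=f_u, step=step, dLc=float(contour_from_step(step, f_u, c))
                    )
                )
            i = j + w
        else:
            i += 1
    return events


def _kde_mode(values: np.ndarray) -> float:
    """Mode of a sample via Gaussian KDE evaluated on a fine grid."""
    values = np.asarray(values, dtype=float)
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


def event_summary(events, force_threshold: float | None = None):
    """Scatter table and marginal summaries of unfolding events.

    Returns (table, summary): a DataFrame of (t_s, F_pN, step_nm, dLc_nm)
    pairs and a dict of marginal statistics (mode via KDE, mean, sd) for
    the unfolding force and the contour-length increment.  With a single
    event the sd is undefined and flagged as NaN with ``degenerate=True``.
    If ``force_threshold`` is given, events are additionally labelled
    weak/strong and summarized per class.
    """
    if not events:
        raise ValueError("no events to summarize")
    table = pd.DataFrame(
        {
            "t_s": [e.t_U for e in events],
            "F_pN": [e.F_U for e in events],
            "step_nm": [e.step for e in events],
            "dLc_nm": [e.dLc for e in events],
        }
    )

    def marg(vals):
        vals = np.asarray(vals, dtype=float)
        return {
            "mode": _kde_mode(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "n": int(vals.size),
        }

    summary = {
        "F_U": marg(table["F_pN"]),
        "dLc": marg(table["dLc_nm"]),
        "degenerate": len(events) == 1,
    }
    if force_threshold is not None:
        weak = table[table["F_pN"] < force_threshold]
        strong = table[table["F_pN"] >= force_threshold]
        table = table.assign(
            label=np.where(table["F_pN"] < force_threshold, "weak", "strong")
        )
        summary["weak"] = marg(weak["F_pN"]) if len(weak) else None
        summary["strong"] = marg(strong["F_pN"]) if len(strong) else None
        summary["weak_dLc"] = marg(weak["dLc_nm"]) if len(weak) else None
        summary["strong_dLc"] = marg(strong["dLc_nm"]) if len(strong) else None
    return table, summary
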