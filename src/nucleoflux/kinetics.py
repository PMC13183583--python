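"""Two-compartment light-gated nucleocytoplasmic transport model.

The model assumes first-order exchange of a fluorescent cargo between
nucleus and cytoplasm.  During the recovery phase (light off, import
signal exposed) the compartment concentrations follow

    [N](t) = [N]_e - ([N]_e - [N]_0) e^{-kt}
    [C](t) = [C]_e + ([C]_0 - [C]_e) e^{-kt}

with a single relaxation rate k = k_I + k_E (sum of the active import and
export rate constants).  Mass conservation links the two amplitudes through
the relative nucleus-to-cytoplasm volume factor

    v = ([C]_0 - [C]_e) / ([N]_e - [N]_0)

so that, for a nucleus that starts empty ([N]_0 = 0), the concentration
ratio follows the single closed form

    [N]/[C](t) = K_e (1 - e^{-kt}) / (1 + v K_e e^{-kt})

where K_e = [N]_e/[C]_e = k_I/k_E is the steady-state nucleus-to-cytoplasm
accumulation.  Export experiments track [C]/[N] and obey the mirrored
expression with K_e = [C]_e/[N]_e = k_E/k_I.

Derivation of the ratio form: substituting [N] = [N]_e(1 - E) and
[C] = [C]_e + v [N]_e E (E = e^{-kt}) gives
[N]/[C] = ([N]_e/[C]_e)(1-E) / (1 + v ([N]_e/[C]_e) E), i.e. exactly the
closed form above with K_e = [N]_e/[C]_e.  Note v must divide by
([N]_e - [N]_0) for this to hold.

Rates are handled in s^-1 internally; reported tables use ks^-1
(1 ks^-1 = 1e-3 s^-1) as is conventional for these slow exchange processes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TransportParams",
    "FitResult",
    "CellCohort",
    "QCReason",
    "ratio_recovery",
    "export_ratio_recovery",
    "rates_from_fit",
    "fit_recovery",
    "qc_filter",
    "split_percent",
    "compare_groups",
]

_MASS_TOL = 1e-9

# fit bounds: K_e in (0, 50], k in (0, 1 s^-1], v in [0.1, 10]
_KE_BOUNDS = (1e-9, 50.0)
_K_BOUNDS = (1e-9, 1.0)
_V_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class TransportParams:
    """Kinetic parameter bundle for one cell.

    K_e is the steady-state accumulation ratio of the destination over the
    source compartment (nucleus/cytoplasm in import mode); ``k`` is the
    total relaxation rate in s^-1 with k = k_I + k_E; ``v`` the relative
    nucleus-to-cytoplasm volume factor.  N0/Ne/C0/Ce are the initial and
    steady-state normalized concentrations of the recovery phase.
    """

    K_e: float
    k: float
    k_I: float
    k_E: float
    v: float
    N0: float = 0.0
    Ne: float = 1.0
    C0: float = 0.0
    Ce: float = 0.0

    def __post_init__(self):
        if min(self.k, self.k_I, self.k_E) < 0:
            raise ValueError("rate constants must be non-negative")
        if self.v <= 0:
            raise ValueError("volume factor v must be positive")
        if self.K_e <= 0:
            raise ValueError("K_e must be positive")
        if abs(self.k - (self.k_I + self.k_E)) > _MASS_TOL * max(1.0, self.k):
            raise ValueError("k must equal k_I + k_E")
        if abs(self.v * (self.Ne - self.N0) - (self.C0 - self.Ce)) > _MASS_TOL * max(
            1.0, abs(self.C0)
        ):
            raise ValueError("mass conservation v*(Ne-N0) = C0-Ce violated")

    @classmethod
    def from_accumulation(
        cls,
        K_e: float,
        k: float,
        v: float = 1.0,
        *,
        N0: float = 0.0,
        scale: float = 1.0,
    ) -> "TransportParams":
        """Build a consistent bundle from (K_e, k, v).

        ``scale`` sets the steady-state nuclear concentration Ne;
        Ce = Ne/K_e and C0 follows from mass conservation.
        """
        if K_e <= 0 or k <= 0 or v <= 0:
            raise ValueError("K_e, k, v must be positive")
        k_I = k * K_e / (1.0 + K_e)
        k_E = k - k_I
        Ne = float(scale)
        Ce = Ne / K_e
        C0 = Ce + v * (Ne - N0)
        return cls(K_e=K_e, k=k, k_I=k_I, k_E=k_E, v=v, N0=N0, Ne=Ne, C0=C0, Ce=Ce)


class QCReason(enum.Enum):
    """Fixed enumeration of quality-control rejection reasons."""

    PASS = "PASS"
    POOR_ACTIVATION = "POOR_ACTIVATION"
    UNPHYSICAL = "UNPHYSICAL"
    OUTLIER = "OUTLIER"


@dataclass
class FitResult:
    """Recovery-curve fit for one cell."""

    params: TransportParams
    stderr: dict
    residual_norm: float
    converged: bool
    n_points: int
    cell_id: str = ""
    mode: str = "import"

    def __post_init__(self):
        if any(v < 0 for v in self.stderr.values() if np.isfinite(v)):
            raise ValueError("standard errors must be non-negative")


@dataclass
class CellCohort:
    """A set of per-cell fits for one construct, with QC bookkeeping."""

    fits: list
    construct: str = ""
    qc_status: list = field(default_factory=list)

    def __post_init__(self):
        if not self.qc_status:
            self.qc_status = [QCReason.PASS] * len(self.fits)
        if len(self.qc_status) != len(self.fits):
            raise ValueError("qc_status must align with fits")

    def passing(self) -> list:
        return [f for f, s in zip(self.fits, self.qc_status) if s is QCReason.PASS]


def _check_ratio_args(K_e, k, v):
    if K_e <= 0 or k <= 0 or v <= 0:
        raise ValueError("K_e, k and v must all be positive")


def ratio_recovery(t, K_e: float, k: float, v: float):
    """Nucleus-to-cytoplasm concentration ratio during import recovery.

    Returns K_e (1 - e^{-kt}) / (1 + v K_e e^{-kt}); 0 at t = 0, strictly
    increasing, and -> K_e as t -> inf.  ``t`` in seconds, ``k`` in s^-1.
    """
    _check_ratio_args(K_e, k, v)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    E = np.exp(-k * t)
    return K_e * (-np.expm1(-k * t)) / (1.0 + v * K_e * E)


def export_ratio_recovery(t, K_e: float, k: float, v: float):
    """Cytoplasm-to-nucleus ratio during export recovery.

    Identical functional form to :func:`ratio_recovery` with the
    compartments swapped: here K_e is the cytoplasm-to-nucleus accumulation
    (k_E/k_I) and v enters as the same volume factor.
    """
    return ratio_recovery(t, K_e, k, v)


def rates_from_fit(K_e: float, k: float, mode: str = "import"):
    """Decompose the total relaxation rate into (k_I, k_E).

    Import mode: K_e = k_I/k_E, so k_I = k K_e/(1+K_e) and k_E = k - k_I.
    Export mode: roles swapped.  Units follow ``k``.
    """
    if K_e <= 0 or k <= 0:
        raise ValueError("K_e and k must be positive")
    fast = k * K_e / (1.0 + K_e)
    slow = k - fast
    if mode == "import":
        return fast, slow
    if mode == "export":
        return slow, fast
    raise ValueError(f"unknown mode {mode!r}")


def fit_recovery(tc, mode: str = "import", v_policy="free") -> FitResult:
    """Fit a recovery-phase ratio time course to the closed-form model.

    Parameters
    ----------
    tc : TimeCourse or pandas.DataFrame
        Must expose recovery-phase times (seconds, re-zeroed at light off)
        and the nucleus/cytoplasm ratio.  For export mode the tracked
        quantity is the inverse ratio [C]/[N].
    mode : "import" | "export"
    v_policy : "free" or ("fixed", value)
        Whether the volume factor is a free parameter (bounded [0.1, 10])
        or held fixed.  Note that k and v are only weakly identified
        jointly from a single ratio curve (the product v*K_e controls the
        early-time curvature), so fix v whenever it is known.

    Weighted least squares on the ratio series with weights 1/max(y,
    floor) — the right weighting for multiplicative intensity noise, with
    the floor (5% of the plateau) preventing the near-zero early points
    from dominating.  Initial guesses K_e0 = final ratio, k0 = ln 2 /
    t_half, v0 = 1.  Standard errors come from the Jacobian curvature at
    the optimum.
    """
    t, y = _recovery_series(tc, mode)
    if len(t) < 5:
        raise ValueError("need at least 5 recovery-phase points")
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("ratios must be finite and non-negative")
    if np.all(y <= 0):
        raise ValueError("degenerate all-zero ratio series")

    ke0 = float(np.clip(y[-1], _KE_BOUNDS[0] * 10, _KE_BOUNDS[1] * 0.9))
    half = 0.5 * y[-1]
    above = np.nonzero(y >= half)[0]
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 2 or 1.0)
    k0 = float(np.clip(math.log(2.0) / t_half, _K_BOUNDS[0] * 10, _K_BOUNDS[1] * 0.9))

    fixed_v = None
    if isinstance(v_policy, (tuple, list)):
        tag, fixed_v = v_policy
        if tag != "fixed":
            raise ValueError("v_policy must be 'free' or ('fixed', v)")
    elif v_policy != "free":
        raise ValueError("v_policy must be 'free' or ('fixed', v)")

    w = 1.0 / np.maximum(y, 0.05 * max(y.max(), 1e-12))
    if fixed_v is None:
        x0 = np.array([ke0, k0, 1.0])
        lo = np.array([_KE_BOUNDS[0], _K_BOUNDS[0], _V_BOUNDS[0]])
        hi = np.array([_KE_BOUNDS[1], _K_BOUNDS[1], _V_BOUNDS[1]])
        model = lambda p: w * (ratio_recovery(t, p[0], p[1], p[2]) - y)
    else:
        x0 = np.array([ke0, k0])
        lo = np.array([_KE_BOUNDS[0], _K_BOUNDS[0]])
        hi = np.array([_KE_BOUNDS[1], _K_BOUNDS[1]])
        model = lambda p: w * (ratio_recovery(t, p[0], p[1], fixed_v) - y)

    sol = optimize.least_squares(model, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    names = ["K_e", "k", "v"][: len(sol.x)]
    p = dict(zip(names, sol.x))
    v_hat = fixed_v if fixed_v is not None else p["v"]

    # curvature-based standard errors
    dof = max(len(t) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(sol.x), np.nan)
    stderr = dict(zip(names, se))
    if fixed_v is not None:
        stderr["v"] = 0.0

    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    params = TransportParams.from_accumulation(p["K_e"], p["k"], v_hat)
    cell_id = getattr(tc, "cell_id", "") or ""
    return FitResult(
        params=params,
        stderr=stderr,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        converged=converged,
        n_points=len(t),
        cell_id=cell_id,
        mode=mode,
    )


def _recovery_series(tc, mode):
    """Pull (t, ratio) for the recovery phase from a TimeCourse/DataFrame."""
    if hasattr(tc, "recovery_series"):
        t, r = tc.recovery_series()
    else:  # DataFrame with columns phase, t_s, ratio
        rec = tc[tc["phase"] == "recovery"]
        t = rec["t_s"].to_numpy(dtype=float)
        r = rec["ratio"].to_numpy(dtype=float)
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if mode == "export":
        with np.errstate(divide="ignore"):
            r = np.where(r > 0, 1.0 / r, np.inf)
    elif mode != "import":
        raise ValueError(f"unknown mode {mode!r}")
    return t, r


def _near_bound(x, lo, hi, frac=0.01):
    # relative proximity: rates span orders of magnitude, so an absolute
    # span criterion would tag every slow-exchange fit as pinned
    return x <= lo * (1.0 + frac) or x >= hi * (1.0 - frac)


def qc_filter(
    cohort: CellCohort,
    activation_traces: dict | None = None,
    *,
    theta_act: float = 0.5,
    mad_sigma: float = 3.5,
) -> CellCohort:
    """Semi-automatic filtering of spurious cell fits.

    Discards, with a tagged reason:

    * POOR_ACTIVATION — the nucleus did not empty during the activation
      phase: end-of-activation ratio exceeds ``theta_act`` times the cell's
      recovery plateau proxy (the fitted K_e).
    * UNPHYSICAL — non-convergent fit, or any parameter within 1% of its
      bound.
    * OUTLIER — K_e or k_I beyond median +/- ``mad_sigma`` scaled-MAD within
      the construct group (computed over cells surviving the first two
      checks).

    ``activation_traces`` maps cell_id -> activation-phase ratio array
    (destination/source ratio, same orientation as the fit).  Deterministic
    given thresholds.
    """
    fits = cohort.fits
    status = [QCReason.PASS] * len(fits)

    for i, f in enumerate(fits):
        if not f.converged or not np.isfinite(f.params.K_e):
            status[i] = QCReason.UNPHYSICAL
            continue
        if (
            _near_bound(f.params.K_e, *_KE_BOUNDS)
            or _near_bound(f.params.k, *_K_BOUNDS)
            or _near_bound(f.params.v, *_V_BOUNDS)
        ):
            status[i] = QCReason.UNPHYSICAL
            continue
        if activation_traces is not None:
            trace = activation_traces.get(f.cell_id)
            if trace is not None and len(trace):
                end_ratio = float(np.asarray(trace, dtype=float)[-1])
                if end_ratio > theta_act * f.params.K_e:
                    status[i] = QCReason.POOR_ACTIVATION

    # robust outlier sweep on survivors
    ok = [i for i, s in enumerate(status) if s is QCReason.PASS]
    if len(ok) >= 3:
        for key in ("K_e", "k_I"):
            vals = np.array([getattr(fits[i].params, key) for i in ok])
            med = np.median(vals)
            mad = 1.4826 * np.median(np.abs(vals - med))
            if mad <= 0:
                continue
            for i, x in zip(ok, vals):
                if abs(x - med) > mad_sigma * mad:
                    status[i] = QCReason.OUTLIER

    return CellCohort(fits=fits, construct=cohort.construct, qc_status=status)


def split_percent(group_N, group_C) -> float:
    """Percentage split between N- and C-terminal-entry constructs.

    Split = 100 (mean_N/mean_C - 1), positive when the N-terminal-entry
    construct accumulates (or transports) faster.  Applies to accumulation
    values or rate constants alike.
    """
    a = np.asarray(group_N, dtype=float)
    b = np.asarray(group_C, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    mb = b.mean()
    if mb <= 0:
        raise ValueError("C-group mean must be positive")
    return 100.0 * (a.mean() / mb - 1.0)


def compare_groups(a, b):
    """Two-tailed Mann-Whitney comparison of two value groups.

    Returns (U, two-sided P, (mean_a, sem_a), (mean_b, sem_b)).  Uses the
    exact distribution where feasible and the tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    if not np.isfinite(p):  # all observations tied: no evidence either way
        p = 1.0
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(x.size))
    return (
        float(res.statistic),
        min(p, 1.0),
        (float(a.mean()), sem(a)),
        (float(b.mean()), sem(b)),
    )
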