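"""Seeded synthetic-data generators for every pipeline input.

Four generators with known ground truth:

* cell time courses — two-phase (activation/recovery) first-order
  nucleocytoplasmic exchange with multiplicative lognormal intensity noise;
* microscopy frame stacks — elliptical cell/nucleus compartments, flat
  background plane, Poisson-like shot noise, plus ground-truth masks;
* force-ramp trajectories — Bell-model unfolding events under a linear
  ramp with FJC elastic extension of the released contour length;
* TF disorder datasets — per-residue disorder profiles with an elevated
  NLS-to-terminus region.

All generation is driven by ``numpy.random.default_rng(seed)``; identical
specs and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import TransportParams
from .quant import ACTIVATION, RECOVERY, FrameStack, MaskPair, TimeCourse
from .tweezers import DEFAULT_FJC, FJCConstants, RampTrajectory, UnfoldingEvent, fjc_extension
from .tfsurvey import TFRecord, terminal_region

__all__ = [
    "CellSimSpec",
    "FrameGeometry",
    "RampSimSpec",
    "TFSimSpec",
    "gen_cell_timecourse",
    "gen_frames",
    "gen_ramp_trajectory",
    "bell_rupture_forces",
    "bell_mode_force",
    "bell_survival",
    "gen_tf_dataset",
    "write_timecourses",
    "write_frame_stack",
    "write_trajectory",
    "write_tf_dataset",
]


# ---------------------------------------------------------------------------
# cell time courses

@dataclass(frozen=True)
class CellSimSpec:
    """Simulation spec for one cell's two-phase time course.

    Defaults follow the standard imaging schedule: 10 min activation and
    45 min recovery at one frame per minute.  ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal intensity
    noise applied per frame and compartment.  During activation the export
    signal is exposed: the cell relaxes from the nuclear-accumulated steady
    state toward a cytoplasm-dominant state with accumulation ratio
    ``activation_ratio`` at rate ``activation_rate_factor * k``.
    """

    params: TransportParams
    activation_duration: float = 600.0  # s
    recovery_duration: float = 2700.0  # s
    frame_interval: float = 60.0  # s
    noise_cv: float = 0.1
    seed: int = 0
    activation_ratio: float = 0.05
    activation_rate_factor: float = 4.0

    def __post_init__(self):
        if self.recovery_duration <= 0 or self.frame_interval <= 0:
            raise ValueError("durations and frame interval must be positive")
        if self.activation_duration < 0:
            raise ValueError("activation duration must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.activation_ratio <= 0 or self.activation_rate_factor <= 0:
            raise ValueError("activation parameters must be positive")


def _lognormal_factors(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def _noiseless_phases(spec: CellSimSpec):
    """Closed-form (t, phase, N, C) series for both phases."""
    p = spec.params
    Ne, Ce, v, k = p.Ne, p.Ce, p.v, p.k
    M = v * Ne + Ce  # conserved "mass" in concentration units

    t_act = np.arange(0.0, spec.activation_duration, spec.frame_interval)
    if spec.activation_duration > 0 and len(t_act):
        # activation: relax from (Ne, Ce) toward the light-on steady state
        Ka = spec.activation_ratio
        Na = M / (v + 1.0 / Ka)
        k_act = spec.activation_rate_factor * k
        N_act = Na + (Ne - Na) * np.exp(-k_act * t_act)
        C_act = M - v * N_act
        # recovery begins at t = activation_duration
        N0_rec = float(Na + (Ne - Na) * math.exp(-k_act * spec.activation_duration))
    else:
        t_act = np.array([])
        N_act = C_act = np.array([])
        N0_rec = 0.0  # recovery-only simulations start from an emptied nucleus

    t_rec = np.arange(0.0, spec.recovery_duration + 0.5 * spec.frame_interval, spec.frame_interval)
    N_rec = Ne - (Ne - N0_rec) * np.exp(-k * t_rec)
    C_rec = M - v * N_rec  # mass conservation: v*N + C = M at every instant
    return t_act, N_act, C_act, t_rec, N_rec, C_rec, N0_rec


def gen_cell_timecourse(spec: CellSimSpec):
    """Simulate one cell's phased ratio time course.

    Returns (TimeCourse, ground_truth) where ground_truth holds the input
    TransportParams, the recovery-phase initial nuclear concentration, and
    the noiseless ratio series.  Multiplicative lognormal noise (CV =
    ``spec.noise_cv``) is applied independently to the nuclear and
    cytoplasmic signals of each frame.
    """
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    t_act, N_act, C_act, t_rec, N_rec, C_rec, N0_rec = _noiseless_phases(spec)

    t = np.concatenate([t_act, t_rec])
    phase = np.array([ACTIVATION] * len(t_act) + [RECOVERY] * len(t_rec), dtype=object)
    N = np.concatenate([N_act, N_rec])
    C = np.concatenate([C_act, C_rec])
    ratio_true = np.divide(N, C, out=np.full_like(N, np.inf), where=C > 0)

    N_obs = N * _lognormal_factors(rng, spec.noise_cv, len(N))
    C_obs = C * _lognormal_factors(rng, spec.noise_cv, len(C))
    ratio = np.divide(N_obs, C_obs, out=np.full_like(N, np.inf), where=C_obs > 0)

    tc = TimeCourse(t_s=t, phase=phase, N=N_obs, C=C_obs, ratio=ratio)
    truth = {
        "params": p,
        "N0_recovery": N0_rec,
        "ratio_true": ratio_true,
        "N_true": N,
        "C_true": C,
    }
    return tc, truth


# ---------------------------------------------------------------------------
# frame stacks

@dataclass(frozen=True)
class FrameGeometry:
    """Elliptical cell and nucleus geometry on a pixel grid.

    Ellipses are (center_row, center_col, semi_axis_row, semi_axis_col) in
    pixels; the nucleus must lie strictly inside the cell.  ``background``
    is a flat additive intensity plane; ``gain`` converts intensity to
    expected photon counts for Poisson-like shot noise (0 disables noise).
    """

    shape: tuple = (96, 96)
    cell: tuple = (48, 48, 40, 34)
    nucleus: tuple = (48, 48, 16, 13)
    background: float = 10.0
    gain: float = 0.0
    blur_sigma: float = 0.0

    def masks(self) -> MaskPair:
        h, w = self.shape
        rr, cc = np.mgrid[0:h, 0:w]

        def ellipse(par):
            r0, c0, ar, ac = par
            return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0

        nuc, cell = ellipse(self.nucleus), ellipse(self.cell)
        # strict containment: dilate nucleus ellipse by one pixel-equivalent
        r0, c0, ar, ac = self.nucleus
        grown = ((rr - r0) / (ar + 1)) ** 2 + ((cc - c0) / (ac + 1)) ** 2 <= 1.0
        if np.any(grown & ~cell):
            raise ValueError("nucleus ellipse must lie strictly inside the cell ellipse")
        return MaskPair(nucleus=nuc, cell=cell)


def gen_frames(spec: CellSimSpec, geometry: FrameGeometry = FrameGeometry()):
    """Render a synthetic frame stack realizing the kinetic model.

    The total fluorophore amount is partitioned between the compartments
    according to the noiseless concentrations and the compartment pixel
    areas (uniform intensity within each compartment), a flat background
    plane is added, and Poisson shot noise is applied when ``gain`` > 0.

    Returns (FrameStack, MaskPair, truth) with truth carrying the
    ground-truth masks' noiseless nuclear/cytoplasmic signal fractions and
    ratio series.
    """
    masks = geometry.masks()
    rng = np.random.default_rng(spec.seed)
    t_act, N_act, C_act, t_rec, N_rec, C_rec, _ = _noiseless_phases(spec)
    t = np.concatenate([t_act, t_rec + spec.activation_duration])
    phase = np.array([ACTIVATION] * len(t_act) + [RECOVERY] * len(t_rec), dtype=object)
    N = np.concatenate([N_act, N_rec])  # concentrations
    C = np.concatenate([C_act, C_rec])

    a_nuc = int(masks.nucleus.sum())
    a_cyt = int(masks.cytoplasm.sum())
    frames = np.empty((len(t),) + geometry.shape, dtype=float)
    n_frac = np.empty(len(t))
    for i in range(len(t)):
        img = np.full(geometry.shape, float(geometry.background))
        img[masks.nucleus] += N[i]
        img[masks.cytoplasm] += C[i]
        if geometry.blur_sigma > 0:
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, geometry.blur_sigma)
        if geometry.gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * geometry.gain) / geometry.gain
        frames[i] = img
        tot = N[i] * a_nuc + C[i] * a_cyt
        n_frac[i] = N[i] * a_nuc / tot if tot > 0 else np.nan

    stack = FrameStack(frames=frames, times=t, phases=phase)
    with np.errstate(divide="ignore"):
        truth = {
            "masks": masks,
            "n_frac": n_frac,
            "c_frac": 1.0 - n_frac,
            "ratio": n_frac / (1.0 - n_frac),
            "params": spec.params,
        }
    return stack, masks, truth


# ---------------------------------------------------------------------------
# force-ramp trajectories

@dataclass(frozen=True)
class RampSimSpec:
    """Simulation spec for a Bell-model force-ramp trajectory.

    Each state is (k0, delta_x, dLc): intrinsic unfolding rate (s^-1),
    distance to the transition state (nm), and released contour length
    (nm).  The ramp is F = loading_rate * t up to ``f_max``; each state
    draws its rupture force independently from the Bell survival function.
    """

    states: tuple  # of (k0, delta_x, dLc)
    loading_rate: float = 1.0  # pN/s
    sample_rate: float = 100.0  # Hz
    noise_sd: float = 1.0  # nm
    drift: float = 0.0  # nm/s
    seed: int = 0
    f_max: float = 120.0  # pN
    fjc: FJCConstants = DEFAULT_FJC

    def __post_init__(self):
        for k0, dx, dlc in self.states:
            if k0 <= 0 or dx <= 0 or dlc < 0:
                raise ValueError("states require k0 > 0, delta_x > 0, dLc >= 0")
        if self.loading_rate <= 0 or self.sample_rate <= 0 or self.f_max <= 0:
            raise ValueError("loading_rate, sample_rate, f_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def bell_survival(F, k0, delta_x, loading_rate, kT=4.11):
    """Bell-model survival S(F) under a linear ramp.

    S(F) = exp(-(k0 kT)/(r dx) (e^{F dx/kT} - 1)).
    """
    F = np.asarray(F, dtype=float)
    a = k0 * kT / (loading_rate * delta_x)
    return np.exp(-a * np.expm1(F * delta_x / kT))


def bell_mode_force(k0, delta_x, loading_rate, kT=4.11):
    """Most probable rupture force (kT/dx) ln(r dx / (k0 kT))."""
    return (kT / delta_x) * math.log(loading_rate * delta_x / (k0 * kT))


def bell_rupture_forces(k0, delta_x, loading_rate, n, rng, kT=4.11):
    """Draw n rupture forces by inverse-transform sampling of S(F)."""
    u = rng.uniform(size=n)
    a = k0 * kT / (loading_rate * delta_x)
    return (kT / delta_x) * np.log1p(-np.log(u) / a)


def gen_ramp_trajectory(spec: RampSimSpec):
    """Simulate a force-ramp extension trajectory with unfolding events.

    Returns (RampTrajectory, events): the noisy trajectory and the list of
    true UnfoldingEvents that occur before ``f_max`` (time order).  The
    extension is the FJC extension at the current force of all contour
    length released so far, plus linear drift and Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    kT = spec.fjc.kT
    duration = spec.f_max / spec.loading_rate
    t = np.arange(0.0, duration, 1.0 / spec.sample_rate)
    force = spec.loading_rate * t

    ruptures = []
    for k0, dx, dlc in spec.states:
        f_u = float(bell_rupture_forces(k0, dx, spec.loading_rate, 1, rng, kT)[0])
        if f_u < spec.f_max:
            ruptures.append((f_u, dlc))
    ruptures.sort()

    ext = np.zeros_like(t)
    events = []
    for f_u, dlc in ruptures:
        after = force >= f_u
        if dlc > 0:
            ext[after] += fjc_extension(force[after], dlc, spec.fjc)
        k = int(np.argmax(after))
        t_u = float(t[k])
        step = float(fjc_extension(f_u, dlc, spec.fjc)) if dlc > 0 else 0.0
        if step > 0:
            events.append(UnfoldingEvent(t_U=t_u, F_U=f_u, step=step, dLc=float(dlc)))
    ext += spec.drift * t
    if spec.noise_sd > 0:
        ext = ext + rng.normal(0.0, spec.noise_sd, size=len(t))
    traj = RampTrajectory(
        time=t,
        force=force,
        extension=ext,
        loading_rate=spec.loading_rate,
        sample_rate=spec.sample_rate,
    )
    return traj, events


# ---------------------------------------------------------------------------
# TF disorder datasets

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class TFSimSpec:
    """Simulation spec for a synthetic TF disorder dataset.

    Per-residue disorder = clip(baseline + delta inside the NLS-to-closest-
    terminus region + Gaussian noise, 0, 1).  The NLS interval is placed
    uniformly along each sequence.  Defaults reflect typical human TF
    statistics: lengths 200-800 residues, NLS 8-16 residues, baseline
    disorder 0.45.
    """

    n_proteins: int = 300
    length_range: tuple = (200, 800)
    nls_length_range: tuple = (8, 16)
    baseline_disorder_mean: float = 0.45
    region_disorder_delta: float = 0.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        lo, hi = self.length_range
        nlo, nhi = self.nls_length_range
        if lo <= 0 or hi < lo or nlo <= 0 or nhi < nlo or nhi > lo:
            raise ValueError("invalid length ranges")
        if not (0.0 <= self.baseline_disorder_mean <= 1.0):
            raise ValueError("baseline disorder mean must lie in [0, 1]")
        if not (0.0 <= min(1.0, self.baseline_disorder_mean + self.region_disorder_delta)):
            raise ValueError("baseline + delta must clip into [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_tf_dataset(spec: TFSimSpec, with_sequences: bool = False):
    """Generate TFRecords with a planted disorder elevation near the NLS.

    Returns (records, truth) where truth maps record id to the ground-truth
    region (side, (start, end)) and the planted delta.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    nlo, nhi = spec.nls_length_range
    records, truth = [], {}
    for i in range(spec.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        nls_len = int(rng.integers(nlo, nhi + 1))
        start = int(rng.integers(1, L - nls_len + 2))
        end = start + nls_len - 1
        seq = "".join(rng.choice(_AA, size=L)) if with_sequences else None
        rec = TFRecord(
            id=f"TF{i:04d}",
            length=L,
            nls=(start, end, 1.0),
            disorder=np.zeros(L),
            sequence=seq,
        )
        side, (rlo, rhi) = terminal_region(rec)
        profile = np.full(L, spec.baseline_disorder_mean)
        profile[rlo - 1 : rhi] += spec.region_disorder_delta
        if spec.noise_sd > 0:
            profile = profile + rng.normal(0.0, spec.noise_sd, size=L)
        rec.disorder = np.clip(profile, 0.0, 1.0)
        records.append(rec)
        truth[rec.id] = {"side": side, "region": (rlo, rhi), "delta": spec.region_disorder_delta}
    return records, truth


# ---------------------------------------------------------------------------
# writers

def write_timecourses(timecourses, path):
    """Write one or more TimeCourses to a single CSV."""
    frames = []
    for i, tc in enumerate(timecourses):
        df = tc.to_frame()
        if not tc.cell_id:
            df["cell_id"] = f"cell{i:04d}"
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def write_frame_stack(stack: FrameStack, masks: MaskPair, out_dir):
    """Write a stack as multi-page TIFF + mask TIFFs + frame sidecar CSV."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "stack.tif", stack.frames.astype(np.float32))
    tifffile.imwrite(out / "nucleus_mask.tif", masks.nucleus.astype(np.uint8) * 255)
    tifffile.imwrite(out / "cell_mask.tif", masks.cell.astype(np.uint8) * 255)
    pd.DataFrame({"t_s": stack.times, "phase": stack.phases}).to_csv(
        out / "frames.csv", index=False
    )
    return out


def write_trajectory(traj: RampTrajectory, path):
    traj.to_frame().to_csv(path, index=False)
    return Path(path)


def write_tf_dataset(records, out_dir):
    """Write FASTA (when sequences exist) + disorder TSV + NLS TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows_d, rows_n = [], []
    fasta_lines = []
    for r in records:
        if r.sequence:
            fasta_lines.append(f">{r.id}\n{r.sequence}\n")
        for pos, score in enumerate(r.disorder, start=1):
            rows_d.append((r.id, pos, score))
        s, e, sc = r.nls
        rows_n.append((r.id, int(s), int(e), float(sc)))
    if fasta_lines:
        (out / "sequences.fasta").write_text("".join(fasta_lines))
    pd.DataFrame(rows_d, columns=["id", "position", "score"]).to_csv(
        out / "disorder.tsv", sep="\t", index=False
    )
    pd.DataFrame(rows_n, columns=["id", "start", "end", "score"]).to_csv(
        out / "nls.tsv", sep="\t", index=False
    )
    return out
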