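"""Quantification of live-cell image stacks into compartment time courses.

Converts background-corrected frames plus nucleus/cell masks into
normalized nuclear and cytoplasmic signals: N_norm = sum(nucleus)/sum(cell)
and C_norm = 1 - N_norm, used as proxies for the compartment
concentrations.  The ratio is taken on integrated (summed) intensities; the
volume factor v of the kinetic model absorbs compartment-size effects.
Cytoplasm is defined as cell minus nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "FrameStack",
    "MaskPair",
    "background_correct",
    "quantify_frame",
    "build_timecourse",
    "read_stack",
    "read_mask",
]

ACTIVATION = "activation"
RECOVERY = "recovery"


@dataclass
class TimeCourse:
    """Phased nuclear/cytoplasmic signal series for one cell.

    ``t_s`` is the phase-local clock: it re-zeroes at the start of the
    recovery phase (first frame after illumination off).  ``N`` and ``C``
    are the normalized compartment signals (or model concentrations when
    simulated) and ``ratio`` = N/C.
    """

    t_s: np.ndarray
    phase: np.ndarray
    N: np.ndarray
    C: np.ndarray
    ratio: np.ndarray
    cell_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t_s)
        for arr in (self.phase, self.N, self.C, self.ratio):
            if len(arr) != n:
                raise ValueError("all series must have equal length")

    def __len__(self):
        return len(self.t_s)

    def recovery_series(self):
        m = self.phase == RECOVERY
        return self.t_s[m], self.ratio[m]

    def activation_series(self):
        m = self.phase == ACTIVATION
        return self.t_s[m], self.ratio[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "phase": self.phase,
                "t_s": self.t_s,
                "N_norm": self.N,
                "C_norm": self.C,
                "ratio": self.ratio,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id: str | None = None) -> "TimeCourse":
        if cell_id is not None:
            df = df[df["cell_id"] == cell_id]
        else:
            cell_id = str(df["cell_id"].iloc[0]) if "cell_id" in df else ""
        return cls(
            t_s=df["t_s"].to_numpy(dtype=float),
            phase=df["phase"].to_numpy(dtype=object),
            N=df["N_norm"].to_numpy(dtype=float),
            C=df["C_norm"].to_numpy(dtype=float),
            ratio=df["ratio"].to_numpy(dtype=float),
            cell_id=str(cell_id),
        )


@dataclass
class FrameStack:
    """Stack of same-shape 2-D intensity frames with timestamps and phases."""

    frames: np.ndarray  # (T, H, W)
    times: np.ndarray  # seconds, strictly increasing
    phases: np.ndarray  # "activation" | "recovery"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.times) != len(self.frames) or len(self.phases) != len(self.frames):
            raise ValueError("times/phases must align with frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class MaskPair:
    """Binary nucleus and cell masks; nucleus must be a subset of cell."""

    nucleus: np.ndarray
    cell: np.ndarray

    def __post_init__(self):
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        self.cell = np.asarray(self.cell, dtype=bool)
        if self.nucleus.shape != self.cell.shape:
            raise ValueError("masks must share a shape")
        if not self.nucleus.any():
            raise ValueError("nucleus mask is empty")
        if not self.cell.any():
            raise ValueError("cell mask is empty")
        if np.any(self.nucleus & ~self.cell):
            raise ValueError("nucleus mask must be contained in cell mask")

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.cell & ~self.nucleus


def background_correct(frame: np.ndarray, background_region: np.ndarray) -> np.ndarray:
    """Subtract the median of a cell-free background region; clip at zero."""
    frame = np.asarray(frame, dtype=float)
    bg = np.asarray(background_region, dtype=bool)
    if not bg.any():
        raise ValueError("background region is empty")
    return np.clip(frame - float(np.median(frame[bg])), 0.0, None)


def quantify_frame(frame: np.ndarray, masks: MaskPair):
    """Normalized nuclear and cytoplasmic signal of one corrected frame.

    Returns (N_norm, C_norm) with N_norm + C_norm = 1 exactly.
    """
    frame = np.asarray(frame, dtype=float)
    total = float(frame[masks.cell].sum())
    if total <= 0:
        raise ValueError("zero total cell intensity")
    n = float(frame[masks.nucleus].sum()) / total
    return n, 1.0 - n


def build_timecourse(
    stack: FrameStack,
    masks: MaskPair,
    background_region: np.ndarray | None = None,
    cell_id: str = "",
) -> TimeCourse:
    """Quantify every frame of a stack into a phased time course.

    The recovery clock is re-zeroed at the first recovery frame; the
    activation clock starts at the first frame.  A nucleus==cell mask makes
    C_norm zero and the ratio is flagged infinite rather than raising.
    """
    if masks is None:
        raise ValueError("missing MaskPair (nucleus and cell masks)")
    n_list, c_list = [], []
    for i, frame in enumerate(stack.frames):
        if background_region is not None:
            frame = background_correct(frame, background_region)
        try:
            n, c = quantify_frame(frame, masks)
        except ValueError as e:
            raise ValueError(f"frame {i}: {e}") from e
        n_list.append(n)
        c_list.append(c)
    N = np.array(n_list)
    C = np.array(c_list)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(C > 0, N / np.where(C > 0, C, 1.0), np.inf)

    t = stack.times.astype(float).copy()
    rec = stack.phases == RECOVERY
    if rec.any():
        t0_rec = t[rec][0]
        t = np.where(rec, t - t0_rec, t - t[0])
    else:
        t = t - t[0]
    return TimeCourse(
        t_s=t, phase=stack.phases.copy(), N=N, C=C, ratio=ratio, cell_id=cell_id
    )


def read_stack(tiff_path, frames_csv) -> FrameStack:
    """Read a multi-page TIFF plus its frame-time/phase sidecar CSV."""
    import tifffile

    frames = tifffile.imread(str(tiff_path))
    if frames.ndim == 2:
        frames = frames[None]
    tbl = pd.read_csv(frames_csv)
    return FrameStack(
        frames=frames,
        times=tbl["t_s"].to_numpy(dtype=float),
        phases=tbl["phase"].to_numpy(dtype=object),
    )


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (PNG/TIFF); non-zero pixels are True."""
    import imageio.v3 as iio

    img = iio.imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0
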