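"""Behavioral and physiology scores.

Implements the startle-induced negative geotaxis (SING) climbing score, the
olfactory two-choice preference index, ΔF/F fluorescence traces with two
baseline conventions, Ca²⁺ activity metrics (active-frame fraction and
maximal amplitude against a 2×SD baseline threshold), and the nicotine
feeding-dose arithmetic.

SING partitions ~20 flies over five stacked tubes after repeated startles and
scores ``Σ tube_i × i / (total × 5)``, so the score lives in [0.2, 1] with 1 =
all flies climbed to the top tube. The preference index is
``(n_A − n_B) / total`` in [−1, 1]. ΔF/F is ``(F − F0)/F0`` with F0 either the
mean of the five frames preceding a stimulus (in vivo, evoked responses) or
the minimal five-frame rolling mean (in vitro, spontaneous activity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TubeCounts",
    "TraceSet",
    "sing_score",
    "preference_index",
    "dff_trace",
    "activity_metrics",
    "nicotine_dose",
]


@dataclass
class TubeCounts:
    """Flies per tube (1..5) at the end of a SING assay."""

    tubes: tuple[int, int, int, int, int]

    @property
    def total(self) -> int:
        return int(sum(self.tubes))


@dataclass
class TraceSet:
    """ROI fluorescence traces: ``F`` is frames x ROIs, in arbitrary units.

    ``stimulus_frame`` marks stimulus onset for the pre-stimulus baseline
    mode; it is irrelevant for the minimal-window mode.
    """

    F: np.ndarray
    frame_rate: float
    stimulus_frame: int | None = None

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim == 1:
            self.F = self.F[:, None]
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.F.shape[0]

    @property
    def n_rois(self) -> int:
        return self.F.shape[1]


def sing_score(counts: TubeCounts) -> float:
    """Tube-weighted climbing score in [0.2, 1]."""
    tubes = np.asarray(counts.tubes, dtype=float)
    if tubes.shape != (5,):
        raise ValueError("expected counts for exactly 5 tubes")
    if np.any(tubes < 0):
        raise ValueError("tube counts must be non-negative")
    total = tubes.sum()
    if total == 0:
        raise ValueError("no flies counted")
    weights = np.arange(1, 6, dtype=float)
    return float((tubes * weights).sum() / (total * 5.0))


def preference_index(n_a: int, n_b: int, total: int) -> float:
    """Odor-choice preference index (n_A − n_B)/total in [−1, 1]."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if n_a < 0 or n_b < 0 or n_a + n_b > total:
        raise ValueError("tube counts must be non-negative and sum to <= total")
    return (n_a - n_b) / total


def _rolling_mean5_min(F: np.ndarray) -> np.ndarray:
    """Per ROI, the minimal mean over all 5-frame windows."""
    n = F.shape[0]
    if n < 5:
        raise ValueError("need at least 5 frames for a 5-frame baseline")
    csum = np.cumsum(F, axis=0)
    csum = np.vstack([np.zeros((1, F.shape[1])), csum])
    windows = (csum[5:] - csum[:-5]) / 5.0  # (n-4) x rois
    return windows.min(axis=0)


def dff_trace(traces: TraceSet, baseline_mode: str = "prestim_mean5") -> np.ndarray:
    """ΔF/F = (F − F0)/F0 per ROI.

    ``prestim_mean5``: F0 is the mean of the 5 frames before
    ``traces.stimulus_frame``. ``min_mean5``: F0 is the minimal 5-frame
    rolling mean across the whole trace.
    """
    F = traces.F
    if baseline_mode == "prestim_mean5":
        s = traces.stimulus_frame
        if s is None or s < 5:
            raise ValueError("prestim_mean5 requires stimulus_frame >= 5")
        F0 = F[s - 5 : s].mean(axis=0)
    elif baseline_mode == "min_mean5":
        F0 = _rolling_mean5_min(F)
    else:
        raise ValueError(f"unknown baseline_mode: {baseline_mode!r}")
    if np.any(F0 <= 0):
        raise ValueError("baseline F0 must be positive for all ROIs")
    return (F - F0[None, :]) / F0[None, :]


def activity_metrics(dff: np.ndarray, baseline_frames, k_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI (activity fraction, maximal amplitude).

    A frame is active when its ΔF/F exceeds ``k_sd`` × SD of the baseline
    frames; the activity fraction is active frames / total frames and the
    amplitude is the trace maximum. A zero baseline SD makes the threshold 0
    (any positive excursion counts as activity).
    """
    dff = np.asarray(dff, dtype=float)
    if dff.ndim == 1:
        dff = dff[:, None]
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames must be nonempty")
    if baseline_frames.min() < 0 or baseline_frames.max() >= dff.shape[0]:
        raise ValueError("baseline frames outside trace")
    sd = dff[baseline_frames].std(axis=0, ddof=0)
    threshold = k_sd * sd
    active = dff > threshold[None, :]
    fraction = active.mean(axis=0)
    amplitude = dff.max(axis=0)
    return fraction, amplitude


def nicotine_dose(
    concentration_per_ml: float = 0.2,
    food_ul_per_day: float = 1.0,
    body_weight_mg: float = 0.1,
) -> float:
    """Daily nicotine uptake per mg body weight from food dosing.

    With nicotine mixed into food at ``concentration_per_ml`` (amount per ml
    of food), a fly eating ``food_ul_per_day`` µl of food ingests
    ``concentration_per_ml / 1000 × food_ul_per_day`` per day; dividing by
    body weight gives the per-mg daily dose. At the defaults (0.2 per ml,
    ~1 µl/day, ~0.1 mg fly) this is 0.002 — the amount a smoker absorbs with
    roughly 10 cigarettes a day, scaled by body weight.
    """
    if concentration_per_ml < 0 or food_ul_per_day < 0:
        raise ValueError("concentration and intake must be non-negative")
    if body_weight_mg <= 0:
        raise ValueError("body_weight_mg must be positive")
    daily_uptake = concentration_per_ml / 1000.0 * food_ul_per_day
    return daily_uptake / body_weight_mg
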