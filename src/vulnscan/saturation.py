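"""Cell-type discovery saturation: subsampling curves and Michaelis–Menten fits.

How many cells must be sequenced before (nearly) all cell types of a tissue
are recovered? Subsamples of increasing size are drawn without replacement
from a labeled cell population; a type counts as detected when at least
``threshold`` of its cells land in the draw. The mean detected-type count as
a function of sample size follows a saturating curve that is summarized by
Michaelis–Menten kinetics ``V(n) = Vmax * n / (Km + n)``: ``Vmax`` is the
asymptotic type count and ``Km`` the number of cells at half-saturation.

Per-type draw counts are sampled with the multivariate hypergeometric
distribution — identical in law to drawing individual cells without
replacement, but O(#types) per draw, which keeps a 0..50,000-cell grid at 50
repetitions cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats


@dataclass
class SaturationCurve:
    sizes: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    detection_threshold: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mean_detected": self.mean, "sd_detected": self.sd}
        )


@dataclass
class MMFit:
    vmax: float
    km: float
    rss: float

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.vmax * n / (self.km + n)


def _type_counts(cell_labels) -> np.ndarray:
    return pd.Series(list(cell_labels)).value_counts().to_numpy()


def subsample_curve(
    cell_labels,
    max_n: int = 50_000,
    step: int = 100,
    reps: int = 50,
    threshold: int = 1,
    seed: int = 0,
    nested: bool = False,
) -> SaturationCurve:
    """Detected cell-type counts over subsample sizes 0..max_n in steps.

    For each size, ``reps`` independent draws without replacement are taken
    and the number of types with at least ``threshold`` drawn cells is
    recorded (mean and SD over draws). ``nested=True`` instead reuses one
    random ordering of the population per repetition so that draws are nested
    across sizes and the per-repetition curve is monotone.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = _type_counts(cell_labels)
    if counts.size == 0:
        raise ValueError("cell_labels is empty")
    N = int(counts.sum())
    if max_n > N:
        warnings.warn(f"max_n={max_n} exceeds population size {N}; truncated", UserWarning)
        max_n = N
    sizes = np.arange(0, max_n + 1, step)
    rng = np.random.default_rng(seed)
    detected = np.zeros((reps, len(sizes)))
    if nested:
        labels_idx = np.repeat(np.arange(len(counts)), counts)
        for r in range(reps):
            perm = rng.permutation(labels_idx)
            # position (1-based) of the threshold-th cell of each type
            first = np.full(len(counts), N + 1)
            seen = np.zeros(len(counts), dtype=int)
            for pos, t in enumerate(perm, start=1):
                seen[t] += 1
                if seen[t] == threshold:
                    first[t] = pos
            detected[r] = (first[None, :] <= sizes[:, None]).sum(axis=1)
    else:
        for j, n in enumerate(sizes):
            if n == 0:
                continue
            for r in range(reps):
                draw = rng.multivariate_hypergeometric(counts, int(n))
                detected[r, j] = int((draw >= threshold).sum())
    return SaturationCurve(
        sizes=sizes,
        mean=detected.mean(axis=0),
        sd=detected.std(axis=0, ddof=0),
        n_reps=reps,
        detection_threshold=threshold,
    )


def expected_detection(cell_labels, n: int, threshold: int = 1) -> float:
    """Closed-form E[#types detected] at draw size n under the hypergeometric law."""
    counts = _type_counts(cell_labels)
    N = int(counts.sum())
    return float(sum(scipy.stats.hypergeom.sf(threshold - 1, N, int(K), int(n)) for K in counts))


def fit_michaelis_menten(curve: SaturationCurve) -> MMFit:
    """Nonlinear least squares of mean detected = Vmax n / (Km + n).

    Initialized at Vmax = max mean and Km = the size whose mean is nearest
    half of it. Requires at least 3 distinct sizes with nonzero mean.
    """
    sizes = np.asarray(curve.sizes, dtype=float)
    mean = np.asarray(curve.mean, dtype=float)
    nz = mean > 0
    if len(np.unique(sizes[nz])) < 3:
        raise ValueError("need >= 3 distinct sizes with nonzero mean")
    vmax0 = float(mean.max())
    km0 = float(sizes[np.argmin(np.abs(mean - vmax0 / 2.0))])
    km0 = max(km0, float(sizes[sizes > 0].min()) if (sizes > 0).any() else 1.0)

    def f(n, vmax, km):
        return vmax * n / (km + n)

    try:
        popt, _ = scipy.optimize.curve_fit(
            f, sizes, mean, p0=[vmax0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge (initial Vmax={vmax0}, Km={km0})"
        ) from err
    vmax, km = float(popt[0]), float(popt[1])
    rss = float(((mean - f(sizes, vmax, km)) ** 2).sum())
    return MMFit(vmax=vmax, km=km, rss=rss)
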