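"""Spot detection, channel registration, and red-conditioned colocalization.

Diffraction-limited spots are detected per channel by matched filtering
(Gaussian smoothing at the PSF scale), robust thresholding (median + k * MAD
of the filtered image), and sub-pixel refinement by least-squares 2-D
Gaussian fitting.  Colocalization follows the red-conditioned convention:
each red spot pairs with at most one green spot within a pairing radius, and
C is the paired fraction of all red spots.

Coordinates are 0-based pixel-center throughout; distances are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .stoichiometry import ColocalizationMeasurement

__all__ = [
    "ColocalizationParams",
    "detect_spots",
    "register_channels",
    "colocalize",
    "field_density_qc",
    "chance_colocalization_rate",
]


@dataclass(frozen=True)
class ColocalizationParams:
    """Detection and pairing settings.

    ``threshold_k`` scales the MAD of the matched-filtered image; the
    default is calibrated so a blank noise field yields zero detections in
    >= 99% of realizations while spots at signal-to-noise >= 5 are recovered
    essentially completely.  ``pairing_radius`` defaults to about 2 px
    (1.5x a typical PSF sigma).
    """

    psf_sigma: float = 1.2
    threshold_k: float = 8.0
    pairing_radius: float = 2.0
    registration_shift: tuple[float, float] = (0.0, 0.0)
    fit_window: int = 4  # half-width of the Gaussian-fit window, px

    def __post_init__(self) -> None:
        if self.pairing_radius <= 0:
            raise ValueError("pairing_radius must be > 0")


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return offset + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))


def _refine_spot(
    image: np.ndarray, x: float, y: float, params: ColocalizationParams
) -> tuple[float, float, float] | None:
    """Least-squares Gaussian fit in a small window; returns (x, y, integral)."""
    h, w = image.shape
    r = params.fit_window
    cx, cy = int(round(x)), int(round(y))
    if not (r <= cx < w - r and r <= cy < h - r):
        return None
    win = image[cy - r : cy + r + 1, cx - r : cx + r + 1].astype(float)
    yy, xx = np.mgrid[cy - r : cy + r + 1, cx - r : cx + r + 1]
    offset0 = float(win.min())
    amp0 = float(win.max() - offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            win.ravel(),
            p0=(amp0, x, y, params.psf_sigma, offset0),
            bounds=(
                (0.0, cx - r, cy - r, 0.3, -np.inf),
                (np.inf, cx + r, cy + r, 4.0 * params.psf_sigma, np.inf),
            ),
            maxfev=200,
        )
    except RuntimeError:
        return None
    amp, x0, y0, sigma, _ = popt
    return float(x0), float(y0), float(2.0 * np.pi * amp * sigma**2)


def detect_spots(
    image: np.ndarray,
    params: ColocalizationParams = ColocalizationParams(),
    field_id: int | str = 0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in a single-channel image.

    Returns a table with columns x, y (sub-pixel), integrated_intensity and
    field_id.  Candidate local maxima of the matched-filtered image above
    median + k * MAD are refined by Gaussian fitting; detections closer than
    2 PSF sigma are merged, keeping the brighter.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if image.max() == image.min():
        raise ValueError("constant image: no detectable structure")

    filtered = ndimage.gaussian_filter(image, params.psf_sigma)
    med = np.median(filtered)
    mad = np.median(np.abs(filtered - med)) * 1.4826
    threshold = med + params.threshold_k * max(mad, 1e-12)
    peaks = peak_local_max(
        filtered,
        min_distance=max(1, int(round(2 * params.psf_sigma))),
        threshold_abs=threshold,
        exclude_border=params.fit_window,
    )

    rows = []
    for py, px in peaks:
        refined = _refine_spot(image, float(px), float(py), params)
        if refined is None:
            continue
        x0, y0, integral = refined
        rows.append({"x": x0, "y": y0, "integrated_intensity": integral})
    df = pd.DataFrame(rows, columns=["x", "y", "integrated_intensity"])

    # merge duplicates within 2 sigma, keep brighter
    if len(df) > 1:
        df = df.sort_values("integrated_intensity", ascending=False).reset_index(
            drop=True
        )
        keep = np.ones(len(df), dtype=bool)
        xy = df[["x", "y"]].to_numpy()
        for i in range(len(df)):
            if not keep[i]:
                continue
            d = np.hypot(*(xy[i + 1 :] - xy[i]).T)
            keep[i + 1 :] &= d >= 2.0 * params.psf_sigma
        df = df[keep].reset_index(drop=True)
    df["field_id"] = field_id
    return df


def register_channels(
    red: pd.DataFrame,
    green: pd.DataFrame,
    params: ColocalizationParams = ColocalizationParams(),
    max_shift: float = 10.0,
) -> tuple[float, float]:
    """Estimate the translation (dx, dy) mapping green coordinates onto red.

    Coarse stage: mode of all pairwise red-green coordinate differences
    within ``max_shift`` on a 1-px histogram.  Fine stage: mean residual of
    pairs matched at the coarse shift within the pairing radius.
    """
    if len(red) < 10 or len(green) < 10:
        raise ValueError("registration requires >= 10 spots per channel")
    r = red[["x", "y"]].to_numpy()
    g = green[["x", "y"]].to_numpy()
    diff = r[:, None, :] - g[None, :, :]  # red - green
    flat = diff.reshape(-1, 2)
    inside = (np.abs(flat) <= max_shift).all(axis=1)
    if not inside.any():
        raise ValueError("no candidate shifts within max_shift: unregisterable")
    flat = flat[inside]
    bins = np.arange(-max_shift - 0.5, max_shift + 1.5)
    hist, _, _ = np.histogram2d(flat[:, 0], flat[:, 1], bins=(bins, bins))
    ix, iy = np.unravel_index(np.argmax(hist), hist.shape)
    coarse = np.array([bins[ix] + 0.5, bins[iy] + 0.5])

    resid = flat - coarse
    close = np.hypot(resid[:, 0], resid[:, 1]) <= max(params.pairing_radius, 1.0)
    if not close.any():
        raise ValueError("no convergent shift: unregisterable data")
    fine = flat[close].mean(axis=0)
    return float(fine[0]), float(fine[1])


def _greedy_pairs(
    red_xy: np.ndarray, green_xy: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """One-to-one nearest-neighbor assignment by ascending pair distance."""
    if len(red_xy) == 0 or len(green_xy) == 0:
        return []
    d = np.hypot(
        red_xy[:, 0:1] - green_xy[None, :, 0].reshape(1, -1),
        red_xy[:, 1:2] - green_xy[None, :, 1].reshape(1, -1),
    )
    ri, gi = np.nonzero(d <= radius)
    order = np.argsort(d[ri, gi], kind="stable")
    used_r: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ri[k]), int(gi[k])
        if i in used_r or j in used_g:
            continue
        pairs.append((i, j))
        used_r.add(i)
        used_g.add(j)
    return pairs


def colocalize(
    red: pd.DataFrame,
    green: pd.DataFrame,
    params: ColocalizationParams = ColocalizationParams(),
) -> ColocalizationMeasurement:
    """Red-conditioned colocalization over one or more fields.

    Applies ``params.registration_shift`` to green coordinates, then pairs
    each red spot to at most one green spot within ``pairing_radius``
    (nearest first, one-to-one).  Returns per-field (n_red, n_paired)
    counts; C is the pooled paired fraction of red spots.
    """
    if len(red) == 0:
        raise ValueError("empty measurement: no red spots")
    dx, dy = params.registration_shift
    per_field = []
    for fid in sorted(red["field_id"].unique(), key=str):
        r = red[red["field_id"] == fid]
        g = green[green["field_id"] == fid] if len(green) else green
        red_xy = r[["x", "y"]].to_numpy()
        green_xy = (
            g[["x", "y"]].to_numpy() + np.array([dx, dy]) if len(g) else np.empty((0, 2))
        )
        pairs = _greedy_pairs(red_xy, green_xy, params.pairing_radius)
        per_field.append((len(r), len(pairs)))
    return ColocalizationMeasurement(per_field_counts=per_field)


def chance_colocalization_rate(green_density_per_px2: float, radius: float) -> float:
    """Expected false-colocalization rate for spatially independent channels.

    A red spot pairs by chance when at least one green spot of a Poisson
    field falls within the pairing radius: 1 - exp(-rho * pi * r^2).
    """
    return 1.0 - np.exp(-green_density_per_px2 * np.pi * radius**2)


def field_density_qc(
    n_spots: int,
    field_area_um2: float,
    bounds: tuple[float, float] = (1.0, 4.0),
) -> tuple[float, bool]:
    """Spot density per 100 um^2 and whether it lies in the working range."""
    if field_area_um2 <= 0:
        raise ValueError("field area must be > 0")
    density = 100.0 * n_spots / field_area_um2
    return density, bounds[0] <= density <= bounds[1]
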