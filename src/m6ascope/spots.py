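"""Single-molecule spot detection with sub-pixel 2D Gaussian localization.

The detection chain mirrors standard single-molecule TIRF processing:
rolling-ball background subtraction (radius 3 px), Gaussian blur
(sigma 1.1 px), local maxima above an intensity threshold, then a
least-squares 2D Gaussian fit in a small window around each maximum to
localize the molecule centre to sub-pixel (better than half-pixel)
accuracy.

Coordinates are 0-based (row, col) with the origin at the centre of the
top-left pixel; a spot sitting exactly on pixel (10, 20) has fitted centre
(10.0, 20.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

__all__ = [
    "Image",
    "Spot",
    "SpotSet",
    "subtract_background",
    "smooth",
    "estimate_threshold",
    "fit_gaussian_2d",
    "detect_spots",
]


@dataclass
class Image:
    """A 2D intensity raster with acquisition metadata.

    ``pixel_size_nm`` defaults to 100 (one camera pixel is ~100 nm of sample
    on the 60x TIRF path).
    """

    pixels: np.ndarray
    channel: str = ""
    round: int = 0
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image.pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Spot:
    """A sub-pixel localized single molecule."""

    row: float
    col: float
    amplitude: float
    sigma: float
    background: float
    channel: str = ""
    fit_rss: float = 0.0
    status: str = "ok"  # "ok" or "failed"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class SpotSet:
    """Detected spots from one image, plus source metadata."""

    spots: list[Spot] = field(default_factory=list)
    channel: str = ""
    round: int = 0
    shape: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def coordinates(self, ok_only: bool = True) -> np.ndarray:
        """(n, 2) array of (row, col) centres."""
        pts = [(s.row, s.col) for s in self.spots if s.ok or not ok_only]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def ok_spots(self) -> "SpotSet":
        return replace(self, spots=[s for s in self.spots if s.ok])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "round": self.round,
                    "channel": s.channel or self.channel,
                    "row": s.row,
                    "col": s.col,
                    "amplitude": s.amplitude,
                    "sigma": s.sigma,
                    "background": s.background,
                    "fit_rss": s.fit_rss,
                    "status": s.status,
                }
                for s in self.spots
            ],
            columns=[
                "round", "channel", "row", "col", "amplitude",
                "sigma", "background", "fit_rss", "status",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpotSet":
        spots = [
            Spot(
                row=float(r.row), col=float(r.col), amplitude=float(r.amplitude),
                sigma=float(r.sigma), background=float(r.background),
                channel=str(r.channel), fit_rss=float(r.fit_rss), status=str(r.status),
            )
            for r in df.itertuples()
        ]
        rnd = int(df["round"].iloc[0]) if len(df) else 0
        ch = str(df["channel"].iloc[0]) if len(df) else ""
        return cls(spots=spots, channel=ch, round=rnd)


def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, Image) else np.asarray(image, dtype=float)


def _wrap_like(pixels: np.ndarray, image) -> "Image | np.ndarray":
    if isinstance(image, Image):
        return Image(pixels, channel=image.channel, round=image.round,
                     pixel_size_nm=image.pixel_size_nm)
    return pixels


def subtract_background(image, radius: int = 3):
    """Rolling-ball background subtraction, clipped at zero.

    Parameters
    ----------
    image : Image or 2D array
    radius : int
        Rolling-ball radius in pixels (default 3).
    """
    a = _as_array(image)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(a.shape):
        raise ValueError(f"radius {radius} exceeds image extent {a.shape}")
    bg = rolling_ball(a, radius=radius)
    return _wrap_like(np.clip(a - bg, 0.0, None), image)


def smooth(image, sigma: float = 1.1):
    """Gaussian blur with a normalized kernel (default sigma 1.1 px)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = _as_array(image)
    return _wrap_like(ndimage.gaussian_filter(a, sigma=sigma, mode="nearest"), image)


def estimate_threshold(image, k: float = 5.0) -> float:
    """Detection threshold as background median + k * MAD.

    A pragmatic stand-in for a manually chosen pixel threshold: robust
    centre plus ``k`` robust standard deviations (MAD scaled to sigma).
    """
    a = _as_array(image)
    med = float(np.median(a))
    mad = float(np.median(np.abs(a - med))) * 1.4826
    return med + k * mad


def _gauss2d(params, rr, cc):
    amp, r0, c0, sig, bg = params
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sig**2)) + bg


def fit_gaussian_2d(image, peak: tuple[int, int], window: int = 3,
                    channel: str | None = None) -> Spot:
    """Least-squares isotropic 2D Gaussian fit around an integer peak.

    Fits amplitude * G((row, col); centre, sigma) + background over a
    (2*window+1)^2 neighbourhood (clipped at borders, at least 3x3).
    Failures are reported as a Spot with ``status='failed'`` rather than
    being dropped.
    """
    a = _as_array(image)
    ch = channel if channel is not None else (image.channel if isinstance(image, Image) else "")
    pr, pc = int(peak[0]), int(peak[1])
    r0, r1 = max(0, pr - window), min(a.shape[0], pr + window + 1)
    c0, c1 = max(0, pc - window), min(a.shape[1], pc + window + 1)
    patch = a[r0:r1, c0:c1]
    failed = Spot(row=float(pr), col=float(pc), amplitude=0.0, sigma=1.0,
                  background=0.0, channel=ch, fit_rss=np.inf, status="failed")
    if patch.shape[0] < 3 or patch.shape[1] < 3:
        return failed
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
    bg0 = float(patch.min())
    amp0 = float(patch.max() - bg0)
    if amp0 <= 0:
        return failed
    x0 = np.array([amp0, float(pr), float(pc), 1.3, bg0])
    lo = [0.0, r0 - 1.0, c0 - 1.0, 0.2, -np.inf]
    hi = [np.inf, r1, c1, max(r1 - r0, c1 - c0), np.inf]

    def resid(p):
        return (_gauss2d(p, rr, cc) - patch).ravel()

    try:
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                     max_nfev=200)
    except Exception:
        return failed
    amp, r_fit, c_fit, sig, bg = sol.x
    if not sol.success or amp <= 0 or sig <= 0:
        return failed
    if not (-0.5 <= r_fit <= a.shape[0] - 0.5 and -0.5 <= c_fit <= a.shape[1] - 0.5):
        return failed
    return Spot(row=float(r_fit), col=float(c_fit), amplitude=float(amp),
                sigma=float(sig), background=float(bg), channel=ch,
                fit_rss=float(np.sum(sol.fun**2)), status="ok")


def _merge_close_maxima(peaks: np.ndarray, values: np.ndarray,
                        merge_radius: float) -> np.ndarray:
    """Keep the brighter of any two maxima closer than ``merge_radius``."""
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -values))  # brightness desc, then coords
    kept: list[np.ndarray] = []
    for i in order:
        p = peaks[i]
        if all(np.hypot(*(p - q)) > merge_radius for q in kept):
            kept.append(p)
    return np.asarray(kept, dtype=int).reshape(-1, 2)


def detect_spots(
    image,
    threshold: float | None = None,
    *,
    background_radius: int = 3,
    smooth_sigma: float = 1.1,
    fit_window: int = 3,
    merge_radius: float = 2.0,
    threshold_k: float = 5.0,
) -> SpotSet:
    """Full detection chain: subtract background, blur, find maxima, fit.

    Parameters
    ----------
    image : Image or 2D array
    threshold : float, optional
        Pixel threshold applied to the blurred, background-subtracted image;
        maxima must exceed it strictly.  When omitted it is estimated as
        median + ``threshold_k`` * MAD of that image.
    background_radius, smooth_sigma
        Rolling-ball radius and blur sigma (defaults 3 px and 1.1).
    fit_window
        Gaussian-fit half-width (7x7 window by default).
    merge_radius
        Maxima closer than this are merged to the brighter one (default 2 px).
    """
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be >= 0")
    bg_sub = subtract_background(image, radius=background_radius)
    pre = smooth(bg_sub, sigma=smooth_sigma)
    prep = _as_array(pre)
    if threshold is None:
        threshold = estimate_threshold(prep, k=threshold_k)
    ch = image.channel if isinstance(image, Image) else ""
    rnd = image.round if isinstance(image, Image) else 0
    peaks = peak_local_max(prep, min_distance=1, threshold_abs=threshold,
                           exclude_border=False)
    # peak_local_max keeps plateaus at == threshold; enforce strict inequality
    if len(peaks):
        vals = prep[peaks[:, 0], peaks[:, 1]]
        keep = vals > threshold
        peaks, vals = peaks[keep], vals[keep]
    spots: list[Spot] = []
    if len(peaks):
        peaks = _merge_close_maxima(peaks, vals, merge_radius)
        # maxima come from the blurred image; the fit runs on the unblurred
        # background-subtracted image to keep the PSF narrow
        for pr, pc in peaks:
            spots.append(fit_gaussian_2d(bg_sub, (pr, pc), window=fit_window,
                                         channel=ch))
    return SpotSet(spots=spots, channel=ch, round=rnd,
                   shape=tuple(prep.shape))
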