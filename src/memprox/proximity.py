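"""Distance-to-surface statistics: D(r), r_c detection, occurrence fraction R.

The membrane "surface" is operationalised as the set of (non-excluded)
lipid atoms of both leaflets: a particle's distance to the surface is the
minimum Euclidean distance to any such atom, with minimum-image wrapping
in x and y only (slab geometry; z is the bilayer normal and never
wrapped).  Glycosyl-tagged atoms can be excluded so that the distance
refers to the phospholipid surface proper.

The slice density is

    D(r) = N(r) / (Dx * Dy * dr * f)

with N(r) the particle count summed over all f frames in the half-open
slab [r, r + dr).  The near-surface occurrence fraction is the percentage
R = 100 * A_r / A where A_r is the area under D(r) up to the cutoff r_c
(first local minimum of D after its first peak) and A the total area up
to r_max.  Since the Eq.-normaliser is constant across bins, R is computed
in the exactly-proportional count-sum form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .ensemble import AtomSelection, FrameEnsemble

__all__ = [
    "SurfaceDistanceSeries",
    "RadialDensity",
    "PeakReport",
    "CutoffResult",
    "DEFAULT_RC",
    "surface_distances",
    "radial_density",
    "first_minimum_after_peak",
    "near_surface_fraction",
    "relative_reduction",
]

#: Species-wise cutoff defaults (Å) used when no interior minimum is found.
DEFAULT_RC = {"O2-": 3.2, "K+": 3.2, "Na+": 2.8, "Cl-": 3.8}


@dataclass
class SurfaceDistanceSeries:
    """Per-frame minimum distances of target particles to the surface."""

    distances: np.ndarray  # (n_frames, n_targets), Å
    species: str = ""
    excluded_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2:
            raise ValueError("distances must be (n_frames, n_targets)")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    @property
    def n_targets(self) -> int:
        return self.distances.shape[1]


@dataclass
class RadialDensity:
    """Binned counts N(r) and slice densities D(r) versus surface distance."""

    bin_width: float
    r_max: float
    counts: np.ndarray  # summed over frames, per bin
    density: np.ndarray  # particles / Å^3 per frame, per bin
    area: float  # Dx * Dy, Å^2
    n_frames: int
    n_excluded: int = 0  # particles with r >= r_max, summed over frames
    species: str = ""

    @property
    def edges(self) -> np.ndarray:
        n_bins = len(self.counts)
        return np.arange(n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + 0.5 * self.bin_width


@dataclass
class PeakReport:
    """First-peak summary: cutoff, areas and occurrence fraction."""

    r_peak: float  # Å, bin centre of the first-peak maximum
    r_c: float  # Å
    area_near: float  # area under D on [0, r_c]
    area_total: float  # area under D on [0, r_max]
    R: float  # percent, 2 decimals
    species: str = ""
    rc_defaulted: bool = False
    n_frames: int = 0


class CutoffResult(NamedTuple):
    r_c: float
    defaulted: bool


def surface_distances(
    ensemble: FrameEnsemble,
    target: AtomSelection,
    membrane: AtomSelection,
    exclude_tags: frozenset | set = frozenset(),
    pbc_xy: bool = True,
    species: str = "",
) -> SurfaceDistanceSeries:
    """Minimum distance of each target particle to the membrane surface.

    ``exclude_tags`` removes membrane atoms carrying any of the given tags
    (e.g. ``{"glycosyl"}``) before the minimisation.  With ``pbc_xy`` the
    x and y separations use the minimum-image convention; z is never
    wrapped.
    """
    exclude_tags = frozenset(exclude_tags)
    t_idx = target.indices
    m_idx = membrane.indices
    if np.intersect1d(t_idx, m_idx).size:
        raise ValueError("target and membrane selections must be disjoint")
    if exclude_tags:
        keep = np.array(
            [not (ensemble.tags[i] & exclude_tags) for i in m_idx], dtype=bool
        )
        m_idx = m_idx[keep]
    if m_idx.size == 0:
        raise ValueError("membrane selection empty after tag exclusion")
    if t_idx.size == 0:
        raise ValueError("empty target selection")

    out = np.empty((ensemble.n_frames, t_idx.size))
    for f in range(ensemble.n_frames):
        tc = ensemble.coords[f, t_idx]  # (T, 3)
        mc = ensemble.coords[f, m_idx]  # (M, 3)
        d = tc[:, None, :] - mc[None, :, :]
        if pbc_xy:
            dx_len, dy_len = ensemble.box[f, 0], ensemble.box[f, 1]
            d[..., 0] -= dx_len * np.round(d[..., 0] / dx_len)
            d[..., 1] -= dy_len * np.round(d[..., 1] / dy_len)
        sq = d[..., 0] * d[..., 0] + d[..., 1] * d[..., 1] + d[..., 2] * d[..., 2]
        out[f] = np.sqrt(sq.min(axis=1))
    return SurfaceDistanceSeries(out, species=species, excluded_tags=exclude_tags)


def radial_density(
    sds: SurfaceDistanceSeries,
    bin_width: float = 0.2,
    r_max: float = 40.0,
    area: float = 80.0 * 80.0,
) -> RadialDensity:
    """Bin distances into half-open slabs and normalise to slice densities."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    n_bins_f = r_max / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("r_max must be a positive multiple of bin_width")
    r = sds.distances.ravel()
    inside = r < r_max
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(r[inside], bins=edges)
    f = sds.n_frames
    density = counts / (area * bin_width * f)
    return RadialDensity(
        bin_width=bin_width,
        r_max=float(r_max),
        counts=counts.astype(np.int64),
        density=density,
        area=float(area),
        n_frames=f,
        n_excluded=int((~inside).sum()),
        species=sds.species,
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return y.astype(float)
    half = window // 2
    padded = np.pad(y.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def first_minimum_after_peak(
    rd: RadialDensity,
    smooth_window: int = 3,
    default_rc: Optional[float] = None,
    species: Optional[str] = None,
) -> CutoffResult:
    """Locate r_c: the first local minimum of D(r) after its first peak.

    The curve is smoothed with a centred moving average (odd ``window``
    bins); the first local maximum with prominence above 5% of the global
    maximum is taken as the first peak, and the first subsequent strict
    local minimum's right bin edge is returned.  When no such minimum
    exists the species default (or ``default_rc``) is returned with the
    ``defaulted`` flag set.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd bin count")
    if default_rc is None and species is not None:
        default_rc = DEFAULT_RC.get(species)
    if default_rc is None and rd.species:
        default_rc = DEFAULT_RC.get(rd.species)

    if int(np.count_nonzero(rd.density)) < 5:
        if default_rc is not None:
            return CutoffResult(float(default_rc), True)
        raise ValueError("too few populated bins and no default r_c")

    s = _moving_average(rd.density, smooth_window)
    peak_idx = _first_prominent_peak(s)
    if peak_idx is not None:
        for i in range(peak_idx + 1, len(s) - 1):
            if s[i] < s[i - 1] and s[i] < s[i + 1]:
                return CutoffResult(float((i + 1) * rd.bin_width), False)
    if default_rc is not None:
        return CutoffResult(float(default_rc), True)
    raise ValueError("no interior minimum after first peak and no default r_c")


def _first_prominent_peak(s: np.ndarray) -> Optional[int]:
    from scipy.signal import find_peaks

    if s.max() <= 0:
        return None
    peaks, _ = find_peaks(s, prominence=0.05 * s.max())
    return int(peaks[0]) if peaks.size else None


def near_surface_fraction(rd: RadialDensity, r_c: float) -> PeakReport:
    """Occurrence fraction R = 100 * A_r / A at cutoff ``r_c`` (percent).

    Areas are accumulated in the count-sum form (exactly proportional to
    the area under D since the normaliser is bin-independent); a bin
    belongs to the near-surface region iff its right edge is <= r_c.
    """
    if not 0.0 < r_c <= rd.r_max + 1e-9:
        raise ValueError("r_c must lie in (0, r_max]")
    right_edges = rd.edges[1:]
    near = right_edges <= r_c + 1e-9
    a_r = int(rd.counts[near].sum())
    a = int(rd.counts.sum())
    if a == 0:
        raise ValueError("no particles within r_max; occurrence fraction undefined")
    r_percent = round(100.0 * a_r / a, 2)
    near_density = rd.density[near]
    if near_density.size and near_density.max() > 0:
        r_peak = float(rd.centers[near][int(np.argmax(near_density))])
    else:
        r_peak = float(rd.centers[int(np.argmax(rd.density))])
    return PeakReport(
        r_peak=r_peak,
        r_c=float(r_c),
        area_near=float(rd.density[near].sum() * rd.bin_width),
        area_total=float(rd.density.sum() * rd.bin_width),
        R=r_percent,
        species=rd.species,
        n_frames=rd.n_frames,
    )


def relative_reduction(r_ref: float, r_test: float) -> float:
    """Percentage reduction of an occurrence fraction relative to a reference.

    ``100 * (r_ref - r_test) / r_ref`` to 2 decimals; negative values mean
    an increase.
    """
    if r_ref <= 0:
        raise ValueError("reference fraction must be positive")
    return round(100.0 * (r_ref - r_test) / r_ref, 2)
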