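"""Rigid-body superposition (Kabsch) and RMSD-based equilibration checks.

The RMSD of a frame against a reference after optimal least-squares
superposition,

    RMSD = sqrt( sum_a ||r_a(t_j) - r_a(ref)||^2 / N_a ),

is computed per frame against either the first frame or the time-mean
structure <r_a> obtained by iterative superposition.  A trajectory is
considered equilibrated when the ordinary-least-squares slope of the
trailing RMSD window is flat (|slope| below a tolerance in Å/ns),
formalising the usual "RMSD approximates a straight line" criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .ensemble import AtomSelection, FrameEnsemble

__all__ = [
    "RmsdSeries",
    "superpose",
    "rmsd_series",
    "equilibration_plateau",
]

#: default frame spacing, ps (5 ns production / 1000 frames)
DEFAULT_DT_PS = 5.0


@dataclass
class RmsdSeries:
    times: np.ndarray  # ps
    rmsd: np.ndarray  # Å
    selection_label: str = ""
    n_atoms: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum() / a.shape[0]))


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns the fitted coordinates and the post-fit RMSD.  A proper
    rotation (det = +1) is enforced; degenerate (collinear) geometries
    are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference atom counts differ")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms of shape (N, 3)")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = mob_c @ rot.T + reference.mean(axis=0)
    return fitted, _rmsd(fitted, reference)


def rmsd_series(
    ensemble: FrameEnsemble,
    reference_mode: str = "first_frame",
    selection: AtomSelection | None = None,
    dt_ps: float = DEFAULT_DT_PS,
) -> RmsdSeries:
    """Per-frame RMSD versus a reference, after superposition.

    ``reference_mode`` is ``"first_frame"`` (reference = frame 0) or
    ``"mean_structure"`` (reference = time-mean coordinates, refined by
    two rounds of superposition to the evolving mean).
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None or len(selection) == 0:
        raise ValueError("empty selection")
    coords = ensemble.coords[:, selection.indices, :]
    n_frames = coords.shape[0]
    if reference_mode == "first_frame":
        ref = coords[0]
        rmsds = np.empty(n_frames)
        for f in range(n_frames):
            _, rmsds[f] = superpose(coords[f], ref)
    elif reference_mode == "mean_structure":
        ref = coords[0]
        fitted = coords.copy()
        for _ in range(2):  # two refinement rounds against the evolving mean
            for f in range(n_frames):
                fitted[f], _ = superpose(coords[f], ref)
            ref = fitted.mean(axis=0)
        rmsds = np.empty(n_frames)
        for f in range(n_frames):
            _, rmsds[f] = superpose(coords[f], ref)
    else:
        raise ValueError("reference_mode must be 'first_frame' or 'mean_structure'")
    return RmsdSeries(
        times=np.arange(n_frames) * dt_ps,
        rmsd=rmsds,
        selection_label=selection.label,
        n_atoms=len(selection),
    )


def equilibration_plateau(
    series: RmsdSeries, window: int, slope_tol: float = 0.05
) -> Tuple[bool, float]:
    """OLS slope of the trailing RMSD window; plateau iff |slope| <= tol.

    ``window`` is in frames; the slope is returned in Å/ns
    (``series.times`` are in ps).
    """
    if window < 3:
        raise ValueError("window must span at least 3 frames")
    if window > series.n_frames:
        raise ValueError("window exceeds series length")
    t = series.times[-window:]
    y = series.rmsd[-window:]
    slope_per_ps = np.polyfit(t, y, 1)[0]
    slope_per_ns = float(slope_per_ps * 1000.0)
    return bool(abs(slope_per_ns) <= slope_tol), slope_per_ns
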