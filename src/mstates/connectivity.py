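"""Spatial filtering, analytic phase, and microstate-specific PLV.

Connectivity is estimated on a signal path parallel to the one used for
back-fitting: the raw recording is surface-Laplacian filtered (spherical
spline current source density, which sharpens topographies and mitigates
volume conduction), band-filtered to the alpha band, and Hilbert-
transformed per artifact-free segment.  A fraction of each segment's
phase samples is discarded at both ends against Hilbert edge effects.
Phase samples belonging to one microstate class are then pooled and the
phase-locking value

    PLV_ij = | mean over class samples of exp(i (phi_j - phi_i)) |

is computed for every channel pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .dynamics import MicrostateSequence
from .recording import EEGRecording, ParameterError, StructuralError, bandpass_zero_phase

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# surface Laplacian (spherical spline CSD, Perrin-style)


def _gh_matrices(cosang: np.ndarray, m: int, n_legendre: int) -> tuple[np.ndarray, np.ndarray]:
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, n_legendre + 1):
        pn = eval_legendre(n, cosang)
        factor = (2 * n + 1) / (4 * np.pi)
        g += factor * pn / (n * (n + 1)) ** m
        h += factor * pn / (n * (n + 1)) ** (m - 1)
    return g, h


def surface_laplacian_matrix(positions: np.ndarray, spline_order: int = 4,
                             n_legendre: int = 50, lambda_reg: float = 1e-5,
                             ) -> np.ndarray:
    """Linear operator mapping scalp potentials to spherical-spline CSD.

    ``spline_order`` is the spline flexibility m, ``n_legendre`` the number
    of Legendre terms in the g/h series, ``lambda_reg`` the smoothing
    regularizer added to the G matrix.  Output units are CSD on the unit
    sphere (potential per steradian); only relative amplitudes matter
    downstream.
    """
    positions = np.asarray(positions, dtype=float)
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    G, H = _gh_matrices(cosang, spline_order, n_legendre)
    Gs = G + lambda_reg * np.eye(len(G))
    try:
        Gi = np.linalg.inv(Gs)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"degenerate electrode geometry: {exc}") from exc
    total = Gi.sum()
    if abs(total) < 1e-12:
        raise StructuralError("degenerate electrode geometry (singular G)")
    ones = np.ones((len(G), 1))
    # spline coefficients with the flat-component constraint removed
    TC = Gi - (Gi @ ones @ ones.T @ Gi) / total
    return H @ TC


def surface_laplacian(rec: EEGRecording, spline_order: int = 4, n_legendre: int = 50,
                      lambda_reg: float = 1e-5) -> EEGRecording:
    """Spherical-spline current-source-density estimate, per sample; linear."""
    if rec.positions is None:
        raise ParameterError("surface Laplacian needs electrode positions")
    L = surface_laplacian_matrix(rec.positions, spline_order, n_legendre, lambda_reg)
    return replace(rec, data=L @ rec.data)


# ---------------------------------------------------------------------------
# analytic phase


@dataclass
class PhaseSeries:
    """Per-channel instantaneous phase with an edge-discard validity mask."""

    phase: np.ndarray  # (n_channels, n_samples), radians in (-pi, pi]
    valid: np.ndarray  # (n_samples,) bool
    fs: float


def analytic_phase(rec: EEGRecording, band: tuple[float, float] = (8.0, 12.0),
                   edge_discard: float = 0.10) -> PhaseSeries:
    """Band-filter, Hilbert-transform, and mask segment edges.

    Everything happens per artifact-free segment; ``floor(edge_discard *
    len)`` samples per side of each segment are masked out.  Segments too
    short to survive the discard are dropped with a warning.
    """
    if not (0 <= edge_discard < 0.5):
        raise ParameterError("edge_discard must lie in [0, 0.5)")
    filt = bandpass_zero_phase(rec, *band)
    phase = np.zeros_like(filt.data)
    valid = np.zeros(rec.n_samples, dtype=bool)
    for a, b, seg in filt.iter_segments():
        n = b - a
        cut = int(np.floor(edge_discard * n))
        if n - 2 * cut <= 0 or (edge_discard > 0 and cut == 0):
            logger.warning("segment [%d, %d) too short for edge discard; dropped", a, b)
            continue
        phase[:, a:b] = np.angle(signal.hilbert(seg, axis=1))
        valid[a + cut : b - cut] = True
    return PhaseSeries(phase=phase, valid=valid, fs=rec.fs)


# ---------------------------------------------------------------------------
# microstate-specific PLV


@dataclass
class ConnectivityStack:
    """Per-class symmetric PLV matrices for one recording."""

    plv: np.ndarray          # (k, n_channels, n_channels), entries in [0, 1]
    counts: np.ndarray       # (k,) valid samples per class
    reliable: np.ndarray     # (k,) bool, counts >= n_min
    class_labels: list[str]

    @property
    def k(self) -> int:
        return self.plv.shape[0]


def microstate_plv(phases: PhaseSeries, seq: MicrostateSequence,
                   n_min: int = 250) -> ConnectivityStack:
    """PLV over the pooled valid samples of each microstate class.

    Only per-sample phase differences enter the estimator, so pooling
    samples across artifact segments cannot create spurious phase jumps.
    Classes with fewer than ``n_min`` valid samples are flagged
    unreliable rather than silently reported.
    """
    if phases.phase.shape[1] != seq.labels.size:
        raise StructuralError("phases and labels are not sample-aligned")
    k = seq.k
    n_ch = phases.phase.shape[0]
    plv = np.zeros((k, n_ch, n_ch))
    counts = np.zeros(k, dtype=int)
    for c in range(k):
        idx = phases.valid & (seq.labels == c)
        counts[c] = idx.sum()
        if counts[c] == 0:
            continue
        z = np.exp(1j * phases.phase[:, idx])
        g = z @ z.conj().T / counts[c]
        m = np.abs(g)
        m = 0.5 * (m + m.T)  # enforce exact symmetry against rounding
        np.fill_diagonal(m, 1.0)
        plv[c] = m
    reliable = counts >= n_min
    for c in np.flatnonzero(~reliable):
        logger.warning("class %d has only %d valid samples (< %d); flagged",
                       c, counts[c], n_min)
    return ConnectivityStack(plv=plv, counts=counts, reliable=reliable,
                             class_labels=list(seq.class_labels) or
                             [str(c) for c in range(k)])
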