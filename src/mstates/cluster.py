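"""Polarity-invariant microstate clustering and model-order selection.

Topographic clustering of EEG maps differs from ordinary k-means in one
essential way: a scalp map and its negation describe the same generator
configuration, so similarity is the *absolute* spatial (Pearson)
correlation and the cluster prototype must be sign-invariant.  The
modified k-means here assigns each map to the template with the largest
|correlation| and updates each template as the dominant eigenvector of
its cluster's map covariance -- exact polarity invariance by construction.

Model order (the number of microstate classes) is chosen with the
Krzanowski-Lai criterion on the within-cluster dispersion curve, averaged
over recordings after per-recording max-normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .recording import EEGRecording, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_LABELS = "ABCDEFGHIJ"


# ---------------------------------------------------------------------------
# GFP and peak extraction


def global_field_power(rec: EEGRecording) -> np.ndarray:
    """Per-sample GFP: population standard deviation across channels."""
    if rec.n_channels < 2:
        raise ParameterError("GFP needs at least 2 channels")
    return rec.data.std(axis=0, ddof=0)


def extract_gfp_peaks(gfp: np.ndarray, segments: list[tuple[int, int]] | None = None,
                      discard_fraction: float = 0.15, sd_multiple: float = 3.0,
                      sd_center: str = "mean") -> np.ndarray:
    """Indices of GFP local maxima, after low-peak and outlier exclusion.

    Interior strict local maxima are found within each segment; then the
    lowest ``floor(discard_fraction * n)`` peaks by GFP value are dropped
    (maps with low GFP have uncertain state assignment), and outlier
    peaks -- those exceeding the all-sample mean GFP by more than
    ``sd_multiple`` times the all-sample SD of the GFP -- are dropped.
    GFP is a non-negative quantity whose mean usually exceeds a few times
    its own SD, so the outlier cut is centered at the mean by default;
    ``sd_center="zero"`` gives the uncentered variant (GFP > k * SD),
    which on typical recordings removes nearly all peaks.
    """
    gfp = np.asarray(gfp, dtype=float)
    if not (0 <= discard_fraction < 1):
        raise ParameterError("discard_fraction must lie in [0, 1)")
    if sd_multiple <= 0:
        raise ParameterError("sd_multiple must be positive")
    if sd_center not in ("mean", "zero"):
        raise ParameterError("sd_center must be 'mean' or 'zero'")
    segments = segments or [(0, gfp.size)]
    peaks: list[np.ndarray] = []
    for a, b in segments:
        g = gfp[a:b]
        if g.size < 3:
            continue
        loc = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])) + 1 + a
        peaks.append(loc)
    if not peaks or sum(p.size for p in peaks) == 0:
        logger.warning("no GFP peaks found")
        return np.array([], dtype=int)
    idx = np.concatenate(peaks)
    n_drop = int(np.floor(discard_fraction * idx.size))
    if n_drop:
        order = np.argsort(gfp[idx], kind="stable")
        idx = np.delete(idx, order[:n_drop])
    center = gfp.mean() if sd_center == "mean" else 0.0
    idx = idx[gfp[idx] <= center + sd_multiple * gfp.std(ddof=0)]
    return np.sort(idx)


# ---------------------------------------------------------------------------
# map normalization helpers


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def _normalize(maps: np.ndarray) -> np.ndarray:
    c = _center(np.asarray(maps, dtype=float))
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return c / norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of ``a`` and rows of ``b``."""
    return _normalize(np.atleast_2d(a)) @ _normalize(np.atleast_2d(b)).T


# ---------------------------------------------------------------------------
# the estimator


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-invariant k-means for EEG topographies.

    Parameters
    ----------
    n_clusters : int
        Number of microstate templates.
    n_init : int, default 100
        Independent restarts; the restart with the largest global
        explained variance (GEV) wins.
    max_iter : int, default 200
    tol : float, default 1e-7
        Convergence threshold on the GEV change between iterations.
    random_state : int or None

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_channels)
        Unit-norm, zero-mean templates.  Polarity is a gauge: any row may
        be negated without changing the model.
    labels_ : ndarray
        Training-map assignments.
    gev_ : float
        GEV of the training maps under the fitted templates.
    dispersion_ : float
        Within-cluster sum of squared distances of the normalized maps to
        their sign-aligned template (the W(k) used by Krzanowski-Lai).
    """

    def __init__(self, n_clusters: int = 5, n_init: int = 100, max_iter: int = 200,
                 tol: float = 1e-7, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # polarity-invariant template update
    @staticmethod
    def _principal_map(cluster_maps: np.ndarray) -> np.ndarray:
        cov = cluster_maps.T @ cluster_maps
        w, v = np.linalg.eigh(cov)
        vec = v[:, -1]
        vec = vec - vec.mean()
        n = np.linalg.norm(vec)
        return vec / n if n > 0 else vec

    def _single_run(self, Xc: np.ndarray, Xn: np.ndarray, gfp: np.ndarray,
                    rng: np.random.Generator):
        n, _ = Xn.shape
        k = self.n_clusters
        templates = Xn[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        labels = np.zeros(n, dtype=int)
        for it in range(self.max_iter):
            corr = Xn @ templates.T
            labels = np.argmax(np.abs(corr), axis=1)
            # GEV with GFP weighting
            best = np.abs(corr[np.arange(n), labels])
            gev = float(np.sum((gfp * best) ** 2) / np.sum(gfp**2))
            for c in range(k):
                members = labels == c
                if not members.any():
                    worst = int(np.argmin(np.max(np.abs(corr), axis=1)))
                    logger.info("re-seeding empty cluster %d from worst-explained map", c)
                    templates[c] = Xn[worst]
                    continue
                templates[c] = self._principal_map(Xc[members])
            if abs(gev - prev_gev) < self.tol:
                break
            prev_gev = gev
        corr = Xn @ templates.T
        labels = np.argmax(np.abs(corr), axis=1)
        best = np.abs(corr[np.arange(n), labels])
        gev = float(np.sum((gfp * best) ** 2) / np.sum(gfp**2))
        return templates, labels, gev, it + 1

    def fit(self, X: np.ndarray, y=None):
        """Cluster maps (n_maps x n_channels)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D (maps x channels)")
        if X.shape[0] < self.n_clusters:
            raise ParameterError(
                f"k={self.n_clusters} exceeds the {X.shape[0]} available maps")
        Xc = _center(X)
        gfp = X.std(axis=1, ddof=0)
        Xn = _normalize(X)
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_init)
        best = None
        for ss in seeds:
            run = self._single_run(Xc, Xn, gfp, np.random.default_rng(ss))
            if best is None or run[2] > best[2]:
                best = run
        templates, labels, gev, n_iter = best
        self.cluster_centers_ = templates
        self.labels_ = labels
        self.gev_ = gev
        self.n_iter_ = n_iter
        corr = np.abs(Xn @ templates.T)[np.arange(X.shape[0]), labels]
        self.dispersion_ = float(np.sum(2.0 - 2.0 * corr))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Polarity-invariant assignment of new maps to the fitted templates."""
        check_is_fitted(self, "cluster_centers_")
        corr = _normalize(np.asarray(X, dtype=float)) @ self.cluster_centers_.T
        return np.argmax(np.abs(corr), axis=1)


# ---------------------------------------------------------------------------
# template containers and wrappers


@dataclass
class TemplateSet:
    """A set of k microstate templates (zero-mean, unit-norm rows)."""

    maps: np.ndarray
    labels: list[str] = field(default_factory=list)
    gev_train: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if not self.labels:
            self.labels = [DEFAULT_LABELS[i] if i < len(DEFAULT_LABELS) else str(i)
                           for i in range(self.maps.shape[0])]

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def modified_kmeans(maps: np.ndarray, k: int, n_repeats: int = 100,
                    max_iter: int = 200, tol: float = 1e-7,
                    seed: int | None = None) -> TemplateSet:
    """Functional wrapper over :class:`ModifiedKMeans`."""
    est = ModifiedKMeans(n_clusters=k, n_init=n_repeats, max_iter=max_iter,
                         tol=tol, random_state=seed).fit(maps)
    return TemplateSet(maps=est.cluster_centers_, gev_train=est.gev_)


def gev(maps: np.ndarray, gfp: np.ndarray, templates: np.ndarray,
        labels: np.ndarray) -> float:
    """Global explained variance: GFP-weighted squared spatial correlation.

    ``GEV = sum_t (GFP_t * C_t)^2 / sum_t GFP_t^2`` with ``C_t`` the
    correlation between map ``t`` and its assigned template.
    """
    gfp = np.asarray(gfp, dtype=float)
    total = np.sum(gfp**2)
    if total == 0:
        raise ParameterError("GEV undefined: zero total GFP")
    corr = spatial_correlation(maps, np.asarray(templates))
    c = np.abs(corr[np.arange(len(labels)), np.asarray(labels, dtype=int)])
    return float(np.sum((gfp * c) ** 2) / total)


@dataclass
class ClusterRunResult:
    """Best clustering per k on one recording's peak maps."""

    templates: dict[int, TemplateSet]
    gev_curve: dict[int, float]
    dispersion: dict[int, float]


def cluster_k_range(maps: np.ndarray, k_range=range(2, 11), n_repeats: int = 100,
                    seed: int | None = None, **kw) -> ClusterRunResult:
    """Fit the modified k-means for every k; collect GEV and W(k) curves."""
    seeds = np.random.SeedSequence(seed).generate_state(len(list(k_range)))
    templates, gev_curve, disp = {}, {}, {}
    for i, k in enumerate(k_range):
        est = ModifiedKMeans(n_clusters=k, n_init=n_repeats,
                             random_state=int(seeds[i]) % 2**31, **kw).fit(maps)
        templates[k] = TemplateSet(maps=est.cluster_centers_, gev_train=est.gev_)
        gev_curve[k] = est.gev_
        disp[k] = est.dispersion_
    return ClusterRunResult(templates=templates, gev_curve=gev_curve, dispersion=disp)


def kl_curve(dispersion: dict[int, float], p: int) -> dict[int, float]:
    """Krzanowski-Lai index for each interior k of a contiguous dispersion curve.

    ``DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k)``;
    ``KL(k) = |DIFF(k) / DIFF(k+1)|``; ``p`` is the map dimensionality
    (channel count).
    """
    ks = sorted(dispersion)
    if len(ks) < 3:
        raise ParameterError("KL needs at least 3 contiguous k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ParameterError("k range must be contiguous")
    diff = {k: (k - 1) ** (2 / p) * dispersion[k - 1] - k ** (2 / p) * dispersion[k]
            for k in ks[1:]}
    out = {}
    for k in ks[1:-1]:
        denom = diff[k + 1]
        out[k] = np.inf if denom == 0 else abs(diff[k] / denom)
    return out


def select_k_kl(dispersions: list[dict[int, float]], p: int) -> int:
    """Select the model order maximizing the mean max-normalized KL curve.

    Each recording's KL curve is divided by its own maximum before
    averaging, so every recording contributes equally; ties break to the
    smallest k.
    """
    curves = []
    for disp in dispersions:
        kl = kl_curve(disp, p)
        vals = np.array([kl[k] for k in sorted(kl)])
        finite = vals[np.isfinite(vals)]
        top = finite.max() if finite.size else 1.0
        vals = np.where(np.isfinite(vals), vals / (top if top > 0 else 1.0), 1.0)
        curves.append(vals)
    mean_curve = np.mean(curves, axis=0)
    ks = sorted(kl_curve(dispersions[0], p))
    return int(ks[int(np.argmax(mean_curve))])


def group_templates(per_recording: list[TemplateSet], k: int,
                    seed: int | None = None, n_repeats: int = 100) -> TemplateSet:
    """Re-cluster the pooled per-recording templates into k group templates.

    Every recording must contribute exactly k templates so that each
    participant has equal weight in the group solution.
    """
    if any(ts.k != k for ts in per_recording):
        raise ParameterError("all recordings must contribute exactly k templates")
    pooled = np.vstack([ts.maps for ts in per_recording])
    return modified_kmeans(pooled, k, n_repeats=n_repeats, seed=seed)


def common_templates(group_a: TemplateSet, group_b: TemplateSet,
                     seed: int | None = None, n_repeats: int = 100) -> TemplateSet:
    """Cluster the two groups' pooled templates into one common set."""
    if group_a.k != group_b.k:
        raise ParameterError("groups must have the same number of templates")
    if group_a.maps.shape[1] != group_b.maps.shape[1]:
        raise ParameterError("groups must share the channel space")
    pooled = np.vstack([group_a.maps, group_b.maps])
    return modified_kmeans(pooled, group_a.k, n_repeats=n_repeats, seed=seed)


def order_templates(templates: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Match templates to a labeled reference set and align polarity.

    The one-to-one assignment maximizing total |spatial correlation| is
    found by the Hungarian algorithm; each output row takes the matched
    reference label and is sign-flipped to correlate positively with its
    reference.  Exact ties fall to the reference-order solution the
    assignment solver returns first.
    """
    if reference.k < templates.k:
        raise ParameterError("reference must have at least as many maps")
    corr = spatial_correlation(templates.maps, reference.maps)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.argsort(cols)
    maps, labels = [], []
    for i in order:
        r, c = rows[i], cols[i]
        sign = 1.0 if corr[r, c] >= 0 else -1.0
        maps.append(sign * templates.maps[r])
        labels.append(reference.labels[c])
    return TemplateSet(maps=np.stack(maps), labels=labels, gev_train=templates.gev_train)
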