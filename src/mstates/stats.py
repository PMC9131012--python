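"""Signed network-based statistics and permutation inference.

Mass-univariate edge tests on connectivity matrices are corrected at the
family level by a signed variant of the network-based statistic: edges
with parametric p below a primary threshold are split by the sign of
their test statistic, connected components are formed over the electrode
graph for each sign, and each component's size (the sum of its edge
statistics) is referred to a permutation null distribution of largest
component sizes of the matching sign.  Component p-values follow

    p = (2 * #{|S_null| > |s_obs|} + 1) / (N + 1),

clamped to 1 (the formula can exceed 1 for small observed components).

The module also provides scalar permutation tests (two-sample, paired,
correlation) with the same p-value convention, Bonferroni-Holm
correction, BCa bootstrap intervals, and summary-statistic effect sizes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .recording import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """What comparison to run and how to calibrate it."""

    kind: str = "two_sample"  # two_sample | paired | correlation
    p_thr: float = 0.01
    n_perm: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("two_sample", "paired", "correlation"):
            raise ParameterError(f"unknown design kind {self.kind!r}")
        if not (0 < self.p_thr < 1):
            raise ParameterError("p_thr must lie in (0, 1)")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")


@dataclass
class ComponentResult:
    """A signed suprathreshold connected component."""

    sign: int
    edges: list[tuple[int, int]]
    size: float
    p: float | None = None
    null_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# edge-level statistics


def _upper(stack: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    stack = np.asarray(stack, dtype=float)
    iu = np.triu_indices(stack.shape[-1], 1)
    return stack[..., iu[0], iu[1]], iu


def _two_sample_t(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = xa.shape[0], xb.shape[0]
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (xa.mean(axis=0) - xb.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t[sp2 == 0] = np.nan
    p = 2 * sps.t.sf(np.abs(t), df=na + nb - 2)
    return t, p


def _paired_t(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    return t, p


def _pearson_r(x: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    sc = scores - scores.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * sc[:, None]).sum(axis=0) / denom
    r[denom == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1] = 0.0
    return r, p


def edge_statistics(stacks: np.ndarray, design: DesignSpec,
                    groups: np.ndarray | None = None,
                    stacks_b: np.ndarray | None = None,
                    scores: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric statistic and parametric p-value maps over all edges.

    ``two_sample``: pooled-variance t between the two levels of ``groups``.
    ``paired``: paired t on ``stacks - stacks_b``.  ``correlation``:
    Pearson r against ``scores`` (returned statistic is r).  Zero-variance
    edges yield NaN and are excluded from thresholding downstream.
    """
    x, iu = _upper(stacks)
    n_ch = stacks.shape[-1]
    if design.kind == "two_sample":
        groups = np.asarray(groups)
        levels = np.unique(groups)
        if len(levels) != 2:
            raise ParameterError("two_sample design needs exactly 2 group levels")
        xa, xb = x[groups == levels[0]], x[groups == levels[1]]
        if min(len(xa), len(xb)) < 2:
            raise ParameterError("need >= 2 subjects per group")
        stat_e, p_e = _two_sample_t(xa, xb)
    elif design.kind == "paired":
        xb, _ = _upper(stacks_b)
        if x.shape[0] < 2:
            raise ParameterError("need >= 2 pairs")
        stat_e, p_e = _paired_t(x - xb)
    else:
        scores = np.asarray(scores, dtype=float)
        if x.shape[0] < 3:
            raise ParameterError("need >= 3 subjects for correlation")
        stat_e, p_e = _pearson_r(x, scores)
    if np.isnan(stat_e).any():
        logger.info("%d zero-variance edges excluded", int(np.isnan(stat_e).sum()))
    stat = np.full((n_ch, n_ch), np.nan)
    pmap = np.full((n_ch, n_ch), np.nan)
    stat[iu] = stat_e
    stat[iu[1], iu[0]] = stat_e
    pmap[iu] = p_e
    pmap[iu[1], iu[0]] = p_e
    return stat, pmap


# ---------------------------------------------------------------------------
# signed components


def _find_components(stat_e: np.ndarray, p_e: np.ndarray, p_thr: float,
                     iu: tuple[np.ndarray, np.ndarray], n_nodes: int, sign: int,
                     ) -> list[ComponentResult]:
    keep = np.isfinite(stat_e) & (p_e < p_thr)
    keep &= stat_e > 0 if sign > 0 else stat_e < 0
    sel = np.flatnonzero(keep)
    if sel.size == 0:
        return []
    parent = list(range(n_nodes))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in sel:
        ra, rb = find(int(iu[0][e])), find(int(iu[1][e]))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for e in sel:
        groups.setdefault(find(int(iu[0][e])), []).append(int(e))
    out = []
    for edges in groups.values():
        out.append(ComponentResult(
            sign=sign,
            edges=[(int(iu[0][e]), int(iu[1][e])) for e in edges],
            size=float(stat_e[edges].sum()),
        ))
    return out


def signed_components(stat: np.ndarray, pmap: np.ndarray, p_thr: float,
                      ) -> tuple[list[ComponentResult], list[ComponentResult]]:
    """Positive and negative suprathreshold components of symmetric maps."""
    if stat.shape != pmap.shape or stat.shape[0] != stat.shape[1]:
        raise ParameterError("stat and p maps must be square and same shape")
    stat_e, iu = _upper(stat)
    p_e, _ = _upper(pmap)
    n = stat.shape[0]
    return (_find_components(stat_e, p_e, p_thr, iu, n, +1),
            _find_components(stat_e, p_e, p_thr, iu, n, -1))


# ---------------------------------------------------------------------------
# permutation machinery


def _perm_p(count: int, n_perm: int) -> float:
    return min(1.0, (2 * count + 1) / (n_perm + 1))


def _signed_count(stat_perm: np.ndarray, stat_obs: float) -> int:
    """Exceedances in the tail matching the observed sign.

    The doubled (2c+1)/(N+1) convention needs a one-tailed count (like the
    sign-matched component null); counting |stat| exceedances and doubling
    would make null p-values stochastically twice uniform.
    """
    if stat_obs >= 0:
        return int(np.sum(stat_perm > stat_obs))
    return int(np.sum(stat_perm < stat_obs))


def _edge_fn(design: DesignSpec, x: np.ndarray, groups, xb, scores):
    """Return (observed stat/p, iterator of permuted stat/p, n_used, exact)."""
    if design.kind == "two_sample":
        levels = np.unique(groups)
        idx_a = np.flatnonzero(groups == levels[0])
        n = x.shape[0]
        na = idx_a.size
        obs = _two_sample_t(x[groups == levels[0]], x[groups == levels[1]])
        from math import comb
        space = comb(n, na)
        exact = space <= design.n_perm
        if exact:
            logger.info("enumerating all %d label assignments", space)

            def perms():
                for combo in itertools.combinations(range(n), na):
                    mask = np.zeros(n, dtype=bool)
                    mask[list(combo)] = True
                    yield _two_sample_t(x[mask], x[~mask])
            n_used = space
        else:
            rng = np.random.default_rng(design.seed)

            def perms():
                for _ in range(design.n_perm):
                    mask = np.zeros(n, dtype=bool)
                    mask[rng.choice(n, size=na, replace=False)] = True
                    yield _two_sample_t(x[mask], x[~mask])
            n_used = design.n_perm
        return obs, perms, n_used, exact
    if design.kind == "paired":
        d = x - xb
        n = d.shape[0]
        obs = _paired_t(d)
        exact = 2**n <= design.n_perm
        if exact:
            logger.info("enumerating all %d sign assignments", 2**n)

            def perms():
                for bits in itertools.product((1.0, -1.0), repeat=n):
                    yield _paired_t(d * np.asarray(bits)[:, None])
            n_used = 2**n
        else:
            rng = np.random.default_rng(design.seed)

            def perms():
                for _ in range(design.n_perm):
                    signs = rng.choice((1.0, -1.0), size=n)
                    yield _paired_t(d * signs[:, None])
            n_used = design.n_perm
        return obs, perms, n_used, exact
    # correlation: shuffle the score order
    scores = np.asarray(scores, dtype=float)
    obs = _pearson_r(x, scores)
    rng = np.random.default_rng(design.seed)

    def perms():
        for _ in range(design.n_perm):
            yield _pearson_r(x, rng.permutation(scores))
    return obs, perms, design.n_perm, False


def nbs_test(stacks: np.ndarray, design: DesignSpec,
             groups: np.ndarray | None = None,
             stacks_b: np.ndarray | None = None,
             scores: np.ndarray | None = None) -> list[ComponentResult]:
    """Signed-component permutation test over connectivity stacks.

    Permutation schemes: group labels shuffled (two-sample), signs of the
    per-subject condition differences flipped (paired), score order
    shuffled (correlation).  Each permutation contributes the sizes of
    its largest positive and largest negative components to the two null
    distributions; each observed component is referred to the null of its
    own sign via the (2c+1)/(N+1) formula.  If the permutation space is
    smaller than ``n_perm`` it is enumerated exactly.
    """
    x, iu = _upper(stacks)
    n_nodes = stacks.shape[-1]
    if groups is not None:
        groups = np.asarray(groups)
    (stat_obs, p_obs), perms, n_used, exact = _edge_fn(design, x, groups,
                                                       None if stacks_b is None
                                                       else _upper(stacks_b)[0],
                                                       scores)
    observed = (_find_components(stat_obs, p_obs, design.p_thr, iu, n_nodes, +1)
                + _find_components(stat_obs, p_obs, design.p_thr, iu, n_nodes, -1))
    if not observed:
        return []
    null_pos = np.zeros(n_used)
    null_neg = np.zeros(n_used)
    for i, (stat_p, p_p) in enumerate(perms()):
        pos = _find_components(stat_p, p_p, design.p_thr, iu, n_nodes, +1)
        neg = _find_components(stat_p, p_p, design.p_thr, iu, n_nodes, -1)
        null_pos[i] = max((c.size for c in pos), default=0.0)
        null_neg[i] = min((c.size for c in neg), default=0.0)
    for comp in observed:
        null = null_pos if comp.sign > 0 else null_neg
        count = int(np.sum(np.abs(null) > abs(comp.size)))
        if exact:
            comp.p = np.sum(np.abs(null) >= abs(comp.size)) / n_used
            comp.p = max(comp.p, 1.0 / n_used)
        else:
            comp.p = _perm_p(count, n_used)
        comp.null_summary = {"n_perm": n_used, "exact": exact,
                             "null_max_abs": float(np.max(np.abs(null)))}
    return sorted(observed, key=lambda c: c.p)


def mean_fcscc(matrix: np.ndarray, component: ComponentResult) -> float:
    """Mean connectivity strength over a component's edges for one subject."""
    if not component.edges:
        raise ParameterError("empty component")
    matrix = np.asarray(matrix, dtype=float)
    return float(np.mean([matrix[i, j] for i, j in component.edges]))


# ---------------------------------------------------------------------------
# scalar permutation tests


def permutation_test_scalar(x: np.ndarray, y: np.ndarray, design: str = "two_sample",
                            n_perm: int = 100_000, seed: int | None = None,
                            ) -> tuple[float, float]:
    """Two-sided permutation test using the t statistic.

    ``two_sample`` shuffles group membership; ``paired`` flips the signs
    of the per-subject differences.  p = (2 * #{|t*| > |t|} + 1) / (N+1),
    clamped to 1; spaces smaller than ``n_perm`` are enumerated exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design == "paired":
        d = x - y
        n = d.size
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        t_obs = _paired_t(d[:, None])[0][0]
        if not np.isfinite(t_obs):
            warnings.warn("constant differences; p = 1")
            return float(t_obs), 1.0
        if 2**n <= n_perm:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
            t_all = _paired_t((signs * d).T)[0]
            p = float(np.mean(np.abs(t_all) >= abs(t_obs) - 1e-12))
            return float(t_obs), p
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        t_all = _paired_t((signs * d).T)[0]
        return float(t_obs), _perm_p(_signed_count(t_all, t_obs), n_perm)

    if design != "two_sample":
        raise ParameterError(f"unknown design {design!r}")
    pooled = np.concatenate([x, y])
    n, na = pooled.size, x.size
    t_obs = _two_sample_t(x[:, None], y[:, None])[0][0]
    if not np.isfinite(t_obs):
        warnings.warn("zero pooled variance; p = 1")
        return float(t_obs), 1.0
    from math import comb
    if comb(n, na) <= n_perm:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            t = _two_sample_t(pooled[mask][:, None], pooled[~mask][:, None])[0][0]
            total += 1
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        return float(t_obs), count / total
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, n)).argsort(axis=1)
        perm = pooled[keys]
        t = _two_sample_t(perm[:, :na].T, perm[:, na:].T)[0]
        count += _signed_count(t, t_obs)
        done += b
    return float(t_obs), _perm_p(count, n_perm)


def permutation_correlation(features: np.ndarray, scores: np.ndarray,
                            n_perm: int = 100_000, seed: int | None = None,
                            ) -> tuple[float, float]:
    """Pearson r with a permutation p-value obtained by shuffling the scores."""
    x = np.asarray(features, dtype=float)
    s = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise ParameterError("need n >= 3")
    if x.std() == 0 or s.std() == 0:
        raise ParameterError("zero-variance input; correlation undefined")
    r_obs = _pearson_r(x[:, None], s)[0][0]
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    xnorm = np.linalg.norm(xc)
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, s.size)).argsort(axis=1)
        sp = s[keys]
        spc = sp - sp.mean(axis=1, keepdims=True)
        r = spc @ xc / (xnorm * np.linalg.norm(spc, axis=1))
        count += _signed_count(r, r_obs)
        done += b
    return float(r_obs), _perm_p(count, n_perm)


def holm_correction(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bca_bootstrap_ci(x: np.ndarray, y: np.ndarray, statistic=None,
                     n_boot: int = 10_000, level: float = 0.95,
                     seed: int | None = None) -> tuple[float, float]:
    """BCa bootstrap interval for a paired statistic (default: Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ParameterError("need n >= 5 for a bootstrap interval")
    if statistic is None:
        def statistic(a, b):  # noqa: ANN001
            return sps.pearsonr(a, b)[0]
    rng = np.random.default_rng(seed)
    try:
        res = sps.bootstrap((x, y), statistic, paired=True, vectorized=False,
                            n_resamples=n_boot, confidence_level=level,
                            method="BCa", rng=rng)
        lo, hi = res.confidence_interval
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("non-finite BCa interval")
    except Exception:  # noqa: BLE001 - degenerate bootstrap distribution
        warnings.warn("degenerate BCa bootstrap; falling back to percentile")
        res = sps.bootstrap((x, y), statistic, paired=True, vectorized=False,
                            n_resamples=n_boot, confidence_level=level,
                            method="percentile", rng=np.random.default_rng(seed))
        lo, hi = res.confidence_interval
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# summary-statistic effect sizes


def cohens_d_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d from group summaries, with pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("SDs must be positive")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float((mean1 - mean2) / sp)


def cramers_v(table) -> float:
    """Cramer's V of a 2x2 contingency table (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ParameterError("zero margin; V undefined")
    chi2 = sps.chi2_contingency(t, correction=False)[0]
    return float(np.sqrt(chi2 / t.sum()))
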