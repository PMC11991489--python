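"""Group-level statistics: outlier handling, paired tests, BH-FDR, and the
network-based statistic (NBS).

NBS controls family-wise error over the 78 edges of a 13-ROI network: edges
are tested with a paired t-test, edges with p below the edge threshold form
suprathreshold masks (one per contrast direction: increases and decreases are
connected separately, as a component mixing opposite effects is not a
coherent finding), and each component's size (edge count, with the summed
|t| as a continuous tie-breaker) is compared against the permutation null of
the largest component over both directions.  For a matched two-condition
design the exchangeability unit is the per-subject difference matrix,
permuted by random sign flips.  Component p-values use the +1-corrected
estimator ``(1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


def replace_outliers(x: np.ndarray, z_limit: float = 3.0) -> np.ndarray:
    """Replace values with |z| > ``z_limit`` by the mean of the unflagged values.

    The z-score uses the full-sample mean and SD.  Idempotent: a second pass
    changes nothing, because replacements sit at the center of the data.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise StatsError("need at least 3 values to assess outliers")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy()
    z = (x - x.mean()) / sd
    flagged = np.abs(z) > z_limit
    if flagged.all():
        raise StatsError("all values flagged as outliers")
    out = x.copy()
    out[flagged] = x[~flagged].mean()
    return out


@dataclass
class PairedSample:
    """Per-subject matched values under two conditions."""

    a: np.ndarray
    b: np.ndarray
    subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise StatsError("paired sample requires matching 1-D arrays")
        if self.a.size < 2:
            raise StatsError("need at least 2 subjects")


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Two-sided paired t-test; identical vectors give (0.0, 1.0)."""
    d = sample.a - sample.b
    if np.allclose(d, 0):
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        raise StatsError("zero variance of nonzero differences: t undefined")
    t, p = spstats.ttest_rel(sample.a, sample.b)
    return float(t), float(p)


def wilcoxon_signed(sample: PairedSample) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test."""
    d = sample.a - sample.b
    if np.allclose(d, 0):
        return 0.0, 1.0
    w, p = spstats.wilcoxon(sample.a, sample.b)
    return float(w), float(p)


def friedman(*groups: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test over k >= 3 matched samples."""
    if len(groups) < 3:
        raise StatsError("Friedman test needs at least 3 matched groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if np.allclose(np.diff(np.vstack(arrs), axis=0), 0):
        return 0.0, 1.0
    chi2, p = spstats.friedmanchisquare(*arrs)
    return float(chi2), float(p)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# Network-based statistic
# ---------------------------------------------------------------------------

@dataclass
class NbsResult:
    t_matrix: np.ndarray
    p_matrix: np.ndarray
    components: list  # list of edge lists [(i, j), ...], largest first
    component_sizes: np.ndarray
    component_intensity: np.ndarray  # sum of |t| over component edges
    component_p: np.ndarray
    null_max_size: np.ndarray
    null_max_intensity: np.ndarray
    edge_alpha: float
    comp_alpha: float
    n_perm: int

    def significant_components(self) -> list:
        return [
            comp for comp, p in zip(self.components, self.component_p)
            if p < self.comp_alpha
        ]


#: stand-in t value for a zero-variance nonzero difference (keeps arithmetic finite)
_T_HUGE = 1e12


def _edge_t_p(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired t and two-sided p per edge from subject difference vectors.

    A constant nonzero difference (zero variance) is treated as an arbitrarily
    large |t| rather than an undefined one.
    """
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.sign(mean) * _T_HUGE)
    p = 2.0 * spstats.t.sf(np.abs(t), df=n - 1)
    return t, p


def _mask_components(mask_edges: np.ndarray, iu, ju, n_nodes: int,
                     tvals: np.ndarray):
    """Connected components of the suprathreshold edge mask.

    Returns (edge lists, sizes, intensities) ordered by (size, intensity)
    descending, where a component's intensity is the sum of |t| over its
    edges.  Intensity breaks ties between equal-sized components so the
    permutation statistic is effectively continuous.
    """
    if not mask_edges.any():
        return [], np.zeros(0, dtype=int), np.zeros(0)
    rows = iu[mask_edges]
    cols = ju[mask_edges]
    tv = np.abs(tvals[mask_edges])
    adj = csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    comps, intens = [], []
    for c in range(n_comp):
        edge_sel = labels[rows] == c
        if edge_sel.sum() > 0:
            comps.append([(int(i), int(j)) for i, j in zip(rows[edge_sel], cols[edge_sel])])
            intens.append(float(tv[edge_sel].sum()))
    order = sorted(range(len(comps)), key=lambda i: (len(comps[i]), intens[i]),
                   reverse=True)
    comps = [comps[i] for i in order]
    intens = np.array([intens[i] for i in order])
    sizes = np.array([len(c) for c in comps], dtype=int)
    return comps, sizes, intens


def _signed_components(tvals: np.ndarray, crit: float, iu, ju, n_nodes: int):
    """Suprathreshold components per contrast direction, merged and ordered."""
    comps, sizes, intens = [], [], []
    for mask in (tvals > crit, tvals < -crit):
        c, s, it = _mask_components(mask, iu, ju, n_nodes, tvals)
        comps += c
        sizes += list(s)
        intens += list(it)
    order = sorted(range(len(comps)), key=lambda i: (sizes[i], intens[i]),
                   reverse=True)
    return (
        [comps[i] for i in order],
        np.array([sizes[i] for i in order], dtype=int),
        np.array([intens[i] for i in order]),
    )


def _perm_null(diffs_e: np.ndarray, iu, ju, n_nodes: int, edge_alpha: float,
               n_perm: int, rng: np.random.Generator):
    """Null distribution of the largest component (size, intensity) over both
    contrast directions, under per-subject sign flips of the differences."""
    n_subj, n_edges = diffs_e.shape
    crit = spstats.t.isf(edge_alpha / 2.0, df=n_subj - 1)  # |t| threshold
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_subj))
    # t statistics for all permutations at once
    flipped_mean = signs @ diffs_e / n_subj  # (n_perm, n_edges)
    # per-permutation variance: E[d^2] is invariant to sign flips
    sq_mean = (diffs_e**2).mean(axis=0)
    var = (sq_mean[None, :] - flipped_mean**2) * n_subj / (n_subj - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = np.where(var > 1e-300, flipped_mean / np.sqrt(var / n_subj),
                          np.sign(flipped_mean) * _T_HUGE)
    null_size = np.zeros(n_perm, dtype=int)
    null_int = np.zeros(n_perm)
    for k in range(n_perm):
        if np.any(np.abs(t_perm[k]) > crit):
            _, sizes, intens = _signed_components(t_perm[k], crit, iu, ju, n_nodes)
            if sizes.size:
                null_size[k] = int(sizes[0])
                null_int[k] = float(intens[0])
    return null_size, null_int


def nbs_paired(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    edge_alpha: float = 0.05,
    comp_alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | np.random.SeedSequence | None = 0,
) -> NbsResult:
    """Network-based statistic for a matched two-condition design.

    Parameters
    ----------
    stack_a, stack_b
        ``(n_subjects, N, N)`` symmetric connectivity matrices, subject-matched.
    """
    stack_a = np.asarray(stack_a, dtype=float)
    stack_b = np.asarray(stack_b, dtype=float)
    if stack_a.shape != stack_b.shape or stack_a.ndim != 3:
        raise StatsError("stacks must be matching (subjects, N, N) arrays")
    n_subj, n_nodes, _ = stack_a.shape
    if n_subj < 2:
        raise StatsError("need at least 2 subjects")

    iu, ju = np.triu_indices(n_nodes, k=1)
    diffs_e = (stack_a - stack_b)[:, iu, ju]  # (subjects, edges)

    t_e, p_e = _edge_t_p(diffs_e)
    t_mat = np.zeros((n_nodes, n_nodes))
    p_mat = np.ones((n_nodes, n_nodes))
    t_mat[iu, ju] = t_mat.T[iu, ju] = 0.0  # filled below
    t_mat[iu, ju] = t_e
    t_mat += t_mat.T
    p_mat[iu, ju] = p_e
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)

    crit = spstats.t.isf(edge_alpha / 2.0, df=n_subj - 1)
    comps, sizes, intens = _signed_components(t_e, crit, iu, ju, n_nodes)

    rng = np.random.default_rng(seed)
    null_size, null_int = _perm_null(diffs_e, iu, ju, n_nodes, edge_alpha, n_perm, rng)
    # lexicographic tail count: (size, intensity) >= observed
    comp_p = np.array(
        [
            (1 + int(((null_size > s) | ((null_size == s) & (null_int >= i))).sum()))
            / (n_perm + 1)
            for s, i in zip(sizes, intens)
        ],
        dtype=float,
    )
    return NbsResult(
        t_matrix=t_mat,
        p_matrix=p_mat,
        components=comps,
        component_sizes=sizes,
        component_intensity=intens,
        component_p=comp_p,
        null_max_size=null_size,
        null_max_intensity=null_int,
        edge_alpha=edge_alpha,
        comp_alpha=comp_alpha,
        n_perm=n_perm,
    )
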