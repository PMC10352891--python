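"""Group inference: covariate-adjusted GLMs, multiple-comparison control,
network-based statistics, and demographic-table tests.

Three levels of comparison between patients and controls are supported:

* network level — Gaussian-identity GLMs on the three composite scores with
  age and gender as nuisance covariates, Bonferroni-gated at alpha / 3;
* edge level — edge-wise GLMs over the 276 unordered node pairs with
  network-based statistics (NBS): supra-threshold edges (two-tailed p below
  the primary threshold, sign matching the tested direction) form connected
  components whose sizes are referred to a permutation null of maximal
  component sizes under group-label exchange;
* nodal level — GLMs on the 24 weighted degrees with Benjamini-Hochberg FDR.

Demographic comparisons follow the usual routing: Kolmogorov-Smirnov
normality screen, then pooled two-sample t (normal) or Mann-Whitney U
(non-normal), and Pearson chi-squared for gender.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .network import NetworkPartition, DEFAULT_PARTITION

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "NbsComponent",
    "NbsResult",
    "glm_group_test",
    "bonferroni_gate",
    "fdr_bh",
    "nbs",
    "edge_index_pairs",
    "partial_correlation_test",
    "two_sample_t_pooled",
    "two_sample_t",
    "mann_whitney_u",
    "chi_squared_2x2",
    "ks_normality",
    "compare_continuous",
]


@dataclass
class DesignMatrix:
    """Subjects x regressors design: intercept, group (patient=1), covariates."""

    matrix: np.ndarray
    columns: list[str]
    group_col: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def group(self) -> np.ndarray:
        return self.matrix[:, self.group_col]

    @classmethod
    def from_phenotypes(cls, phenotypes: pd.DataFrame, covariates: bool = True) -> "DesignMatrix":
        """Intercept + patient indicator (+ centered age, male indicator)."""
        required = {"subject_id", "group"} | ({"age", "gender"} if covariates else set())
        missing = required - set(phenotypes.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        levels = set(phenotypes["group"])
        if levels != {"control", "patient"}:
            raise ValueError(f"expected exactly the groups control/patient, got {sorted(levels)}")
        grp = (phenotypes["group"] == "patient").to_numpy(float)
        cols = [np.ones(len(phenotypes)), grp]
        names = ["intercept", "group"]
        if covariates:
            age = phenotypes["age"].to_numpy(float)
            cols.append(age - age.mean())
            names.append("age")
            cols.append((phenotypes["gender"] == "male").to_numpy(float))
            names.append("gender")
        return cls(matrix=np.column_stack(cols), columns=names, group_col=1)

    def with_group(self, group_values: np.ndarray) -> "DesignMatrix":
        m = self.matrix.copy()
        m[:, self.group_col] = group_values
        return DesignMatrix(matrix=m, columns=list(self.columns), group_col=self.group_col)


@dataclass(frozen=True)
class GlmResult:
    group_coefficient: float
    standard_error: float
    statistic: float
    p_two_tailed: float
    n: int


def glm_group_test(values: np.ndarray, design: DesignMatrix) -> GlmResult:
    """Gaussian-identity GLM of ``values`` on the design; two-tailed group test.

    With no covariates (intercept + group only) this reproduces the pooled
    two-sample t statistic exactly.
    """
    y = np.asarray(values, dtype=float).ravel()
    if len(y) != design.n:
        raise ValueError("response length does not match design")
    if design.n <= design.matrix.shape[1] + 1:
        raise ValueError("too few subjects for the design")
    fit = sm.OLS(y, design.matrix).fit()
    g = design.group_col
    se = float(fit.bse[g])
    if se == 0 or not np.isfinite(fit.tvalues[g]):
        # perfect fit / constant response: no evidence against the null
        return GlmResult(group_coefficient=float(fit.params[g]), standard_error=se,
                         statistic=0.0, p_two_tailed=1.0, n=design.n)
    return GlmResult(
        group_coefficient=float(fit.params[g]),
        standard_error=se,
        statistic=float(fit.tvalues[g]),
        p_two_tailed=float(fit.pvalues[g]),
        n=design.n,
    )


def bonferroni_gate(p_values: list[float], alpha: float = 0.05, m: int | None = None) -> list[bool]:
    """Reject iff p < alpha / m (m defaults to the number of tests)."""
    m = len(p_values) if m is None else m
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    return [p < alpha / m for p in p_values]


def fdr_bh(p_values: list[float], q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up decisions at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return list(reject)


# ---------------------------------------------------------------------------
# network-based statistics


def edge_index_pairs(n_nodes: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the upper-triangle edge order used throughout."""
    return np.triu_indices(n_nodes, k=1)


def _edge_group_stats(X: np.ndarray, Y: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS group t statistics and two-tailed p over edge columns."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    cov_gg = np.linalg.inv(X.T @ X)[g, g]
    se = np.sqrt(sigma2 * cov_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[g] / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return t, p


def _component_sizes(supra: np.ndarray, n_nodes: int, rows: np.ndarray, cols: np.ndarray) -> list[tuple[list[int], int]]:
    """Connected components of the supra-threshold graph as (edge list, size)."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    r, c = rows[idx], cols[idx]
    adj = sparse.coo_matrix((np.ones(idx.size), (r, c)), shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[int]] = {}
    for e, (i, j) in zip(idx, zip(r, c)):
        comps.setdefault(labels[i], []).append(int(e))
    return sorted(((edges, len(edges)) for edges in comps.values()),
                  key=lambda t: -t[1])


def _max_component_size(supra: np.ndarray, n_nodes: int, rows: np.ndarray, cols: np.ndarray) -> int:
    comps = _component_sizes(supra, n_nodes, rows, cols)
    return comps[0][1] if comps else 0


@dataclass
class NbsComponent:
    edges: list[tuple[str, str]]
    edge_indices: list[int]
    size: int
    corrected_p: float


@dataclass
class NbsResult:
    direction: str  # "patient_gt_control" | "control_gt_patient"
    primary_p_threshold: float
    components: list[NbsComponent]
    max_null_sizes: np.ndarray

    @property
    def significant_components(self) -> list[NbsComponent]:
        return [c for c in self.components if c.corrected_p < 0.05]


def nbs(
    edge_values: np.ndarray,
    design: DesignMatrix,
    partition: NetworkPartition = DEFAULT_PARTITION,
    primary_p: float = 0.01,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, NbsResult]:
    """Network-based statistics on a subjects x 276 edge matrix.

    Edge-wise group effects come from the same Gaussian GLM as
    :func:`glm_group_test`; edges with two-tailed p < ``primary_p`` and the
    direction's sign form the supra-threshold graph.  Group labels are
    permuted across subjects (covariates stay attached); the null is the
    maximal supra-threshold component size over BOTH signs in each
    permutation, so the two reported directions jointly control the
    family-wise error rate.  Corrected p-values use the
    (1 + exceedances) / (1 + n_perm) estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n_nodes = len(partition.nodes)
    rows, cols = edge_index_pairs(n_nodes)
    Y = np.asarray(edge_values, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != len(rows):
        raise ValueError(f"edge matrix must be subjects x {len(rows)}")
    if Y.shape[0] != design.n:
        raise ValueError("edge matrix and design disagree on subject count")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    X = design.matrix
    g = design.group_col
    t_obs, p_obs = _edge_group_stats(X, Y, g)

    group = X[:, g]
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        Xp = X.copy()
        Xp[:, g] = rng.permutation(group)
        t_b, p_b = _edge_group_stats(Xp, Y, g)
        m_pos = _max_component_size((p_b < primary_p) & (t_b > 0), n_nodes, rows, cols)
        m_neg = _max_component_size((p_b < primary_p) & (t_b < 0), n_nodes, rows, cols)
        null[b] = max(m_pos, m_neg)

    labels = partition.labels
    results: dict[str, NbsResult] = {}
    for direction, sign in (("patient_gt_control", 1), ("control_gt_patient", -1)):
        supra = (p_obs < primary_p) & (sign * t_obs > 0)
        comps = []
        for edge_idx, size in _component_sizes(supra, n_nodes, rows, cols):
            corrected = (1 + int(np.sum(null >= size))) / (1 + n_perm)
            comps.append(
                NbsComponent(
                    edges=[(labels[rows[e]], labels[cols[e]]) for e in edge_idx],
                    edge_indices=edge_idx,
                    size=size,
                    corrected_p=corrected,
                )
            )
        results[direction] = NbsResult(
            direction=direction,
            primary_p_threshold=primary_p,
            components=comps,
            max_null_sizes=null.copy(),
        )
    return results


# ---------------------------------------------------------------------------
# correlation and demographic tests


def partial_correlation_test(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Partial correlation of x and y controlling for covariate columns.

    Both variables are residualized on [intercept, covariates]; the residual
    Pearson correlation is tested with t on n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = len(x), Z.shape[1]
    if len(y) != n or Z.shape[0] != n:
        raise ValueError("inputs must share a common length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    A = np.column_stack([np.ones(n), Z])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant residuals after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_c = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def two_sample_t_pooled(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled two-sample t from summary statistics; returns (t, p).

    t = (mean2 - mean1) / sqrt(sp^2 (1/n1 + 1/n2)) with sp^2 the pooled
    variance; degrees of freedom n1 + n2 - 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (mean2 - mean1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Raw-data pooled two-sample t via the summary-statistics path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return two_sample_t_pooled(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U, z, p) where U counts pairs with x ranked above y, z applies a
    continuity correction, and p is two-tailed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2
    n = n1 + n2
    mu = n1 * n2 / 2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise ValueError("all values tied; U variance is zero")
    sd = np.sqrt(var)
    if U > mu:
        z = (U - mu - 0.5) / sd
    elif U < mu:
        z = (U - mu + 0.5) / sd
    else:
        z = 0.0
    p = 2 * stats.norm.sf(abs(z))
    return float(U), float(z), float(p)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction, 1 df) on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-squared undefined with a zero margin")
    expected = np.outer(row, col) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def ks_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample KS test against a normal with sample-estimated mean/sd.

    Returns (statistic, p, is_normal) where ``is_normal`` is p >= alpha;
    routes the downstream choice between t and Mann-Whitney U tests.
    """
    v = np.asarray(values, float)
    if len(v) < 5:
        raise ValueError("need at least 5 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p), bool(p >= alpha)


def compare_continuous(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> dict:
    """KS-screened group comparison: pooled t if both normal, else U test."""
    _, _, nx = ks_normality(x, alpha)
    _, _, ny = ks_normality(y, alpha)
    if nx and ny:
        t, p = two_sample_t(x, y)
        return {"test": "t", "statistic": t, "p": p}
    U, z, p = mann_whitney_u(x, y)
    return {"test": "mann_whitney", "statistic": z, "U": U, "p": p}
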