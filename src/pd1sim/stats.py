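"""Sampling and nonparametric statistics for the in-silico trials.

Latin hypercube sampling with a log-normal transform, partial rank
correlation coefficients (PRCC) with Student-t significance, top-down
concordance on Savage scores, Kruskal-Wallis with Bonferroni-corrected
pairwise rank-sum post-hocs, Wilcoxon tests, and empirical prediction
intervals.

LHS and PRCC are implemented here (they are the analysis machinery this
package exists for); the classical hypothesis tests delegate to
scipy.stats and are validated against exact enumeration in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ParamSpec", "SensitivityResult", "lhs_lognormal", "prcc", "prcc_matrix",
    "topdown_concordance", "savage_scores", "kruskal_wallis_bonferroni",
    "wilcoxon_signed_rank", "wilcoxon_rank_sum", "prediction_interval",
]


@dataclass(frozen=True)
class ParamSpec:
    """Log-normal sampling specification for one parameter."""

    name: str
    geometric_mean: float
    gsd: float = 1.5          # geometric standard deviation (>= 1)
    role: str = "sampled"     # "sampled" | "fixed"

    def __post_init__(self):
        if self.geometric_mean <= 0:
            raise ValueError(f"{self.name}: geometric_mean must be > 0")
        if self.gsd < 1:
            raise ValueError(f"{self.name}: gsd must be >= 1")
        if self.role not in ("sampled", "fixed"):
            raise ValueError(f"{self.name}: role must be sampled|fixed")


@dataclass
class SensitivityResult:
    """LHS design, simulated outputs, and PRCC significance tables."""

    design: pd.DataFrame        # n x k sampled parameters
    outputs: pd.DataFrame       # n x m model outputs
    prcc: pd.DataFrame          # k x m coefficients
    pvalues: pd.DataFrame       # k x m
    significant: pd.DataFrame   # boolean mask after threshold/correction
    n_failed: int = 0           # simulations excluded from the analysis

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: parameter, output, prcc, p, significant."""
        rows = []
        for param in self.prcc.index:
            for out in self.prcc.columns:
                rows.append({
                    "parameter": param, "output": out,
                    "prcc": self.prcc.loc[param, out],
                    "p": self.pvalues.loc[param, out],
                    "significant": bool(self.significant.loc[param, out]),
                })
        return pd.DataFrame(rows)


def lhs_lognormal(specs: list[ParamSpec], n: int,
                  seed: int | np.random.Generator) -> pd.DataFrame:
    """Stratified log-normal Latin hypercube sample.

    Each column occupies all n probability strata ((i + u_i)/n with
    u_i ~ U(0,1)), permuted independently across rows, mapped through the
    log-normal quantile function GM * exp(Phi^-1(p) * ln GSD).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    bad = [s.name for s in specs if s.role != "sampled"]
    if bad:
        raise ValueError(f"non-sampled specs passed to lhs_lognormal: {bad}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cols = {}
    for spec in specs:
        u = rng.uniform(size=n)
        probs = (np.arange(n) + u) / n
        probs = probs[rng.permutation(n)]
        if spec.gsd == 1.0:
            warnings.warn(f"{spec.name}: gsd=1 yields a constant column",
                          stacklevel=2)
            cols[spec.name] = np.full(n, spec.geometric_mean)
        else:
            z = sps.norm.ppf(probs)
            cols[spec.name] = spec.geometric_mean * np.exp(
                z * np.log(spec.gsd))
    return pd.DataFrame(cols)


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def prcc(design: np.ndarray | pd.DataFrame,
         output: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each design column with the output.

    All columns and the output are rank-transformed (average ranks for
    ties).  For parameter j, the coefficient is the Pearson correlation
    of the residuals of rank(x_j) and rank(y) after linear regression on
    the other rank-transformed parameters; significance uses
    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - (k - 1).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(output, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("output length must match design rows")
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    R = np.column_stack([_rank(X[:, j]) for j in range(k)])
    ry = _rank(y)
    names = (list(design.columns) if isinstance(design, pd.DataFrame)
             else [f"x{j}" for j in range(k)])
    coeffs = np.empty(k)
    pvals = np.empty(k)
    dof = n - 2 - (k - 1)
    ones = np.ones((n, 1))
    for j in range(k):
        Z = np.column_stack([ones, np.delete(R, j, axis=1)])
        # residualize rank(x_j) and rank(y) on the other ranked columns
        beta_x, _, rank_z, _ = np.linalg.lstsq(Z, R[:, j], rcond=None)
        if rank_z < Z.shape[1]:
            raise ValueError(
                f"rank-deficient design: column {names[j]} is collinear "
                "with the remaining columns")
        beta_y = np.linalg.lstsq(Z, ry, rcond=None)[0]
        ex = R[:, j] - Z @ beta_x
        ey = ry - Z @ beta_y
        denom = np.sqrt((ex @ ex) * (ey @ ey))
        r = float(ex @ ey / denom) if denom > 0 else 0.0
        r = min(1.0, max(-1.0, r))
        coeffs[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * sps.t.sf(abs(t), dof)
    return coeffs, pvals


def prcc_matrix(design: pd.DataFrame, outputs: pd.DataFrame,
                alpha: float = 0.01,
                bonferroni_grid: bool = False) -> SensitivityResult:
    """PRCC of every parameter against every output column."""
    co = {}
    pv = {}
    for col in outputs.columns:
        c, p = prcc(design, outputs[col].to_numpy())
        co[col] = c
        pv[col] = p
    prcc_df = pd.DataFrame(co, index=design.columns)
    p_df = pd.DataFrame(pv, index=design.columns)
    thresh = alpha / p_df.size if bonferroni_grid else alpha
    return SensitivityResult(design=design, outputs=outputs, prcc=prcc_df,
                             pvalues=p_df, significant=p_df < thresh)


def savage_scores(ranks: np.ndarray) -> np.ndarray:
    """Savage scores S_i = sum_{j=rank_i}^{n} 1/j, averaged over ties."""
    r = np.asarray(ranks, dtype=float)
    n = r.size
    tail = np.cumsum(1.0 / np.arange(n, 0, -1))[::-1]  # tail[i] = sum_{j>=i+1} 1/j
    order = _rank(r)  # average ranks; may be fractional under ties
    scores = np.empty(n)
    # average the Savage scores over tied blocks
    unique, inverse = np.unique(order, return_inverse=True)
    sorted_scores = tail  # score for integer rank i+1 is tail[i]
    for u in range(unique.size):
        members = np.flatnonzero(inverse == u)
        m = members.size
        # tied block occupies integer ranks round(unique[u]-(m-1)/2) .. +m-1
        start = int(round(unique[u] - (m - 1) / 2.0)) - 1
        scores[members] = sorted_scores[start:start + m].mean()
    return scores


def topdown_concordance(ranking_a: np.ndarray,
                        ranking_b: np.ndarray) -> float:
    """Top-down coefficient of concordance between two rankings.

    Pearson correlation of the Savage-score vectors; emphasizes agreement
    at the top ranks.  1.0 for identical rankings.
    """
    a = np.asarray(ranking_a, dtype=float)
    b = np.asarray(ranking_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rankings must be 1-D and of equal length")
    sa = savage_scores(a)
    sb = savage_scores(b)
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    denom = np.sqrt((sa @ sa) * (sb @ sb))
    if denom == 0:
        raise ValueError("degenerate (constant) ranking")
    return float(sa @ sb / denom)


def kruskal_wallis_bonferroni(groups: list[np.ndarray]
                              ) -> tuple[float, float, np.ndarray]:
    """Kruskal-Wallis omnibus test with Bonferroni pairwise post-hocs.

    Returns (H, omnibus p, g x g matrix of pairwise two-sided rank-sum
    p-values multiplied by the number of pairs, clipped at 1; diagonal
    NaN).
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    g = len(arrays)
    if np.all(pooled == pooled[0]):
        H, p_omni = 0.0, 1.0
    else:
        H, p_omni = sps.kruskal(*arrays)
    n_pairs = g * (g - 1) // 2
    pmat = np.full((g, g), np.nan)
    for i in range(g):
        for j in range(i + 1, g):
            if (np.all(arrays[i] == arrays[i][0])
                    and np.all(arrays[j] == arrays[j][0])
                    and arrays[i][0] == arrays[j][0]):
                p_ij = 1.0
            else:
                _, p_ij = sps.mannwhitneyu(arrays[i], arrays[j],
                                           alternative="two-sided")
            pmat[i, j] = pmat[j, i] = min(1.0, p_ij * n_pairs)
    return float(H), float(p_omni), pmat


def wilcoxon_signed_rank(paired_a: np.ndarray,
                         paired_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 (no ties among |differences|), the tie/continuity-corrected
    normal approximation otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; degenerate test",
                      stacklevel=2)
        return 0.0, 1.0
    if d.size < 5:
        raise ValueError("need >= 5 nonzero differences")
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(sample_a: np.ndarray,
                      sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def prediction_interval(samples: np.ndarray, lower_pct: float = 20.0,
                        upper_pct: float = 80.0
                        ) -> tuple[float, float, float]:
    """Median and empirical prediction interval (type-7 quantiles).

    Defaults to the 60% interval (20th to 80th percentile) used to
    summarize per-patient replicate distributions.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples")
    lo, med, hi = np.quantile(x, [lower_pct / 100.0, 0.5, upper_pct / 100.0],
                              method="linear")
    return float(med), float(lo), float(hi)
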