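"""Distance matrices and matrix correlation statistics.

Community dissimilarity uses Bray-Curtis on OTU counts; environmental
dissimilarity is Euclidean distance over z-scored variables.  Association
between matrices is tested with Mantel and partial Mantel permutation
tests; BioENV searches all variable subsets for the environmental distance
matrix that best rank-correlates with the community matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables_io import OtuTable, SampleMetadata

__all__ = [
    "bray_curtis",
    "env_distance",
    "read_distance_matrix",
    "write_distance_matrix",
    "mantel",
    "partial_mantel",
    "bioenv",
    "pearson_test",
    "MantelResult",
    "BioEnvResult",
]


def bray_curtis(t: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns, in [0, 1]."""
    m = t.counts.to_numpy().T.astype(float)
    if m.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = [s for s, tot in zip(t.sample_ids, m.sum(axis=1)) if tot == 0]
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return DistanceMatrix(squareform(pdist(m, metric="braycurtis")), ids=t.sample_ids)


def env_distance(
    m: SampleMetadata | pd.DataFrame,
    variables: list[str],
    level: str = "sample",
) -> DistanceMatrix:
    """Euclidean distance over z-scored environmental variables.

    Each variable is normalised to zero mean and unit (population) s.d.
    over the included units before distances are taken.
    """
    df = m.frame(level) if isinstance(m, SampleMetadata) else m
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"variables not in metadata: {missing}")
    if not variables:
        raise ValueError("need at least one variable")
    sub = df[list(variables)].astype(float)
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in variables: {bad}")
    sd = sub.std(ddof=0)
    const = sd.index[sd == 0].tolist()
    if const:
        raise ValueError(f"constant variable(s) cannot be z-scored: {const}")
    z = (sub - sub.mean()) / sd
    return DistanceMatrix(
        squareform(pdist(z.to_numpy(), metric="euclidean")), ids=list(df.index)
    )


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square labelled distance matrix from TSV (labels in the first
    row and first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id"
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    controlled: list[str] = field(default_factory=list)
    seed: int | None = None
    tail: str = "greater"


def _aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices have different unit labels")
    order = [d2.index(i) for i in d1.ids]
    return d1.data, d2.data[np.ix_(order, order)]


def _corr_rows(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with vector ``v``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc * rc).sum(axis=1) * (vc * vc).sum())
    return (rc @ vc) / denom


def _permuted_upper(d: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Upper triangles of d with rows/columns jointly relabelled by each
    permutation (one row per permutation)."""
    return d[perms[:, iu[0]], perms[:, iu[1]]]


def _pvalue(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    if tail == "greater":
        exceed = np.sum(r_perm >= r_obs - 1e-12)
    elif tail == "two-sided":
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return float(1 + exceed) / (1 + r_perm.size)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of upper-triangle distances.

    Significance by jointly permuting rows/columns of ``d1``; the p-value
    uses the permutation-inclusive estimator (1 + #exceedances)/(1 + n_perm)
    and is one-tailed (greater) by default.  ``exact=True`` enumerates all
    n! relabellings instead (identity included, so p is never 0); feasible
    for small n only.
    """
    a, b = _aligned(d1, d2)
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 units")
    iu = np.triu_indices(n, k=1)
    v1, v2 = a[iu], b[iu]
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = _corr_rows(_permuted_upper(a, perms, iu), v2)
        if tail == "greater":
            p = float(np.mean(r_perm >= r_obs - 1e-12))
        else:
            p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        return MantelResult(
            r=r_obs, p=p, n_perm=perms.shape[0], seed=None, tail=tail
        )
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = _corr_rows(_permuted_upper(a, perms, iu), v2)
    return MantelResult(
        r=r_obs, p=_pvalue(r_obs, r_perm, tail), n_perm=n_perm, seed=seed, tail=tail
    )


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    controls: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    control_names: list[str] | None = None,
) -> MantelResult:
    """Partial Mantel test controlling linearly for other distance matrices.

    The statistic is the correlation of the residuals of d1 and d2 after
    least-squares projection onto the control distances (plus intercept).
    Significance: permute d1's labels, re-residualise the permuted vector
    against the fixed controls, and correlate with d2's fixed residual.
    """
    if not controls:
        raise ValueError("partial Mantel needs at least one control matrix")
    a, b = _aligned(d1, d2)
    n = a.shape[0]
    if n < 4:
        raise ValueError("partial Mantel needs at least 4 units")
    iu = np.triu_indices(n, k=1)
    ctrl_cols = []
    for c in controls:
        _, cc = _aligned(d1, c)
        ctrl_cols.append(cc[iu])
    design = np.column_stack([np.ones(iu[0].size)] + ctrl_cols)
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise ValueError(
            f"control matrices are collinear (design condition number {cond:.3g})"
        )
    q, _ = np.linalg.qr(design)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    r2v = resid(b[iu])
    r1v = resid(a[iu])
    # a control that fully explains either matrix leaves a ~zero residual;
    # the partial correlation then degenerates to 0
    scale1 = float(np.linalg.norm(a[iu] - a[iu].mean()))
    scale2 = float(np.linalg.norm(b[iu] - b[iu].mean()))
    if np.linalg.norm(r1v) <= 1e-9 * max(scale1, 1e-30) or np.linalg.norm(
        r2v
    ) <= 1e-9 * max(scale2, 1e-30):
        names = control_names or [f"control_{i}" for i in range(len(controls))]
        return MantelResult(
            r=0.0, p=1.0, n_perm=n_perm, controlled=list(names), seed=seed, tail=tail
        )
    r_obs = float(np.corrcoef(r1v, r2v)[0, 1])
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    rows = _permuted_upper(a, perms, iu)
    rows_resid = rows - (rows @ q) @ q.T
    r_perm = _corr_rows(rows_resid, r2v)
    names = control_names or [f"control_{i}" for i in range(len(controls))]
    return MantelResult(
        r=r_obs,
        p=_pvalue(r_obs, r_perm, tail),
        n_perm=n_perm,
        controlled=list(names),
        seed=seed,
        tail=tail,
    )


@dataclass
class BioEnvResult:
    best_subset: tuple[str, ...]
    best_rho: float
    ranking: pd.DataFrame  # columns: subset, size, rho; sorted by rho desc


def bioenv(
    community: DistanceMatrix,
    m: SampleMetadata | pd.DataFrame,
    variables: list[str],
    level: str = "sample",
) -> BioEnvResult:
    """BioENV: exhaustive best-subset search with Spearman rank correlation.

    For every nonempty subset of ``variables`` the z-scored Euclidean
    distance matrix is compared (Spearman, average ranks for ties) with the
    community matrix; the subset maximising rho wins.  Limited to 15
    variables (2^15 - 1 subsets).
    """
    if len(variables) > 15:
        raise ValueError(
            f"{len(variables)} variables would need {2**len(variables)-1} "
            "subsets; pre-select 15 or fewer"
        )
    variables = sorted(variables)
    df = m.frame(level) if isinstance(m, SampleMetadata) else m
    order = [list(df.index).index(i) for i in community.ids]
    df = df.iloc[order]
    iu = np.triu_indices(len(community.ids), k=1)
    comm = community.data[iu]
    comm_rank = scipy.stats.rankdata(comm)

    sub = df[variables].astype(float)
    sd = sub.std(ddof=0)
    const = sd.index[sd == 0].tolist()
    if const:
        raise ValueError(f"constant variable(s) cannot be z-scored: {const}")
    z = ((sub - sub.mean()) / sd).to_numpy()

    records = []
    best: tuple[float, tuple[str, ...]] | None = None
    for k in range(1, len(variables) + 1):
        for combo in itertools.combinations(range(len(variables)), k):
            ev = pdist(z[:, combo], metric="euclidean")
            rho = float(
                scipy.stats.spearmanr(comm_rank, scipy.stats.rankdata(ev)).statistic
            )
            names = tuple(variables[i] for i in combo)
            records.append({"subset": names, "size": k, "rho": rho})
            if best is None or rho > best[0]:
                best = (rho, names)
    ranking = (
        pd.DataFrame(records)
        .sort_values(["rho", "size"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return BioEnvResult(best_subset=best[1], best_rho=best[0], ranking=ranking)


def pearson_test(x, y) -> tuple[float, float, float]:
    """Pearson r with Student-t significance (df = n - 2, two-tailed).

    Returns (r, t, p).  |r| = 1 yields infinite t and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return (float(np.sign(r)), float(np.sign(r)) * float("inf"), 0.0)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df=n - 2))
    return (r, float(t), p)
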