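"""Landscape correlates of diet: buffers, factor analysis, MEMs, AICc averaging.

Per-cat dietary dependence (arcsine-square-root transformed proportions) is
regressed on landscape composition around the capture site.  Land-use
coverage inside 100/200/500 m buffers and building density are collapsed to
two oblique factors (ML extraction, Promax rotation, number of factors by
parallel analysis); spatial autocorrelation is absorbed by Moran's
eigenvector maps (MEM) built from a Delaunay-triangulation neighbour graph;
all-subsets Gaussian GLMs are ranked by AICc and averaged over the ΔAICc<2
set (full averaging: terms absent from a model contribute zero).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay
from shapely.geometry import Point

from .fecal import InvalidInputError

__all__ = [
    "RADII",
    "buffer_coverage",
    "building_density",
    "FactorSolution",
    "factor_analysis",
    "MEMBasis",
    "mem_construct",
    "mem_select",
    "arcsine_sqrt",
    "AveragedModel",
    "fit_and_average",
    "aicc",
]

RADII = (100.0, 200.0, 500.0)  # m; buffer radii around capture locations


# ---------------------------------------------------------------------------
# Buffer covariates
# ---------------------------------------------------------------------------

def buffer_coverage(site_xy, landuse, radius: float) -> dict[str, float]:
    """Area fraction of each land-use class within ``radius`` m of the site.

    ``landuse`` is either a mapping class -> shapely geometry (polygon
    layers), or a DataFrame with columns x, y, landuse_class interpreted as a
    regular grid of cell centres (fractions are cell counts inside the disc).
    """
    x, y = float(site_xy[0]), float(site_xy[1])
    disc = Point(x, y).buffer(radius, quad_segs=64)
    if isinstance(landuse, pd.DataFrame):
        d2 = (landuse["x"] - x) ** 2 + (landuse["y"] - y) ** 2
        inside = landuse[d2 <= radius**2]
        if inside.empty:
            raise InvalidInputError("buffer falls outside the land-use grid")
        counts = inside["landuse_class"].value_counts()
        return {c: float(counts.get(c, 0)) / len(inside) for c in landuse["landuse_class"].unique()}
    total = disc.area
    out = {}
    covered = 0.0
    for cls, geom in landuse.items():
        a = disc.intersection(geom).area
        out[cls] = a / total
        covered += a
    if covered < 0.99 * total:
        raise InvalidInputError("land-use layer does not cover the buffer")
    return out


def building_density(site_xy, buildings: pd.DataFrame, radius: float) -> float:
    """Buildings per km² within ``radius`` m of the site (point counts)."""
    x, y = float(site_xy[0]), float(site_xy[1])
    d2 = (buildings["x"] - x) ** 2 + (buildings["y"] - y) ** 2
    n = int((d2 <= radius**2).sum())
    area_km2 = math.pi * radius**2 / 1e6
    return n / area_km2


def site_covariates(
    sites: pd.DataFrame,
    landuse,
    buildings: pd.DataFrame,
    radii=RADII,
    classes=("forest", "residential", "farmland"),
) -> pd.DataFrame:
    """Coverage per class and radius plus building density per radius, per site."""
    rows = []
    for _, s in sites.iterrows():
        row = {"cat_id": s.get("cat_id"), "x": s["x"], "y": s["y"]}
        for r in radii:
            cov = buffer_coverage((s["x"], s["y"]), landuse, r)
            for c in classes:
                row[f"{c}_{int(r)}m"] = cov.get(c, 0.0)
            row[f"building_density_{int(r)}m"] = building_density(
                (s["x"], s["y"]), buildings, r
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Factor analysis (ML extraction, Promax rotation, parallel analysis)
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # variables x factors (pattern matrix)
    phi: np.ndarray  # factor correlation matrix
    scores: pd.DataFrame  # sites x factors (regression method)
    communalities: pd.Series
    n_factors: int
    rotation: str
    parallel_suggested: int


def _varimax(L: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """Kaiser-normalized varimax; returns rotated loadings and rotation matrix."""
    p, k = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return (A @ R) * h[:, None], R


def _promax(L: np.ndarray, power: int = 4):
    """Promax oblique rotation following the classic varimax-target recipe."""
    V, rot = _varimax(L)
    Q = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def parallel_analysis(X: np.ndarray, n_rep: int = 100, seed: int = 0) -> int:
    """Number of factors whose correlation eigenvalues beat random-data means."""
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_rep, p))
    for r in range(n_rep):
        Z = rng.standard_normal((n, p))
        rand[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    return int(np.sum(obs > rand.mean(axis=0)))


def factor_analysis(
    covariates: pd.DataFrame,
    n_factors: int = 2,
    rotation: str = "promax",
    promax_power: int = 4,
    seed: int = 0,
) -> FactorSolution:
    """ML factor extraction with Promax rotation and regression factor scores.

    The covariate matrix is standardized (analysis on the correlation
    matrix).  Parallel analysis (random-data eigenvalue comparison) is run
    alongside and its suggested factor count reported; the fitted count stays
    at ``n_factors`` unless the caller changes it.
    """
    from sklearn.decomposition import FactorAnalysis as _FA

    X = covariates.to_numpy(dtype=float)
    n, p = X.shape
    if p < n_factors + 1:
        raise InvalidInputError("need at least n_factors+1 variables")
    if n <= p:
        raise InvalidInputError("need more sites than variables")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise InvalidInputError("constant covariate column")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    cond = np.linalg.cond(corr)
    if np.min(np.linalg.eigvalsh(corr)) <= 1e-10:
        raise InvalidInputError(
            f"correlation matrix not positive definite (condition number {cond:.3g})"
        )

    fa = _FA(n_components=n_factors, svd_method="lapack", random_state=seed)
    fa.fit(Z)
    L = fa.components_.T  # unrotated ML loadings on standardized scale

    if rotation == "promax":
        pattern, phi = _promax(L, power=promax_power)
    elif rotation == "varimax":
        pattern, _ = _varimax(L)
        phi = np.eye(n_factors)
    else:
        pattern, phi = L, np.eye(n_factors)

    # orient each factor so its largest-|loading| variable loads positively
    for k in range(n_factors):
        i = int(np.argmax(np.abs(pattern[:, k])))
        if pattern[i, k] < 0:
            pattern[:, k] *= -1
            phi[k, :] *= -1
            phi[:, k] *= -1

    structure = pattern @ phi
    weights = np.linalg.solve(corr, structure)  # Thurstone regression scores
    scores = Z @ weights
    communal = np.sum(pattern * structure, axis=1)

    cols = [f"Factor{k + 1}" for k in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(pattern, index=covariates.columns, columns=cols),
        phi=phi,
        scores=pd.DataFrame(scores, index=covariates.index, columns=cols),
        communalities=pd.Series(communal, index=covariates.columns),
        n_factors=n_factors,
        rotation=rotation,
        parallel_suggested=parallel_analysis(X, seed=seed),
    )


# ---------------------------------------------------------------------------
# Moran's eigenvector maps
# ---------------------------------------------------------------------------

@dataclass
class MEMBasis:
    vectors: pd.DataFrame  # sites x MEM1..MEMm, eigenvalue-descending
    eigenvalues: np.ndarray
    edges: list  # Delaunay adjacency as (i, j) index pairs


def mem_construct(sites_xy, jitter: float = 0.0, seed: int = 0) -> MEMBasis:
    """Moran's eigenvector maps from a Delaunay-triangulation neighbour graph.

    The binary adjacency matrix W is doubly centered and eigendecomposed;
    eigenvectors ordered by descending eigenvalue become MEM1, MEM2, ...
    (positive eigenvalues encode positive spatial autocorrelation).  The
    near-zero eigenvalue direction absorbed by centering is dropped.  Sign
    convention: first non-zero loading positive.  Duplicate coordinates are
    an error unless ``jitter`` > 0, in which case they are perturbed.
    """
    xy = np.asarray(sites_xy, dtype=float)
    n = len(xy)
    if n < 3:
        raise InvalidInputError("need at least 3 sites")
    uniq = {tuple(p) for p in xy.round(9)}
    if len(uniq) < n:
        if jitter > 0:
            rng = np.random.default_rng(seed)
            xy = xy + rng.normal(0.0, jitter, size=xy.shape)
        else:
            raise InvalidInputError("duplicate coordinates (set jitter to perturb)")
    try:
        tri = Delaunay(xy)
        edges = set()
        for simplex in tri.simplices:
            for a, b in itertools.combinations(simplex, 2):
                edges.add((min(a, b), max(a, b)))
    except Exception:
        # collinear fallback: chain graph along the dominant axis
        order = np.argsort(xy[:, 0] + 1e-9 * xy[:, 1])
        edges = {(min(a, b), max(a, b)) for a, b in zip(order[:-1], order[1:])}

    W = np.zeros((n, n))
    for a, b in edges:
        W[a, b] = W[b, a] = 1.0
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ W @ H
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > 1e-9 * max(np.abs(vals).max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    if vecs.shape[1] > n - 1:
        vals, vecs = vals[: n - 1], vecs[:, : n - 1]
    for k in range(vecs.shape[1]):
        nz = np.nonzero(np.abs(vecs[:, k]) > 1e-12)[0]
        if len(nz) and vecs[nz[0], k] < 0:
            vecs[:, k] *= -1
    cols = [f"MEM{k + 1}" for k in range(vecs.shape[1])]
    return MEMBasis(
        vectors=pd.DataFrame(vecs, columns=cols),
        eigenvalues=vals,
        edges=sorted(edges),
    )


def mem_select(
    basis: MEMBasis, responses: pd.DataFrame, k_max: int = 10, alpha: float = 0.05
) -> pd.DataFrame:
    """Retain MEM1..MEM_J, J the largest index significant for any response.

    Significance is a per-vector OLS t-test of each response on that MEM
    alone at level ``alpha`` — the simplest reading of "largest significant
    MEM"; swap this function to use permutation Moran's I instead.
    Returns an empty frame (zero columns) when nothing is significant.
    """
    m = min(k_max, basis.vectors.shape[1])
    biggest = 0
    for col in responses.columns:
        y = responses[col].to_numpy(dtype=float)
        for k in range(m):
            v = basis.vectors.iloc[:, k].to_numpy()
            r = stats.linregress(v, y)
            if r.pvalue < alpha:
                biggest = max(biggest, k + 1)
    return basis.vectors.iloc[:, :biggest]


# ---------------------------------------------------------------------------
# Response transform and AICc model averaging
# ---------------------------------------------------------------------------

def arcsine_sqrt(p, tol: float = 1e-9):
    """Variance-stabilizing arcsine-square-root transform of a proportion."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise InvalidInputError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))


def aicc(rss: float, n: int, n_terms: int) -> float:
    """Gaussian AICc; k counts the intercept, slope terms and the variance."""
    k = n_terms + 2
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class AveragedModel:
    response: str
    terms: list
    estimates: pd.DataFrame  # term -> estimate, adjusted SE, z, p, stars
    candidates: pd.DataFrame  # model id, terms, AICc, delta, weight
    n_models_averaged: int


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def fit_and_average(
    y, design: pd.DataFrame, response_name: str = "y", delta_max: float = 2.0
) -> AveragedModel:
    """All-subsets Gaussian GLM with AICc ranking and ΔAICc<2 full averaging.

    Every subset of ``design``'s columns (plus intercept) is fitted by OLS;
    models within ``delta_max`` AICc of the best form the averaging set, with
    Akaike weights renormalized to sum to 1 over that set.  Averaged
    estimates use full averaging (a term absent from a model contributes 0)
    and the standard adjusted SE combining within-model variance and
    between-model spread; z and two-sided normal p follow.
    """
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    n, t = X.shape
    if np.isnan(y).any() or np.isnan(X).any():
        raise InvalidInputError("complete cases required")
    full = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(full) < t + 1:
        # name the aliased columns for the error message
        bad = []
        base = np.ones((n, 1))
        for j, c in enumerate(design.columns):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(c)
            else:
                base = cand
        raise InvalidInputError(f"design is rank deficient (aliased: {bad or 'intercept'})")

    terms = list(design.columns)
    records = []
    for r in range(t + 1):
        for subset in itertools.combinations(range(t), r):
            Xs = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta
            rss = float(resid @ resid)
            ic = aicc(max(rss, 1e-300), n, len(subset))
            dof = n - Xs.shape[1]
            s2 = rss / dof if dof > 0 else np.nan
            XtX_inv = np.linalg.inv(Xs.T @ Xs)
            se = np.sqrt(np.diag(XtX_inv) * s2)
            records.append(
                {
                    "subset": subset,
                    "aicc": ic,
                    "beta": dict(zip(["(Intercept)"] + [terms[j] for j in subset], beta)),
                    "se": dict(zip(["(Intercept)"] + [terms[j] for j in subset], se)),
                }
            )

    cand = pd.DataFrame(
        {
            "terms": [
                " + ".join(terms[j] for j in r["subset"]) or "(Intercept)"
                for r in records
            ],
            "aicc": [r["aicc"] for r in records],
        }
    )
    best = cand["aicc"].min()
    cand["delta"] = cand["aicc"] - best
    in_set = cand["delta"] < delta_max
    w = np.exp(-0.5 * cand.loc[in_set, "delta"])
    cand["weight"] = 0.0
    cand.loc[in_set, "weight"] = w / w.sum()
    cand = cand.sort_values("aicc").reset_index(drop=True)

    sel = [(rec, wt) for rec, wt in zip(records, np.where(in_set,
           np.exp(-0.5 * (np.array([r["aicc"] for r in records]) - best)), 0.0))
           if wt > 0]
    wsum = sum(wt for _, wt in sel)
    sel = [(rec, wt / wsum) for rec, wt in sel]

    all_terms = ["(Intercept)"] + terms
    est_rows = []
    for term in all_terms:
        b_bar = sum(wt * rec["beta"].get(term, 0.0) for rec, wt in sel)
        se_adj = sum(
            wt
            * math.sqrt(
                rec["se"].get(term, 0.0) ** 2
                + (rec["beta"].get(term, 0.0) - b_bar) ** 2
            )
            for rec, wt in sel
        )
        z = abs(b_bar) / se_adj if se_adj > 0 else 0.0
        p = 2.0 * (1.0 - stats.norm.cdf(z))
        est_rows.append(
            {"term": term, "estimate": b_bar, "adj_se": se_adj, "z": z, "p": p,
             "stars": _stars(p)}
        )
    estimates = pd.DataFrame(est_rows).set_index("term")

    return AveragedModel(
        response=response_name,
        terms=terms,
        estimates=estimates,
        candidates=cand,
        n_models_averaged=len(sel),
    )


def residual_morans_i(residuals, edges, n_sites: int) -> float:
    """Moran's I of residuals on the binary neighbour graph (diagnostic)."""
    r = np.asarray(residuals, dtype=float)
    r = r - r.mean()
    W = np.zeros((n_sites, n_sites))
    for a, b in edges:
        W[a, b] = W[b, a] = 1.0
    s0 = W.sum()
    denom = float(r @ r)
    if denom == 0 or s0 == 0:
        return 0.0
    return float(n_sites / s0 * (r @ W @ r) / denom)
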