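"""Mann-Whitney U comparisons and the Mantel distance-decay test.

The U test compares gene-abundance groups (e.g. detoxification vs
metabolism genes); the Mantel test asks whether geographic distance
between sites predicts dissimilarity in arsenic-gene content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .abundance import SiteProfiles

EARTH_RADIUS_KM = 6371.0


@dataclass
class UTestResult:
    U: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    n_sites: int


def mann_whitney(x, y) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x_i > y_j (ties count 1/2).  The p-value is exact
    (full null enumeration) for n1, n2 <= 10 without ties, otherwise a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = len(x) <= 10 and len(y) <= 10 and not has_ties
    method = "exact" if exact else "normal_approx"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    # the asymptotic tail can underflow to exactly 0; keep p in (0, 1]
    p = max(float(res.pvalue), np.finfo(float).tiny)
    return UTestResult(U=float(res.statistic), n1=len(x), n2=len(y), p_value=p, method=method)


def geographic_distance(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km between sites.

    *sites* needs columns site_id, latitude, longitude (decimal degrees).
    """
    lat = sites["latitude"].to_numpy(float)
    lon = sites["longitude"].to_numpy(float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    ids = sites["site_id"].astype(str).tolist()
    return pd.DataFrame(d, index=ids, columns=ids)


def gene_content_distance(profiles: SiteProfiles, metric: str = "braycurtis") -> pd.DataFrame:
    """Site × site dissimilarity of rplB-normalized gene content.

    Non-detections count as 0 here (a dissimilarity needs complete
    vectors); a site with an all-zero vector is an error.
    """
    mat = profiles.normalized.fillna(0.0)
    zero = mat.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"all-zero gene vector at sites: {list(mat.index[zero])}")
    d = squareform(pdist(mat.to_numpy(float), metric=metric))
    return pd.DataFrame(d, index=mat.index, columns=mat.index)


def mantel(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool | None = None,
) -> MantelResult:
    """One-sided Mantel test (positive association) with add-one p-value.

    r is the Pearson correlation of the upper triangles; the null permutes
    the site labels of the second matrix.  p >= 1/(n_permutations + 1).
    With few sites (n <= 6, or ``exact=True``) the null is enumerated over
    all n! relabelings instead of sampled: p = #{r_perm >= r_obs} / n!,
    the identity permutation included, so p > 0 still holds.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and same shape")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 sites")
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            raise ValueError("distance matrices indexed by different site orders")
    for m in (a, b):
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix not symmetric with zero diagonal")
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    if exact is None:
        exact = n <= 6
    tol = 1e-12  # float fuzz must not flip >= at enumerated ties
    if exact:
        from itertools import permutations as iperm

        perms = list(iperm(range(n)))
        count = sum(
            1
            for perm in perms
            if np.corrcoef(va, b[np.ix_(perm, perm)][iu])[0, 1] >= r_obs - tol
        )
        p = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            vb_p = b[np.ix_(perm, perm)][iu]
            if np.corrcoef(va, vb_p)[0, 1] >= r_obs - tol:
                count += 1
        p = (1.0 + count) / (n_permutations + 1)
        n_used = n_permutations
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_used, seed=seed, n_sites=n)
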