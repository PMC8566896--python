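"""DOM-microbe linkage: correlation networks and (partial) Mantel tests.

Two complementary views of the coupling between DOM molecular
composition and microbial community structure:

* a molecule-by-OTU Pearson screen over the most abundant features of
  each table (defaults mirror common practice: top 100 DOM molecules,
  top 100 bacterial / 50 fungal OTUs, edges at p < 0.01, unadjusted),
  yielding a bipartite :class:`AssociationNetwork`;
* Mantel and partial Mantel permutation tests correlating whole
  between-sample distance matrices (community vs. DOM composition vs.
  environment), with seeded joint row/column label permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .community import top_n_features
from .errors import SampleMismatchError, ValidationError, ZeroVarianceError

__all__ = [
    "AssociationNetwork",
    "MantelResult",
    "pearson_with_p",
    "build_network",
    "distance_matrix",
    "mantel",
    "partial_mantel",
]

logger = logging.getLogger(__name__)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt(n-2)/sqrt(1-r^2).

    Requires equal-length vectors, n >= 4 and nonzero variance in both
    (a constant vector raises :class:`ZeroVarianceError`; network
    construction skips such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValidationError(f"need n >= 4 paired samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AssociationNetwork:
    """Bipartite DOM-molecule/OTU correlation network.

    ``edges`` has columns dom_id, otu_id, r, p, sign; every edge passed
    the significance screen.  ``summary`` reports pairs_tested, n_edges
    and the distinct node counts.
    """

    edges: pd.DataFrame
    dom_ids: list[str]
    otu_ids: list[str]
    top_n_dom: int
    top_n_otu: int
    alpha: float
    fdr: bool = False

    @property
    def summary(self) -> dict[str, int]:
        return {
            "pairs_tested": len(self.dom_ids) * len(self.otu_ids),
            "n_edges": len(self.edges),
            "n_dom_nodes": int(self.edges["dom_id"].nunique()) if len(self.edges) else 0,
            "n_otu_nodes": int(self.edges["otu_id"].nunique()) if len(self.edges) else 0,
        }

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for dom in self.edges["dom_id"].unique():
            g.add_node(str(dom), kind="dom")
        for otu in self.edges["otu_id"].unique():
            g.add_node(str(otu), kind="otu")
        for row in self.edges.itertuples(index=False):
            g.add_edge(str(row.dom_id), str(row.otu_id), r=float(row.r), p=float(row.p),
                       sign=row.sign)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided t-based p between rows of x and
    rows of y (identical to ``scipy.stats.pearsonr`` per pair)."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xn, yn)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def build_network(
    dom: pd.DataFrame,
    otu: pd.DataFrame,
    top_n_dom: int = 100,
    top_n_otu: int = 100,
    alpha: float = 0.01,
    fdr: bool = False,
) -> AssociationNetwork:
    """Screen all top-N DOM molecules against all top-N OTUs.

    ``dom`` holds per-sample normalized molecule intensities (molecules x
    samples, the M_i weights); ``otu`` holds OTU relative abundances
    (OTUs x samples).  Both must share an identical ordered sample set of
    at least 4 samples.  Pearson r/p is computed for every pair on the
    relative abundances; edges keep pairs with p < alpha (unadjusted by
    default; ``fdr=True`` applies Benjamini-Hochberg and keeps pairs
    whose adjusted p < alpha).  Zero-variance features are skipped with a
    logged reason.
    """
    if list(dom.columns) != list(otu.columns):
        missing_dom = set(otu.columns) - set(dom.columns)
        missing_otu = set(dom.columns) - set(otu.columns)
        raise SampleMismatchError(
            "DOM and OTU tables must share an identical ordered sample set; "
            f"missing from DOM: {sorted(missing_dom)}; missing from OTU: "
            f"{sorted(missing_otu)}; order must match"
        )
    n = dom.shape[1]
    if n < 4:
        raise ValidationError(f"need >= 4 paired samples, got {n}")

    dom_top = top_n_features(dom, top_n_dom)
    otu_top = top_n_features(otu, top_n_otu)

    x = dom_top.to_numpy(dtype=float)
    y = otu_top.to_numpy(dtype=float)
    const_x = np.ptp(x, axis=1) == 0
    const_y = np.ptp(y, axis=1) == 0
    for fid in dom_top.index[const_x]:
        logger.info("skipping DOM molecule %s: zero variance across samples", fid)
    for fid in otu_top.index[const_y]:
        logger.info("skipping OTU %s: zero variance across samples", fid)

    r, p = _pairwise_pearson(x, y)
    valid = ~np.outer(const_x, const_y) & ~const_x[:, None] & ~const_y[None, :]

    if fdr:
        from statsmodels.stats.multitest import multipletests

        flat = p[valid]
        rej = np.zeros_like(p, dtype=bool)
        if flat.size:
            rej_flat = multipletests(flat, alpha=alpha, method="fdr_bh")[0]
            rej[valid] = rej_flat
        keep = rej
    else:
        keep = valid & (p < alpha)

    di, oi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "dom_id": np.asarray(dom_top.index.astype(str))[di],
            "otu_id": np.asarray(otu_top.index.astype(str))[oi],
            "r": r[di, oi],
            "p": p[di, oi],
        }
    )
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    edges = edges.sort_values(["dom_id", "otu_id"], kind="stable").reset_index(drop=True)
    return AssociationNetwork(
        edges=edges,
        dom_ids=dom_top.index.astype(str).tolist(),
        otu_ids=otu_top.index.astype(str).tolist(),
        top_n_dom=top_n_dom,
        top_n_otu=top_n_otu,
        alpha=alpha,
        fdr=fdr,
    )


def distance_matrix(matrix: pd.DataFrame, metric: str = "bray_curtis") -> pd.DataFrame:
    """Symmetric between-sample distances from a feature x sample table.

    ``bray_curtis`` first closes each sample to proportions;
    ``euclidean`` standardizes every feature to a z-score (population
    SD) before computing distances.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    samples = matrix.columns
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if metric == "bray_curtis":
        totals = x.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValidationError("sample with zero total abundance")
        d = pdist(x / totals, metric="braycurtis")
    elif metric == "euclidean":
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0  # constant features contribute nothing
        d = pdist((x - mu) / sd, metric="euclidean")
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=samples, columns=samples)


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic with its one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int
    controlled: str | None = None


def _validate_square(d: pd.DataFrame | np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(d, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be a square matrix")
    if a.shape[0] < 4:
        raise ValidationError(f"{name} must be at least 4x4")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError(f"{name} is not symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-10):
        raise ValidationError(f"{name} has a nonzero diagonal")
    return a


def _tri_corr(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    den = np.sqrt((ac**2).sum() * (bc**2).sum())
    if den == 0:
        raise ZeroVarianceError("distance matrix with constant off-diagonal entries")
    return float((ac @ bc) / den)


def mantel(
    da, db, n_perm: int = 999, seed: int | None = None
) -> MantelResult:
    """Mantel test: Pearson correlation of the unfolded upper triangles,
    one-sided (greater) permutation p-value.

    Permutations relabel the rows and columns of ``da`` jointly;
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`` so p is never 0.
    """
    a = _validate_square(da, "dA")
    b = _validate_square(db, "dB")
    if a.shape != b.shape:
        raise ValidationError("distance matrices must have identical shape")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    r_obs = _tri_corr(va, vb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        r_perm = _tri_corr(a[np.ix_(perm, perm)][iu], vb)
        if r_perm >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = (1 - rac**2) * (1 - rbc**2)
    if den <= 1e-12:
        return 0.0  # a control collinear with a matrix leaves no residual variance
    return (rab - rac * rbc) / np.sqrt(den)


def partial_mantel(
    da, db, dc, n_perm: int = 999, seed: int | None = None, controlled: str = "dC"
) -> MantelResult:
    """Partial Mantel test of dA vs dB controlling for dC.

    The statistic is the first-order partial correlation
    ``(r_ab - r_ac r_bc) / sqrt((1-r_ac^2)(1-r_bc^2))`` of the unfolded
    upper triangles (equivalent to correlating the regression residuals
    of dA and dB on dC); permutations relabel dA jointly and recompute
    r_ab and r_ac while r_bc stays fixed.
    """
    a = _validate_square(da, "dA")
    b = _validate_square(db, "dB")
    c = _validate_square(dc, "dC")
    if not (a.shape == b.shape == c.shape):
        raise ValidationError("distance matrices must have identical shape")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb, vc = a[iu], b[iu], c[iu]
    rbc = _tri_corr(vb, vc)
    r_obs = _partial_r(_tri_corr(va, vb), _tri_corr(va, vc), rbc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        vap = a[np.ix_(perm, perm)][iu]
        r_perm = _partial_r(_tri_corr(vap, vb), _tri_corr(vap, vc), rbc)
        if r_perm >= r_obs:
            count += 1
    return MantelResult(
        r=r_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm, controlled=controlled
    )
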