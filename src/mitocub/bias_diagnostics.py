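"""Mutation-vs-selection diagnostics and RSCU clustering.

Four classic diagnostics of what drives codon usage bias:

* Neutrality plot — GC12 (mean GC of codon positions 1-2) regressed on GC3;
  a slope near 1 means the three positions drift together under mutation
  pressure, a slope near 0 means selection constrains positions 1-2.
* ENC plot — observed ENC against GC3(s) compared with the null curve
  ENC_expected = 2 + GC3 + 29 / (GC3^2 + (1 - GC3)^2) expected when
  composition alone sets the bias; points falling below indicate selection.
* PR2 plot — A/T vs G/C balance at third positions of fourfold-degenerate
  sites; displacement from (0.5, 0.5) shows strand-asymmetric pressure.
* Pearson correlation matrix over the per-gene indices.
* Hierarchical clustering of RSCU vectors with 1 - Pearson r distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, RegressorMixin

from .codon_metrics import CodonCounts, third_position_counts
from .genetic_code import GeneticCode, get_code

# Slope threshold used only for the verbal interpretation in reports:
# above it mutation pressure is called dominant, below it selection.
SLOPE_INTERPRETATION_CUTOFF = 0.5


# ---------------------------------------------------------------------------
# neutrality plot
# ---------------------------------------------------------------------------


@dataclass
class NeutralityResult:
    """OLS fit of GC12 on GC3 across genes (values in percent)."""

    points: list[tuple[float, float]]
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    stderr: float

    @property
    def interpretation(self) -> str:
        if self.slope >= SLOPE_INTERPRETATION_CUTOFF:
            return "mutation-dominated (slope near 1)"
        return "selection-dominated (slope near 0)"


class NeutralityRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares of GC12 on GC3, sklearn-style.

    ``fit(X, y)`` takes GC3 values as X (1d or single-column 2d) and GC12 as
    y; fitted attributes are ``slope_``, ``intercept_``, ``rvalue_``,
    ``pvalue_`` (two-sided t-test on the slope) and ``stderr_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be one-dimensional GC3 values")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("X and y lengths differ")
        if x.size < 3:
            raise ValueError("need at least 3 genes for the neutrality fit")
        if np.ptp(x) == 0:
            raise ValueError("GC3 has zero variance; slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.rvalue_ = float(res.rvalue)
        self.pvalue_ = float(res.pvalue)
        self.stderr_ = float(res.stderr)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_


def neutrality_regression(profiles: pd.DataFrame) -> NeutralityResult:
    """Neutrality-plot regression from a per-gene profile table.

    Expects ``gc3`` and ``gc12`` columns in percent (as produced by
    :class:`~mitocub.codon_metrics.CodonUsageProfiler`).
    """
    sub = profiles[["gc3", "gc12"]].dropna()
    reg = NeutralityRegression().fit(sub["gc3"].to_numpy(), sub["gc12"].to_numpy())
    return NeutralityResult(
        points=list(zip(sub["gc3"], sub["gc12"])),
        slope=reg.slope_,
        intercept=reg.intercept_,
        pearson_r=reg.rvalue_,
        p_value=reg.pvalue_,
        stderr=reg.stderr_,
    )


# ---------------------------------------------------------------------------
# ENC plot
# ---------------------------------------------------------------------------


def enc_expected(gc3):
    """Null ENC under composition-only bias: 2 + s + 29/(s^2 + (1-s)^2).

    ``gc3`` is a fraction in [0, 1]; scalar or array.  Raises outside the
    domain.
    """
    s = np.asarray(gc3, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("GC3 must lie in [0, 1]")
    val = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(val) if np.isscalar(gc3) or np.ndim(gc3) == 0 else val


@dataclass
class EncPlotResult:
    """Observed ENC vs GC3 with deviations from the null curve."""

    genes: list[str]
    points: list[tuple[float, float]]  # (gc3 fraction, enc)
    deviations: list[float]  # observed - expected
    x_variable: str  # "gc3s" or "gc3"

    @property
    def n_below(self) -> int:
        return sum(1 for d in self.deviations if d < 0)

    @property
    def n_above(self) -> int:
        return sum(1 for d in self.deviations if d > 0)


def enc_plot(profiles: pd.DataFrame, x: str = "gc3s") -> EncPlotResult:
    """Per-gene deviation of observed ENC from the expected curve.

    ``x`` picks the abscissa: ``"gc3s"`` (synonymous third positions, the
    classic choice and the default) or ``"gc3"`` (all third positions).
    Profile GC columns are percentages; the curve takes fractions.
    """
    if x not in ("gc3s", "gc3"):
        raise ValueError("x must be 'gc3s' or 'gc3'")
    sub = profiles[["gene", x, "enc"]].dropna()
    frac = sub[x].to_numpy() / 100.0
    encs = sub["enc"].to_numpy()
    dev = encs - enc_expected(frac)
    return EncPlotResult(
        genes=list(sub["gene"]),
        points=list(zip(frac, encs)),
        deviations=[float(d) for d in dev],
        x_variable=x,
    )


# ---------------------------------------------------------------------------
# PR2 plot
# ---------------------------------------------------------------------------


@dataclass
class Pr2Point:
    """One gene's PR2 coordinates: x = G3/(G3+C3), y = A3/(A3+T3)."""

    gene: str
    x: float
    y: float
    quadrant: str | None  # "I".."IV", None when undefined or on a boundary

    @staticmethod
    def _quadrant(x: float, y: float) -> str | None:
        if math.isnan(x) or math.isnan(y) or x == 0.5 or y == 0.5:
            return None
        if y > 0.5:
            return "I" if x > 0.5 else "II"
        return "IV" if x > 0.5 else "III"


def pr2(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    *,
    fourfold_only: bool = True,
    gene: str | None = None,
) -> Pr2Point:
    """PR2 coordinates of one gene from its codon counts.

    Strict mode (default) tallies third-position bases over the
    fourfold-degenerate boxes only, Sueoka's definition; with
    ``fourfold_only=False`` all synonymously variable codons count.  A zero
    denominator yields NaN coordinates and no quadrant.
    """
    code = code or get_code(1)
    t = third_position_counts(counts, code, fourfold_only=fourfold_only)
    gc = t["G"] + t["C"]
    at = t["A"] + t["T"]
    x = t["G"] / gc if gc else math.nan
    y = t["A"] / at if at else math.nan
    return Pr2Point(
        gene=gene or counts.source, x=x, y=y, quadrant=Pr2Point._quadrant(x, y)
    )


def pr2_table(
    counts_list: list[CodonCounts],
    code: GeneticCode | None = None,
    *,
    fourfold_only: bool = True,
) -> pd.DataFrame:
    """PR2 coordinates for a list of genes as a tidy DataFrame."""
    pts = [pr2(c, code, fourfold_only=fourfold_only) for c in counts_list]
    return pd.DataFrame(
        {
            "gene": [p.gene for p in pts],
            "x_g3_over_g3c3": [p.x for p in pts],
            "y_a3_over_a3t3": [p.y for p in pts],
            "quadrant": [p.quadrant for p in pts],
        }
    )


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

CORRELATION_VARIABLES = [
    "n_codons", "gc1", "gc2", "gc3", "gc_all", "gc3s", "cai", "cbi", "fop", "enc",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r, two-sided p, and significance stars."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame = field(repr=False)


def correlation_matrix(
    profiles: pd.DataFrame, variables: list[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlations among per-gene indices with 0.05/0.01 stars.

    No multiple-testing correction is applied (the report notes this);
    constant variables get NaN correlations.
    """
    variables = variables or [
        v for v in CORRELATION_VARIABLES if v in profiles.columns
    ]
    if len(profiles) < 3:
        raise ValueError("need at least 3 genes for correlations")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = profiles[[variables[i], variables[j]]].dropna()
            xi = sub.iloc[:, 0].to_numpy(dtype=float)
            xj = sub.iloc[:, 1].to_numpy(dtype=float)
            if len(sub) < 3 or np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    stars = np.full((k, k), "", dtype=object)
    stars[p < 0.05] = "*"
    stars[p < 0.01] = "**"
    np.fill_diagonal(stars, "")
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=list(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        stars=pd.DataFrame(stars, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# RSCU clustering
# ---------------------------------------------------------------------------


@dataclass
class RscuDendrogram:
    """Agglomerative clustering of RSCU vectors (1 - Pearson r distance)."""

    leaves: list[str]
    linkage: np.ndarray = field(repr=False)
    newick: str

    @property
    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]


def _linkage_to_newick(Z: np.ndarray, leaves: list[str]) -> str:
    """Serialize a scipy linkage as Newick with branch lengths from heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaves[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    # root branch length 0
    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


class RscuClusterer(BaseEstimator):
    """Hierarchical clustering of genomes/genes by their RSCU vectors.

    Distance is 1 - Pearson correlation between RSCU vectors; linkage is
    average (UPGMA-style) by default, configurable.  ``fit`` accepts a
    DataFrame (rows = entities, columns = codons) or array with ``labels``.

    Attributes
    ----------
    linkage_ : ndarray
        scipy linkage matrix.
    newick_ : str
        Newick serialization with branch lengths derived from merge heights.
    labels_in_ : list of str
        Row labels in input order.
    """

    def __init__(self, linkage: str = "average"):
        self.linkage = linkage

    def fit(self, X, y=None, labels: list[str] | None = None):
        if isinstance(X, pd.DataFrame):
            labels = labels or [str(i) for i in X.index]
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            labels = labels or [f"row{i}" for i in range(mat.shape[0])]
        if mat.shape[0] < 2:
            raise ValueError("need at least 2 rows to cluster")
        # columns with any NaN (unobserved families) are dropped pairwise-safe:
        mat = mat[:, ~np.isnan(mat).any(axis=0)]
        sd = mat.std(axis=1)
        if np.any(sd == 0):
            bad = [labels[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance RSCU row(s): {bad}; correlation undefined")
        dist = pdist(mat, metric="correlation")  # exactly 1 - Pearson r
        self.linkage_ = hierarchy.linkage(dist, method=self.linkage)
        self.labels_in_ = list(labels)
        self.newick_ = _linkage_to_newick(self.linkage_, self.labels_in_)
        return self


def rscu_cluster(
    rscu_rows: pd.DataFrame, linkage: str = "average"
) -> RscuDendrogram:
    """Cluster RSCU row vectors; returns leaves, linkage and Newick text."""
    model = RscuClusterer(linkage=linkage).fit(rscu_rows)
    return RscuDendrogram(
        leaves=model.labels_in_, linkage=model.linkage_, newick=model.newick_
    )
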