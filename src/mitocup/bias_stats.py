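"""Selection/mutation analyses of codon usage: ENc-plot expectation,
neutrality regression, index correlations and RSCU matrix assembly.

The ENc-plot standard curve ENc = 2 + s + 29/(s^2 + (1-s)^2) gives the ENc
expected when composition (GC3s) alone drives codon choice; genes are
classified "on" the curve within a band of +/- 1 ENc unit, "above" or
"below" otherwise.  The neutrality plot regresses GC12 on GC3 across a
species panel per gene; the slope x 100 is read as the mutational-pressure
percentage M and 100 - M as the selection/constraint percentage N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import SENSE_CODONS, CodonUsageTable

__all__ = ["EncPlotPoint", "NeutralityFit", "expected_enc", "enc_plot_points",
           "neutrality_fit", "correlate_indices", "assemble_rscu_matrix"]

ON_CURVE_BAND = 1.0  # ENc units


@dataclass
class EncPlotPoint:
    species: str
    gene: str
    enc_obs: float
    gc3s: float

    @property
    def enc_expected(self) -> float:
        return expected_enc(self.gc3s)

    @property
    def residual(self) -> float:
        return self.enc_obs - self.enc_expected

    @property
    def position(self) -> str:
        r = self.residual
        if abs(r) <= ON_CURVE_BAND:
            return "on"
        return "above" if r > 0 else "below"


@dataclass
class NeutralityFit:
    gene: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    @property
    def mutation_percent(self) -> float:
        return self.slope * 100.0

    @property
    def selection_percent(self) -> float:
        return 100.0 - self.mutation_percent

    @property
    def slope_flagged(self) -> bool:
        return not (0.0 <= self.mutation_percent <= 100.0)


def expected_enc(gc3s: float) -> float:
    """Composition-only expected ENc at a given GC3s."""
    if not (0.0 <= gc3s <= 1.0):
        raise ValueError("gc3s must lie in [0, 1]")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_plot_points(index_table: pd.DataFrame,
                    method_col: str = "enc_sun") -> pd.DataFrame:
    """ENc-plot coordinates from a per-gene index table.

    Expects columns ``species``, ``gene``, ``gc3s`` and the ENc column named
    by ``method_col``.
    """
    pts = [EncPlotPoint(r.species, r.gene, getattr(r, method_col), r.gc3s)
           for r in index_table.itertuples()]
    return pd.DataFrame(
        {"species": p.species, "gene": p.gene, "enc_obs": p.enc_obs,
         "gc3s": p.gc3s, "enc_expected": p.enc_expected,
         "residual": p.residual, "position": p.position}
        for p in pts
    )


def neutrality_fit(points, gene: str = "") -> NeutralityFit:
    """OLS of GC12 on GC3 across species for one gene.

    ``points`` is an iterable of (gc12, gc3) pairs (fractions or
    percentages; the slope and therefore the M/N partition are
    scale-invariant).  M + N = 100 by construction.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("neutrality fit needs at least 3 points")
    gc12, gc3 = pts[:, 0], pts[:, 1]
    if np.ptp(gc3) == 0:
        return NeutralityFit(gene, math.nan, math.nan, math.nan, math.nan,
                             len(pts))
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(gene, res.slope, res.intercept, res.rvalue ** 2,
                         res.pvalue, len(pts))


DEFAULT_PAIRS = (("enc", "gc3"), ("enc", "gc3s"), ("enc", "gc1"),
                 ("enc", "gc2"), ("enc", "length"))


def correlate_indices(table: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Pearson correlations between codon-usage index columns."""
    rows = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({x}, {y}) has fewer than 3 rows")
        if sub[x].nunique() == 1 or sub[y].nunique() == 1:
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "pearson_r": r, "p_value": p,
                     "n": len(sub)})
    return pd.DataFrame(rows)


def assemble_rscu_matrix(tables: list[CodonUsageTable],
                         matrix: str = "covariance"):
    """Species x sense-codon RSCU matrix and its principal components.

    Absent amino acids (NaN RSCU) are set to 0.  ``matrix`` selects the
    eigendecomposition basis: ``covariance`` (centred) or ``correlation``
    (standardized; zero-variance codons dropped).  Returns
    ``(rscu_df, scores_df, explained_variance)``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 species for a RSCU matrix")
    data = pd.DataFrame(
        [{c: t.rscu.get(c, math.nan) for c in SENSE_CODONS} for t in tables],
        index=[t.label for t in tables],
    ).fillna(0.0)
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if matrix == "correlation":
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
    elif matrix != "covariance":
        raise ValueError("matrix must be 'covariance' or 'correlation'")
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = x @ evecs
    k = min(x.shape)
    scores_df = pd.DataFrame(
        scores[:, :k], index=data.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return data, scores_df, np.clip(evals, 0, None)
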