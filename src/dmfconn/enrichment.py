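"""Imaging-transcriptomics decoding and gene-set enrichment.

Decoding: for each donor brain, every gene's spatial expression profile is
regressed on an unthresholded imaging map; the donor-specific slopes are
tested against zero with a one-sample t test across donors, and genes with
a positive t surviving Benjamini-Hochberg FDR are retained.  Enrichment of
the decoded list in a target gene set (e.g. an interactome pruned to
disease-dysregulated members) is quantified with the 2x2 odds ratio within
the gene universe and an inclusive upper-tail hypergeometric p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneExpressionAtlas", "GeneSet", "DecodedGeneList",
           "EnrichmentResult", "donor_slopes", "decode_genes", "fdr_bh",
           "odds_ratio", "hypergeom_p", "enrich", "prune_interactome"]


@dataclass
class GeneExpressionAtlas:
    """Donor x gene x location expression values."""

    donors: list[str]
    genes: list[str]
    locations: list[str]
    X: np.ndarray             # donor x gene x location

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.donors), len(self.genes),
                            len(self.locations)):
            raise ValueError("X must be donor x gene x location")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")


@dataclass
class GeneSet:
    """A named gene list within a declared universe."""

    name: str
    members: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.universe = set(self.universe)
        if not self.members <= self.universe:
            raise ValueError("gene-set members must lie within the universe")


@dataclass
class DecodedGeneList:
    """Genes whose expression tracks the imaging map (t > 0, q < threshold)."""

    table: pd.DataFrame       # gene, t, p, q, retained
    q_threshold: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "gene"])


@dataclass
class EnrichmentResult:
    overlap_k: int
    size_A: int
    size_B: int
    N: int
    odds_ratio: float
    p_hypergeometric: float
    q: float | None = None


def donor_slopes(atlas: GeneExpressionAtlas, imaging_map: np.ndarray,
                 zscore_expression: bool = False) -> pd.DataFrame:
    """Per-donor, per-gene least-squares slope of expression on the map.

    The imaging map is mean-centred; expression is used untransformed
    unless ``zscore_expression`` standardizes it per donor and gene.
    Returns a donor x gene DataFrame of slopes.
    """
    x = np.asarray(imaging_map, dtype=float)
    if x.shape != (len(atlas.locations),):
        raise ValueError("imaging map must have one value per atlas location")
    if x.size < 3:
        raise ValueError("need >= 3 locations")
    if not np.all(np.isfinite(x)):
        raise ValueError("imaging map must be finite")
    xc = x - x.mean()
    ssx = xc @ xc
    if ssx == 0:
        raise ValueError("imaging map is constant")
    X = atlas.X
    if zscore_expression:
        sd = X.std(axis=2, keepdims=True)
        X = (X - X.mean(axis=2, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    slopes = X @ xc / ssx  # donor x gene
    return pd.DataFrame(slopes, index=atlas.donors, columns=atlas.genes)


def decode_genes(slopes: pd.DataFrame,
                 q_threshold: float = 0.05) -> DecodedGeneList:
    """One-sample t across donors + BH-FDR; keep genes with t > 0, q < thr.

    Genes with zero across-donor slope variance have an undefined t and are
    excluded with a warning.
    """
    if slopes.shape[0] < 2:
        raise ValueError("need >= 2 donors")
    S = slopes.to_numpy(dtype=float)
    sd = S.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_1samp(S, popmean=0.0, axis=0)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) with zero slope "
                      "variance excluded from decoding")
        t[degenerate] = np.nan
        p[degenerate] = np.nan
    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = fdr_bh(p[valid])
    retained = np.isfinite(q) & (t > 0) & (q < q_threshold)
    table = pd.DataFrame({"gene": slopes.columns, "t": t, "p": p, "q": q,
                          "retained": retained})
    return DecodedGeneList(table=table, q_threshold=q_threshold)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _cells(k: int, size_A: int, size_B: int, N: int):
    if not (0 <= k <= min(size_A, size_B)):
        raise ValueError("overlap k must lie in [0, min(A, B)]")
    if size_A + size_B - k > N:
        raise ValueError("lists cannot exceed the universe")
    return (float(k), float(size_A - k), float(size_B - k),
            float(N - size_A - size_B + k))


def odds_ratio(k: int, size_A: int, size_B: int, N: int) -> float:
    """Cross-product odds ratio of the 2x2 list-membership table.

    OR = [k * (N - A - B + k)] / [(A - k) * (B - k)]; when any cell is
    zero, 0.5 is added to all four cells first (Haldane-Anscombe).
    """
    a, b, c, d = _cells(k, size_A, size_B, N)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeom_p(k: int, size_A: int, size_B: int, N: int) -> float:
    """Inclusive upper-tail overlap probability P(X >= k).

    X counts members of a size-B set in size-A draws without replacement
    from a universe of N genes.
    """
    _cells(k, size_A, size_B, N)  # validate counts
    return float(stats.hypergeom.sf(k - 1, N, size_B, size_A))


def enrich(decoded: DecodedGeneList | set[str],
           target: GeneSet) -> EnrichmentResult:
    """Overlap enrichment of a decoded gene list in a target gene set."""
    genes = set(decoded.genes) if isinstance(decoded, DecodedGeneList) \
        else set(decoded)
    if not genes <= target.universe:
        raise ValueError("decoded genes must lie within the target universe")
    k = len(genes & target.members)
    A, B, N = len(genes), len(target.members), len(target.universe)
    return EnrichmentResult(overlap_k=k, size_A=A, size_B=B, N=N,
                            odds_ratio=odds_ratio(k, A, B, N),
                            p_hypergeometric=hypergeom_p(k, A, B, N))


def prune_interactome(interactors: GeneSet, dysregulated: GeneSet) -> GeneSet:
    """Keep interactors that are also dysregulated (set intersection)."""
    members = interactors.members & dysregulated.members
    if not members:
        warnings.warn("pruned interactome is empty")
    return GeneSet(name=f"{interactors.name}&{dysregulated.name}",
                   members=members, universe=interactors.universe)
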