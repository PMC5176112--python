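"""Population structure and divergence on dominant duplication markers.

Presence/absence duplication genotypes are analysed as dominant binary
markers: PCA for population structure, a Hudson-type two-population F_ST on
presence frequencies with finite-sample correction, and a label-permutation
outlier scan with Benjamini-Hochberg FDR control. Result tables from external
Bayesian outlier scanners (BayeScan-style log10 posterior odds, BayPass-style
XtX) can be imported so that a two-method outlier intersection can be formed
from user-supplied outputs.

The F_ST estimator for presence frequencies p1, p2 with sample sizes n1, n2::

    F_ST = [ (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) ]
           / [ p1(1-p2) + p2(1-p1) ]

It equals 1 exactly for fixed differences, is symmetric in the two groups,
and is undefined (signalled) when both groups are fixed for the same state.
Negative estimates (sampling noise at equal frequencies) are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotyping import GenotypeMatrix


# ---------------------------------------------------------------------------
# PCA


def pca_binary(
    m: Union[GenotypeMatrix, pd.DataFrame], n_components: Optional[int] = None
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of the dominant-marker matrix.

    Samples are rows; missing cells are mean-imputed per locus; columns
    (loci) are centred. Returns per-sample component scores and the fraction
    of total variance explained per component (non-increasing, sums to <= 1).
    A constant matrix is signalled with a warning and zero variance
    fractions.
    """
    data = m.data if isinstance(m, GenotypeMatrix) else m
    X = data.to_numpy(dtype=float).T  # samples x loci
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 loci")
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum())
    k = min(X.shape) if n_components is None else min(n_components, *X.shape)
    if total_var == 0.0:
        warnings.warn("constant genotype matrix: zero total variance", stacklevel=2)
        scores = np.zeros((X.shape[0], k))
        ratios = np.zeros(k)
    else:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Xc)
        ratios = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    index = data.columns if hasattr(data, "columns") else range(X.shape[0])
    return pd.DataFrame(scores, index=index, columns=cols), ratios


# ---------------------------------------------------------------------------
# F_ST


def fst_dominant(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson-type F_ST between two groups of dominant binary markers."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"frequency {p} outside [0, 1]")
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        raise ValueError("both groups fixed for the same state: F_ST undefined")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    return num / den


def _fst_arrays(k1, n1, k2, n2) -> np.ndarray:
    """Vectorised Hudson F_ST from carrier counts; NaN where undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = k1 / n1
        p2 = k2 / n2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        out = num / den
    out = np.where((den == 0) | (n1 < 2) | (n2 < 2), np.nan, out)
    return out


# ---------------------------------------------------------------------------
# permutation outlier scan


def outlier_scan(
    m: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    n_perm: int = 10000,
    fdr: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    randomized_p: bool = False,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Per-locus F_ST with a group-label permutation p-value and BH-adjusted
    q-value.

    Group labels are shuffled jointly across loci (whole sample columns) so
    the null preserves inter-locus correlation. The default p-value is the
    conservative ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``; with
    ``randomized_p`` ties between permuted and observed statistics are broken
    uniformly at random, making the p-value exactly uniform under
    exchangeability. Loci flagged at ``q < fdr``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need >= 2 samples per group")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = list(group1) + list(group2)
    G = m.data[ids].to_numpy(dtype=float)  # loci x samples
    obs_mask = ~np.isnan(G)
    G0 = np.where(obs_mask, G, 0.0)
    n_loci, n_samples = G.shape
    n1 = len(group1)

    def group_stats(indicator: np.ndarray) -> np.ndarray:
        """indicator: samples x B membership of group1 -> F_ST loci x B."""
        c1 = obs_mask.astype(float) @ indicator            # non-missing in g1
        c2 = obs_mask.astype(float) @ (1.0 - indicator)
        k1 = G0 @ indicator
        k2 = G0 @ (1.0 - indicator)
        return _fst_arrays(k1, c1, k2, c2)

    obs_ind = np.zeros((n_samples, 1))
    obs_ind[:n1, 0] = 1.0
    fst_obs = group_stats(obs_ind)[:, 0]

    exceed = np.zeros(n_loci)
    ties = np.zeros(n_loci)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        ind = np.zeros((n_samples, b))
        for j in range(b):
            ind[rng.permutation(n_samples)[:n1], j] = 1.0
        fst_perm = group_stats(ind)
        with np.errstate(invalid="ignore"):
            exceed += np.nansum(fst_perm > fst_obs[:, None], axis=1)
            ties += np.nansum(
                np.isclose(fst_perm, fst_obs[:, None], rtol=0, atol=1e-12), axis=1
            )
        done += b

    if randomized_p:
        u = rng.random(n_loci)
        pvals = (exceed + u * (1.0 + ties)) / (n_perm + 1.0)
    else:
        pvals = (1.0 + exceed + ties) / (n_perm + 1.0)
    pvals = np.where(np.isnan(fst_obs), np.nan, np.minimum(pvals, 1.0))

    valid = ~np.isnan(pvals)
    qvals = np.full(n_loci, np.nan)
    if valid.any():
        _, q, _, _ = multipletests(pvals[valid], method="fdr_bh")
        qvals[valid] = q
    flagged = (qvals < fdr) & valid

    with np.errstate(invalid="ignore"):
        p1 = np.nansum(G0[:, :n1], axis=1) / np.maximum(obs_mask[:, :n1].sum(axis=1), 1)
        p2 = np.nansum(G0[:, n1:], axis=1) / np.maximum(obs_mask[:, n1:].sum(axis=1), 1)
    return pd.DataFrame(
        {
            "locus": m.loci,
            "freq1": p1,
            "freq2": p2,
            "fst": fst_obs,
            "pvalue": pvals,
            "qvalue": qvals,
            "flagged": flagged,
        }
    ).set_index("locus")


# ---------------------------------------------------------------------------
# two-method intersection


@dataclass(frozen=True)
class OutlierReport:
    """Outlier loci from two scans and their intersection."""

    set_a: Tuple[str, ...]
    set_b: Tuple[str, ...]
    intersection: Tuple[str, ...]

    def __post_init__(self):
        inter = set(self.intersection)
        if not (inter <= set(self.set_a) and inter <= set(self.set_b)):
            raise ValueError("intersection not contained in both sets")


def intersect_outliers(
    a: Sequence[str],
    b: Sequence[str],
    coordinates: Optional[Dict[str, Tuple[str, int, int]]] = None,
) -> OutlierReport:
    """Cross-reference two outlier locus sets; the intersection is ordered by
    genome coordinate when ``coordinates`` (locus -> (chrom, start, end)) is
    given, else lexicographically."""
    inter = set(a) & set(b)
    if coordinates:
        order = sorted(inter, key=lambda l: coordinates.get(l, (l, 0, 0)))
    else:
        order = sorted(inter)
    return OutlierReport(
        set_a=tuple(sorted(set(a))),
        set_b=tuple(sorted(set(b))),
        intersection=tuple(order),
    )


# ---------------------------------------------------------------------------
# importers for external outlier-scanner tables


def read_bayescan_outliers(
    path, loci: Optional[Sequence[str]] = None, log10_po_threshold: float = 1.0
) -> Set[str]:
    """Parse a BayeScan ``_fst.txt``-style table and return the loci with
    log10 posterior odds above ``log10_po_threshold`` (default 1: strong
    support for selection).

    The table is whitespace-separated with a header naming a ``log10(PO)``
    column; the first (unnamed or index) column is the 1-based locus index,
    mapped through ``loci`` when given, else the index string itself.
    """
    df = pd.read_csv(path, sep=r"\s+")
    col = _find_column(df, ("log10(po)", "log10_po", "log10po"))
    return _thresholded(df, col, lambda v: v > log10_po_threshold, loci)


def read_baypass_outliers(
    path, loci: Optional[Sequence[str]] = None, xtx_threshold: float = 7.9
) -> Set[str]:
    """Parse a BayPass XtX summary table and return the loci whose (mean)
    XtX exceeds ``xtx_threshold`` (default 7.9: a calibrated significance
    threshold of the simulated null)."""
    df = pd.read_csv(path, sep=r"\s+")
    col = _find_column(df, ("m_xtx", "xtx", "mean_xtx"))
    return _thresholded(df, col, lambda v: v > xtx_threshold, loci)


def _find_column(df: pd.DataFrame, aliases: Tuple[str, ...]) -> str:
    for c in df.columns:
        if c.strip().lower() in aliases:
            return c
    raise ValueError(f"no column matching {aliases} in {list(df.columns)}")


def _thresholded(df, col, pred, loci) -> Set[str]:
    default_index = isinstance(df.index, pd.RangeIndex)
    out = set()
    for i, (_, row) in enumerate(df.iterrows()):
        if pred(float(row[col])):
            if loci is not None:
                out.add(loci[i])
            elif default_index:
                out.add(str(i + 1))
            else:
                out.add(str(df.index[i]))
    return out
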