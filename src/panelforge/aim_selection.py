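"""Ancestry-informative-marker (AIM) selection.

Per-locus pairwise FST is estimated with the Weir & Cockerham (1984)
variance-components estimator theta = a / (a + b + c), where a, b and c are
the among-population, among-individual-within-population and
within-individual components at a biallelic locus.  Loci are then ranked
per chromosome and per population pair and the top k retained (default
k = 5000 per chromosome, after the published panel-design workflow this
package re-implements), the final panel being the union across pairs.

Nei's Gst and Hudson's estimator are provided for sensitivity analyses.
A panel-size heuristic interpolates between two published anchor points
(FST 0.01 -> 20,000 SNPs; FST 0.001 -> 100,000 SNPs) on a log-log scale.
Panel utility is validated by leave-one-out population assignment with a
linear discriminant fitted on PCA-reduced genotype dosages (a DAPC-style
check).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .panel_io import chrom_sort_key

__all__ = [
    "per_locus_fst",
    "weir_cockerham_components",
    "fst_table",
    "select_top_aims",
    "recommend_min_snps",
    "maf_filter",
    "assignment_validation",
]

_ESTIMATORS = ("weir_cockerham", "nei", "hudson")


def _pop_stats(genotypes: np.ndarray, labels: np.ndarray, pair: tuple[str, str]):
    """Per-population sample sizes, alt-allele frequencies and observed
    heterozygote frequencies for the two populations of ``pair``.

    ``genotypes``: (n_samples, n_loci) alt dosages 0/1/2, -1 for missing.
    """
    genotypes = np.asarray(genotypes)
    labels = np.asarray(labels)
    stats = []
    for pop in pair:
        rows = genotypes[labels == pop]
        if rows.shape[0] < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
        valid = rows >= 0
        n = valid.sum(axis=0).astype(float)  # diploid individuals per locus
        if np.any(n < 2):
            raise ValueError("fewer than 2 genotyped individuals at some locus")
        dos = np.where(valid, rows, 0).astype(float)
        p = dos.sum(axis=0) / (2.0 * n)
        h = ((rows == 1) & valid).sum(axis=0) / n
        stats.append((n, p, h))
    return stats


def weir_cockerham_components(
    genotypes: np.ndarray, labels: np.ndarray, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components (a, b, c) for two
    populations, vectorized across loci.

    a: among populations; b: among individuals within populations;
    c: within individuals (heterozygosity/2).  theta = a / (a + b + c).
    """
    (n1, p1, h1), (n2, p2, h2) = _pop_stats(genotypes, labels, pair)
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0
        )
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def per_locus_fst(
    genotypes: np.ndarray,
    labels,
    pair: tuple[str, str],
    estimator: str = "weir_cockerham",
) -> np.ndarray:
    """Per-locus FST between the two populations of ``pair``.

    Returns one value per locus; loci monomorphic across the pooled pair are
    undefined (NaN).  Weir–Cockerham values may be slightly negative at
    undifferentiated loci — that is expected and kept.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {_ESTIMATORS}")
    labels = np.asarray(labels)
    (n1, p1, h1), (n2, p2, h2) = _pop_stats(genotypes, labels, pair)
    p_pool = (2 * n1 * p1 + 2 * n2 * p2) / (2 * n1 + 2 * n2)
    mono = (p_pool <= 0.0) | (p_pool >= 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "weir_cockerham":
            a, b, c = weir_cockerham_components(genotypes, labels, pair)
            theta = a / (a + b + c)
        elif estimator == "nei":
            hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
            pm = (p1 + p2) / 2.0
            ht = 2 * pm * (1 - pm)
            theta = (ht - hs) / ht
        else:  # hudson (Bhatia et al. ratio form, per locus)
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            theta = num / den
    theta = np.asarray(theta, dtype=float)
    theta[mono] = np.nan
    return theta


def fst_table(
    panel,
    pairs: list[tuple[str, str]] | None = None,
    estimator: str = "weir_cockerham",
    biallelic: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-SNP, per-pair FST table from a GenotypePanel.

    Columns: chrom, pos, pair ("popA|popB"), fst, biallelic.
    """
    pops = sorted(set(panel.pop_labels))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    if biallelic is None:
        biallelic = np.ones(panel.n_loci, dtype=bool)
    frames = []
    labels = np.asarray(panel.pop_labels)
    for a, b in pairs:
        theta = per_locus_fst(panel.genotypes, labels, (a, b), estimator)
        frames.append(pd.DataFrame({
            "chrom": panel.chrom,
            "pos": panel.pos,
            "pair": f"{a}|{b}",
            "fst": theta,
            "biallelic": biallelic,
        }))
    return pd.concat(frames, ignore_index=True)


def select_top_aims(fst_df: pd.DataFrame, k: int = 5000) -> pd.DataFrame:
    """Per chromosome and population pair, retain the k loci with highest
    FST (undefined and non-biallelic loci excluded); the panel is the union
    of (chrom, pos) across pairs, each locus reported once with its best
    pair and FST.

    Ties at the k-th rank and duplicate selections are broken
    deterministically by (chromosome order, position), so the output is
    invariant to input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = fst_df[fst_df["biallelic"] & fst_df["fst"].notna()].copy()
    if eligible.empty:
        warnings.warn("no eligible loci; empty AIM panel", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", "pair", "fst"])
    eligible["_ck"] = eligible["chrom"].map(chrom_sort_key)
    # deterministic ranking: fst desc, then chrom order, position asc
    eligible = eligible.sort_values(
        ["_ck", "pair", "fst", "pos"], ascending=[True, True, False, True], kind="mergesort"
    )
    top = eligible.groupby(["chrom", "pair"], sort=False).head(k)
    # union across pairs: keep the highest-fst pair per locus
    top = top.sort_values(["_ck", "pos", "fst"], ascending=[True, True, False], kind="mergesort")
    panel = top.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return panel.drop(columns="_ck").reset_index(drop=True)[["chrom", "pos", "pair", "fst"]]


# published anchor points: (FST, SNPs needed for accurate inference)
_ANCHOR_LO = (0.001, 100_000)
_ANCHOR_HI = (0.01, 20_000)


def recommend_min_snps(fst: float) -> int:
    """Minimum panel size for accurate population inference at a given FST.

    Anchored at 100,000 SNPs for FST = 0.001 and 20,000 for FST = 0.01,
    log-log interpolated in between, rounded up to the nearest 1000;
    clamped at the anchors outside that range.  Monotone non-increasing.
    """
    if not (0.0 < fst < 1.0):
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    if fst <= _ANCHOR_LO[0]:
        return _ANCHOR_LO[1]
    if fst >= _ANCHOR_HI[0]:
        return _ANCHOR_HI[1]
    t = (math.log(fst) - math.log(_ANCHOR_LO[0])) / (math.log(_ANCHOR_HI[0]) - math.log(_ANCHOR_LO[0]))
    log_n = math.log(_ANCHOR_LO[1]) + t * (math.log(_ANCHOR_HI[1]) - math.log(_ANCHOR_LO[1]))
    return int(math.ceil(math.exp(log_n) / 1000.0) * 1000)


def maf_filter(genotypes: np.ndarray, maf_min: float = 0.01) -> np.ndarray:
    """Boolean mask of loci with minor allele frequency strictly > maf_min,
    pooled over all non-missing calls across samples."""
    if not (0.0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    g = np.asarray(genotypes)
    valid = g >= 0
    n_alleles = 2.0 * valid.sum(axis=0)
    alt = np.where(valid, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_alleles > 0, maf, 0.0)
    return maf > maf_min


def assignment_validation(
    genotypes: np.ndarray,
    labels,
    n_pcs: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Leave-one-out population assignment accuracy on PCA-reduced dosages.

    Centers and unit-scales each locus, projects onto the top ``n_pcs``
    principal components, then evaluates a linear discriminant by
    leave-one-out: each sample is assigned by a discriminant fitted on all
    other samples.  Returns (accuracy, PC coordinates).
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels)
    n_samples = g.shape[0]
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 populations")
    if not (1 <= n_pcs < n_samples):
        raise ValueError("n_pcs must be >= 1 and < sample count")
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    x = (g - mu) / sd
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(x)
    rank = np.linalg.matrix_rank(x)
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds the genotype-matrix rank {rank}")

    correct = 0
    idx = np.arange(n_samples)
    for i in range(n_samples):
        train = idx != i
        lda = LinearDiscriminantAnalysis()
        lda.fit(pcs[train], labels[train])
        if lda.predict(pcs[i:i + 1])[0] == labels[i]:
            correct += 1
    return correct / n_samples, pcs
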