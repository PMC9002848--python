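"""Filtering, TMM normalization, CPM/RPKM and expression classification.

The between-sample normalization is the trimmed mean of M-values (TMM):
each library is compared to a reference library chosen by upper-quartile
similarity, per-gene log2 expression ratios (M) are doubly trimmed — by M
and by average log intensity (A) — and the library's scaling factor is the
weighted mean of the surviving M values, with inverse asymptotic binomial
variances as weights.  Factors are rescaled to geometric mean 1 so that
effective library size = raw library size x factor.

Expression calls use RPKM (fragments per kilobase per million, on the
TMM-effective library sizes): a gene is expressed at a time point when its
mean RPKM over that time point's replicates is >= 0.3, and its overall
level is binned as low [0.3, 1), medium [1, 10), high [10, 100) or
very high [100, inf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import CountMatrix, GeneAnnotation

logger = logging.getLogger("floraltime")

RPKM_EXPRESSED = 0.3
LEVEL_BINS = (0.3, 1.0, 10.0, 100.0)
LEVEL_NAMES = ("not_expressed", "low", "medium", "high", "very_high")


@dataclass
class NormalizationFactors:
    """Per-sample raw library size and TMM scaling factor."""

    sample_ids: list[str]
    library_sizes: np.ndarray
    tmm_factors: np.ndarray

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "library_size": self.library_sizes.astype(np.int64),
            "tmm_factor": self.tmm_factors,
        })


@dataclass
class ExpressionProfiles:
    """Per-gene CPM/RPKM, per-time-point mean RPKM and expressed calls.

    ``expressed`` is a boolean genes x time-points frame
    (mean RPKM >= 0.3); ``level`` and ``pattern`` are filled by
    :func:`classify_expression`.
    """

    cpm: pd.DataFrame
    rpkm: pd.DataFrame
    mean_rpkm: pd.DataFrame           # genes x time points
    expressed: pd.DataFrame           # boolean, genes x time points
    level: pd.Series | None = None
    pattern: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    def expressed_at(self, gene_id: str) -> set[int]:
        row = self.expressed.loc[gene_id]
        return set(self.expressed.columns[row.to_numpy(bool)])

    def expressed_any(self) -> pd.Series:
        """Genes expressed at one or more time points."""
        return self.expressed.any(axis=1)


# ---------------------------------------------------------------------------
# Low-count filter
# ---------------------------------------------------------------------------

def filter_low_counts(cm: CountMatrix, min_cpm: float = 1.0) -> CountMatrix:
    """Keep genes whose mean CPM (raw library sizes, no TMM) exceeds
    ``min_cpm`` in at least one time point.

    The filter runs before normalization, on unadjusted library sizes.
    """
    lib = cm.library_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("library size of zero; cannot compute CPM")
    cpm = cm.counts / lib * 1e6
    keep = np.zeros(cm.n_genes, dtype=bool)
    for _, cols in cm.groups().items():
        keep |= cpm[:, cols].mean(axis=1) > min_cpm
    if not keep.any():
        raise ValueError("no genes pass filter")
    logger.info("filter_low_counts: kept %d / %d genes (mean CPM > %g in >=1 time point)",
                int(keep.sum()), cm.n_genes, min_cpm)
    return cm.subset_genes(keep)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """TMM factor of one library against the reference (log2 scale folded
    back to a ratio).  Trims ``trim_m`` from each tail of M and ``trim_a``
    from each tail of A; weights are inverse delta-method binomial
    variances."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_obs = np.log2(obs / n_obs)
        log_ref = np.log2(ref / n_ref)
        m = log_obs - log_ref
        a = (log_obs + log_ref) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0:
        logger.warning("TMM: no co-expressed genes with the reference; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        logger.warning("TMM: trimming removed all genes; factor set to 1")
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference library = the sample whose 75th-percentile CPM is closest to
    the mean of the 75th percentiles (computed after dropping all-zero
    genes).
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.library_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("zero-size library")
    x = cm.counts[cm.counts.sum(axis=1) > 0].astype(float)
    q75 = np.quantile(x / lib, 0.75, axis=0, method="linear")
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(cm.n_samples)
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(sample_ids=cm.sample_ids, library_sizes=cm.library_sizes,
                                tmm_factors=factors)


# ---------------------------------------------------------------------------
# CPM / RPKM and classification
# ---------------------------------------------------------------------------

def cpm_rpkm(cm: CountMatrix, nf: NormalizationFactors,
             annotation: dict[str, GeneAnnotation] | dict[str, int],
             rpkm_threshold: float = RPKM_EXPRESSED) -> ExpressionProfiles:
    """CPM and RPKM on TMM-effective library sizes, per-time-point mean
    RPKM, and expressed calls (mean RPKM >= ``rpkm_threshold``).

    ``annotation`` maps gene id to either a :class:`GeneAnnotation` or a
    bare length in bp.
    """
    lengths = np.empty(cm.n_genes)
    missing = []
    for i, g in enumerate(cm.gene_ids):
        ann = annotation.get(g)
        if ann is None:
            missing.append(g)
            continue
        lengths[i] = ann.length_bp if isinstance(ann, GeneAnnotation) else int(ann)
    if missing:
        raise ValueError(f"missing gene length(s): {missing[:10]}"
                         + (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
    eff = nf.effective_sizes
    cpm = pd.DataFrame(cm.counts / eff * 1e6, index=cm.gene_ids, columns=cm.sample_ids)
    rpkm = cpm * 1e3 / lengths[:, None]
    mean_rpkm = pd.DataFrame(
        {t: rpkm.iloc[:, cols].mean(axis=1) for t, cols in cm.groups().items()}
    )
    expressed = mean_rpkm >= rpkm_threshold
    return ExpressionProfiles(cpm=cpm, rpkm=rpkm, mean_rpkm=mean_rpkm, expressed=expressed)


def classify_expression(profiles: ExpressionProfiles) -> pd.DataFrame:
    """Assign each gene a level category and a time-point pattern.

    Level = bin of the mean RPKM over the time points where the gene is
    expressed (not_expressed if none).  Pattern = the subset of time points
    with an expressed call, e.g. ``"10+15"``; genes fall in exactly one of
    the 2^T subsets.  Returns the per-gene table and stores ``level`` /
    ``pattern`` on ``profiles``; the tally per pattern is
    ``result.groupby("pattern").size()``.
    """
    mr = profiles.mean_rpkm
    exp = profiles.expressed
    masked = mr.where(exp)
    level_mean = masked.mean(axis=1)  # NaN when nowhere expressed
    level = pd.Series(
        np.select(
            [level_mean.isna(), level_mean < LEVEL_BINS[1], level_mean < LEVEL_BINS[2],
             level_mean < LEVEL_BINS[3]],
            LEVEL_NAMES[:4],
            default=LEVEL_NAMES[4],
        ),
        index=mr.index, name="level",
    )
    tps = list(exp.columns)
    pattern = exp.apply(
        lambda row: "+".join(str(t) for t in tps if row[t]) or "none", axis=1)
    pattern.name = "pattern"
    profiles.level = level
    profiles.pattern = pattern
    out = pd.DataFrame({"level": level, "pattern": pattern,
                        "mean_rpkm_expressed": level_mean})
    return out


# ---------------------------------------------------------------------------
# MDS quality control
# ---------------------------------------------------------------------------

def log_cpm(cm: CountMatrix, nf: NormalizationFactors, prior_count: float = 2.0) -> pd.DataFrame:
    """log2 CPM on effective library sizes with a library-size-scaled prior
    count (keeps zeros finite and damps low-count fold changes)."""
    eff = nf.effective_sizes.astype(float)
    prior = prior_count * eff / eff.mean()
    lc = np.log2((cm.counts + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(lc, index=cm.gene_ids, columns=cm.sample_ids)


def mds_qc(cm: CountMatrix, nf: NormalizationFactors, top_n: int = 500,
           prior_count: float = 2.0) -> pd.DataFrame:
    """2-D sample ordination for quality control.

    Pairwise sample distance = root-mean-square of the ``top_n`` largest
    absolute log2 fold changes of normalized log CPM ("leading log
    fold change"); coordinates from classical metric MDS (principal
    coordinates).  Deterministic up to axis sign.
    """
    if cm.n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    if cm.n_genes < top_n:
        logger.warning("mds_qc: only %d genes < top_n=%d; using all", cm.n_genes, top_n)
        top_n = cm.n_genes
    lc = log_cpm(cm, nf, prior_count).to_numpy()
    n = cm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (lc[:, i] - lc[:, j]) ** 2
            top = np.partition(diff2, len(diff2) - top_n)[-top_n:]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    coords = classical_mds(d, n_dims=2)
    return pd.DataFrame(coords, index=cm.sample_ids, columns=["dim1", "dim2"])


def classical_mds(d: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Principal-coordinates analysis of a distance matrix (Torgerson
    double-centering + eigendecomposition)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)
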