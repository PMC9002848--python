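"""Negative-binomial GLM differential expression between time points.

Counts are modelled as NB(mu, phi) with variance mu + phi*mu^2, a log link
and log effective library sizes as offsets, in a one-way layout over time
points.  A single dispersion phi shared across genes is estimated by
maximizing the summed Cox-Reid adjusted profile log-likelihood; each
time-point pair is then tested with a true likelihood-ratio test (full
model: separate group abundances; reduced: equal abundance in the two
groups), with the statistic referred to chi-square(1) and
Benjamini-Hochberg FDR applied within each contrast.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .data_io import CountMatrix
from .normalize import NormalizationFactors

logger = logging.getLogger("floraltime")

_POISSON_PHI = 1e-12  # below this, use the Poisson log-likelihood

VENN_CONTRASTS = ("10v15", "15v19", "19v29", "10v29")


@dataclass
class DispersionEstimate:
    """Common NB dispersion and the (phi, objective) trace of the search."""

    phi: float
    trace: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# NB log-likelihood and one-way group fits
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples (y, mu: genes x
    samples).  mu = 0 cells contribute 0 iff y = 0 there."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    pos = mu > 0
    out = np.zeros(y.shape)
    if phi <= _POISSON_PHI:
        out[pos] = y[pos] * np.log(mu[pos]) - mu[pos] - gammaln(y[pos] + 1.0)
    else:
        r = 1.0 / phi
        m, yy = mu[pos], y[pos]
        out[pos] = (gammaln(yy + r) - gammaln(r) - gammaln(yy + 1.0)
                    + r * np.log(r / (r + m)) + yy * np.log(m / (r + m)))
    bad = (~pos) & (y > 0)
    if np.any(bad):
        out[bad] = -np.inf
    return out.sum(axis=-1)


def _fit_abundance(y: np.ndarray, eff: np.ndarray, phi: float,
                   tol: float = 1e-10, max_iter: int = 100):
    """MLE of per-gene abundance a (fragments per unit effective library)
    for one group: mu_ij = a_i * eff_j.

    Fisher scoring on beta = log a; vectorized over genes.  Returns
    (abundance, loglik, converged).  All-zero genes get abundance 0 with
    the exact boundary log-likelihood.
    """
    y = np.asarray(y, float)
    eff = np.asarray(eff, float)
    tot = y.sum(axis=1)
    a = np.where(tot > 0, tot / eff.sum(), np.nan)
    zero = tot == 0
    converged = np.ones(y.shape[0], dtype=bool)
    if phi > _POISSON_PHI:
        beta = np.log(np.where(zero, 1.0, a))
        ll_old = None
        active = ~zero
        for _ in range(max_iter):
            if not active.any():
                break
            mu = np.exp(beta)[:, None] * eff[None, :]
            denom = 1.0 + phi * mu
            score = ((y - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = np.where(active, score / np.maximum(info, 1e-300), 0.0)
            step = np.clip(step, -10.0, 10.0)
            beta = beta + step
            ll = nb_loglik(y, np.exp(beta)[:, None] * eff[None, :], phi)
            if ll_old is not None:
                rel = np.abs(ll - ll_old) / (np.abs(ll_old) + 1.0)
                active = active & (rel >= 1e-14)
            ll_old = ll
            if np.all(np.abs(step) < tol):
                break
        else:
            converged = np.abs(score / np.maximum(info, 1e-300)) < 1e-4
        a = np.where(zero, 0.0, np.exp(beta))
    else:
        a = np.where(zero, 0.0, a)  # Poisson MLE is closed-form
    mu = a[:, None] * eff[None, :]
    return a, nb_loglik(y, mu, phi), converged


def _fisher_weight_sum(a: np.ndarray, eff: np.ndarray, phi: float) -> np.ndarray:
    """Sum over a group's samples of the GLM working weights mu/(1+phi*mu)
    at the fitted abundance (the 1x1 Fisher information per gene)."""
    mu = a[:, None] * eff[None, :]
    return (mu / (1.0 + phi * mu)).sum(axis=1)


# ---------------------------------------------------------------------------
# Common dispersion (Cox-Reid adjusted profile likelihood)
# ---------------------------------------------------------------------------

def _apl_objective(counts: np.ndarray, eff: np.ndarray, group_cols: dict[int, np.ndarray],
                   phi: float) -> float:
    """Summed Cox-Reid adjusted profile log-likelihood at dispersion phi.

    The adjustment subtracts 0.5*log det(X'WX); in the one-way layout the
    information is diagonal across groups, so det = product of per-group
    weight sums.  Groups with zero total count for a gene carry no
    estimable parameter and are excluded from that gene's adjustment.
    """
    total = 0.0
    for _, cols in group_cols.items():
        y = counts[:, cols]
        a, ll, _ = _fit_abundance(y, eff[cols], phi)
        w = _fisher_weight_sum(a, eff[cols], phi)
        cr = np.where(w > 0, 0.5 * np.log(np.maximum(w, 1e-300)), 0.0)
        total += float(np.sum(ll - cr))
    return total


def _golden_max(f, lo: float, hi: float, tol: float) -> tuple[float, list]:
    """Golden-section search for the maximum of a unimodal f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    trace = []

    def fm(x):
        v = f(x)
        trace.append((x, v))
        return v

    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fm(c), fm(d)
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fm(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fm(d)
    return (a + b) / 2.0, trace


def estimate_common_dispersion(cm: CountMatrix, nf: NormalizationFactors,
                               log10_bounds: tuple[float, float] = (-6.0, 1.0),
                               tol: float = 1e-6) -> DispersionEstimate:
    """Estimate the common NB dispersion by golden-section search on
    log10(phi) over ``log10_bounds``.

    Needs at least one time point with >= 2 replicates; with all-singleton
    groups the profile likelihood carries no dispersion information.
    """
    groups = cm.groups()
    if max(len(c) for c in groups.values()) < 2:
        raise ValueError("dispersion not estimable: all groups are singletons")
    counts = cm.counts.astype(float)
    eff = nf.effective_sizes.astype(float)

    def objective(log10_phi: float) -> float:
        return _apl_objective(counts, eff, groups, 10.0 ** log10_phi)

    best, trace = _golden_max(objective, log10_bounds[0], log10_bounds[1], tol)
    return DispersionEstimate(phi=float(10.0 ** best),
                              trace=[(10.0 ** x, v) for x, v in trace])


# ---------------------------------------------------------------------------
# Pairwise LRT
# ---------------------------------------------------------------------------

def contrast_name(early: int, late: int) -> str:
    return f"{early}v{late}"


def all_contrasts(timepoints: list[int]) -> list[tuple[int, int]]:
    """All (early, late) time-point pairs, early < late."""
    return list(itertools.combinations(sorted(timepoints), 2))


def fit_and_test(cm: CountMatrix, nf: NormalizationFactors, phi: float,
                 contrasts: list[tuple[int, int]] | None = None,
                 fdr_threshold: float = 0.05,
                 prior_count: float = 0.125) -> pd.DataFrame:
    """Likelihood-ratio tests between time-point pairs.

    For each contrast (early, late): full model fits separate abundances in
    the two groups, the reduced model one shared abundance; the LR statistic
    is twice the log-likelihood difference, p from chi-square(1).  log2 fold
    change is oriented late vs early and computed from the fitted
    abundances, each damped by ``prior_count`` pseudo-fragments so that
    all-zero groups give a finite value.  Non-converged genes get p = NA and
    are excluded from the FDR denominator.

    Returns a long frame with columns gene_id, contrast, log2fc, lr_stat,
    p, fdr, significant, direction; FDR is Benjamini-Hochberg within each
    contrast.
    """
    if contrasts is None:
        contrasts = all_contrasts(cm.timepoints)
    groups = cm.groups()
    eff = nf.effective_sizes.astype(float)
    counts = cm.counts.astype(float)

    fits = {}
    for t, cols in groups.items():
        fits[t] = _fit_abundance(counts[:, cols], eff[cols], phi)

    frames = []
    for early, late in contrasts:
        if early not in groups or late not in groups:
            raise ValueError(f"contrast {early}v{late}: time point missing from data")
        a_e, ll_e, conv_e = fits[early]
        a_l, ll_l, conv_l = fits[late]
        cols = np.concatenate([groups[early], groups[late]])
        _, ll_joint, conv_j = _fit_abundance(counts[:, cols], eff[cols], phi)
        lr = np.maximum(2.0 * (ll_e + ll_l - ll_joint), 0.0)
        converged = conv_e & conv_l & conv_j
        p = np.where(converged, chi2.sf(lr, df=1), np.nan)
        delta_e = prior_count / eff[groups[early]].sum()
        delta_l = prior_count / eff[groups[late]].sum()
        log2fc = np.log2(a_l + delta_l) - np.log2(a_e + delta_e)
        n_bad = int((~converged).sum())
        if n_bad:
            logger.warning("contrast %sv%s: %d gene(s) did not converge; p set to NA",
                           early, late, n_bad)
        frames.append(pd.DataFrame({
            "gene_id": cm.gene_ids,
            "contrast": contrast_name(early, late),
            "log2fc": log2fc,
            "lr_stat": lr,
            "p": p,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["fdr"] = np.nan
    for name, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  NA entries pass
    through as NA and do not count towards m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# DEG summaries
# ---------------------------------------------------------------------------

def summarize_degs(results: pd.DataFrame,
                   venn_contrasts: tuple[str, ...] = VENN_CONTRASTS) -> pd.DataFrame:
    """Per-DEG Venn cell over the reported contrasts and overall trend.

    A gene enters the summary if it is significant in any tested contrast.
    ``venn_cell`` is the '+'-joined subset of ``venn_contrasts`` where the
    gene is significant ('none' when it is significant only elsewhere);
    cells partition the DEGs.  ``trend`` looks at every significant
    contrast, oriented late vs early: increasing_only when all fold changes
    are positive, decreasing_only when all negative, else variable.
    """
    sig = results[results["significant"].fillna(False)]
    if sig.empty:
        return pd.DataFrame(columns=["venn_cell", "trend", "n_significant"])
    rows = {}
    for gene, sub in sig.groupby("gene_id", sort=False):
        in_venn = [c for c in venn_contrasts if (sub["contrast"] == c).any()]
        cell = "+".join(in_venn) if in_venn else "none"
        fc = sub["log2fc"].to_numpy()
        if np.all(fc > 0):
            trend = "increasing_only"
        elif np.all(fc < 0):
            trend = "decreasing_only"
        else:
            trend = "variable"
        rows[gene] = (cell, trend, len(sub))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["venn_cell", "trend", "n_significant"])
    out.index.name = "gene_id"
    return out


def deg_gene_sets(results: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """Up/down-regulated gene-id sets per contrast (significant genes only)."""
    out: dict[str, dict[str, set[str]]] = {}
    sig = results[results["significant"].fillna(False)]
    for name, sub in sig.groupby("contrast"):
        out[name] = {
            "up": set(sub.loc[sub["log2fc"] > 0, "gene_id"]),
            "down": set(sub.loc[sub["log2fc"] < 0, "gene_id"]),
        }
    return out
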