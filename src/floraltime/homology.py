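"""Homologue copy-number spectra and duplication enrichment.

Flax is a paleopolyploid: a single Arabidopsis gene typically has several
flax homologues.  This module inverts the flax -> Arabidopsis map to count
copies per Arabidopsis gene, stratifies the spectrum by membership in a
flowering-gene list, and asks whether flowering genes are more often
duplicated than the rest of the genome with a Pearson chi-square test on
the 2x2 {flowering, other} x {single-copy, multi-copy} table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_io import GeneAnnotation

logger = logging.getLogger("floraltime")


@dataclass
class CopyNumberTable:
    """Copy counts per Arabidopsis gene with flowering stratification."""

    table: pd.DataFrame          # index arabidopsis_id; columns copies, flowering
    missing_flowering: list[str]  # flowering-list ids with no flax copy

    def strata_counts(self) -> pd.DataFrame:
        """2x2 counts: rows (flowering, non_flowering), cols (single_copy,
        multi_copy)."""
        t = self.table
        single = t["copies"] == 1
        return pd.DataFrame(
            [[int((t["flowering"] & single).sum()), int((t["flowering"] & ~single).sum())],
             [int((~t["flowering"] & single).sum()), int((~t["flowering"] & ~single).sum())]],
            index=["flowering", "non_flowering"],
            columns=["single_copy", "multi_copy"],
        )

    @property
    def n_flowering_homologues(self) -> int:
        """Total flax flowering-gene homologues, counting copies."""
        return int(self.table.loc[self.table["flowering"], "copies"].sum())


@dataclass
class ContingencyTest:
    observed: np.ndarray
    chi2: float
    df: int
    p: float
    n: int


def copy_number_spectrum(annotation: dict[str, GeneAnnotation],
                         flowering_list: set[str]) -> CopyNumberTable:
    """Invert the flax -> Arabidopsis map into per-Arabidopsis copy counts.

    Flowering-list entries with zero flax copies are reported as missing
    homologues (with a warning) rather than entered in the spectrum.
    """
    pairs = [(a.arabidopsis_homologue,) for a in annotation.values()
             if a.arabidopsis_homologue is not None]
    counts = pd.DataFrame(pairs, columns=["arabidopsis_id"]).groupby("arabidopsis_id").size()
    table = pd.DataFrame({"copies": counts})
    table["flowering"] = table.index.isin(set(flowering_list))
    missing = sorted(set(flowering_list) - set(table.index))
    if missing:
        logger.warning("%d flowering-list gene(s) have no flax homologue (e.g. %s)",
                       len(missing), missing[:5])
    return CopyNumberTable(table=table, missing_flowering=missing)


def duplication_test(table: CopyNumberTable | np.ndarray) -> ContingencyTest:
    """Pearson chi-square (1 df, no continuity correction) for association
    between flowering status and duplication (single vs multi copy)."""
    if isinstance(table, CopyNumberTable):
        obs = table.strata_counts().to_numpy(float)
    else:
        obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")
    if np.allclose(obs[0] / obs[0].sum(), obs[1] / obs[1].sum()):
        # identical row proportions: chi2 exactly 0 (avoids fp fuzz)
        return ContingencyTest(observed=obs, chi2=0.0, df=1, p=1.0, n=int(obs.sum()))
    stat, p, df, _ = chi2_contingency(obs, correction=False)
    return ContingencyTest(observed=obs, chi2=float(stat), df=int(df), p=float(p),
                           n=int(obs.sum()))
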