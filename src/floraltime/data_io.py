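"""Shared data model and tabular I/O.

All inputs and outputs are plain text: tab-separated tables (UTF-8, lines
starting with ``#`` ignored) or MatrixMarket triplets for sparse count
matrices.  The central container is :class:`CountMatrix` — an integer
fragment-count matrix (genes x samples) with per-sample metadata — plus
per-gene annotation records (:class:`GeneAnnotation`) carrying gene length,
the Arabidopsis homologue mapping, flowering-gene and transcription-factor
flags, and GO term assignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("floraltime")

HOMOLOGUE_STATUSES = ("characterized", "unknown_function", "no_homologue")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library: time point (days after planting), replicate
    and experiment identifiers."""

    sample_id: str
    timepoint_dap: int
    replicate: int
    experiment: int = 1

    def __post_init__(self) -> None:
        if self.timepoint_dap <= 0:
            raise ValueError(f"timepoint_dap must be positive, got {self.timepoint_dap}")
        if self.replicate <= 0:
            raise ValueError(f"replicate must be positive, got {self.replicate}")
        if self.experiment <= 0:
            raise ValueError(f"experiment must be positive, got {self.experiment}")


@dataclass
class CountMatrix:
    """Integer fragment counts, genes x samples, with sample metadata.

    Invariants: gene ids unique, counts non-negative integers, one
    :class:`SampleInfo` per column in column order.
    """

    gene_ids: list[str]
    counts: np.ndarray
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        keys = [(s.timepoint_dap, s.experiment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (timepoint, experiment, replicate) in sample sheet")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts != np.round(self.counts)):
                raise ValueError("non-integer count in matrix")
            self.counts = self.counts.astype(np.int64)
        elif not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be numeric")
        if np.any(self.counts < 0):
            raise ValueError("negative count in matrix")
        self.counts = self.counts.astype(np.int64)

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def timepoints(self) -> list[int]:
        """Distinct time points in ascending order."""
        return sorted({s.timepoint_dap for s in self.samples})

    @property
    def library_sizes(self) -> np.ndarray:
        """Total fragments per library (column sums)."""
        return self.counts.sum(axis=0)

    def groups(self) -> dict[int, np.ndarray]:
        """Column indices per time point, ascending."""
        tps = np.array([s.timepoint_dap for s in self.samples])
        return {t: np.flatnonzero(tps == t) for t in self.timepoints}

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            counts=self.counts[keep],
            samples=list(self.samples),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: length, Arabidopsis homologue and its status,
    flowering-gene flag, TF family and GO terms."""

    gene_id: str
    length_bp: int
    arabidopsis_homologue: str | None = None
    homologue_status: str = "no_homologue"
    is_flowering_homologue: bool = False
    tf_family: str | None = None
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"gene {self.gene_id}: length_bp must be >= 1, got {self.length_bp}")
        if self.homologue_status not in HOMOLOGUE_STATUSES:
            raise ValueError(f"gene {self.gene_id}: bad homologue_status {self.homologue_status!r}")
        if (self.homologue_status == "no_homologue") != (self.arabidopsis_homologue is None):
            raise ValueError(
                f"gene {self.gene_id}: homologue_status {self.homologue_status!r} inconsistent "
                f"with arabidopsis_homologue={self.arabidopsis_homologue!r}"
            )
        if self.is_flowering_homologue and self.arabidopsis_homologue is None:
            raise ValueError(f"gene {self.gene_id}: flowering flag without an Arabidopsis homologue")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_sample_sheet(path) -> list[SampleInfo]:
    """Sample sheet TSV with columns sample_id, timepoint_dap, replicate,
    experiment (experiment optional, defaults to 1)."""
    df = _read_tsv(path)
    required = {"sample_id", "timepoint_dap", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(SampleInfo(
            sample_id=str(row["sample_id"]),
            timepoint_dap=int(row["timepoint_dap"]),
            replicate=int(row["replicate"]),
            experiment=int(row["experiment"]) if "experiment" in df.columns else 1,
        ))
    return out


def read_counts(path, samplesheet_path) -> CountMatrix:
    """Read a count matrix plus its sample sheet.

    ``path`` is either a TSV (header row of sample ids, first column gene
    ids) or a MatrixMarket ``.mtx`` file with sibling ``<stem>.rows`` /
    ``<stem>.cols`` index files (one id per line).  Columns are reordered to
    the sample-sheet order; non-integer cells, duplicate gene ids and
    matrix/sheet sample mismatches are hard errors.
    """
    samples = read_sample_sheet(samplesheet_path)
    path = str(path)
    if path.endswith(".mtx"):
        stem = path[: -len(".mtx")]
        with open(stem + ".rows") as fh:
            gene_ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        with open(stem + ".cols") as fh:
            col_ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        df = pd.DataFrame(dense, index=gene_ids, columns=col_ids)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id(s) in count matrix: {dupes[:5]}")
    sheet_ids = [s.sample_id for s in samples]
    missing = [s for s in sheet_ids if s not in df.columns]
    if missing:
        raise ValueError(f"sample(s) in sheet missing from matrix: {missing}")
    extra = [c for c in df.columns if c not in set(sheet_ids)]
    if extra:
        raise ValueError(f"sample(s) in matrix missing from sheet: {extra}")
    df = df[sheet_ids]
    values = df.to_numpy()
    if np.issubdtype(values.dtype, np.object_) or (
        np.issubdtype(values.dtype, np.floating)
        and (np.any(~np.isfinite(values.astype(float)))
             or np.any(values.astype(float) != np.round(values.astype(float))))
    ):
        raise ValueError("non-integer count in matrix")
    return CountMatrix(gene_ids=list(df.index.astype(str)), counts=values, samples=samples)


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix as TSV (inverse of the TSV branch of
    :func:`read_counts`)."""
    cm.to_frame().to_csv(path, sep="\t")


def write_sample_sheet(samples: list[SampleInfo], path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.timepoint_dap, s.replicate, s.experiment) for s in samples],
        columns=["sample_id", "timepoint_dap", "replicate", "experiment"],
    ).to_csv(path, sep="\t", index=False)


def read_annotation(
    lengths_path,
    homologue_path=None,
    flowering_path=None,
    tf_path=None,
    go_path=None,
) -> dict[str, GeneAnnotation]:
    """Assemble one :class:`GeneAnnotation` per gene in the lengths table.

    * lengths TSV: ``gene_id <tab> length_bp`` (required; defines the gene
      universe).
    * homologue TSV: ``flax_id <tab> arabidopsis_id <tab> status`` with
      status in {characterized, unknown_function}.  Genes absent from it get
      ``no_homologue``.
    * flowering TSV: one Arabidopsis id per line (first column); flax genes
      whose homologue is listed are flagged.
    * tf TSV: ``gene_id <tab> family``.
    * go TSV: ``gene_id <tab> go_id`` (one pair per line).

    Missing optional files yield empty annotation sets with a warning.
    """
    lengths = _read_tsv(lengths_path, header=0)
    if lengths.shape[1] < 2:
        raise ValueError("lengths TSV needs columns gene_id, length_bp")
    lengths.columns = ["gene_id", "length_bp", *lengths.columns[2:]]

    homologue: dict[str, tuple[str, str]] = {}
    if homologue_path is not None:
        hdf = _read_tsv(homologue_path, header=0)
        hdf.columns = ["flax_id", "arabidopsis_id", "status", *hdf.columns[3:]]
        for _, row in hdf.iterrows():
            status = str(row["status"])
            if status not in ("characterized", "unknown_function"):
                raise ValueError(f"homologue table: bad status {status!r} for {row['flax_id']}")
            homologue[str(row["flax_id"])] = (str(row["arabidopsis_id"]), status)
    else:
        logger.warning("no homologue table given; all genes treated as no_homologue")

    flowering_at: set[str] = set()
    if flowering_path is not None:
        flowering_at = set(_read_tsv(flowering_path, header=None)[0].astype(str))
    else:
        logger.warning("no flowering-gene list given; flowering flags all False")

    tf_family: dict[str, str] = {}
    if tf_path is not None:
        tdf = _read_tsv(tf_path, header=0)
        tdf.columns = ["gene_id", "family", *tdf.columns[2:]]
        tf_family = dict(zip(tdf["gene_id"].astype(str), tdf["family"].astype(str)))
    else:
        logger.warning("no TF-family table given; TF annotations empty")

    go_terms: dict[str, set[str]] = {}
    if go_path is not None:
        gdf = _read_tsv(go_path, header=0)
        gdf.columns = ["gene_id", "go_id", *gdf.columns[2:]]
        for g, t in zip(gdf["gene_id"].astype(str), gdf["go_id"].astype(str)):
            go_terms.setdefault(g, set()).add(t)
    else:
        logger.warning("no GO table given; GO annotations empty")

    out: dict[str, GeneAnnotation] = {}
    for _, row in lengths.iterrows():
        gid = str(row["gene_id"])
        length = int(row["length_bp"])
        if length <= 0:
            raise ValueError(f"gene {gid}: non-positive length {length}")
        at_id, status = homologue.get(gid, (None, "no_homologue"))
        out[gid] = GeneAnnotation(
            gene_id=gid,
            length_bp=length,
            arabidopsis_homologue=at_id,
            homologue_status=status,
            is_flowering_homologue=at_id is not None and at_id in flowering_at,
            tf_family=tf_family.get(gid),
            go_terms=frozenset(go_terms.get(gid, ())),
        )
    return out
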