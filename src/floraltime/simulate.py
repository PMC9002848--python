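"""Synthetic SAM time-course generator with planted structure.

Emulates a 4-time-point (10/15/19/29 dap) replicated bulk RNA-seq count
matrix with the gene classes the pipeline is built to separate:

* housekeeping — expressed at a constant level at all time points;
* increasing / decreasing — monotone log-linear trajectories (the planted
  "flowering" signal, in roughly the 2:1 up:down ratio seen in flowering
  DEG clusters);
* timepoint_restricted — expressed at a single time point;
* unexpressed — background below the RPKM call threshold;
* candidate_tracker — uncharacterized genes whose trajectory copies a
  trend template plus small log-normal jitter (the planted novel
  candidates).

Counts are NB(mu, phi) draws with mu = expected CPM x library size / 1e6;
library sizes are log-uniform so TMM factors are exercised.  Annotation
tables (lengths, homologue map with copy-number structure, flowering list,
TF families with one DEG-enriched family, GO terms with one term enriched
among increasing genes) are emitted together with a per-gene truth table.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountMatrix, GeneAnnotation, SampleInfo

TIMEPOINTS = (10, 15, 19, 29)

GENE_CLASSES = ("housekeeping", "increasing", "decreasing",
                "timepoint_restricted", "unexpressed", "candidate_tracker")

DEFAULT_PROPORTIONS = {
    "housekeeping": 0.50,
    "increasing": 0.08,
    "decreasing": 0.04,
    "timepoint_restricted": 0.05,
    "unexpressed": 0.28,
    "candidate_tracker": 0.05,
}

TF_FAMILIES = ("MADS", "SBP", "AP2", "MYB", "bHLH", "WRKY", "NAC", "GRF")
PLANTED_TF_FAMILY = "MADS"
PLANTED_GO_TERM = "GO:0009908"  # flower development; planted in increasing genes


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a realistic small study."""

    n_genes: int = 5000
    timepoints: tuple[int, ...] = TIMEPOINTS
    replicates: int = 3
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    base_cpm_logmean: float = 3.0       # ln scale of relative abundance (rescaled to CPM)
    base_cpm_logsd: float = 1.6
    phi: float = 0.05                   # NB dispersion of biological replicates
    trend_log2fc: float = 2.0           # total log2 change, first to last time point
    tracker_jitter_sd: float = 0.05     # log2 jitter around the trend template
    library_size_range: tuple[float, float] = (8e6, 1.5e7)
    length_logmean: float = 7.2         # ln bp; ~1300 bp median transcript
    length_logsd: float = 0.5
    min_length_bp: int = 300
    homologue_rate: float = 0.7         # genes with an Arabidopsis homologue
    unknown_function_rate: float = 0.4  # of homologues (trackers always uncharacterized)
    flowering_rate: float = 0.6         # of characterized trend-class homologues
    tf_family_size: int = 40
    go_background_terms: int = 30
    composition_bias: bool = False      # spike 5% of genes in sample 1 (TMM stressor)
    seed: int = 0

    def validate(self) -> None:
        if set(self.proportions) != set(GENE_CLASSES):
            raise ValueError(f"proportions must cover exactly {GENE_CLASSES}")
        vals = np.array(list(self.proportions.values()))
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError("class proportions must be non-negative and sum to 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per time point")
        if self.n_genes < 100:
            raise ValueError("n_genes too small for a meaningful study")


@dataclass
class SimulatedStudy:
    """Everything :func:`simulate` produces."""

    counts: CountMatrix
    annotation: dict[str, GeneAnnotation]
    tables: dict[str, pd.DataFrame]   # the annotation TSV payloads
    truth: pd.DataFrame               # per-gene class labels / planted flags
    config: SimulationConfig


def _class_sizes(cfg: SimulationConfig) -> dict[str, int]:
    sizes = {c: int(np.floor(cfg.proportions[c] * cfg.n_genes)) for c in GENE_CLASSES}
    # distribute rounding remainder to the largest classes, deterministically
    rest = cfg.n_genes - sum(sizes.values())
    for c in sorted(GENE_CLASSES, key=lambda c: -cfg.proportions[c]):
        if rest == 0:
            break
        sizes[c] += 1
        rest -= 1
    return sizes


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Draw one synthetic study (counts + annotation + truth) from ``cfg``."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_tp = len(cfg.timepoints)
    sizes = _class_sizes(cfg)
    classes = np.repeat(list(sizes.keys()), list(sizes.values()))
    rng.shuffle(classes)
    gene_ids = [f"Lus{i:08d}.g" for i in range(1, cfg.n_genes + 1)]

    # --- expected CPM trajectories -------------------------------------
    base = np.exp(rng.normal(cfg.base_cpm_logmean, cfg.base_cpm_logsd, cfg.n_genes)) + 2.0
    frac = np.arange(n_tp) / (n_tp - 1)
    cpm = np.empty((cfg.n_genes, n_tp))
    tracker_template = np.empty(cfg.n_genes, dtype=object)
    for i, cls in enumerate(classes):
        b = base[i]
        if cls == "housekeeping":
            cpm[i] = b
        elif cls == "increasing":
            cpm[i] = b * 2.0 ** (cfg.trend_log2fc * frac)
        elif cls == "decreasing":
            cpm[i] = b * 2.0 ** (-cfg.trend_log2fc * frac)
        elif cls == "timepoint_restricted":
            cpm[i] = 0.02
            cpm[i, rng.integers(n_tp)] = b
        elif cls == "unexpressed":
            cpm[i] = 0.005
        else:  # candidate_tracker: trend template + log2 jitter
            up = rng.random() < 0.687  # ~2:1, like the opposing trend clusters
            sign = 1.0 if up else -1.0
            tracker_template[i] = "increasing" if up else "decreasing"
            jitter = rng.normal(0.0, cfg.tracker_jitter_sd, n_tp)
            cpm[i] = b * 2.0 ** (sign * cfg.trend_log2fc * frac + jitter)

    # CPM is a relative unit: rescale so the expected per-library total is
    # 1e6, i.e. the simulated panel behaves as a whole (small) transcriptome
    cpm *= 1e6 / cpm.sum(axis=0).mean()

    # --- libraries and counts ------------------------------------------
    n_samples = n_tp * cfg.replicates
    lo, hi = cfg.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))
    samples = [SampleInfo(sample_id=f"T{t}_R{r}", timepoint_dap=t, replicate=r)
               for t in cfg.timepoints for r in range(1, cfg.replicates + 1)]
    cpm_sample = np.repeat(cpm, cfg.replicates, axis=1)
    if cfg.composition_bias:
        spike = rng.random(cfg.n_genes) < 0.05
        cpm_sample[spike, 0] *= 8.0
    mu = cpm_sample * lib[None, :] / 1e6
    counts = _nb_draw(rng, mu, cfg.phi).astype(np.int64)
    cm = CountMatrix(gene_ids=gene_ids, counts=counts, samples=samples)

    # --- gene lengths ---------------------------------------------------
    lengths = np.maximum(
        np.round(np.exp(rng.normal(cfg.length_logmean, cfg.length_logsd, cfg.n_genes))),
        cfg.min_length_bp,
    ).astype(int)

    # --- homologue map with copy-number structure ----------------------
    # Walk the (shuffled) genes with a homologue, grouping consecutive runs
    # under one Arabidopsis id so copy numbers follow a duplication-rich
    # spectrum.  Trend (planted flowering) genes always have a
    # characterized homologue; trackers are always uncharacterized and
    # group only with each other, so the uncharacterized DEG pool has clean
    # planted semantics.
    trend = np.isin(classes, ["increasing", "decreasing"])
    is_tracker = classes == "candidate_tracker"
    has_hom = rng.random(cfg.n_genes) < cfg.homologue_rate
    has_hom[trend] = True
    has_hom[is_tracker] = rng.random(int(is_tracker.sum())) < 0.5
    copy_choices = np.array([1, 2, 3, 4, 5])
    copy_probs = np.array([0.20, 0.45, 0.20, 0.10, 0.05])
    arabidopsis_of = np.empty(cfg.n_genes, dtype=object)
    at_counter = 0
    for pool_mask in (has_hom & ~is_tracker, has_hom & is_tracker):
        hom_idx = np.flatnonzero(pool_mask)
        rng.shuffle(hom_idx)
        pos = 0
        while pos < len(hom_idx):
            c = int(rng.choice(copy_choices, p=copy_probs))
            at_counter += 1
            at_id = f"AT{at_counter:07d}"
            for j in hom_idx[pos:pos + c]:
                arabidopsis_of[j] = at_id
            pos += c

    status = np.empty(cfg.n_genes, dtype=object)
    for i in range(cfg.n_genes):
        if arabidopsis_of[i] is None:
            status[i] = "no_homologue"
        elif is_tracker[i]:
            status[i] = "unknown_function"
        elif trend[i]:
            status[i] = "characterized"
        else:
            status[i] = ("unknown_function" if rng.random() < cfg.unknown_function_rate
                         else "characterized")
    # an Arabidopsis gene's copies must share a status; harmonize by group,
    # with characterized winning when a group mixes (trend genes stay known)
    at_series = pd.Series(arabidopsis_of)
    for at_id, idx in at_series.groupby(at_series).groups.items():
        idx = np.asarray(idx)
        if (status[idx] == "characterized").any():
            status[idx] = "characterized"
        else:
            status[idx] = status[idx[0]]

    # --- flowering list -------------------------------------------------
    flowering_at: set[str] = set()
    for at_id, idx in at_series.groupby(at_series).groups.items():
        idx = np.asarray(idx)
        if status[idx[0]] != "characterized":
            continue
        if trend[idx].any() and rng.random() < cfg.flowering_rate:
            flowering_at.add(str(at_id))
    # a few list entries with no flax homologue at all (exercises reporting)
    missing_flowering = [f"AT{at_counter + i + 1:07d}" for i in range(10)]
    flowering_list = sorted(flowering_at) + missing_flowering

    # --- TF families: one family enriched in trend (DE) classes --------
    tf_family = np.empty(cfg.n_genes, dtype=object)
    expressed_like = np.flatnonzero(np.isin(classes, ["housekeeping", "increasing",
                                                      "decreasing"]))
    trend_idx = np.flatnonzero(trend)
    hk_idx = np.flatnonzero(classes == "housekeeping")
    n_from_trend = int(0.7 * cfg.tf_family_size)
    planted = np.concatenate([
        rng.choice(trend_idx, size=min(n_from_trend, len(trend_idx)), replace=False),
        rng.choice(hk_idx, size=cfg.tf_family_size - min(n_from_trend, len(trend_idx)),
                   replace=False),
    ])
    tf_family[planted] = PLANTED_TF_FAMILY
    pool = np.setdiff1d(expressed_like, planted)
    rng.shuffle(pool)
    pos = 0
    for fam in TF_FAMILIES:
        if fam == PLANTED_TF_FAMILY:
            continue
        take = pool[pos:pos + cfg.tf_family_size]
        tf_family[take] = fam
        pos += cfg.tf_family_size

    # --- GO terms: background Poisson(2) + one planted term ------------
    go_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    bg_terms = [f"GO:{7000000 + i}" for i in range(cfg.go_background_terms)]
    n_bg = rng.poisson(2.0, cfg.n_genes)
    for i, g in enumerate(gene_ids):
        if n_bg[i] > 0:
            for t in rng.choice(bg_terms, size=min(n_bg[i], len(bg_terms)), replace=False):
                go_terms[g].add(str(t))
    inc = classes == "increasing"
    planted_go = (rng.random(cfg.n_genes) < 0.02) | (inc & (rng.random(cfg.n_genes) < 0.6))
    for i in np.flatnonzero(planted_go):
        go_terms[gene_ids[i]].add(PLANTED_GO_TERM)

    # --- assemble annotation & tables ----------------------------------
    annotation: dict[str, GeneAnnotation] = {}
    for i, g in enumerate(gene_ids):
        at_id = arabidopsis_of[i]
        annotation[g] = GeneAnnotation(
            gene_id=g,
            length_bp=int(lengths[i]),
            arabidopsis_homologue=None if at_id is None else str(at_id),
            homologue_status=str(status[i]),
            is_flowering_homologue=at_id is not None and str(at_id) in flowering_at,
            tf_family=None if tf_family[i] is None else str(tf_family[i]),
            go_terms=frozenset(go_terms[g]),
        )

    tables = {
        "lengths": pd.DataFrame({"gene_id": gene_ids, "length_bp": lengths}),
        "homologues": pd.DataFrame(
            [(g, str(arabidopsis_of[i]), str(status[i]))
             for i, g in enumerate(gene_ids) if arabidopsis_of[i] is not None],
            columns=["flax_id", "arabidopsis_id", "status"]),
        "flowering": pd.DataFrame({"arabidopsis_id": flowering_list}),
        "tf_families": pd.DataFrame(
            [(g, str(tf_family[i])) for i, g in enumerate(gene_ids)
             if tf_family[i] is not None],
            columns=["gene_id", "family"]),
        "go_terms": pd.DataFrame(
            [(g, t) for g in gene_ids for t in sorted(go_terms[g])],
            columns=["gene_id", "go_id"]),
    }

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": classes,
        "is_planted_candidate": classes == "candidate_tracker",
        "tracker_template": [tracker_template[i] if classes[i] == "candidate_tracker"
                             else "" for i in range(cfg.n_genes)],
        "tf_family": ["" if tf_family[i] is None else str(tf_family[i])
                      for i in range(cfg.n_genes)],
        "planted_tf_family": PLANTED_TF_FAMILY,
        "planted_go_term": PLANTED_GO_TERM,
        **{f"true_cpm_{t}": cpm[:, j] for j, t in enumerate(cfg.timepoints)},
    }).set_index("gene_id")

    return SimulatedStudy(counts=cm, annotation=annotation, tables=tables,
                          truth=truth, config=cfg)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write the study as the TSVs the readers consume; returns the paths."""
    from pathlib import Path

    from .data_io import write_counts, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["counts"] = str(outdir / "counts.tsv")
    write_counts(study.counts, paths["counts"])
    paths["samples"] = str(outdir / "samples.tsv")
    write_sample_sheet(study.counts.samples, paths["samples"])
    for name, df in study.tables.items():
        p = outdir / f"{name}.tsv"
        header = name != "flowering"  # flowering list: bare ids, one per line
        df.to_csv(p, sep="\t", index=False, header=header)
        paths[name] = str(p)
    paths["truth"] = str(outdir / "truth.tsv")
    study.truth.to_csv(paths["truth"], sep="\t")
    return paths
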