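"""Genotype quality control.

Three concerns live here:

* locus/sample filtering (missingness, then minor allele frequency) on the
  dosage matrix;
* scoring competing SNP-calling parameter sets by how tightly technical
  replicates cluster in an ordination of genotype (Hamming) distances — the
  best parameter set is the one whose replicates nearly coincide, with a
  more-SNPs tie-break among near-equal scores;
* the read-fraction ploidy diagnostic: in an autotetraploid, heterozygous
  calls draw alternate-read fractions around 0.25, 0.5 and 0.75 instead of
  only 0.5, so the fraction of heterozygous-call mass sitting in the
  0.25/0.75 windows indexes tetrasomic behavior.

Upstream caller-side filters (one SNP per tag, genotype-likelihood and
haplotype pruning) are assumed already applied to the inputs; the filter
report records that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, LandgenError, ValidationError
from .synthetic_landscape import ReadDepthTable

__all__ = [
    "FilterConfig",
    "ReplicateScore",
    "PloidyReport",
    "filter_genotypes",
    "hamming_distance_matrix",
    "classical_mds",
    "score_parameter_sets",
    "ploidy_diagnostic",
    "classify_ploidy",
]


@dataclass
class FilterConfig:
    """Locus/sample filter thresholds (fractions in [0, 1])."""

    max_locus_missing: float = 0.30
    min_maf: float = 0.05
    max_sample_missing: float = 1.0  # 1.0 disables the sample filter

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "min_maf", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise LandgenError(f"{name} must be in [0, 1]")


def filter_genotypes(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Apply missingness then MAF filters; return kept matrix and a report.

    Loci with missing fraction strictly above ``max_locus_missing`` go
    first; MAF is then computed on non-missing calls of the surviving loci
    and loci with MAF strictly below ``min_maf`` are dropped (a locus at
    exactly the threshold is kept).  Applying the same filters twice is a
    no-op.
    """
    cfg = cfg or FilterConfig()
    d = gm.dosage
    n = gm.n_samples

    miss_frac = np.isnan(d).mean(axis=0)
    keep_missing = miss_frac <= cfg.max_locus_missing
    removed_missing = int((~keep_missing).sum())

    keep_samples = np.ones(n, dtype=bool)
    removed_samples = 0
    if cfg.max_sample_missing < 1.0:
        smiss = np.isnan(d[:, keep_missing]).mean(axis=1)
        keep_samples = smiss <= cfg.max_sample_missing
        removed_samples = int((~keep_samples).sum())
        if not keep_samples.any():
            raise LandgenError("sample missingness filter removed every sample")

    sub = d[np.ix_(keep_samples, keep_missing)]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(sub, axis=0)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = ~np.isnan(maf) & (maf >= cfg.min_maf)
    removed_maf = int((~keep_maf).sum())

    keep_loci = np.flatnonzero(keep_missing)[keep_maf]
    report = {
        "n_input_loci": gm.n_loci,
        "n_input_samples": gm.n_samples,
        "removed_locus_missingness": removed_missing,
        "removed_sample_missingness": removed_samples,
        "removed_maf": removed_maf,
        "n_output_loci": int(len(keep_loci)),
        "n_output_samples": int(keep_samples.sum()),
        "upstream_caller_filters": "assumed applied (one SNP per tag, "
        "likelihood and haplotype pruning)",
    }
    if len(keep_loci) == 0:
        raise LandgenError(f"all loci removed by filters; attrition: {report}")
    out = gm.subset(samples=np.flatnonzero(keep_samples), loci=keep_loci)
    return out, report


# ---------------------------------------------------------------------------
# Replicate-concordance scoring of SNP-calling parameter sets
# ---------------------------------------------------------------------------


@dataclass
class ReplicateScore:
    parameter_set_id: str
    n_snps: int
    score: float
    n_ordination_dims: int = 2


def hamming_distance_matrix(gm: GenotypeMatrix, sample_ids=None) -> np.ndarray:
    """Pairwise dosage-aware Hamming distance, normalized per pair.

    Per shared non-missing locus the contribution is |d_i - d_j|, so a
    hom/het mismatch counts 0.5 and a hom/hom mismatch 1.
    """
    idx = (
        np.arange(gm.n_samples)
        if sample_ids is None
        else gm.sample_index(sample_ids)
    )
    d = gm.dosage[idx]
    n = len(idx)
    ok = np.isfinite(d)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            ns = int(shared.sum())
            if ns == 0:
                ids = [gm.sample_ids[idx[i]], gm.sample_ids[idx[j]]]
                raise LandgenError(f"no shared non-missing loci for pair {ids}")
            dist[i, j] = dist[j, i] = np.abs(d[i, shared] - d[j, shared]).sum() / ns
    return dist


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson MDS: eigen-decomposition of the double-centered squared
    distances; coordinates scaled by sqrt of (non-negative) eigenvalues."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def score_parameter_sets(
    call_sets: dict[str, GenotypeMatrix],
    rep_map: dict[str, list[str]],
    k: int = 2,
    epsilon_frac: float = 0.10,
) -> list[ReplicateScore]:
    """Rank parameter sets by replicate concordance in ordination space.

    Score = (mean pairwise distance among replicates of the same source)
    / (mean pairwise distance between replicates of different sources),
    computed on a classical-MDS embedding of dosage Hamming distances.
    Ranking is ascending; among call sets whose scores are within
    ``epsilon_frac`` of the minimum, the one with the most SNPs wins.
    """
    if k < 2:
        raise LandgenError("ordination dimension k must be >= 2")
    all_reps = [r for reps in rep_map.values() for r in reps]
    scores: list[ReplicateScore] = []
    for ps_id, gm in call_sets.items():
        missing = set(all_reps) - set(gm.sample_ids)
        if missing:
            raise ValidationError(
                f"call set {ps_id!r} lacks replicate samples {sorted(missing)[:5]}"
            )
        dist = hamming_distance_matrix(gm, all_reps)
        coords = classical_mds(dist, k=k)
        pos = {r: i for i, r in enumerate(all_reps)}
        source_of = {r: s for s, reps in rep_map.items() for r in reps}
        within, between = [], []
        for i, ri in enumerate(all_reps):
            for rj in all_reps[i + 1 :]:
                dd = float(np.linalg.norm(coords[pos[ri]] - coords[pos[rj]]))
                (within if source_of[ri] == source_of[rj] else between).append(dd)
        mb = float(np.mean(between)) if between else np.nan
        mw = float(np.mean(within)) if within else 0.0
        # replicates that coincide up to eigen-solver noise score exactly 0
        score = 0.0 if mw <= 1e-12 * max(mb, 1.0) else mw / mb
        scores.append(ReplicateScore(ps_id, gm.n_loci, score, k))
    smin = min(s.score for s in scores)
    eps = epsilon_frac * smin
    # near-minimal sets first (most SNPs breaking the tie), then by score
    def key(s: ReplicateScore):
        near = s.score <= smin + eps
        return (0 if near else 1, -s.n_snps if near else 0, s.score)

    return sorted(scores, key=key)


# ---------------------------------------------------------------------------
# Ploidy diagnostic
# ---------------------------------------------------------------------------


@dataclass
class PloidyReport:
    """Per-individual heterozygote read-fraction summary.

    ``table`` columns: n_eligible_loci, n_het_calls, m25, m50, m75,
    tetraploid_index, flagged.  ``histograms`` maps sample id to the
    bin-width-0.02 histogram of alternate-read fractions.
    """

    table: pd.DataFrame
    histograms: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    bin_width: float = 0.02


def ploidy_diagnostic(
    reads: ReadDepthTable,
    min_depth: int = 60,
    min_loci: int = 1000,
    mode: str = "het_only",
    bin_width: float = 0.02,
    het_window: tuple[float, float] = (0.05, 0.95),
) -> PloidyReport:
    """Summarize alternate-read fractions at high-coverage heterozygous calls.

    Eligible loci have depth >= ``min_depth``; heterozygous calls are
    eligible loci whose alt fraction lies strictly inside ``het_window``.
    Window masses m25/m50/m75 are the fractions of heterozygous-call mass
    in [0.20, 0.30], [0.45, 0.55] and [0.70, 0.80]; the tetraploid index is
    (m25 + m75) / (m25 + m50 + m75).  Individuals with fewer than
    ``min_loci`` eligible loci are flagged and not scored.
    """
    if mode not in ("het_only", "all"):
        raise LandgenError(f"unknown mode {mode!r}")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    rows = []
    hists: dict[str, np.ndarray] = {}
    for i, sid in enumerate(reads.sample_ids):
        tot = reads.total[i]
        alt = reads.alt[i]
        eligible = tot >= min_depth
        n_eligible = int(eligible.sum())
        frac = alt[eligible] / tot[eligible]
        het = (frac > het_window[0]) & (frac < het_window[1])
        plot_frac = frac[het] if mode == "het_only" else frac
        hists[sid] = np.histogram(plot_frac, bins=edges)[0]
        hfrac = frac[het]
        n_het = int(het.sum())
        flagged = n_eligible < min_loci
        if flagged or n_het == 0:
            m25 = m50 = m75 = ti = np.nan
        else:
            m25 = float(((hfrac >= 0.20) & (hfrac <= 0.30)).mean())
            m50 = float(((hfrac >= 0.45) & (hfrac <= 0.55)).mean())
            m75 = float(((hfrac >= 0.70) & (hfrac <= 0.80)).mean())
            denom = m25 + m50 + m75
            ti = (m25 + m75) / denom if denom > 0 else np.nan
        rows.append(
            {
                "sample_id": sid,
                "n_eligible_loci": n_eligible,
                "n_het_calls": n_het,
                "m25": m25,
                "m50": m50,
                "m75": m75,
                "tetraploid_index": ti,
                "flagged": flagged,
            }
        )
    return PloidyReport(pd.DataFrame(rows).set_index("sample_id"), hists, bin_width)


def classify_ploidy(report: PloidyReport, threshold: float = 0.3) -> pd.Series:
    """Call autotetraploid when the tetraploid index exceeds ``threshold``.

    The default threshold sits in the wide gap between the index values the
    read simulator produces for diploid (~0) and tetrasomic (~0.5+)
    individuals at 60x depth; flagged individuals get "unscored".
    """
    t = report.table

    def call(row):
        if row["flagged"] or not np.isfinite(row["tetraploid_index"]):
            return "unscored"
        return (
            "autotetraploid" if row["tetraploid_index"] > threshold else "diploid"
        )

    return t.apply(call, axis=1)
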