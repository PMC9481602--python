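"""Label-free AE-MS interactome statistics.

Implements the standard affinity-enrichment workflow for MaxQuant-style
protein-group tables: decoy/contaminant filtering, log2 transform,
valid-value filtering, left-censored (downshifted-normal) imputation, a
variance-moderated one-way ANOVA with permutation-based FDR, z-scoring,
per-bait median profiles, correlation clustering, and bait-bait
correlation.  The moderated statistic is SAM-style,

    d = sqrt(MS_between) / (sqrt(MS_within) + s0),

where the constant s0 penalizes proteins whose apparent enrichment rests
on an implausibly small within-group variance.  Also included are two
small targeted-MS ratios: PRM normalization against a reference peptide
and the deacetylated fraction from intact-protein peak areas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import PeakFormatError, ValidationError

__all__ = [
    "LFQMatrix",
    "ImputeConfig",
    "AnovaConfig",
    "AnovaResult",
    "ClusterOutput",
    "load_and_filter_lfq",
    "impute_missing",
    "anova_s0",
    "profile_and_cluster",
    "bait_correlation",
    "prm_normalize",
    "deacetylation_fraction",
]


@dataclass
class LFQMatrix:
    """Protein × sample log2 intensities with bait-group column labels.

    ``values`` is a DataFrame (rows: protein ids, columns: sample names)
    with NaN as the explicit missing marker; ``groups`` maps each sample
    column to its bait label.
    """

    values: pd.DataFrame
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValidationError(f"columns without a bait group: {sorted(missing)}")

    @property
    def baits(self) -> List[str]:
        seen: List[str] = []
        for col in self.values.columns:
            g = self.groups[col]
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, bait: str) -> List[str]:
        return [c for c in self.values.columns if self.groups[c] == bait]


@dataclass(frozen=True)
class ImputeConfig:
    """Downshifted-normal imputation parameters (Perseus-style semantics).

    Missing entries of a sample column with observed mean μ and SD σ are
    drawn from Normal(μ − shift·σ, (width·σ)²): values just below the
    detection limit.
    """

    width: float = 0.3
    shift: float = 1.2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.shift < 0:
            raise ValidationError("width > 0 and shift >= 0 required")


@dataclass(frozen=True)
class AnovaConfig:
    """Moderated-ANOVA parameters."""

    s0: float = 4.0
    fdr_target: float = 0.002
    n_permutations: int = 250
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")
        if not 0 < self.fdr_target < 1:
            raise ValidationError("fdr_target must be in (0, 1)")


@dataclass
class AnovaResult:
    """Per-protein moderated statistic, q-value and significance flag."""

    d: pd.Series
    q: pd.Series
    significant: pd.Series  # boolean

    def significant_proteins(self) -> List[str]:
        return list(self.significant.index[self.significant])


@dataclass
class ClusterOutput:
    """Clustered z-scored profiles of the significant proteins."""

    zscores: pd.DataFrame  # significant proteins × samples
    bait_medians: pd.DataFrame  # significant proteins × baits
    cluster_ids: pd.Series  # protein -> cluster id (tree cut)
    linkage: Optional[np.ndarray]
    leaf_order: List[str]
    degenerate: bool = False


# ----------------------------------------------------------------- loading

_REVERSE_COL = "Reverse"
_CONTAMINANT_COL = "Potential contaminant"
_SITE_COL = "Only identified by site"
_LFQ_PREFIX = "LFQ intensity "
_ID_COL = "Protein IDs"


def load_and_filter_lfq(
    table: str | Path | pd.DataFrame,
    groups: Dict[str, str],
    min_valid: int = 6,
    n_replicates: int = 8,
    require_all_groups: bool = False,
    drop_site_only: bool = True,
) -> LFQMatrix:
    """Load a MaxQuant-style proteinGroups table and apply the stated filters.

    Steps: drop reverse (decoy) and contaminant rows (and, when the column
    is present and ``drop_site_only``, site-only identifications); log2
    transform LFQ intensities with 0 treated as missing; keep a protein iff
    it has at least ``min_valid`` observed values among the
    ``n_replicates`` runs of at least one bait group (or of every group
    with ``require_all_groups``).

    ``groups`` maps sample names (the part after ``LFQ intensity ``) to
    bait labels.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t")
    else:
        df = table.copy()
    for col in (_REVERSE_COL, _CONTAMINANT_COL):
        if col not in df.columns:
            raise PeakFormatError(f"missing marker column {col!r}")
    if _ID_COL not in df.columns:
        raise PeakFormatError(f"missing identifier column {_ID_COL!r}")

    keep = ~(df[_REVERSE_COL].fillna("").astype(str).str.strip() == "+")
    keep &= ~(df[_CONTAMINANT_COL].fillna("").astype(str).str.strip() == "+")
    if drop_site_only and _SITE_COL in df.columns:
        keep &= ~(df[_SITE_COL].fillna("").astype(str).str.strip() == "+")
    df = df[keep]

    sample_cols = {}
    for sample in groups:
        col = _LFQ_PREFIX + sample
        if col not in df.columns:
            raise PeakFormatError(f"missing intensity column {col!r}")
        sample_cols[sample] = col

    raw = df[[sample_cols[s] for s in groups]].astype(float)
    raw.columns = list(groups)
    raw.index = df[_ID_COL].astype(str)
    with np.errstate(divide="ignore"):
        log2 = np.log2(raw.where(raw > 0))

    matrix = LFQMatrix(values=log2, groups=dict(groups))
    counts = []
    for bait in matrix.baits:
        cols = matrix.group_columns(bait)
        if len(cols) != n_replicates:
            raise ValidationError(
                f"bait {bait!r} has {len(cols)} runs, expected {n_replicates}"
            )
        counts.append(log2[cols].notna().sum(axis=1) >= min_valid)
    ok = pd.concat(counts, axis=1)
    row_keep = ok.all(axis=1) if require_all_groups else ok.any(axis=1)
    matrix.values = log2[row_keep]
    return matrix


# --------------------------------------------------------------- imputation

def impute_missing(m: LFQMatrix, cfg: ImputeConfig = ImputeConfig()) -> LFQMatrix:
    """Impute missing entries from a per-column downshifted normal.

    Observed values are never altered; identical seeds give identical
    matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    out = m.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 2:
            raise ValidationError(f"column {col!r} has < 2 observed values")
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        mu = observed.mean()
        sigma = observed.std(ddof=1)
        draws = rng.normal(mu - cfg.shift * sigma, cfg.width * sigma, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return LFQMatrix(values=out, groups=dict(m.groups))


# ------------------------------------------------------------------- ANOVA

def _moderated_d(values: np.ndarray, group_index: List[np.ndarray], s0: float) -> np.ndarray:
    """Row-wise d = sqrt(MS_between) / (sqrt(MS_within) + s0)."""
    grand = values.mean(axis=1)
    n_total = values.shape[1]
    k = len(group_index)
    ss_between = np.zeros(len(values))
    ss_within = np.zeros(len(values))
    for idx in group_index:
        sub = values[:, idx]
        gmean = sub.mean(axis=1)
        ss_between += len(idx) * (gmean - grand) ** 2
        ss_within += ((sub - gmean[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(ms_between) / (np.sqrt(ms_within) + s0)
    return d


def _label_permutations(
    labels: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Column permutations of the group labels; enumerated completely for
    two balanced groups when that is cheaper than random sampling."""
    uniq = np.unique(labels)
    n = len(labels)
    if len(uniq) == 2:
        n1 = int((labels == uniq[0]).sum())
        total = math.comb(n, n1)
        if total <= n_permutations:
            perms = []
            for combo in itertools.combinations(range(n), n1):
                order = list(combo) + [i for i in range(n) if i not in set(combo)]
                perms.append(np.array(order))
            return perms
    return [rng.permutation(n) for _ in range(n_permutations)]


def anova_s0(m: LFQMatrix, cfg: AnovaConfig = AnovaConfig()) -> AnovaResult:
    """Variance-moderated one-way ANOVA with permutation FDR.

    Per protein, d = sqrt(MS_between)/(sqrt(MS_within)+s0).  q-values are
    estimated by permuting the sample labels: for each observed d*,
    q(d*) = E_perm[#{d_perm >= d*}] / #{d_obs >= d*}, made monotone
    non-increasing in d and clipped to [0, 1].  A protein is significant
    iff q <= fdr_target.  With s0 = 0 and a zero within-group variance the
    statistic is infinite and flagged (returned as inf).
    """
    values = m.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("anova_s0 requires a complete (imputed) matrix")
    baits = m.baits
    if len(baits) < 2:
        raise ValidationError("need >= 2 bait groups")
    cols = list(m.values.columns)
    labels = np.array([m.groups[c] for c in cols])
    group_index = [
        np.array([i for i, c in enumerate(cols) if m.groups[c] == b]) for b in baits
    ]
    if any(len(idx) < 2 for idx in group_index):
        raise ValidationError("need >= 2 columns per group")

    d_obs = _moderated_d(values, group_index, cfg.s0)

    rng = np.random.default_rng(cfg.seed)
    perms = _label_permutations(labels, cfg.n_permutations, rng)
    d_finite = np.nan_to_num(d_obs, nan=-np.inf, posinf=np.inf)
    sorted_obs = np.sort(d_finite)
    n_ge_perm = np.zeros(len(d_obs))
    for perm in perms:
        permuted = values[:, perm]
        d_perm = _moderated_d(permuted, group_index, cfg.s0)
        d_perm = np.sort(d_perm[np.isfinite(d_perm)])
        # count permuted statistics >= each observed d via sorted search
        n_ge_perm += len(d_perm) - np.searchsorted(d_perm, d_finite, side="left")
    mean_fp = n_ge_perm / len(perms)
    n_called = len(d_obs) - np.searchsorted(sorted_obs, d_finite, side="left")
    n_called = np.maximum(n_called, 1)
    q_raw = mean_fp / n_called

    # monotonize (step-up): a larger d never gets a larger q — take the
    # running minimum of the raw estimate from the least significant
    # threshold upward
    idx_desc = np.argsort(-d_finite, kind="stable")
    q = np.empty_like(q_raw)
    q[idx_desc] = np.minimum.accumulate(q_raw[idx_desc][::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    # infinite statistics (zero within-variance at s0=0) are maximally significant
    q[np.isinf(d_obs)] = 0.0

    index = m.values.index
    d_series = pd.Series(d_obs, index=index, name="d")
    q_series = pd.Series(q, index=index, name="q")
    return AnovaResult(
        d=d_series,
        q=q_series,
        significant=(q_series <= cfg.fdr_target),
    )


# -------------------------------------------------------------- clustering

def profile_and_cluster(
    m: LFQMatrix, res: AnovaResult, n_clusters: int = 3
) -> ClusterOutput:
    """Z-score significant proteins, build bait medians, cluster by correlation.

    Significant rows are z-scored across all samples (mean 0, SD 1 per
    row), the per-bait median of replicates is taken, and proteins are
    clustered hierarchically with distance 1 − Pearson and average
    linkage.  Leaf order is deterministic (ties broken by row identifier
    via the index sort preceding linkage).
    """
    sig = res.significant_proteins()
    values = m.values.loc[sorted(sig)]
    if len(values) < 2:
        z = values.sub(values.mean(axis=1), axis=0)
        sd = values.std(axis=1, ddof=0).replace(0, np.nan)
        z = z.div(sd, axis=0).fillna(0.0)
        medians = _bait_medians(z, m)
        return ClusterOutput(
            zscores=z,
            bait_medians=medians,
            cluster_ids=pd.Series(1, index=values.index, dtype=int),
            linkage=None,
            leaf_order=list(values.index),
            degenerate=True,
        )

    z = values.sub(values.mean(axis=1), axis=0)
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValidationError("zero-variance significant protein cannot be z-scored")
    z = z.div(sd, axis=0)
    medians = _bait_medians(z, m)

    corr = np.corrcoef(z.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    cut = hierarchy.fcluster(linkage, t=min(n_clusters, len(z)), criterion="maxclust")
    return ClusterOutput(
        zscores=z,
        bait_medians=medians,
        cluster_ids=pd.Series(cut, index=z.index, dtype=int),
        linkage=linkage,
        leaf_order=[z.index[i] for i in leaves],
    )


def _bait_medians(z: pd.DataFrame, m: LFQMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {bait: z[m.group_columns(bait)].median(axis=1) for bait in m.baits}
    )


def bait_correlation(profiles: ClusterOutput) -> pd.DataFrame:
    """Bait × bait Pearson correlation of the median enrichment profiles.

    Undefined entries (zero-variance bait columns) are returned as NaN.
    """
    medians = profiles.bait_medians
    if len(medians) < 3:
        raise ValidationError("need >= 3 significant proteins for bait correlation")
    corr = medians.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


# -------------------------------------------------------- targeted-MS ratios

def prm_normalize(acetyl_signal: float, reference_signal: float) -> float:
    """Acetylated-peptide signal normalized to the reference peptide signal.

    The reference is the highly abundant C-terminal ubiquitin peptide
    (residues 64-73), which is unaffected by the modification.
    """
    if reference_signal <= 0:
        raise ValidationError("reference signal must be > 0")
    if acetyl_signal < 0:
        raise ValidationError("acetyl signal must be >= 0")
    return acetyl_signal / reference_signal


def deacetylation_fraction(area_acetylated: float, area_deacetylated: float) -> float:
    """Deacetylated fraction from intact-protein peak areas."""
    if area_acetylated < 0 or area_deacetylated < 0:
        raise ValidationError("peak areas must be >= 0")
    total = area_acetylated + area_deacetylated
    if total == 0:
        raise ValidationError("both peak areas are zero")
    return area_deacetylated / total
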