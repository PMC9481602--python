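"""Weighted chemical-shift perturbations and their significance statistics.

The weighted CSP of a backbone amide between two ¹H–¹⁵N spectra is

    Δω = sqrt( ((Δ¹H)² + (Δ¹⁵N)²/25) / 2 )   [ppm]

where the 1/25 factor maps the larger ¹⁵N dispersion onto the ¹H scale.
Significance is judged against two pooled cutoffs — the mean and the mean
plus one (sample) standard deviation of all Δω values, after masking an
exclusion set (all lysines for acetyl-lysine comparisons, or the single
substituted position for point variants).  Significant residues are then
grouped into sequence-contiguous clusters and intersected with the I44/I36
hydrophobic patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .errors import EmptyProfileError, UndefinedStatisticError, ValidationError
from .peaks import PeakList, match_peaks
from .ubiquitin import HydrophobicPatch

__all__ = [
    "CSPProfile",
    "CutoffPair",
    "ResidueCluster",
    "PatchOverlap",
    "weighted_csp",
    "significance_cutoffs",
    "classify_and_cluster",
    "patch_overlap",
    "profile_correlation",
    "write_profile",
    "write_clusters",
]

CLASS_BELOW = "below_mean"
CLASS_ABOVE_MEAN = "above_mean"
CLASS_ABOVE_MEAN_PLUS_SD = "above_mean_plus_sd"
_SIGNIFICANT = {CLASS_ABOVE_MEAN, CLASS_ABOVE_MEAN_PLUS_SD}


@dataclass
class CSPProfile:
    """Per-residue Δω values with an exclusion mask and significance classes."""

    label: str
    values: Dict[int, float]
    excluded: Set[int] = field(default_factory=set)
    classes: Dict[int, str] = field(default_factory=dict)
    residue_types: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r, v in self.values.items():
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"Δω must be finite and >= 0 (residue {r}: {v})")

    def unmasked_values(self) -> Dict[int, float]:
        """Δω values that enter cutoff statistics (exclusion set removed)."""
        return {r: v for r, v in self.values.items() if r not in self.excluded}

    def significant_residues(self) -> Set[int]:
        return {r for r, c in self.classes.items() if c in _SIGNIFICANT}


@dataclass(frozen=True)
class CutoffPair:
    """Mean and mean-plus-one-SD significance cutoffs (ppm)."""

    mean_cutoff: float
    mean_plus_sd_cutoff: float
    n_values: int
    excluded_residues: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mean_cutoff < 0 or self.mean_plus_sd_cutoff < self.mean_cutoff:
            raise ValidationError("cutoffs must satisfy 0 <= mean <= mean+SD")


@dataclass(frozen=True)
class ResidueCluster:
    """A sequence-contiguous run of significantly perturbed residues."""

    members: Tuple[int, ...]
    span: Tuple[int, int]
    max_value: float


@dataclass(frozen=True)
class PatchOverlap:
    """How strongly a hydrophobic patch is hit by significant perturbations."""

    patch: HydrophobicPatch
    n_significant: int
    fraction: float
    member_classes: Dict[int, Optional[str]]


def weighted_csp(
    reference: PeakList, variant: PeakList, excluded: Iterable[int] = ()
) -> CSPProfile:
    """Per-residue weighted CSP between two assignment-paired peak lists.

    Residues listed in ``excluded`` keep their Δω values but are masked from
    cutoff statistics.  Residues present in only one list (e.g. broadened
    out) are absent from the profile.
    """
    pairing = match_peaks(reference, variant, mode="by_assignment")
    if not pairing.pairs:
        raise EmptyProfileError(
            f"no pairable residues between {reference.label!r} and {variant.label!r}"
        )
    values: Dict[int, float] = {}
    residue_types: Dict[int, str] = {}
    for residue, (ref_peak, var_peak) in pairing.pairs.items():
        dh = var_peak.shift_h - ref_peak.shift_h
        dn = var_peak.shift_n - ref_peak.shift_n
        values[residue] = math.sqrt((dh * dh + dn * dn / 25.0) / 2.0)
        residue_types[residue] = ref_peak.residue_type
    return CSPProfile(
        label=f"{variant.label} vs {reference.label}",
        values=values,
        excluded=set(excluded) & set(values),
        residue_types=residue_types,
    )


def significance_cutoffs(profiles: CSPProfile | Sequence[CSPProfile]) -> CutoffPair:
    """Mean / mean+SD cutoffs pooled over one or more profiles.

    The pool is every non-excluded Δω value of every supplied profile; the
    standard deviation uses the n−1 denominator.
    """
    if isinstance(profiles, CSPProfile):
        profiles = [profiles]
    pooled: List[float] = []
    excluded: Set[int] = set()
    for p in profiles:
        pooled.extend(p.unmasked_values().values())
        excluded |= p.excluded
    if len(pooled) < 2:
        raise UndefinedStatisticError(
            f"need >= 2 pooled values for an SD, got {len(pooled)}"
        )
    arr = np.asarray(pooled, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return CutoffPair(
        mean_cutoff=mean,
        mean_plus_sd_cutoff=mean + sd,
        n_values=len(pooled),
        excluded_residues=frozenset(excluded),
    )


def classify_and_cluster(
    profile: CSPProfile,
    cutoffs: CutoffPair,
    gap_tolerance: int = 1,
    min_size: int = 2,
) -> List[ResidueCluster]:
    """Assign significance classes and extract sequence clusters.

    Each non-excluded residue is classed ``below_mean``, ``above_mean``
    (Δω > mean cutoff) or ``above_mean_plus_sd`` (Δω > mean+SD cutoff).
    Clusters are maximal runs of significant residues allowing interruptions
    of at most ``gap_tolerance`` non-significant sequence positions; runs
    with fewer than ``min_size`` significant members are dropped.

    The profile's ``classes`` mapping is filled in place; the cluster list
    is returned.
    """
    if gap_tolerance < 0 or min_size < 1:
        raise ValidationError("gap_tolerance >= 0 and min_size >= 1 required")
    profile.classes.clear()
    for residue, value in profile.unmasked_values().items():
        if value > cutoffs.mean_plus_sd_cutoff:
            profile.classes[residue] = CLASS_ABOVE_MEAN_PLUS_SD
        elif value > cutoffs.mean_cutoff:
            profile.classes[residue] = CLASS_ABOVE_MEAN
        else:
            profile.classes[residue] = CLASS_BELOW

    significant = sorted(profile.significant_residues())
    clusters: List[ResidueCluster] = []
    run: List[int] = []
    for residue in significant:
        if run and residue - run[-1] - 1 > gap_tolerance:
            if len(run) >= min_size:
                clusters.append(_make_cluster(run, profile))
            run = []
        run.append(residue)
    if len(run) >= min_size:
        clusters.append(_make_cluster(run, profile))
    return clusters


def _make_cluster(members: List[int], profile: CSPProfile) -> ResidueCluster:
    return ResidueCluster(
        members=tuple(members),
        span=(members[0], members[-1]),
        max_value=max(profile.values[r] for r in members),
    )


def patch_overlap(profile: CSPProfile, patch: HydrophobicPatch) -> PatchOverlap:
    """Count how many of a patch's four members are significantly perturbed.

    Requires ``classify_and_cluster`` to have filled the profile's classes.
    Members missing from the profile (unassigned/broadened) report ``None``.
    """
    member_classes = {r: profile.classes.get(r) for r in sorted(patch.members)}
    n_sig = sum(1 for c in member_classes.values() if c in _SIGNIFICANT)
    return PatchOverlap(
        patch=patch,
        n_significant=n_sig,
        fraction=n_sig / len(patch.members),
        member_classes=member_classes,
    )


def profile_correlation(a: CSPProfile, b: CSPProfile) -> Tuple[float, int]:
    """Pearson correlation of two CSP profiles over shared, non-excluded residues.

    Returns ``(r, n_shared)``; raises if fewer than 3 residues are shared or
    either profile has zero variance over the shared set.
    """
    shared = sorted(set(a.unmasked_values()) & set(b.unmasked_values()))
    if len(shared) < 3:
        raise UndefinedStatisticError(f"need >= 3 shared residues, got {len(shared)}")
    xa = np.array([a.values[r] for r in shared])
    xb = np.array([b.values[r] for r in shared])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedStatisticError("zero variance over shared residues")
    r, _ = stats.pearsonr(xa, xb)
    return float(r), len(shared)


def write_profile(profile: CSPProfile, path: str | Path) -> None:
    """Serialize a classified profile as TSV."""
    lines = ["residue_number\tresidue_type\tdelta_omega_ppm\tclass"]
    for residue in sorted(profile.values):
        cls = "excluded" if residue in profile.excluded else profile.classes.get(residue, "")
        rtype = profile.residue_types.get(residue, "X")
        lines.append(f"{residue}\t{rtype}\t{profile.values[residue]:.6f}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_clusters(clusters: Sequence[ResidueCluster], path: str | Path) -> None:
    """Serialize a cluster report as TSV."""
    lines = ["first\tlast\tn_members\tmax_value_ppm"]
    for c in clusters:
        lines.append(f"{c.span[0]}\t{c.span[1]}\t{len(c.members)}\t{c.max_value:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
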