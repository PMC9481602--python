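"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its spec plus a seed and emits data
in exactly the containers/formats the corresponding analysis stage
consumes, together with the planted ground truth.  The key identity used
for the NMR generators: a planted weighted CSP Δω decomposes into peak
displacements

    Δ¹H = Δω·√2·cos θ,   Δ¹⁵N = 5·Δω·√2·sin θ,

so the weighted-CSP formula recovers Δω exactly at zero noise for any
direction angle θ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import ubiquitin
from .errors import ValidationError
from .peaks import Peak, PeakList
from .structure import StructureEnsemble
from .titration import TitrationSeries, TitrationStep, concentrations_from_scheme

__all__ = [
    "HsqcSimSpec",
    "TitrationSimSpec",
    "LfqSimSpec",
    "simulate_csp_pair",
    "simulate_titration",
    "simulate_lfq",
    "simulate_ensemble",
    "UB11ACK_TITRATION_DESIGN",
]


def _residue_types(n_residues: int) -> Dict[int, str]:
    """Residue types for a synthetic protein: the canonical ubiquitin
    sequence when the length matches, otherwise alanines; prolines (no
    backbone amide) are absent from peak lists."""
    if n_residues == ubiquitin.N_RESIDUES:
        return {
            r: ubiquitin.residue_type(r)
            for r in range(1, n_residues + 1)
            if r not in ubiquitin.PROLINES
        }
    return {r: "A" for r in range(1, n_residues + 1)}


def _base_shifts(
    residues: Sequence[int],
    h_range: Tuple[float, float],
    n_range: Tuple[float, float],
    rng: np.random.Generator,
) -> Dict[int, Tuple[float, float]]:
    return {
        r: (
            float(rng.uniform(*h_range)),
            float(rng.uniform(*n_range)),
        )
        for r in residues
    }


def csp_displacement(delta_omega: float, theta: float) -> Tuple[float, float]:
    """Decompose a planted Δω into (Δ¹H, Δ¹⁵N) peak displacements."""
    return (
        delta_omega * math.sqrt(2.0) * math.cos(theta),
        5.0 * delta_omega * math.sqrt(2.0) * math.sin(theta),
    )


# ----------------------------------------------------------- HSQC CSP pair

@dataclass(frozen=True)
class HsqcSimSpec:
    """Paired reference/variant HSQC peak lists with planted perturbations.

    ``perturbations`` is a list of (residue, Δω in ppm, direction angle θ
    in radians); ``noise_sd`` (ppm) is added independently to both
    dimensions of both spectra.
    """

    n_residues: int = ubiquitin.N_RESIDUES
    h_range: Tuple[float, float] = (6.5, 10.5)
    n_range: Tuple[float, float] = (103.0, 133.0)
    perturbations: Tuple[Tuple[int, float, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for r, dw, _theta in self.perturbations:
            if not 1 <= r <= self.n_residues:
                raise ValidationError(f"planted residue {r} outside 1..{self.n_residues}")
            if dw < 0:
                raise ValidationError("planted Δω must be >= 0")


def simulate_csp_pair(spec: HsqcSimSpec) -> Tuple[PeakList, PeakList, Set[int]]:
    """Reference and variant peak lists plus the planted residue set.

    At ``noise_sd = 0`` the weighted CSP of the pair equals the planted Δω
    exactly at each perturbed residue and 0 elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    rtypes = _residue_types(spec.n_residues)
    base = _base_shifts(sorted(rtypes), spec.h_range, spec.n_range, rng)
    planted = {r: (dw, theta) for r, dw, theta in spec.perturbations}
    missing_planted = set(planted) - set(rtypes)
    if missing_planted:
        raise ValidationError(
            f"planted residues have no backbone amide: {sorted(missing_planted)}"
        )

    ref_peaks, var_peaks = [], []
    for r in sorted(rtypes):
        h0, n0 = base[r]
        dh, dn = csp_displacement(*planted[r]) if r in planted else (0.0, 0.0)
        noise = rng.normal(0.0, spec.noise_sd, size=4) if spec.noise_sd > 0 else np.zeros(4)
        ref_peaks.append(
            Peak(r, rtypes[r], h0 + noise[0], n0 + noise[1], intensity=1.0)
        )
        var_peaks.append(
            Peak(r, rtypes[r], h0 + dh + noise[2], n0 + dn + noise[3], intensity=1.0)
        )
    return (
        PeakList("reference", ref_peaks),
        PeakList("variant", var_peaks),
        set(planted),
    )


# --------------------------------------------------------------- titration

#: Titration design emulating the low-concentration experiments: protein
#: start 33 µM in 500 µL, seven additions of an 803 µM ligand stock
#: reaching roughly three-fold molar excess at the endpoint.
UB11ACK_TITRATION_DESIGN: Dict[str, object] = {
    "start_protein_uM": 33.0,
    "start_volume_uL": 500.0,
    "ligand_stock_uM": 803.0,
    "added_uL": (0.0, 4.0, 6.0, 8.0, 10.0, 10.0, 12.0, 12.0),
}

#: Six fit residues with distinct saturation amplitudes spanning
#: 0.05-0.5 ppm (the classic spread of interface residues).
DEFAULT_DMAX: Dict[int, float] = {14: 0.05, 43: 0.14, 45: 0.23, 51: 0.32, 67: 0.41, 71: 0.50}


@dataclass(frozen=True)
class TitrationSimSpec:
    """Synthetic HSQC titration generated from the 1:1 binding quadratic.

    ``dmax_true`` maps residues to saturation CSPs (ppm); residues of the
    protein not listed keep Δω = 0 (non-interface).  ``broadening_beta``
    maps residues to an intensity-decay coefficient β ∈ [0, 1]:
    I(step) = I₀·(1 − β·fraction_bound), so β ≈ 1 residues lose almost all
    intensity near saturation and trip the >90% attrition rule.
    """

    kd_true: float = 8.0
    dmax_true: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DMAX))
    design: Dict[str, object] = field(default_factory=lambda: dict(UB11ACK_TITRATION_DESIGN))
    broadening_beta: Dict[int, float] = field(default_factory=dict)
    n_residues: int = ubiquitin.N_RESIDUES
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_true <= 0:
            raise ValidationError("kd_true must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if any(d < 0 for d in self.dmax_true.values()):
            raise ValidationError("dmax values must be >= 0")
        if any(not 0 <= b <= 1 for b in self.broadening_beta.values()):
            raise ValidationError("broadening_beta must lie in [0, 1]")


def _design_concentrations(design: Dict[str, object]) -> List[Tuple[float, float]]:
    if "concentrations" in design:
        return [tuple(pair) for pair in design["concentrations"]]  # type: ignore[misc]
    return concentrations_from_scheme(
        float(design["start_protein_uM"]),
        float(design["start_volume_uL"]),
        float(design["ligand_stock_uM"]),
        list(design["added_uL"]),  # type: ignore[arg-type]
    )


def simulate_titration(
    spec: TitrationSimSpec,
) -> Tuple[TitrationSeries, Dict[str, object]]:
    """Generate a titration series plus a ground-truth sidecar dict."""
    from .titration import binding_isotherm  # local import avoids cycle at module load

    rng = np.random.default_rng(spec.seed)
    conc = _design_concentrations(spec.design)
    rtypes = _residue_types(spec.n_residues)
    base = _base_shifts(sorted(rtypes), (6.5, 10.5), (103.0, 133.0), rng)
    thetas = {r: float(rng.uniform(0.0, 2.0 * math.pi)) for r in rtypes}

    steps: List[TitrationStep] = []
    for step_index, (P, L) in enumerate(conc):
        peaks = []
        for r in sorted(rtypes):
            dmax = spec.dmax_true.get(r, 0.0)
            dw_clean = binding_isotherm(P, L, spec.kd_true, dmax) if dmax > 0 else 0.0
            dw = dw_clean
            if spec.noise_sd > 0 and step_index > 0:
                dw = max(dw + float(rng.normal(0.0, spec.noise_sd)), 0.0)
            dh, dn = csp_displacement(dw, thetas[r])
            beta = spec.broadening_beta.get(r, 0.0)
            fraction_bound = dw_clean / dmax if dmax > 0 else 0.0
            intensity = max(1.0 - beta * fraction_bound, 0.0)
            h0, n0 = base[r]
            peaks.append(Peak(r, rtypes[r], h0 + dh, n0 + dn, intensity=intensity))
        steps.append(
            TitrationStep(
                peaks=PeakList(f"step{step_index}", peaks),
                protein_conc=P,
                ligand_conc=L,
                step_index=step_index,
            )
        )
    truth = {
        "kd_true_uM": spec.kd_true,
        "dmax_true_ppm": dict(spec.dmax_true),
        "concentrations_uM": conc,
        "seed": spec.seed,
        "noise_sd_ppm": spec.noise_sd,
    }
    return TitrationSeries(steps, label=f"synthetic kd={spec.kd_true}"), truth


# --------------------------------------------------------------------- LFQ

_DEFAULT_BAITS = ("wt", "6AcK", "11AcK", "27AcK", "29AcK", "33AcK", "48AcK", "63AcK")


@dataclass(frozen=True)
class LfqSimSpec:
    """Synthetic AE-MS intensity table with planted enrichment clusters.

    Each planted cluster is a block of proteins enriched in a subset of
    baits with per-(protein, bait) log2 effects drawn uniformly from
    ``effect_range``; background proteins carry no effect.  Values below
    ``detection_limit`` (log2 scale) are censored to missing — missingness
    is not at random, emulating the detection limit of the instrument.
    """

    n_proteins: int = 300
    baits: Tuple[str, ...] = _DEFAULT_BAITS
    n_replicates: int = 8
    baseline_mean: float = 27.0
    baseline_sd: float = 1.5
    cluster_sizes: Tuple[int, ...] = (20, 20, 20)
    cluster_baits: Tuple[Tuple[str, ...], ...] = (
        ("wt", "6AcK", "11AcK"),
        ("27AcK", "29AcK", "33AcK"),
        ("48AcK", "63AcK"),
    )
    effect_range: Tuple[float, float] = (4.0, 6.0)
    noise_sd: float = 0.5
    detection_limit: float = 25.0
    n_reverse: int = 5
    n_contaminants: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per bait")
        if len(self.cluster_sizes) != len(self.cluster_baits):
            raise ValidationError("cluster_sizes and cluster_baits must align")
        if sum(self.cluster_sizes) > self.n_proteins:
            raise ValidationError("planted clusters exceed n_proteins")
        for baits in self.cluster_baits:
            unknown = set(baits) - set(self.baits)
            if unknown:
                raise ValidationError(f"unknown baits in cluster pattern: {unknown}")


def simulate_lfq(spec: LfqSimSpec) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Raw-scale MaxQuant-style table plus ground-truth cluster labels.

    The returned DataFrame has ``Protein IDs``, per-run ``LFQ intensity``
    columns (raw scale, 0 = not detected), ``Reverse`` and ``Potential
    contaminant`` marker columns including injected decoy rows.  Ground
    truth maps protein ids to planted cluster ids (0 = background).
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"{bait}_{rep + 1}" for bait in spec.baits for rep in range(spec.n_replicates)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    protein_ids = [f"PROT{i:04d}" for i in range(spec.n_proteins)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_proteins)

    cluster_of: Dict[str, int] = {p: 0 for p in protein_ids}
    effects = np.zeros((spec.n_proteins, len(spec.baits)))
    row = 0
    for cluster_id, (size, baits) in enumerate(
        zip(spec.cluster_sizes, spec.cluster_baits), start=1
    ):
        for _ in range(size):
            cluster_of[protein_ids[row]] = cluster_id
            for j, bait in enumerate(spec.baits):
                if bait in baits:
                    effects[row, j] = rng.uniform(*spec.effect_range)
            row += 1

    bait_index = {b: j for j, b in enumerate(spec.baits)}
    log2 = np.empty((spec.n_proteins, len(samples)))
    for c, sample in enumerate(samples):
        j = bait_index[groups[sample]]
        log2[:, c] = baseline + effects[:, j] + rng.normal(0.0, spec.noise_sd, spec.n_proteins)
    censored = log2 < spec.detection_limit
    raw = np.where(censored, 0.0, np.exp2(log2))

    table = pd.DataFrame({"Protein IDs": protein_ids})
    for c, sample in enumerate(samples):
        table[f"LFQ intensity {sample}"] = raw[:, c]
    table["Reverse"] = ""
    table["Potential contaminant"] = ""

    decoys = []
    for i in range(spec.n_reverse):
        decoys.append(_decoy_row(f"REV__{i}", samples, rng, spec, reverse=True))
    for i in range(spec.n_contaminants):
        decoys.append(_decoy_row(f"CON__{i}", samples, rng, spec, reverse=False))
    if decoys:
        table = pd.concat([table, pd.DataFrame(decoys)], ignore_index=True)

    truth = {
        "groups": groups,
        "cluster_of": cluster_of,
        "planted": [p for p, c in cluster_of.items() if c > 0],
        "seed": spec.seed,
    }
    return table, truth


def _decoy_row(
    pid: str, samples: List[str], rng: np.random.Generator, spec: LfqSimSpec, reverse: bool
) -> Dict[str, object]:
    row: Dict[str, object] = {"Protein IDs": pid}
    for s in samples:
        row[f"LFQ intensity {s}"] = float(
            np.exp2(rng.normal(spec.baseline_mean, spec.baseline_sd))
        )
    row["Reverse"] = "+" if reverse else ""
    row["Potential contaminant"] = "" if reverse else "+"
    return row


# --------------------------------------------------------------- ensembles

def simulate_ensemble(
    n_residues: int = 20,
    atoms_per_residue: int = 3,
    jitter_sd: float = 0.0,
    displacement: Optional[Tuple[Sequence[int], Sequence[float]]] = None,
    n_frames: int = 1,
    seed: int = 0,
    residue_spacing: float = 0.5,
    atom_spacing: float = 0.05,
) -> StructureEnsemble:
    """Extended-chain template ensemble with jitter and planted displacement.

    Residue ``i`` occupies atoms collinear along x starting at
    ``(i-1)·residue_spacing`` nm.  Per-frame Gaussian jitter of SD
    ``jitter_sd`` (nm, isotropic, per atom) emulates thermal motion; the
    optional ``displacement`` = (residues, xyz vector in nm) is a
    systematic shift applied to the listed residues in every frame.
    """
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be >= 0")
    if n_frames < 1 or n_residues < 1 or atoms_per_residue < 1:
        raise ValidationError("n_frames, n_residues and atoms_per_residue must be >= 1")
    rng = np.random.default_rng(seed)
    atom_residues = np.repeat(np.arange(1, n_residues + 1), atoms_per_residue)
    base = np.zeros((n_residues * atoms_per_residue, 3))
    for i in range(len(base)):
        res = atom_residues[i] - 1
        k = i % atoms_per_residue
        base[i, 0] = res * residue_spacing + k * atom_spacing
    if displacement is not None:
        residues, vector = displacement
        vec = np.asarray(vector, dtype=float)
        if vec.shape != (3,):
            raise ValidationError("displacement vector must have 3 components")
        mask = np.isin(atom_residues, list(residues))
        base[mask] += vec
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
    return StructureEnsemble(
        coords=coords,
        atom_residues=atom_residues,
        elements=np.array(["C"] * len(base), dtype=object),
        label="synthetic extended chain",
    )
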