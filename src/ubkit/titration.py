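"""HSQC titration analysis: 1:1 binding isotherm and global Kd fitting.

A titration series is an ordered set of peak lists with per-step total
protein and ligand concentrations.  For a 1:1 complex at total
concentrations [P]_t and [L]_t, the observed fast-exchange CSP of a
residue is the exact quadratic solution

    Δω_obs = Δω_max · ( [P]+[L]+Kd − sqrt(([P]+[L]+Kd)² − 4[P][L]) ) / (2[P])

with a single dissociation constant Kd shared across residues and one
saturation amplitude Δω_max per residue.  The global fit exploits that for
a fixed Kd every Δω_max has a closed-form least-squares solution, reducing
the optimization to one dimension in log10(Kd).

Residue bookkeeping mirrors standard titration practice: CSPs are computed
per step against the ligand-free spectrum; residues losing more than 90%
of their starting intensity (slow/intermediate exchange broadening) are
excluded from fitting; the fit uses residues significant at the titration
endpoint in every experiment and broadened in none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize

from .csp import CSPProfile, CutoffPair, classify_and_cluster, weighted_csp
from .errors import EmptySelectionError, FitError, ValidationError
from .peaks import PeakList

__all__ = [
    "TitrationStep",
    "TitrationSeries",
    "AttritionReport",
    "BindingFitResult",
    "concentrations_from_scheme",
    "per_step_csp",
    "intensity_attrition",
    "select_fit_residues",
    "binding_isotherm",
    "fit_global_kd",
    "write_fit_report",
]

#: "more than 90% decrease" — a residue is excluded iff its remaining
#: intensity fraction is strictly below 0.10.
ATTRITION_FRACTION = 0.10

_LOG_KD_BOUNDS = (-3.0, 5.0)  # Kd bounds 1e-3 .. 1e5 µM, on log10 scale


@dataclass
class TitrationStep:
    """One titration point: a spectrum plus the total concentrations."""

    peaks: PeakList
    protein_conc: float  # [P]_t, µM
    ligand_conc: float  # [L]_t, µM
    step_index: int

    def __post_init__(self) -> None:
        if self.protein_conc < 0 or self.ligand_conc < 0:
            raise ValidationError("concentrations must be >= 0")
        if self.step_index < 0:
            raise ValidationError("step_index must be >= 0")
        if self.step_index == 0 and self.ligand_conc != 0:
            raise ValidationError("step 0 must be ligand-free")


class TitrationSeries:
    """Ordered titration steps with monotone concentration bookkeeping."""

    def __init__(self, steps: Sequence[TitrationStep], label: str = ""):
        if not steps:
            raise ValidationError("a titration series needs at least one step")
        for prev, cur in zip(steps, steps[1:]):
            if cur.step_index <= prev.step_index:
                raise ValidationError("step_index must be strictly increasing")
            if cur.ligand_conc < prev.ligand_conc:
                raise ValidationError("ligand concentration must be non-decreasing")
            if cur.protein_conc > prev.protein_conc:
                raise ValidationError("protein concentration must be non-increasing (dilution)")
        self.steps = list(steps)
        self.label = label

    def __len__(self) -> int:
        return len(self.steps)

    def __repr__(self) -> str:
        return f"TitrationSeries({self.label!r}, n_steps={len(self)})"


@dataclass
class AttritionReport:
    """Remaining intensity fraction at the final step, per residue."""

    fractions: Dict[int, float]
    flagged: Set[int]
    skipped: Set[int] = field(default_factory=set)


@dataclass
class BindingFitResult:
    """Globally fitted Kd with per-residue saturation amplitudes."""

    kd: float  # µM
    kd_se: float  # asymptotic standard error, µM
    dmax: Dict[int, float]  # Δω_max per residue, ppm
    residuals: Dict[Tuple[int, int], float]  # (residue, step) -> ppm
    converged: bool
    n_points: int
    kd_ci: Optional[Tuple[float, float]] = None  # bootstrap percentile interval
    at_bound: bool = False


def concentrations_from_scheme(
    start_protein: float,
    start_volume: float,
    ligand_stock: float,
    added_volumes: Sequence[float],
) -> List[Tuple[float, float]]:
    """Per-step ([P]_t, [L]_t) from cumulative additions of a ligand stock.

    Parameters
    ----------
    start_protein : float
        Protein concentration before any addition (µM).
    start_volume : float
        Starting sample volume (µL).
    ligand_stock : float
        Ligand stock concentration (µM).
    added_volumes : sequence of float
        Volume added at each step (µL); the first entry must be 0 (the
        ligand-free reference spectrum).

    Returns
    -------
    list of (protein_conc, ligand_conc) per step, µM, by cumulative
    dilution: [P] = P0·V0/(V0+ΣΔV), [L] = L_stock·ΣΔV/(V0+ΣΔV).
    """
    if start_protein <= 0 or start_volume <= 0 or ligand_stock <= 0:
        raise ValidationError("start_protein, start_volume and ligand_stock must be > 0")
    if not added_volumes or added_volumes[0] != 0:
        raise ValidationError("first addition must be 0 (ligand-free reference)")
    if any(v < 0 for v in added_volumes):
        raise ValidationError("added volumes must be >= 0")
    out = []
    cumulative = 0.0
    for dv in added_volumes:
        cumulative += dv
        total = start_volume + cumulative
        out.append(
            (start_protein * start_volume / total, ligand_stock * cumulative / total)
        )
    return out


def per_step_csp(series: TitrationSeries) -> Dict[int, CSPProfile]:
    """Weighted CSP of every step > 0 relative to the ligand-free step."""
    reference = series.steps[0].peaks
    return {
        step.step_index: weighted_csp(reference, step.peaks)
        for step in series.steps[1:]
    }


def intensity_attrition(series: TitrationSeries) -> AttritionReport:
    """Remaining intensity fraction final-step / step-0 per residue.

    Residues absent at the final step (broadened beyond detection) get
    fraction 0.  A residue is flagged iff its fraction is strictly below
    0.10, i.e. more than 90% intensity loss; exactly 90% is not flagged.
    Residues with zero or missing step-0 intensity are skipped.
    """
    first = series.steps[0].peaks
    last = series.steps[-1].peaks
    fractions: Dict[int, float] = {}
    skipped: Set[int] = set()
    for peak in first.peaks:
        i0 = peak.intensity
        if i0 is None or i0 == 0:
            skipped.add(peak.residue_number)
            continue
        final = last.get(peak.residue_number)
        i_final = 0.0 if final is None or final.intensity is None else final.intensity
        fractions[peak.residue_number] = i_final / i0
    flagged = {r for r, f in fractions.items() if f < ATTRITION_FRACTION}
    return AttritionReport(fractions=fractions, flagged=flagged, skipped=skipped)


def select_fit_residues(
    endpoint_profiles: Mapping[str, CSPProfile],
    cutoffs: Mapping[str, CutoffPair],
    attrition: Mapping[str, AttritionReport],
) -> Set[int]:
    """Residues significant at every endpoint and broadened in none.

    For each experiment the endpoint profile is classified against that
    experiment's cutoffs; the selection is the intersection of significant
    residues minus the union of attrition-flagged residues.
    """
    if not endpoint_profiles:
        raise ValidationError("need at least one experiment")
    selected: Optional[Set[int]] = None
    for label, profile in endpoint_profiles.items():
        classify_and_cluster(profile, cutoffs[label])
        sig = profile.significant_residues()
        selected = sig if selected is None else selected & sig
    assert selected is not None
    for report in attrition.values():
        selected -= report.flagged
    if not selected:
        raise EmptySelectionError("no residue passes the selection rule; cannot fit")
    return selected


def binding_isotherm(P: float, L: float, kd: float, dmax: float) -> float:
    """Observed CSP of a 1:1 complex at total concentrations P and L (µM).

    Evaluates the exact quadratic bound-fraction solution; the discriminant
    is clamped at zero against round-off near stoichiometric saturation.
    """
    if P <= 0:
        raise ValidationError("protein concentration must be > 0")
    if L < 0 or kd < 0 or dmax < 0:
        raise ValidationError("L, kd and dmax must be >= 0")
    s = P + L + kd
    disc = max(s * s - 4.0 * P * L, 0.0)
    return dmax * (s - math.sqrt(disc)) / (2.0 * P)


def _bound_fraction(P: np.ndarray, L: np.ndarray, kd: float) -> np.ndarray:
    """Vectorized fraction bound (binding_isotherm with dmax = 1)."""
    s = P + L + kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * P)


def _assemble_fit_data(
    series: TitrationSeries, residues: Set[int]
) -> Tuple[List[int], List[np.ndarray], List[np.ndarray], List[np.ndarray], List[List[int]]]:
    """Per-residue observation vectors (a residue contributes only its observed steps)."""
    profiles = per_step_csp(series)
    conc = {s.step_index: (s.protein_conc, s.ligand_conc) for s in series.steps}
    res_list = sorted(residues)
    ys, Ps, Ls, step_ids = [], [], [], []
    for r in res_list:
        y, P, L, steps = [], [], [], []
        for step_index, profile in sorted(profiles.items()):
            if r in profile.values:
                y.append(profile.values[r])
                P.append(conc[step_index][0])
                L.append(conc[step_index][1])
                steps.append(step_index)
        if not y:
            raise FitError(f"residue {r} has no observed titration points")
        ys.append(np.asarray(y))
        Ps.append(np.asarray(P))
        Ls.append(np.asarray(L))
        step_ids.append(steps)
    return res_list, ys, Ps, Ls, step_ids


def _profiled_objective(
    log_kd: float,
    ys: Sequence[np.ndarray],
    Ps: Sequence[np.ndarray],
    Ls: Sequence[np.ndarray],
) -> Tuple[float, List[float]]:
    """SSR at a given log10(Kd) with each Δω_max profiled out in closed form."""
    kd = 10.0**log_kd
    ssr = 0.0
    dmaxes = []
    for y, P, L in zip(ys, Ps, Ls):
        f = _bound_fraction(P, L, kd)
        denom = float(f @ f)
        dmax = float(y @ f) / denom if denom > 0 else 0.0
        dmax = max(dmax, 0.0)
        r = y - dmax * f
        ssr += float(r @ r)
        dmaxes.append(dmax)
    return ssr, dmaxes


def fit_global_kd(
    series: TitrationSeries,
    residues: Set[int],
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> BindingFitResult:
    """Global least-squares fit of a shared Kd across selected residues.

    Minimizes the summed squared CSP residuals over all (residue, step)
    observations with one shared Kd and one Δω_max per residue.  For fixed
    Kd each Δω_max is solved in closed form, so the search is
    one-dimensional on log10(Kd), bounded in [1e-3, 1e5] µM.  The
    asymptotic Kd standard error comes from the Jacobian of the full
    parameter vector; an optional seeded residual bootstrap yields a
    percentile confidence interval.
    """
    if not residues:
        raise ValidationError("no residues selected for fitting")
    res_list, ys, Ps, Ls, step_ids = _assemble_fit_data(series, set(residues))
    n_points = int(sum(len(y) for y in ys))
    n_params = 1 + len(res_list)
    if n_points < n_params:
        raise FitError(
            f"unidentifiable fit: {n_points} observations for {n_params} parameters"
        )

    max_L = max(float(L.max()) for L in Ls)
    x0 = math.log10(max(max_L / 2.0, 10.0 ** _LOG_KD_BOUNDS[0]))

    def objective(log_kd: float) -> float:
        return _profiled_objective(log_kd, ys, Ps, Ls)[0]

    result = optimize.minimize_scalar(
        objective,
        bounds=_LOG_KD_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    # local polish around the start value guards against a distant local
    # minimum of the 1-D profile objective (rare, but cheap to rule out)
    local = optimize.minimize_scalar(
        objective,
        bounds=(max(x0 - 1.5, _LOG_KD_BOUNDS[0]), min(x0 + 1.5, _LOG_KD_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if local.fun < result.fun:
        result = local

    log_kd = float(result.x)
    kd = 10.0**log_kd
    _, dmaxes = _profiled_objective(log_kd, ys, Ps, Ls)
    at_bound = (
        log_kd - _LOG_KD_BOUNDS[0] < 1e-6 or _LOG_KD_BOUNDS[1] - log_kd < 1e-6
    )

    residuals: Dict[Tuple[int, int], float] = {}
    for r, y, P, L, steps, dmax in zip(res_list, ys, Ps, Ls, step_ids, dmaxes):
        model = dmax * _bound_fraction(P, L, kd)
        for s_id, resid in zip(steps, (y - model)):
            residuals[(r, s_id)] = float(resid)

    kd_se = _asymptotic_kd_se(kd, dmaxes, ys, Ps, Ls, n_points, n_params)

    kd_ci = None
    if bootstrap > 0:
        kd_ci = _bootstrap_kd_ci(
            kd, dmaxes, ys, Ps, Ls, n_boot=bootstrap, seed=seed
        )

    return BindingFitResult(
        kd=kd,
        kd_se=kd_se,
        dmax={r: d for r, d in zip(res_list, dmaxes)},
        residuals=residuals,
        converged=bool(result.success) and not at_bound,
        n_points=n_points,
        kd_ci=kd_ci,
        at_bound=at_bound,
    )


def _asymptotic_kd_se(
    kd: float,
    dmaxes: Sequence[float],
    ys: Sequence[np.ndarray],
    Ps: Sequence[np.ndarray],
    Ls: Sequence[np.ndarray],
    n_points: int,
    n_params: int,
) -> float:
    """SE from s²·(JᵀJ)⁻¹ with J over (kd, dmax_1..dmax_R)."""
    if n_points <= n_params:
        return float("nan")
    rows = []
    ssr = 0.0
    h = max(kd * 1e-6, 1e-12)
    for y, P, L, dmax in zip(ys, Ps, Ls, dmaxes):
        f = _bound_fraction(P, L, kd)
        df_dkd = (_bound_fraction(P, L, kd + h) - _bound_fraction(P, L, max(kd - h, 0.0))) / (
            h + min(h, kd)
        )
        rows.append((dmax * df_dkd, f))
        r = y - dmax * f
        ssr += float(r @ r)
    # stack the block-sparse Jacobian: column 0 is d/d(kd), then one
    # column per residue amplitude
    n_res = len(ys)
    J = np.zeros((n_points, 1 + n_res))
    offset = 0
    for i, (dkd_col, f_col) in enumerate(rows):
        n = len(f_col)
        J[offset : offset + n, 0] = dkd_col
        J[offset : offset + n, 1 + i] = f_col
        offset += n
    s2 = ssr / (n_points - n_params)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        return float("nan")


def _bootstrap_kd_ci(
    kd: float,
    dmaxes: Sequence[float],
    ys: Sequence[np.ndarray],
    Ps: Sequence[np.ndarray],
    Ls: Sequence[np.ndarray],
    n_boot: int,
    seed: Optional[int],
) -> Tuple[float, float]:
    """Residual-bootstrap percentile CI for Kd (resampling pooled residuals)."""
    rng = np.random.default_rng(seed)
    fitted = [d * _bound_fraction(P, L, kd) for d, P, L in zip(dmaxes, Ps, Ls)]
    pooled = np.concatenate([y - fhat for y, fhat in zip(ys, fitted)])
    estimates = []
    for _ in range(n_boot):
        draw = rng.choice(pooled, size=len(pooled), replace=True)
        offset = 0
        ys_boot = []
        for fhat in fitted:
            n = len(fhat)
            ys_boot.append(np.maximum(fhat + draw[offset : offset + n], 0.0))
            offset += n
        res = optimize.minimize_scalar(
            lambda x: _profiled_objective(x, ys_boot, Ps, Ls)[0],
            bounds=_LOG_KD_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        estimates.append(10.0 ** float(res.x))
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def write_fit_report(
    fit: BindingFitResult, path_tsv: str | Path, path_json: str | Path
) -> None:
    """Write the fit result as a per-residue TSV plus a JSON summary."""
    lines = ["residue_number\tdmax_ppm"]
    for r in sorted(fit.dmax):
        lines.append(f"{r}\t{fit.dmax[r]:.6f}")
    Path(path_tsv).write_text("\n".join(lines) + "\n")
    payload = {
        "kd_uM": fit.kd,
        "kd_se_uM": fit.kd_se,
        "kd_ci_uM": list(fit.kd_ci) if fit.kd_ci else None,
        "converged": fit.converged,
        "at_bound": fit.at_bound,
        "n_points": fit.n_points,
        "dmax_ppm": {str(r): v for r, v in sorted(fit.dmax.items())},
    }
    Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")
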