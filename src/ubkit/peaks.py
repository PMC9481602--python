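"""Assigned 2D ¹H–¹⁵N peak lists: I/O and cross-spectrum peak pairing.

A peak list holds one cross peak per assigned, non-proline backbone amide.
Two on-disk dialects are supported: Sparky ``.list`` text (assignment
string like ``T14N-H``, w1 = ¹⁵N ppm, w2 = ¹H ppm, optional height) and a
plain TSV with an explicit header.  Pairing between two spectra is either
assignment-based (same residue number) or by nearest trajectory under the
weighted ¹H/¹⁵N metric, a reproducible surrogate for visually following
peak trajectories during a titration.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .errors import PeakFormatError, ValidationError

__all__ = [
    "Peak",
    "PeakList",
    "PeakPairing",
    "read_peak_list",
    "write_peak_list",
    "match_peaks",
    "weighted_distance",
]

#: ppm shifts are written with 4 decimals; exceeds instrument precision,
#: keeps round-trips exact.
SHIFT_DECIMALS = 4

_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)N-H$")


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross peak.

    Parameters
    ----------
    residue_number : int
        1-based position in the protein sequence.
    residue_type : str
        One-letter amino-acid code.
    shift_h : float
        ¹H chemical shift in ppm.
    shift_n : float
        ¹⁵N chemical shift in ppm.
    intensity : float, optional
        Peak height/volume in arbitrary units; ``None`` when not recorded.
    """

    residue_number: int
    residue_type: str
    shift_h: float
    shift_n: float
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValidationError(f"residue_number must be >= 1, got {self.residue_number}")
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_n)):
            raise ValidationError(f"non-finite shift for residue {self.residue_number}")
        if self.intensity is not None and self.intensity < 0:
            raise ValidationError(f"negative intensity for residue {self.residue_number}")


class PeakList:
    """An assigned peak list; unique per residue, prolines simply absent."""

    def __init__(self, label: str, peaks: Iterable[Peak], source_dialect: str = "tsv"):
        self.label = label
        self.source_dialect = source_dialect
        self._by_residue: Dict[int, Peak] = {}
        for peak in peaks:
            if peak.residue_number in self._by_residue:
                raise ValidationError(
                    f"duplicate residue {peak.residue_number} in peak list {label!r}"
                )
            self._by_residue[peak.residue_number] = peak

    @property
    def peaks(self) -> List[Peak]:
        return [self._by_residue[r] for r in sorted(self._by_residue)]

    @property
    def residues(self) -> Set[int]:
        return set(self._by_residue)

    def __len__(self) -> int:
        return len(self._by_residue)

    def __contains__(self, residue_number: int) -> bool:
        return residue_number in self._by_residue

    def __getitem__(self, residue_number: int) -> Peak:
        return self._by_residue[residue_number]

    def get(self, residue_number: int) -> Optional[Peak]:
        return self._by_residue.get(residue_number)

    def __repr__(self) -> str:
        return f"PeakList({self.label!r}, n={len(self)})"


@dataclass
class PeakPairing:
    """Result of matching a reference against a target peak list."""

    pairs: Dict[int, Tuple[Peak, Peak]]
    unmatched_reference: Set[int]
    unmatched_target: Set[int]
    ambiguous: Set[int] = field(default_factory=set)


def weighted_distance(a: Peak, b: Peak) -> float:
    """Weighted ¹H/¹⁵N distance between two peaks (ppm).

    Same functional form as the weighted chemical-shift perturbation:
    ``sqrt(((ΔH)² + (ΔN)²/25) / 2)``; the 1/25 factor rescales the wider
    ¹⁵N dispersion onto the ¹H scale.
    """
    dh = a.shift_h - b.shift_h
    dn = a.shift_n - b.shift_n
    return math.sqrt((dh * dh + dn * dn / 25.0) / 2.0)


def _parse_sparky(lines: Iterable[str], path: str) -> List[Peak]:
    peaks = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0].lower() == "assignment":  # Sparky header line
            continue
        if len(fields) < 3:
            raise PeakFormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
        m = _SPARKY_ASSIGNMENT.match(fields[0])
        if m is None:
            raise PeakFormatError(
                f"{path}:{lineno}: unparsable assignment string {fields[0]!r}"
            )
        try:
            w1 = float(fields[1])  # 15N
            w2 = float(fields[2])  # 1H
            height = float(fields[3]) if len(fields) > 3 else None
        except ValueError as exc:
            raise PeakFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        peaks.append(
            Peak(
                residue_number=int(m.group(2)),
                residue_type=m.group(1).upper(),
                shift_h=w2,
                shift_n=w1,
                intensity=height,
            )
        )
    return peaks


_TSV_COLUMNS = ["residue_number", "residue_type", "shift_n_ppm", "shift_h_ppm", "intensity"]


def _parse_tsv(lines: List[str], path: str) -> List[Peak]:
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _TSV_COLUMNS[:4] if c not in header]
    if missing:
        raise PeakFormatError(f"{path}: missing TSV columns {missing}")
    idx = {c: header.index(c) for c in header}
    peaks = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            intensity_field = (
                fields[idx["intensity"]] if "intensity" in idx and len(fields) > idx["intensity"] else ""
            )
            peaks.append(
                Peak(
                    residue_number=int(fields[idx["residue_number"]]),
                    residue_type=fields[idx["residue_type"]].strip(),
                    shift_h=float(fields[idx["shift_h_ppm"]]),
                    shift_n=float(fields[idx["shift_n_ppm"]]),
                    intensity=float(intensity_field) if intensity_field.strip() else None,
                )
            )
        except (ValueError, IndexError) as exc:
            raise PeakFormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def read_peak_list(path: str | Path, dialect: str = "tsv", label: Optional[str] = None) -> PeakList:
    """Read an assigned peak list from disk.

    Parameters
    ----------
    path : path
        File to read.
    dialect : {"sparky", "tsv"}
        On-disk format.
    label : str, optional
        Label for the resulting list; defaults to the file stem.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "sparky":
        peaks = _parse_sparky(lines, str(path))
    elif dialect == "tsv":
        peaks = _parse_tsv(lines, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return PeakList(label or path.stem, peaks, source_dialect=dialect)


def write_peak_list(peaks: PeakList, path: str | Path, dialect: str = "tsv") -> None:
    """Write a peak list; shifts are emitted with 4 decimal places."""
    path = Path(path)
    fmt = f"{{:.{SHIFT_DECIMALS}f}}"
    lines: List[str] = []
    if dialect == "sparky":
        lines.append(f"{'Assignment':>12} {'w1':>9} {'w2':>9} {'Height':>12}")
        for p in peaks.peaks:
            assignment = f"{p.residue_type}{p.residue_number}N-H"
            height = "" if p.intensity is None else f"{p.intensity:.6g}"
            lines.append(
                f"{assignment:>12} {fmt.format(p.shift_n):>9} {fmt.format(p.shift_h):>9} {height:>12}"
            )
    elif dialect == "tsv":
        lines.append("\t".join(_TSV_COLUMNS))
        for p in peaks.peaks:
            intensity = "" if p.intensity is None else f"{p.intensity:.6g}"
            lines.append(
                "\t".join(
                    [
                        str(p.residue_number),
                        p.residue_type,
                        fmt.format(p.shift_n),
                        fmt.format(p.shift_h),
                        intensity,
                    ]
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def match_peaks(
    reference: PeakList,
    target: PeakList,
    mode: str = "by_assignment",
    max_jump: Optional[float] = None,
) -> PeakPairing:
    """Pair peaks between two spectra.

    ``by_assignment`` pairs identical residue numbers.  ``nearest_trajectory``
    pairs each reference peak with the closest target peak under the weighted
    ¹H/¹⁵N metric, greedily in ascending-distance order, one-to-one, leaving
    candidate pairs farther than ``max_jump`` (ppm) unmatched.  Exact distance
    ties are broken deterministically toward the lower reference residue
    number and flagged in ``ambiguous``.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValidationError("cannot match empty peak lists")
    if mode == "by_assignment":
        shared = reference.residues & target.residues
        return PeakPairing(
            pairs={r: (reference[r], target[r]) for r in sorted(shared)},
            unmatched_reference=reference.residues - shared,
            unmatched_target=target.residues - shared,
        )
    if mode != "nearest_trajectory":
        raise ValueError(f"unknown mode {mode!r}")
    if max_jump is None or max_jump <= 0:
        raise ValidationError("nearest_trajectory requires max_jump > 0")

    candidates = []
    for rp in reference.peaks:
        for tp in target.peaks:
            d = weighted_distance(rp, tp)
            if d <= max_jump:
                candidates.append((d, rp.residue_number, tp.residue_number))
    # greedy ascending distance; ties toward lower reference residue
    candidates.sort()
    pairs: Dict[int, Tuple[Peak, Peak]] = {}
    used_target: Set[int] = set()
    ambiguous: Set[int] = set()
    for i, (d, r, t) in enumerate(candidates):
        if r in pairs or t in used_target:
            continue
        # a tie: the next candidate has the identical distance and competes
        # for the same reference or target peak
        for d2, r2, t2 in candidates[i + 1 :]:
            if d2 > d:
                break
            if (r2 == r or t2 == t) and (r2 not in pairs) and (t2 not in used_target):
                ambiguous.add(r)
        pairs[r] = (reference[r], target[t])
        used_target.add(t)
    matched_targets = {p[1].residue_number for p in pairs.values()}
    return PeakPairing(
        pairs=pairs,
        unmatched_reference=reference.residues - set(pairs),
        unmatched_target=target.residues - matched_targets,
        ambiguous=ambiguous,
    )
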