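import pytest

from ubkit.peaks import Peak, PeakList


@pytest.fixture
def small_peak_list() -> PeakList:
    """Five assigned residues with intensities."""
    return PeakList(
        "ref",
        [
            Peak(8, "L", 8.10, 121.50, 1.0e6),
            Peak(14, "T", 8.72, 121.53, 1.0e6),
            Peak(43, "L", 8.90, 124.10, 8.0e5),
            Peak(44, "I", 9.05, 122.70, 9.0e5),
            Peak(70, "V", 9.20, 127.00, 7.0e5),
        ],
    )


def shifted_copy(peaks: PeakList, label: str, dh: float = 0.0, dn: float = 0.0, residues=None):
    """Copy of a peak list with selected residues displaced by (dh, dn)."""
    moved = []
    for p in peaks.peaks:
        if residues is None or p.residue_number in residues:
            moved.append(
                Peak(p.residue_number, p.residue_type, p.shift_h + dh, p.shift_n + dn, p.intensity)
            )
        else:
            moved.append(p)
    return PeakList(label, moved)
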