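"""MSI calling from five-marker mononucleotide PCR fragment profiles.

The clinical assay amplifies five quasi-monomorphic mononucleotide markers
(NR-21, BAT-26, BAT-25, NR-24, MONO-27) in tumor and matched normal DNA and
compares fragment-length profiles.  A marker is unstable when the tumor
shows a substantial peak at a length well outside the normal profile's
stutter range; a specimen with two or more unstable markers of the five is
MSI positive.

The kit's internal interpretive rules are not public, so the "novel allele"
definition here is explicit and parameterized: a tumor peak (intensity at
least ``intensity_fraction`` of the tumor maximum) at least ``shift_min``
length units away from every normal peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

__all__ = [
    "PROMEGA_MARKERS",
    "MarkerProfile",
    "PcrResult",
    "marker_unstable",
    "call_msi_pcr",
    "DEFAULT_SHIFT_MIN",
    "DEFAULT_INTENSITY_FRACTION",
]

#: the five mononucleotide markers of the Promega MSI analysis panel
PROMEGA_MARKERS = ("NR-21", "BAT-26", "BAT-25", "NR-24", "MONO-27")

#: minimum distance (repeat/length units) from every normal peak for a novel allele
DEFAULT_SHIFT_MIN = 3
#: minimum intensity, as a fraction of the profile maximum, for a peak
DEFAULT_INTENSITY_FRACTION = 0.10

PcrCall = Literal["MSI-positive", "MSI-negative", "indeterminate"]


@dataclass
class MarkerProfile:
    """Tumor and matched-normal fragment-length intensity maps for one marker."""

    marker: str
    tumor: dict[int, float]
    normal: dict[int, float]

    def __post_init__(self) -> None:
        if self.marker not in PROMEGA_MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        for name, profile in (("tumor", self.tumor), ("normal", self.normal)):
            if any(v < 0 for v in profile.values()):
                raise ValueError(f"{self.marker}: negative {name} intensity")

    @property
    def evaluable(self) -> bool:
        return bool(self.tumor) and bool(self.normal)


@dataclass
class PcrResult:
    call: PcrCall
    n_unstable: int
    n_evaluable: int
    unstable_markers: tuple[str, ...]


def _peaks(profile: Mapping[int, float], intensity_fraction: float) -> list[int]:
    """Lengths whose intensity reaches ``intensity_fraction`` of the profile max."""
    if not profile:
        return []
    cutoff = intensity_fraction * max(profile.values())
    return [length for length, inten in profile.items() if inten >= cutoff and inten > 0]


def marker_unstable(
    profile: MarkerProfile,
    shift_min: int = DEFAULT_SHIFT_MIN,
    intensity_fraction: float = DEFAULT_INTENSITY_FRACTION,
) -> bool:
    """True iff the tumor carries a novel allele outside the normal stutter range.

    A novel allele is a tumor peak at a length at least ``shift_min`` units
    from *every* normal peak; peaks within ``shift_min`` of a normal peak are
    attributed to stutter.
    """
    if not profile.evaluable:
        raise ValueError(f"{profile.marker}: empty tumor or normal profile")
    normal_peaks = _peaks(profile.normal, intensity_fraction)
    for length in _peaks(profile.tumor, intensity_fraction):
        if all(abs(length - n) >= shift_min for n in normal_peaks):
            return True
    return False


def call_msi_pcr(
    profiles: Sequence[MarkerProfile],
    shift_min: int = DEFAULT_SHIFT_MIN,
    intensity_fraction: float = DEFAULT_INTENSITY_FRACTION,
    min_unstable: int = 2,
    min_evaluable: int = 2,
) -> PcrResult:
    """Call MSI from the five-marker panel: positive iff >= 2 markers unstable.

    Markers with an empty tumor or normal profile are unevaluable; a
    specimen with fewer than ``min_evaluable`` evaluable markers is
    indeterminate.
    """
    unstable: list[str] = []
    n_evaluable = 0
    for profile in profiles:
        if not profile.evaluable:
            continue
        n_evaluable += 1
        if marker_unstable(profile, shift_min, intensity_fraction):
            unstable.append(profile.marker)
    if n_evaluable < min_evaluable:
        call: PcrCall = "indeterminate"
    elif len(unstable) >= min_unstable:
        call = "MSI-positive"
    else:
        call = "MSI-negative"
    return PcrResult(
        call=call,
        n_unstable=len(unstable),
        n_evaluable=n_evaluable,
        unstable_markers=tuple(unstable),
    )
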