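"""Immunohistochemistry scoring and MLH1 methylation qPCR quantitation.

IHC protein expression is summarized with a quasi-continuous score: each
nuclear staining intensity level (0 = no stain, 1 = faint, 2 = clear coarse
granular stain) is multiplied by the percentage of cells at that level and
the products are summed, giving a score between 0 and 200.  Duplicate
tissue cores are averaged; damaged or missing cores are dropped, and a
sample with no valid core is reported missing.

Methylation-specific qPCR is quantified against a standard curve of known
input quantities: Cq = a + b*log10(quantity) fitted by least squares, then
inverted for the methylated-MLH1, unmethylated-MLH1 and ALUC4 (input
normalization) assays.  Results are expressed as methyl/ALUC4 and
unmethyl/ALUC4 ratios with the s.e.m. across replicates.  A methylation
assay whose Cq is absent or beyond the last standard is reported as "not
detected" with a zero ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IhcObservation",
    "QpcrRun",
    "StandardCurve",
    "AssayQuantity",
    "MethylationReport",
    "ihc_score",
    "score_sample",
    "fit_standard_curve",
    "quantify_methylation",
]

METHYL = "methyl-MLH1"
UNMETHYL = "unmethyl-MLH1"
ALUC4 = "ALUC4"


@dataclass(frozen=True)
class IhcObservation:
    """Percent of cells at each nuclear staining intensity for one core."""

    intensity_percents: Mapping[int, float]

    def __post_init__(self) -> None:
        if not set(self.intensity_percents) <= {0, 1, 2}:
            raise ValueError("intensity levels must be 0, 1 or 2")
        if any(p < 0 for p in self.intensity_percents.values()):
            raise ValueError("percents must be >= 0")


def ihc_score(obs: IhcObservation) -> float:
    """Quasi-continuous IHC score: sum of intensity * percent, in [0, 200].

    Unscored remainder (percents summing below 100) is implicitly
    intensity 0; percents summing above 100 are an input error.
    """
    total = sum(obs.intensity_percents.values())
    if total > 100 + 1e-9:
        raise ValueError(f"intensity percents sum to {total} > 100")
    return float(sum(level * pct for level, pct in obs.intensity_percents.items()))


def score_sample(cores: Sequence[IhcObservation | None]) -> float | None:
    """Average the scores of a sample's valid (non-None) duplicate cores.

    Returns None (sample missing) when no valid core remains.
    """
    scores = [ihc_score(c) for c in cores if c is not None]
    if not scores:
        return None
    return float(np.mean(scores))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Cq = intercept + slope * log10(quantity)."""

    slope: float
    intercept: float
    cq_min: float
    cq_max: float

    def quantity(self, cq: float) -> float:
        return float(10.0 ** ((cq - self.intercept) / self.slope))

    def in_range(self, cq: float, slack: float = 1.0) -> bool:
        return self.cq_min - slack <= cq <= self.cq_max + slack


@dataclass
class QpcrRun:
    """Standards (log10 quantity, Cq) and per-assay sample Cq replicates.

    A missing/undetermined Cq is represented as None (or NaN).
    """

    standards: Sequence[tuple[float, float]]
    samples: Mapping[str, Sequence[float | None]]

    def __post_init__(self) -> None:
        if len({q for q, _ in self.standards}) < 2:
            raise ValueError("standard curve needs >= 2 distinct quantities")
        if any(cq <= 0 for _, cq in self.standards):
            raise ValueError("standard Cq values must be > 0")


@dataclass
class AssayQuantity:
    assay: str
    quantity: float
    sem: float | None        # across replicates; None with < 2 replicates
    detected: bool
    extrapolated: bool


@dataclass
class MethylationReport:
    quantities: dict[str, AssayQuantity]
    ratio_methyl: float
    ratio_unmethyl: float
    ratio_methyl_sem: float | None
    ratio_unmethyl_sem: float | None
    methyl_detected: bool


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    log_q = np.array([q for q, _ in standards], dtype=float)
    cq = np.array([c for _, c in standards], dtype=float)
    if np.allclose(log_q, log_q[0]):
        raise ValueError("singular standard curve: all quantities identical")
    slope, intercept = np.polyfit(log_q, cq, 1)
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        cq_min=float(cq.min()),
        cq_max=float(cq.max()),
    )


def _is_missing(cq: float | None) -> bool:
    return cq is None or (isinstance(cq, float) and math.isnan(cq))


def _quantify_assay(
    assay: str, cqs: Sequence[float | None], curve: StandardCurve
) -> tuple[AssayQuantity, list[float]]:
    valid = [c for c in cqs if not _is_missing(c)]
    # "not detected": no Cq at all, or amplification later than the last
    # (lowest-quantity, highest-Cq) standard plus one cycle of slack
    detected_cqs = [c for c in valid if c <= curve.cq_max + 1.0]
    if not detected_cqs:
        return (
            AssayQuantity(assay=assay, quantity=0.0, sem=None,
                          detected=False, extrapolated=False),
            [],
        )
    quantities = [curve.quantity(c) for c in detected_cqs]
    sem = float(stats.sem(quantities)) if len(quantities) >= 2 else None
    extrapolated = any(not curve.in_range(c) for c in detected_cqs)
    return (
        AssayQuantity(
            assay=assay,
            quantity=float(np.mean(quantities)),
            sem=sem,
            detected=True,
            extrapolated=extrapolated,
        ),
        quantities,
    )


def _ratio(
    num: AssayQuantity, num_reps: list[float], den: AssayQuantity, den_reps: list[float]
) -> tuple[float, float | None]:
    if den.quantity <= 0:
        raise ValueError(f"control assay {den.assay} not detected; ratios undefined")
    if not num.detected:
        return 0.0, None
    ratio = num.quantity / den.quantity
    sem = None
    if len(num_reps) >= 2 and len(num_reps) == len(den_reps):
        per_rep = [n / d for n, d in zip(num_reps, den_reps)]
        sem = float(stats.sem(per_rep))
    return float(ratio), sem


def quantify_methylation(run: QpcrRun) -> MethylationReport:
    """Absolute quantitation by standard curve, expressed relative to ALUC4.

    Fits the standard line, inverts each assay's Cq replicates to input
    quantities, averages replicates (s.e.m. when >= 2), and reports the
    methyl-MLH1/ALUC4 and unmethyl-MLH1/ALUC4 ratios.  Cq values outside
    the standards' Cq range by more than one cycle are flagged as
    extrapolation; a methyl assay with no detectable amplification yields
    ratio 0 and ``methyl_detected=False``.
    """
    curve = fit_standard_curve(run.standards)
    quantities: dict[str, AssayQuantity] = {}
    reps: dict[str, list[float]] = {}
    for assay in (METHYL, UNMETHYL, ALUC4):
        q, r = _quantify_assay(assay, run.samples.get(assay, ()), curve)
        quantities[assay] = q
        reps[assay] = r
    ratio_m, sem_m = _ratio(quantities[METHYL], reps[METHYL],
                            quantities[ALUC4], reps[ALUC4])
    ratio_u, sem_u = _ratio(quantities[UNMETHYL], reps[UNMETHYL],
                            quantities[ALUC4], reps[ALUC4])
    return MethylationReport(
        quantities=quantities,
        ratio_methyl=ratio_m,
        ratio_unmethyl=ratio_u,
        ratio_methyl_sem=sem_m,
        ratio_unmethyl_sem=sem_u,
        methyl_detected=quantities[METHYL].detected,
    )
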