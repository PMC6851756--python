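"""Cross-modality detection accounting and chi-square comparisons.

The reference conflict set plays the role of the manually verified raw-DSA
conflicts.  Each modality's automated detections are matched against it and
summarized with the study's mixed-denominator semantics:

* sensitivity   = detected / reference
* FN rate       = missed / reference                (complements sensitivity)
* FP rate       = spurious / flagged               (flagged = all detections)
* raw-vs-seg FN = raw-visible conflicts the segmentation missed / raw-visible

Pairs of modalities are compared with a 2x2 chi-square on detected/missed
counts (no continuity correction by default) under Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "DetectionTable",
    "ComparisonResult",
    "DetectionMetrics",
    "match_conflicts",
    "detection_metrics",
    "chi_square_compare",
    "sulcal_union",
    "format_percent",
]


@dataclass
class DetectionTable:
    """Per-modality conflict detection counts against the reference set."""

    modality: str
    variant: str = "segmentation"  # raw | segmentation | segmentation+sulcal
    n_reference: int = 0
    n_detected: int = 0
    n_flagged: int = 0
    n_spurious: int = 0
    n_raw_visible: int = 0
    n_raw_missed_by_seg: int = 0
    detected_mask: np.ndarray | None = None  # per-reference-event flags

    def __post_init__(self) -> None:
        if self.n_detected > self.n_reference:
            raise ParameterError("n_detected cannot exceed n_reference")
        if self.n_flagged != self.n_detected + self.n_spurious:
            raise ParameterError("n_flagged must equal n_detected + n_spurious")
        if self.n_raw_missed_by_seg > self.n_raw_visible:
            raise ParameterError("n_raw_missed_by_seg cannot exceed n_raw_visible")

    @property
    def n_missed(self) -> int:
        return self.n_reference - self.n_detected


class DetectionMetrics(NamedTuple):
    sensitivity: Optional[float]      # percent
    fn_rate: Optional[float]          # percent
    fp_rate: Optional[float]          # percent
    raw_seg_fn_rate: Optional[float]  # percent


@dataclass
class ComparisonResult:
    modality_a: str
    modality_b: str
    chi_square: float
    p_value: float
    bonferroni_m: int
    adjusted_alpha: float
    significant: bool
    warnings: list[str] = field(default_factory=list)


def match_conflicts(
    reference_positions: np.ndarray,
    candidate_positions: np.ndarray,
    tolerance: float = 3.0,
    modality: str = "",
    variant: str = "segmentation",
) -> DetectionTable:
    """Greedy nearest-pair matching of candidate events to reference events.

    Pairs are claimed in order of increasing distance; each event matches at
    most once and only within ``tolerance`` mm.  Matched references are
    detected, the rest missed; unmatched candidates are spurious.
    """
    ref = np.atleast_2d(np.asarray(reference_positions, dtype=float)) \
        if np.size(reference_positions) else np.empty((0, 3))
    cand = np.atleast_2d(np.asarray(candidate_positions, dtype=float)) \
        if np.size(candidate_positions) else np.empty((0, 3))
    n_ref, n_cand = ref.shape[0], cand.shape[0]
    detected = np.zeros(n_ref, dtype=bool)
    if n_ref and n_cand:
        dists = np.linalg.norm(ref[:, None, :] - cand[None, :, :], axis=2)
        order = np.argsort(dists, axis=None, kind="stable")
        used_c = np.zeros(n_cand, dtype=bool)
        for flat in order:
            i, j = divmod(int(flat), n_cand)
            if dists[i, j] > tolerance:
                break
            if detected[i] or used_c[j]:
                continue
            detected[i] = True
            used_c[j] = True
    n_det = int(detected.sum())
    return DetectionTable(
        modality=modality,
        variant=variant,
        n_reference=n_ref,
        n_detected=n_det,
        n_flagged=n_cand,
        n_spurious=n_cand - n_det,
        detected_mask=detected,
    )


def detection_metrics(table: DetectionTable) -> DetectionMetrics:
    """Exact percentages with the study's denominators.

    A zero denominator yields ``None`` (an undefined rate, never 0).  Use
    :func:`format_percent` to round for display the way the source tables
    print (nearest integer; one decimal where the integer would hide a
    half-percent).
    """

    def rate(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den else None

    return DetectionMetrics(
        sensitivity=rate(table.n_detected, table.n_reference),
        fn_rate=rate(table.n_missed, table.n_reference),
        fp_rate=rate(table.n_spurious, table.n_flagged),
        raw_seg_fn_rate=rate(table.n_raw_missed_by_seg, table.n_raw_visible),
    )


def format_percent(value: Optional[float], decimals: int = 0) -> Optional[float]:
    """Round half away from zero to the printed precision."""
    if value is None:
        return None
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def chi_square_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]] without correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi_square_compare(
    table_a: DetectionTable,
    table_b: DetectionTable,
    yates: bool = False,
    bonferroni_m: int = 1,
    alpha: float = 0.05,
) -> ComparisonResult:
    """2x2 chi-square on detected/missed counts of two modality variants."""
    a, b = table_a.n_detected, table_a.n_missed
    c, d = table_b.n_detected, table_b.n_missed
    warns: list[str] = []
    n = a + b + c + d
    if n == 0:
        raise ParameterError("both tables are empty")
    expected = np.outer([a + b, c + d], [a + c, b + d]) / n
    if (expected < 1).any():
        warns.append("an expected cell count is below 1; the chi-square approximation is unreliable")
    if yates:
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = n * max(abs(a * d - b * c) - n / 2, 0) ** 2 / denom if denom else 0.0
    else:
        chi2 = chi_square_closed_form(a, b, c, d)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    adj = alpha / bonferroni_m
    return ComparisonResult(
        modality_a=f"{table_a.modality}/{table_a.variant}",
        modality_b=f"{table_b.modality}/{table_b.variant}",
        chi_square=float(chi2),
        p_value=p,
        bonferroni_m=bonferroni_m,
        adjusted_alpha=adj,
        significant=p < adj,
        warnings=warns,
    )


def sulcal_union(
    table: DetectionTable,
    sulcal_flags: Sequence[bool],
) -> DetectionTable:
    """Add the sulcal exclusion zone to a segmentation's detections.

    A reference conflict counts as detected if the segmentation found it or
    it lies inside the sulcal model (the exclusion zone would have forbidden
    the trajectory).  Spurious detections are unchanged.
    """
    flags = np.asarray(sulcal_flags, dtype=bool)
    if table.detected_mask is None:
        raise ParameterError("table lacks per-event detection flags (detected_mask)")
    if flags.shape[0] != table.detected_mask.shape[0]:
        raise ParameterError(
            f"sulcal flag list length {flags.shape[0]} does not match "
            f"{table.detected_mask.shape[0]} reference events"
        )
    union = table.detected_mask | flags
    n_det = int(union.sum())
    return DetectionTable(
        modality=table.modality,
        variant=table.variant + "+sulcal",
        n_reference=table.n_reference,
        n_detected=n_det,
        n_flagged=n_det + table.n_spurious,
        n_spurious=table.n_spurious,
        n_raw_visible=table.n_raw_visible,
        n_raw_missed_by_seg=table.n_raw_missed_by_seg,
        detected_mask=union,
    )


def detection_matrix(tables: Sequence[DetectionTable]) -> pd.DataFrame:
    """Variant x modality sensitivity matrix (percent), Table-1 shaped."""
    rows = {}
    for t in tables:
        rows.setdefault(t.variant, {})[t.modality] = detection_metrics(t).sensitivity
    return pd.DataFrame(rows).T
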