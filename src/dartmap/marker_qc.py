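"""Marker quality filtering and Mendelian segregation tests.

Array markers are retained when they simultaneously satisfy three
inclusive thresholds: scoring reproducibility between technical
replicates (>=95% by default), the cluster-separation quality score Q
(>=65, percent of signal variance between the presence/absence clusters)
and the marker call rate (>=75% of targets scored).

Segregation classes are determined from the parental scores, never by
best fit among candidate ratios: a dominant fragment present in exactly
one parent is a 1:1 pseudo-testcross from that parent; present in both
parents it segregates 3:1; codominant markers are fully informative
(1:1:1:1) with four distinct parental alleles or 1:2:1 when both parents
carry the same heterozygous genotype.  Adherence is tested with a
Pearson chi-square goodness-of-fit (no continuity correction) on the
non-missing progeny scores, with rejection when p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import (
    F2_INTERCROSS,
    FULLY_INFORMATIVE,
    INTERCROSS,
    MISSING,
    TESTCROSS_P1,
    TESTCROSS_P2,
)


class MarkerValidationError(ValueError):
    """A quality metric is outside its valid range."""


class InconsistentMarkerError(ValueError):
    """Progeny segregate although neither parent carries the fragment."""


class AmbiguousParentError(ValueError):
    """Parental scores do not determine a segregation class."""


@dataclass
class MarkerQualityRecord:
    """One array marker: progeny scores plus array quality metrics."""

    marker_id: str
    scores: list[str]
    reproducibility: float
    q_score: float
    call_rate: float | None = None
    parent_scores: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        recomputed = self.recomputed_call_rate()
        if self.call_rate is None:
            self.call_rate = recomputed
        if not 0.0 <= self.reproducibility <= 1.0:
            raise MarkerValidationError(
                f"{self.marker_id}: reproducibility outside [0,1]"
            )
        if not 0.0 <= self.call_rate <= 1.0:
            raise MarkerValidationError(f"{self.marker_id}: call_rate outside [0,1]")

    def recomputed_call_rate(self) -> float:
        scored = sum(1 for s in self.scores if s != MISSING)
        return scored / len(self.scores) if self.scores else 0.0

    def nonmissing(self) -> list[str]:
        return [s for s in self.scores if s != MISSING]


@dataclass
class QCThresholds:
    min_reproducibility: float = 0.95
    min_q: float = 65.0
    min_call_rate: float = 0.75
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_reproducibility <= 1.0:
            raise MarkerValidationError("min_reproducibility outside [0,1]")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise MarkerValidationError("min_call_rate outside [0,1]")
        if not 0.0 < self.alpha < 1.0:
            raise MarkerValidationError("alpha outside (0,1)")


@dataclass
class FilterResult:
    """Pass/fail partition with per-criterion and joint (Venn) tallies."""

    passed: list[str]
    failed: list[str]
    n_pass_reproducibility: int
    n_pass_q: int
    n_pass_call_rate: int
    venn: dict[tuple[bool, bool, bool], int]


def filter_markers(
    records: list[MarkerQualityRecord], thresholds: QCThresholds | None = None
) -> FilterResult:
    """Partition markers by the three quality criteria (all inclusive >=).

    The Venn tally keys are (reproducibility ok, Q ok, call rate ok).
    """
    if not records:
        raise ValueError("no marker records")
    thr = thresholds or QCThresholds()
    passed, failed = [], []
    venn: dict[tuple[bool, bool, bool], int] = {}
    n_rep = n_q = n_cr = 0
    for rec in records:
        ok_rep = rec.reproducibility >= thr.min_reproducibility
        ok_q = rec.q_score >= thr.min_q
        ok_cr = rec.call_rate >= thr.min_call_rate
        n_rep += ok_rep
        n_q += ok_q
        n_cr += ok_cr
        venn[(ok_rep, ok_q, ok_cr)] = venn.get((ok_rep, ok_q, ok_cr), 0) + 1
        (passed if ok_rep and ok_q and ok_cr else failed).append(rec.marker_id)
    return FilterResult(
        passed=passed,
        failed=failed,
        n_pass_reproducibility=n_rep,
        n_pass_q=n_q,
        n_pass_call_rate=n_cr,
        venn=venn,
    )


@dataclass
class SegregationResult:
    marker_id: str
    seg_class: str
    chi_square: float
    df: int
    p_value: float
    mendelian: bool
    observed: dict[str, int] = field(default_factory=dict)


_DOMINANT_PARENTS = {
    ("1", "0"): TESTCROSS_P1,
    ("0", "1"): TESTCROSS_P2,
    ("1", "1"): INTERCROSS,
}


def _expected_model(record: MarkerQualityRecord) -> tuple[str, list[str], list[float]]:
    """Segregation class, progeny categories and expected ratio weights."""
    p1, p2 = record.parent_scores
    if p1 in ("0", "1") and p2 in ("0", "1"):
        if (p1, p2) == ("0", "0"):
            if any(s == "1" for s in record.nonmissing()):
                raise InconsistentMarkerError(
                    f"{record.marker_id}: progeny segregate but neither parent "
                    "carries the fragment"
                )
            raise AmbiguousParentError(f"{record.marker_id}: monomorphic null marker")
        cls = _DOMINANT_PARENTS[(p1, p2)]
        if cls == INTERCROSS:
            return cls, ["1", "0"], [3.0, 1.0]
        return cls, ["1", "0"], [1.0, 1.0]
    if {p1, p2} == {"ab", "cd"} or (p1 == "ab" and p2 == "cd"):
        return FULLY_INFORMATIVE, ["ac", "ad", "bc", "bd"], [1.0] * 4
    if p1 == p2 == "ab":
        return F2_INTERCROSS, ["aa", "ab", "bb"], [1.0, 2.0, 1.0]
    raise AmbiguousParentError(
        f"{record.marker_id}: parent scores {record.parent_scores!r} do not "
        "determine a segregation class"
    )


def classify_and_test(
    record: MarkerQualityRecord, alpha: float = 0.01, min_scored: int = 20
) -> SegregationResult:
    """Classify a marker from its parental scores and chi-square test it.

    Missing progeny scores are dropped from the test denominator.
    Raises :class:`InconsistentMarkerError` for null x null parents with
    segregating progeny and :class:`AmbiguousParentError` when the
    parental data do not determine a class.
    """
    scored = record.nonmissing()
    if len(scored) < min_scored:
        raise ValueError(
            f"{record.marker_id}: only {len(scored)} scored progeny (< {min_scored})"
        )
    cls, categories, weights = _expected_model(record)
    counts = {c: 0 for c in categories}
    for s in scored:
        if s not in counts:
            raise MarkerValidationError(
                f"{record.marker_id}: unexpected progeny code {s!r} for class {cls}"
            )
        counts[s] += 1
    observed = np.array([counts[c] for c in categories], dtype=float)
    expected = np.array(weights) / sum(weights) * observed.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(categories) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        marker_id=record.marker_id,
        seg_class=cls,
        chi_square=chi2,
        df=df,
        p_value=p,
        mendelian=p >= alpha,
        observed={c: int(counts[c]) for c in categories},
    )


def records_from_cross(genotypes: pd.DataFrame, quality: pd.DataFrame) -> list[MarkerQualityRecord]:
    """Build quality records from the synthetic-data genotype dialect."""
    progeny_cols = [c for c in genotypes.columns if c not in ("P1", "P2")]
    records = []
    for mid, row in genotypes.iterrows():
        q = quality.loc[mid]
        records.append(
            MarkerQualityRecord(
                marker_id=str(mid),
                scores=[str(row[c]) for c in progeny_cols],
                reproducibility=float(q.reproducibility),
                q_score=float(q.q_score),
                parent_scores=(str(row["P1"]), str(row["P2"])),
            )
        )
    return records


def qc_report(
    records: list[MarkerQualityRecord],
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-marker QC table: metrics, filter flags, class and chi-square.

    Markers failing classification carry a status code instead of a class
    (``inconsistent_parents`` / ``ambiguous_parents`` / ``too_few_scored``)
    and are never flagged usable.
    """
    thr = thresholds or QCThresholds()
    filt = filter_markers(records, thr)
    passed = set(filt.passed)
    rows = []
    for rec in records:
        entry = {
            "marker_id": rec.marker_id,
            "reproducibility": rec.reproducibility,
            "q_score": rec.q_score,
            "call_rate": rec.call_rate,
            "quality_pass": rec.marker_id in passed,
            "seg_class": "",
            "chi_square": np.nan,
            "df": 0,
            "p_value": np.nan,
            "mendelian": False,
            "status": "ok",
        }
        try:
            res = classify_and_test(rec, alpha=thr.alpha)
            entry.update(
                seg_class=res.seg_class,
                chi_square=res.chi_square,
                df=res.df,
                p_value=res.p_value,
                mendelian=res.mendelian,
            )
        except InconsistentMarkerError:
            entry["status"] = "inconsistent_parents"
        except AmbiguousParentError:
            entry["status"] = "ambiguous_parents"
        except ValueError:
            entry["status"] = "too_few_scored"
        entry["usable"] = bool(
            entry["quality_pass"] and entry["mendelian"] and entry["status"] == "ok"
        )
        rows.append(entry)
    return pd.DataFrame(rows).set_index("marker_id")
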