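"""Cohort filtering and extraction of ictal / pre-ictal / baseline periods.

Cohort rule: seizures labeled FBTCS (focal to bilateral tonic-clonic)
are excluded first, then every person with fewer than ``min_seizures``
remaining electrographic seizures is dropped entirely — the analysis
needs a representative per-person sample of seizures.

Period arithmetic, for a seizure with onset ``o`` and duration ``d``
(seconds, relative to recording start):

* ictal      ``[o + 2, o + d - 2]`` — 2 s trimmed from each end to
  avoid transition phenomena at electrographic onset and offset;
* pre-ictal  ``[o - 60, o - 2]`` — the minute preceding onset, with
  the final 2 s trimmed for the same reason (58 s long);
* baseline   ``[o - 360, o - 300]`` — a 1-min reference window ending
  5 min before onset, far enough from the seizure to stand in for
  interictal activity.

Pre-ictal/baseline windows that would start before the recording or
overlap another seizure's ictal interval are skipped (and logged), as
are seizures whose trimmed ictal period is shorter than the minimum
the spectral estimator accepts (default 2 s, i.e. duration <= 6 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import Recording, SeizureAnnotation

__all__ = [
    "AnalysisPeriod", "Exclusion",
    "ICTAL_TRIM_S", "PREICTAL_WINDOW", "BASELINE_WINDOW",
    "filter_cohort", "extract_periods", "period_bounds",
]

ICTAL_TRIM_S = 2.0
PREICTAL_WINDOW = (-60.0, -2.0)    # relative to onset
BASELINE_WINDOW = (-360.0, -300.0)  # relative to onset


@dataclass(frozen=True)
class AnalysisPeriod:
    """A trimmed analysis segment bound to one seizure."""

    person_id: str
    seizure_id: str
    kind: str          # "ictal" | "preictal" | "baseline"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("ictal", "preictal", "baseline"):
            raise ValueError(f"unknown period kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ValueError(f"empty period [{self.start_s}, {self.end_s}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Exclusion:
    """One logged exclusion with its reason."""

    person_id: str
    seizure_id: str | None
    stage: str      # "cohort" | "period"
    reason: str

    def __str__(self) -> str:
        sid = self.seizure_id or "*"
        return f"[{self.stage}] {self.person_id}/{sid}: {self.reason}"


def period_bounds(onset_s: float, duration_s: float, kind: str) -> tuple[float, float]:
    """Closed-form bounds of one period kind for a given seizure."""
    if kind == "ictal":
        return onset_s + ICTAL_TRIM_S, onset_s + duration_s - ICTAL_TRIM_S
    if kind == "preictal":
        return onset_s + PREICTAL_WINDOW[0], onset_s + PREICTAL_WINDOW[1]
    if kind == "baseline":
        return onset_s + BASELINE_WINDOW[0], onset_s + BASELINE_WINDOW[1]
    raise ValueError(f"unknown period kind {kind!r}")


def filter_cohort(
    annos: Sequence[SeizureAnnotation],
    min_seizures: int = 10,
) -> tuple[list[SeizureAnnotation], list[Exclusion]]:
    """Apply the cohort inclusion rules; returns (kept, exclusion log).

    Order matters: FBTCS removal happens before the per-person count so
    the minimum applies to electrographic seizures only. Idempotent.
    """
    log: list[Exclusion] = []
    if not annos:
        warnings.warn("filter_cohort: empty annotation list", stacklevel=2)
        return [], []

    electrographic: list[SeizureAnnotation] = []
    for a in annos:
        if a.label == "FBTCS":
            log.append(Exclusion(a.person_id, a.seizure_id, "cohort", "FBTCS excluded"))
        else:
            electrographic.append(a)

    counts: dict[str, int] = {}
    for a in electrographic:
        counts[a.person_id] = counts.get(a.person_id, 0) + 1

    kept: list[SeizureAnnotation] = []
    low = {p for p, n in counts.items() if n < min_seizures}
    for a in electrographic:
        if a.person_id in low:
            log.append(Exclusion(
                a.person_id, a.seizure_id, "cohort",
                f"below minimum ({counts[a.person_id]} < {min_seizures} electrographic seizures)",
            ))
        else:
            kept.append(a)
    return kept, log


def extract_periods(
    rec: Recording,
    annos: Iterable[SeizureAnnotation],
    min_ictal_s: float = 2.0,
) -> tuple[list[AnalysisPeriod], list[Exclusion]]:
    """Carve the recording timeline into analysis periods per seizure.

    Returns (periods, exclusion log). Skips are logged, never raised:
    a seizure without a usable ictal period contributes nothing; a
    missing pre-ictal/baseline window drops only that window.
    """
    pid = rec.person_id
    events = sorted((a for a in annos if a.person_id == pid), key=lambda a: a.onset_s)
    ictal_intervals = [(a.seizure_id, a.onset_s, a.end_s) for a in events]
    rec_dur = rec.duration_s

    periods: list[AnalysisPeriod] = []
    log: list[Exclusion] = []

    def collides(start: float, end: float, own_id: str) -> str | None:
        for sid, s0, s1 in ictal_intervals:
            if sid != own_id and start < s1 and end > s0:
                return sid
        return None

    for a in events:
        if a.end_s > rec_dur + 1e-9:
            log.append(Exclusion(pid, a.seizure_id, "period",
                                 f"seizure extends past recording end ({a.end_s:g} > {rec_dur:g} s)"))
            continue
        i0, i1 = period_bounds(a.onset_s, a.duration_s, "ictal")
        if i1 - i0 < min_ictal_s:
            log.append(Exclusion(pid, a.seizure_id, "period",
                                 f"trimmed ictal period {max(i1 - i0, 0):g} s "
                                 f"below minimum {min_ictal_s:g} s"))
            continue
        periods.append(AnalysisPeriod(pid, a.seizure_id, "ictal", i0, i1))

        for kind in ("preictal", "baseline"):
            s, e = period_bounds(a.onset_s, a.duration_s, kind)
            if s < 0:
                log.append(Exclusion(pid, a.seizure_id, "period",
                                     f"{kind} window starts before recording ({s:g} s)"))
                continue
            other = collides(s, e, a.seizure_id)
            if other is not None:
                log.append(Exclusion(pid, a.seizure_id, "period",
                                     f"{kind} window overlaps ictal interval of {other}"))
                continue
            periods.append(AnalysisPeriod(pid, a.seizure_id, kind, s, e))
    return periods, log
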