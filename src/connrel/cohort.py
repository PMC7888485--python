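"""Cohort container shared by the synthetic generator, loaders and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import ParcellatedRun

SESSIONS = (1, 2)


@dataclass
class SubjectData:
    """All runs of one subject, keyed by session (1 or 2)."""

    subject_id: str
    sessions: dict[int, list[ParcellatedRun]] = field(default_factory=dict)

    def runs(self, session: int) -> list[ParcellatedRun]:
        return self.sessions[session]


@dataclass
class Cohort:
    """A set of subjects, each with runs split across two sessions."""

    subjects: list[SubjectData]
    truth: object | None = None  # CohortTruth for synthetic cohorts

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def region_names(self) -> list[str]:
        first = self.subjects[0].sessions[SESSIONS[0]][0]
        return first.region_names

    def subset(self, subject_ids: list[str]) -> "Cohort":
        wanted = set(subject_ids)
        kept = [s for s in self.subjects if s.subject_id in wanted]
        missing = wanted - {s.subject_id for s in kept}
        if missing:
            raise KeyError(f"unknown subject ids: {sorted(missing)}")
        return Cohort(subjects=kept, truth=self.truth)
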