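"""Pedigree container.

A pedigree is a list of records ``(id, father, mother, sex, generation)``
topologically ordered by generation: parents always carry a strictly smaller
generation index than their offspring.  Founders have both parents missing;
non-founders have both parents recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = ["PedigreeRecord", "Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unknown parent, cycle, duplicate id)."""


class PedigreeRecord(NamedTuple):
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"
    generation: int


@dataclass
class Pedigree:
    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, rec in enumerate(self.records):
            if rec.individual_id in self._index:
                raise PedigreeError(f"duplicate individual id {rec.individual_id!r}")
            self._index[rec.individual_id] = i
        self.validate()

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    def is_founder(self, individual_id: str) -> bool:
        rec = self.records[self._index[individual_id]]
        return rec.father_id is None and rec.mother_id is None

    @property
    def founder_ids(self) -> list[str]:
        return [r.individual_id for r in self.records
                if r.father_id is None and r.mother_id is None]

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        rec = self.records[self._index[individual_id]]
        return rec.father_id, rec.mother_id

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise PedigreeError on violation."""
        for rec in self.records:
            has_f, has_m = rec.father_id is not None, rec.mother_id is not None
            if has_f != has_m:
                raise PedigreeError(
                    f"{rec.individual_id!r}: exactly one parent recorded; "
                    "founders must have none, non-founders both")
            if rec.generation < 0:
                raise PedigreeError(f"{rec.individual_id!r}: negative generation")
            for role, pid in (("father", rec.father_id), ("mother", rec.mother_id)):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"{rec.individual_id!r}: unknown {role} {pid!r}")
                parent = self.records[self._index[pid]]
                if parent.generation >= rec.generation:
                    raise PedigreeError(
                        f"{rec.individual_id!r}: {role} {pid!r} has generation "
                        f"{parent.generation} >= {rec.generation} (not topologically "
                        "ordered)")
            if rec.sex not in ("male", "female"):
                raise PedigreeError(f"{rec.individual_id!r}: invalid sex {rec.sex!r}")

    def families(self) -> list[int]:
        """Connected-component label per record (union over parent edges)."""
        parent = list(range(len(self.records)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for i, rec in enumerate(self.records):
            for pid in (rec.father_id, rec.mother_id):
                if pid is not None:
                    union(i, self._index[pid])
        roots: dict[int, int] = {}
        labels = []
        for i in range(len(self.records)):
            r = find(i)
            labels.append(roots.setdefault(r, len(roots)))
        return labels
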