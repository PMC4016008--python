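"""Pedigree representation, genetic map, and PED/FAM text I/O.

A pedigree is a directed acyclic family graph.  Founders are members with
both parents absent; every named parent must itself be a member.  Sex and
affection status follow the 6-column PED/FAM convention (sex 1=male,
2=female, 0=unknown; phenotype 2=affected, 1=unaffected, 0=unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Member",
    "Pedigree",
    "GeneticMap",
    "PedigreeError",
    "read_ped",
    "write_ped",
    "hfm_pedigree",
]

SEXES = ("male", "female", "unknown")
AFFECTION = ("yes", "no", "unknown")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unknown member ids."""


@dataclass(frozen=True)
class Member:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    affected: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id}")
        if self.affected not in AFFECTION:
            raise PedigreeError(f"invalid affection {self.affected!r} for {self.id}")

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """An immutable family graph with validation and topological ordering."""

    def __init__(self, members: Iterable[Member], family_id: str = "FAM1"):
        self.family_id = family_id
        self._members: dict[str, Member] = {}
        for m in members:
            if m.id in self._members:
                raise PedigreeError(f"duplicate member id {m.id!r}")
            self._members[m.id] = m
        if not self._members:
            raise PedigreeError("pedigree has no members")
        self._validate()
        self._topo = self._topological_order()

    def _validate(self) -> None:
        for m in self._members.values():
            for parent, role, want_sex in (
                (m.father, "father", "male"),
                (m.mother, "mother", "female"),
            ):
                if parent is None:
                    continue
                if parent not in self._members:
                    raise PedigreeError(f"{role} {parent!r} of {m.id!r} is not a member")
                psex = self._members[parent].sex
                if psex not in ("unknown", want_sex):
                    raise PedigreeError(
                        f"{role} {parent!r} of {m.id!r} has sex {psex!r}"
                    )
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(
                    f"{m.id!r} has exactly one named parent; need both or neither"
                )
        if not any(m.is_founder for m in self._members.values()):
            raise PedigreeError("pedigree has no founder")

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 on stack, 2 done

        def visit(mid: str, stack: list[str]) -> None:
            st = state.get(mid, 0)
            if st == 2:
                return
            if st == 1:
                raise PedigreeError(f"pedigree graph has a cycle through {mid!r}")
            state[mid] = 1
            m = self._members[mid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent, stack + [mid])
            state[mid] = 2
            order.append(mid)

        for mid in self._members:
            visit(mid, [])
        return order

    # -- accessors ---------------------------------------------------------

    def __contains__(self, mid: str) -> bool:
        return mid in self._members

    def __iter__(self) -> Iterator[Member]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def member(self, mid: str) -> Member:
        try:
            return self._members[mid]
        except KeyError:
            raise PedigreeError(f"unknown member id {mid!r}") from None

    @property
    def members(self) -> list[Member]:
        return list(self._members.values())

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self._members.values() if m.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        """Non-founders in topological (parents-first) order."""
        return [mid for mid in self._topo if not self._members[mid].is_founder]

    def topological_order(self) -> list[str]:
        return list(self._topo)

    def ancestors(self, mid: str) -> set[str]:
        """All strict ancestors of *mid*."""
        out: set[str] = set()
        stack = [mid]
        while stack:
            m = self._members[stack.pop()]
            for parent in (m.father, m.mother):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def affected_ids(self) -> list[str]:
        return [m.id for m in self._members.values() if m.affected == "yes"]


@dataclass(frozen=True)
class GeneticMap:
    """Linear genetic map: physical chromosome lengths plus a cM/Mb rate.

    The default rate of 1 cM per Mb makes genetic length in centimorgans
    numerically equal to physical length in megabases.
    """

    chromosomes: tuple[tuple[str, int], ...]
    map_rate: float = 1.0  # cM per Mb

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genetic map needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.map_rate < 0:
            raise ValueError("map_rate must be non-negative")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_bp(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def length_cm(self, chrom: str) -> float:
        return self.length_bp(chrom) * self.map_rate / 1e6

    def length_morgans(self, chrom: str) -> float:
        return self.length_cm(chrom) / 100.0

    def bp_to_morgans(self, bp: float) -> float:
        return bp * self.map_rate / 1e8

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)


# -- PED/FAM I/O -----------------------------------------------------------

_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_CODE_TO_SEX = {v: k for k, v in _SEX_TO_CODE.items()}
_AFF_TO_CODE = {"yes": "2", "no": "1", "unknown": "0"}
_CODE_TO_AFF = {v: k for k, v in _AFF_TO_CODE.items()}


def write_ped(ped: Pedigree, path) -> None:
    """Write a 6-column whitespace-separated PED/FAM file ("0" = absent)."""
    with open(path, "w") as fh:
        for m in ped:
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        m.id,
                        m.father or "0",
                        m.mother or "0",
                        _SEX_TO_CODE[m.sex],
                        _AFF_TO_CODE[m.affected],
                    ]
                )
                + "\n"
            )


def read_ped(path) -> Pedigree:
    members = []
    family_id = "FAM1"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"PED line has {len(fields)} < 6 columns: {line!r}")
            fam, mid, father, mother, sex, phen = fields[:6]
            family_id = fam
            members.append(
                Member(
                    id=mid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=_CODE_TO_SEX.get(sex, "unknown"),
                    affected=_CODE_TO_AFF.get(phen, "unknown"),
                )
            )
    return Pedigree(members, family_id=family_id)


def hfm_pedigree() -> Pedigree:
    """The bundled five-generation hemifacial-microsomia kinship.

    Five affected relatives span eight meioses: the proband (V.3), her
    mother (IV.3), grandmother (III.1), cousin (V.2, through the unaffected
    obligate-carrier uncle IV.2), and the grandmother's first cousin III.3
    (the proband's first cousin twice removed), connected through the
    generation-I couple.
    """
    return Pedigree(
        [
            Member("I.1", sex="female", affected="yes"),
            Member("I.2", sex="male"),
            Member("II.1", "I.2", "I.1", sex="male"),
            Member("II.2", sex="female"),
            Member("II.3", "I.2", "I.1", sex="female"),
            Member("II.4", sex="male"),
            Member("III.1", "II.1", "II.2", sex="female", affected="yes"),
            Member("III.2", sex="male"),
            Member("III.3", "II.4", "II.3", sex="male", affected="yes"),
            Member("IV.1", sex="female"),
            Member("IV.2", "III.2", "III.1", sex="male", affected="no"),
            Member("IV.3", "III.2", "III.1", sex="female", affected="yes"),
            Member("IV.4", sex="male"),
            Member("V.2", "IV.2", "IV.1", sex="male", affected="yes"),
            Member("V.3", "IV.4", "IV.3", sex="female", affected="yes"),
        ],
        family_id="HFM",
    )
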