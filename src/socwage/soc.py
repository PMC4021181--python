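"""Tiered standard occupational classification codes.

Occupation codes are short digit strings in which each additional digit
refines the classification: 1 digit = major group, 2 = sub-major group,
3 = minor group, 4 = unit group.  A coarser ancestor of a code is simply
a prefix, so the whole hierarchy is derivable from the unit codes alone
and any digit-coded tiered scheme (SOC2000, ISCO-like) works unchanged.

Only the minor and unit tiers carry random effects in the wage models;
the coarser tiers are represented for completeness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Tier",
    "OccupationCode",
    "ClassificationTable",
    "MalformedCodeError",
    "parse_code",
    "ancestor",
]


class MalformedCodeError(ValueError):
    """Raised for occupation code strings that are not 1-4 decimal digits."""


class Tier(enum.IntEnum):
    """Classification tier; the integer value equals the code length."""

    MAJOR = 1
    SUB_MAJOR = 2
    MINOR = 3
    UNIT = 4


@dataclass(frozen=True, order=True)
class OccupationCode:
    """A validated occupation code; tier is implied by string length."""

    code: str

    def __post_init__(self) -> None:
        if not (self.code.isdigit() and 1 <= len(self.code) <= 4):
            raise MalformedCodeError(
                f"malformed occupation code: {self.code!r} "
                "(expected 1-4 decimal digits)"
            )

    @property
    def tier(self) -> Tier:
        return Tier(len(self.code))

    def ancestor(self, tier: Tier) -> "OccupationCode":
        """Return this code's ancestor at ``tier`` (a prefix of the code).

        ``tier`` must be coarser than or equal to this code's own tier;
        asking for a finer tier is an error because a code cannot be
        refined without extra information.
        """
        tier = Tier(tier)
        if tier > self.tier:
            raise ValueError(
                f"cannot derive tier {tier.name} from the coarser code "
                f"{self.code!r} (tier {self.tier.name})"
            )
        return OccupationCode(self.code[: int(tier)])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_code(raw: str) -> OccupationCode:
    """Parse a raw string (whitespace tolerated) into an OccupationCode."""
    if raw is None:
        raise MalformedCodeError("malformed occupation code: None")
    stripped = str(raw).strip()
    if not stripped:
        raise MalformedCodeError(f"malformed occupation code: {raw!r} (empty)")
    return OccupationCode(stripped)


def ancestor(code: OccupationCode, tier: Tier) -> OccupationCode:
    """Functional form of :meth:`OccupationCode.ancestor`."""
    return code.ancestor(tier)


@dataclass(frozen=True)
class ClassificationTable:
    """The set of unit-tier codes of a classification, with optional labels.

    The minor/sub-major/major structure is implied by code prefixes, so a
    table is fully specified by its unit codes.
    """

    units: tuple[OccupationCode, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for u in self.units:
            if u.tier is not Tier.UNIT:
                raise ValueError(f"classification entry {u.code!r} is not unit tier")
            if u.code in seen:
                raise ValueError(f"duplicate unit code {u.code!r}")
            seen.add(u.code)

    @classmethod
    def from_codes(cls, codes: Iterable[str], labels: Mapping[str, str] | None = None
                   ) -> "ClassificationTable":
        units = tuple(sorted({parse_code(c) for c in codes}))
        return cls(units=units, labels=dict(labels or {}))

    @classmethod
    def from_file(cls, path: str | Path, sep: str = ",") -> "ClassificationTable":
        """Read a two-column (unit_code, label) delimited text file.

        A header row is required; lines starting with ``#`` are ignored.
        """
        codes: list[str] = []
        labels: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise ValueError(f"empty classification file: {path}")
        for ln in lines[1:]:  # skip header
            parts = ln.split(sep)
            code = parts[0].strip()
            codes.append(code)
            if len(parts) > 1:
                labels[code] = parts[1].strip()
        return cls.from_codes(codes, labels)

    def to_file(self, path: str | Path, sep: str = ",") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"unit_code{sep}label\n")
            for u in self.units:
                fh.write(f"{u.code}{sep}{self.labels.get(u.code, '')}\n")

    @property
    def unit_codes(self) -> list[str]:
        return sorted(u.code for u in self.units)

    @property
    def minor_codes(self) -> list[str]:
        return sorted({u.ancestor(Tier.MINOR).code for u in self.units})

    def group_index(self) -> dict[str, tuple[int, int]]:
        """Map each unit code to dense, deterministic (minor_id, unit_id).

        Ids are consecutive integers assigned in lexicographic code order,
        so the mapping is reproducible given the table.  Units sharing a
        3-digit prefix share a minor id (nesting by prefix).
        """
        if not self.units:
            raise ValueError("empty classification table")
        unit_codes = self.unit_codes
        minor_codes = self.minor_codes
        minor_id = {m: i for i, m in enumerate(minor_codes)}
        return {
            u: (minor_id[u[:3]], j)
            for j, u in enumerate(unit_codes)
        }
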