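"""Family and rearrangement metadata: breakpoints, pedigree, genotypes.

A case consists of a couple in which one partner carries a balanced
chromosomal rearrangement (reciprocal translocation, Robertsonian
translocation, or inversion), plus one typed relative used to phase the
carrier's haplotypes around the breakpoints: either a parent of the
carrier ("grandparent" of the foetus) or an existing child of the couple
("sibling" of the foetus; "child" is accepted as a synonym).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genome import is_acrocentric

__all__ = [
    "Breakpoint",
    "Rearrangement",
    "Pedigree",
    "GenotypeSet",
    "MISSING",
    "read_breakpoints_bed",
    "write_breakpoints_bed",
]

RearrangementKind = Literal["reciprocal_translocation", "robertsonian", "inversion"]
ParentID = Literal["mother", "father"]

#: missing-genotype sentinel in dosage coding (0 = hom ref, 1 = het, 2 = hom alt)
MISSING = -1


@dataclass(frozen=True)
class Breakpoint:
    """A rearrangement breakpoint as a 0-based half-open genomic interval."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Rearrangement:
    """A balanced structural rearrangement carried by one parent.

    ``breakpoints`` are explicit genomic intervals (no cytogenetic-band
    parsing): two on distinct chromosomes for a reciprocal translocation,
    two pericentromeric intervals on distinct acrocentric chromosomes for
    a Robertsonian translocation, and two on one chromosome for an
    inversion.
    """

    kind: RearrangementKind
    breakpoints: tuple[Breakpoint, ...]
    carrier_parent: ParentID
    carrier_origin: str = "unknown"  # maternal_grandparent | paternal_grandparent | unknown

    def __post_init__(self) -> None:
        if self.kind not in ("reciprocal_translocation", "robertsonian", "inversion"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.carrier_parent not in ("mother", "father"):
            raise ValueError(f"carrier_parent must be mother|father, got {self.carrier_parent!r}")
        if len(self.breakpoints) != 2:
            raise ValueError(f"{self.kind} requires exactly 2 breakpoints")
        chroms = [b.chrom for b in self.breakpoints]
        if self.kind == "inversion":
            if chroms[0] != chroms[1]:
                raise ValueError("inversion breakpoints must share one chromosome")
        else:
            if chroms[0] == chroms[1]:
                raise ValueError(f"{self.kind} breakpoints must be on distinct chromosomes")
        if self.kind == "robertsonian":
            for c in chroms:
                if not is_acrocentric(c):
                    raise ValueError(f"Robertsonian breakpoint on non-acrocentric {c}")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(b.chrom for b in self.breakpoints))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "carrier_parent": self.carrier_parent,
            "carrier_origin": self.carrier_origin,
            "breakpoints": [
                {"id": b.id, "chrom": b.chrom, "start": b.start, "end": b.end}
                for b in self.breakpoints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rearrangement":
        return cls(
            kind=d["kind"],
            breakpoints=tuple(
                Breakpoint(b["id"], b["chrom"], int(b["start"]), int(b["end"]))
                for b in d["breakpoints"]
            ),
            carrier_parent=d["carrier_parent"],
            carrier_origin=d.get("carrier_origin", "unknown"),
        )


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Pedigree:
    """The typed samples of a case and the role of the phasing reference.

    ``reference_role`` is "grandparent" (a parent of the carrier parent),
    or "sibling"/"child" (an existing child of the couple).
    ``reference_carrier_status`` comes from the reference's karyotype and
    is required for child/sibling references and for Hap0 labelling.
    """

    mother: str
    father: str
    reference: str
    reference_role: str
    reference_carrier_status: str | None = None

    def __post_init__(self) -> None:
        if self.reference_role not in ("grandparent", "sibling", "child"):
            raise PedigreeError(f"unknown reference_role {self.reference_role!r}")
        if self.reference_carrier_status not in (None, "carrier", "non_carrier"):
            raise PedigreeError(
                f"reference_carrier_status must be carrier|non_carrier, "
                f"got {self.reference_carrier_status!r}"
            )
        if self.reference_role in ("sibling", "child") and self.reference_carrier_status is None:
            raise PedigreeError(
                "reference_carrier_status is required when the reference is a child/sibling"
            )

    @property
    def is_offspring_reference(self) -> bool:
        return self.reference_role in ("sibling", "child")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mother": self.mother,
                    "father": self.father,
                    "reference": self.reference,
                    "reference_role": self.reference_role,
                    "reference_carrier_status": self.reference_carrier_status,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "Pedigree":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mother=d["mother"],
            father=d["father"],
            reference=d["reference"],
            reference_role=d["reference_role"],
            reference_carrier_status=d.get("reference_carrier_status"),
        )


@dataclass
class GenotypeSet:
    """Diploid genotypes of mother, father and reference at panel SNPs.

    ``df`` has columns ``chrom, pos, mother, father, reference`` with
    dosage coding 0/1/2 and :data:`MISSING` (−1) for no-calls, row-aligned
    with the case panel.
    """

    df: pd.DataFrame = field(repr=False)

    SAMPLES = ("mother", "father", "reference")

    def __post_init__(self) -> None:
        missing = {"chrom", "pos", *self.SAMPLES} - set(self.df.columns)
        if missing:
            raise ValueError(f"genotype frame missing columns: {sorted(missing)}")
        for s in self.SAMPLES:
            vals = self.df[s].to_numpy()
            bad = ~np.isin(vals, (MISSING, 0, 1, 2))
            if bad.any():
                raise ValueError(f"invalid genotype codes for {s}: {np.unique(vals[bad])}")

    def __len__(self) -> int:
        return len(self.df)

    def dosages(self, sample: str) -> np.ndarray:
        return self.df[sample].to_numpy()


def read_breakpoints_bed(path: str | Path) -> list[Breakpoint]:
    """Read breakpoints from a BED file (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}: {line!r}")
            name = parts[3] if len(parts) > 3 else f"bp{len(out) + 1}"
            out.append(Breakpoint(name, parts[0], int(parts[1]), int(parts[2])))
    return out


def write_breakpoints_bed(breakpoints: list[Breakpoint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in breakpoints:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.id}\n")
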