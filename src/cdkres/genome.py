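"""Genome model: chromosome lengths and centromere intervals.

Scar scoring needs to know where chromosomes end (telomeric anchoring of
allelic-imbalance regions) and where the centromere sits (arm boundaries,
centromere-crossing exclusion).  Coordinates are 1-based inclusive
throughout the package; a segment's length is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MB = 1_000_000

#: chromosomes treated as sex chromosomes and excluded from scar scoring by default
SEX_CHROMS = frozenset({"X", "Y"})


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix; ``chr1`` and ``1`` are the same chromosome."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if not (0 < self.cen_start <= self.cen_end <= self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere [{self.cen_start}, {self.cen_end}] "
                f"must lie within (0, {self.length}]"
            )

    @property
    def cen_mid(self) -> int:
        """Arm boundary used for large-scale-transition counting."""
        return (self.cen_start + self.cen_end) // 2

    @property
    def is_autosome(self) -> bool:
        return self.name not in SEX_CHROMS


class GenomeModel:
    """An ordered collection of chromosomes with unique names."""

    def __init__(self, chromosomes: list[Chromosome]):
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome model")
        self._chroms: dict[str, Chromosome] = {c.name: c for c in chromosomes}

    def __contains__(self, name: str) -> bool:
        return normalize_chrom(name) in self._chroms

    def __getitem__(self, name: str) -> Chromosome:
        key = normalize_chrom(name)
        if key not in self._chroms:
            raise KeyError(f"unknown chromosome: {name!r}")
        return self._chroms[key]

    def __iter__(self):
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self if c.is_autosome]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeModel":
        """Read a genome table (columns: chrom, length, cen_start, cen_end)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "length", "cen_start", "cen_end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"genome table missing columns: {sorted(missing)}")
        return cls(
            [
                Chromosome(
                    normalize_chrom(r.chrom), int(r.length), int(r.cen_start), int(r.cen_end)
                )
                for r in df.itertuples()
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "chrom": c.name,
                    "length": c.length,
                    "cen_start": c.cen_start,
                    "cen_end": c.cen_end,
                }
                for c in self
            ]
        ).to_csv(path, sep="\t", index=False)


def default_genome(n_autosomes: int = 22) -> GenomeModel:
    """Deterministic synthetic genome used by the cohort simulator.

    Autosome ``i`` (1-based) is ``250 - 8.5*(i-1)`` Mb long with a 3 Mb
    centromere centred at 45% of its length — a stylised human-karyotype
    stand-in with enough arm real estate to plant isolated scar events.
    """
    chroms = []
    for i in range(1, n_autosomes + 1):
        length = int((250 - 8.5 * (i - 1)) * MB)
        mid = int(0.45 * length)
        chroms.append(Chromosome(str(i), length, mid - 3 * MB // 2, mid + 3 * MB // 2))
    return GenomeModel(chroms)
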