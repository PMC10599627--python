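"""Named gene-set collections with GMT-format I/O.

Gene sets drive the per-cell program scores (cell-cycle G1S/G2M,
quiescence, and the four glioblastoma meta-modules AC/MES/NPC/OPC) and the
preranked enrichment analysis.  The GMT format is the field's plain-text
standard: one set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]

#: category labels used by the scoring stages
CATEGORIES = ("state", "cycle", "quiescence", "custom")


@dataclass
class GeneSetCollection:
    """Mapping of set name -> ordered gene list with a category per set.

    Categories: ``state`` (AC/MES/MES1/MES2/NPC/OPC meta-modules),
    ``cycle`` (G1S, G2M), ``quiescence``, or ``custom``.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            self.categories.setdefault(name, "custom")
        for name, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.sets)
        return [n for n in self.sets if self.categories[n] == category]

    def add(self, name: str, genes: Iterable[str], category: str = "custom") -> None:
        genes = list(genes)
        if name in self.sets:
            raise ValueError(f"duplicate set name {name!r}")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} contains duplicate genes")
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        self.sets[name] = genes
        self.categories[name] = category

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            categories={n: self.categories[n] for n in names},
        )


def read_gmt(path: str | Path, categories: Mapping[str, str] | None = None) -> GeneSetCollection:
    """Read a GMT file.  The description column is ignored unless it names a
    known category, in which case it is used as the set's category."""
    gsc = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            cat = "custom"
            if categories and name in categories:
                cat = categories[name]
            elif desc in CATEGORIES:
                cat = desc
            gsc.add(name, genes, category=cat)
    return gsc


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT; the description column carries the category."""
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, gsc.categories[name], *genes]) + "\n")
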