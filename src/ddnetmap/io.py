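"""Readers and writers for gene-set (GMT) and seed-list files."""

from __future__ import annotations

from pathlib import Path

from .enrichment import TraitGeneSet
from .errors import FormatError

__all__ = ["read_gmt", "write_gmt", "read_seed_list"]


def read_gmt(path) -> list[TraitGeneSet]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ...

    Duplicate set names are an error; duplicate genes within a set are
    deduplicated (order-independent, the sets are unordered anyway).
    """
    path = Path(path)
    sets: list[TraitGeneSet] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                              "description and at least one gene")
        name, desc, *genes = fields
        genes = [g for g in genes if g]  # tolerate trailing tabs
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen.add(name)
        sets.append(TraitGeneSet(name, frozenset(genes), desc))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for ts in sets:
            fh.write("\t".join([ts.trait_name, ts.source or "na",
                                *sorted(ts.genes)]) + "\n")


def read_seed_list(path) -> list[str]:
    """Seed genes, one per line (``#`` comments allowed) or first GMT set."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".gmt":
        return sorted(read_gmt(path)[0].genes)
    genes = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not genes:
        raise FormatError(f"{path}: no seed genes found")
    return list(dict.fromkeys(genes))
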