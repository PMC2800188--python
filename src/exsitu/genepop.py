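"""GENEPOP text-format reader/writer and metadata sidecars.

GENEPOP is the de-facto interchange format for diploid codominant
microsatellite data: a title line, one locus name per line (or one
comma-separated line), then ``Pop`` blocks of ``id ,  AAABBB AAABBB ...``
rows where each token concatenates the two allele codes in a fixed digit
width (2 or 3, auto-detected on read). ``00``/``000`` is the missing code;
GENEPOP has no half-missing convention, and rows mixing one typed and one
missing allele are rejected.

GENEPOP has no native population names. On read, each block is named after
its *last* individual label, unless explicit names are supplied (directly or
via a one-column-per-line sidecar file).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, Locus, UNKNOWN_POP


class GenepopParseError(ValueError):
    pass


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(
    path: str | Path,
    pop_names: Sequence[str] | str | Path | None = None,
) -> GenotypeDataset:
    """Parse a GENEPOP file into a :class:`GenotypeDataset`.

    Parameters
    ----------
    path
        GENEPOP file, 2- or 3-digit allele encoding (auto-detected).
    pop_names
        Optional explicit block names: a sequence, or a path to a text file
        with one name per line. Without it each block is named after its
        last individual label. A block named ``unknown`` holds query
        individuals.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file (line 1)")
    # header: title line then locus names until first Pop
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_ids.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError(f"{path}: no 'Pop' line found (line {i})")
    if not locus_ids:
        raise GenepopParseError(f"{path}: no locus names before first 'Pop' (line 2)")

    blocks: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if _POP_RE.match(raw):
            current = []
            blocks.append(current)
            continue
        if not raw.strip():
            continue
        if current is None:
            raise GenepopParseError(f"{path}: data before 'Pop' at line {lineno + 1}")
        if "," not in raw:
            raise GenepopParseError(
                f"{path}: missing ',' separator at line {lineno + 1}"
            )
        label, rest = raw.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"{path}: expected {len(locus_ids)} genotypes, got {len(tokens)} "
                f"at line {lineno + 1}"
            )
        current.append((label.strip(), tokens, lineno + 1))

    # detect digit width from token lengths
    widths = {len(t) for b in blocks for _, toks, _ in b for t in toks}
    if not widths:
        width = 3
    elif widths == {4}:
        width = 2
    elif widths == {6}:
        width = 3
    else:
        raise GenepopParseError(
            f"{path}: inconsistent genotype token lengths {sorted(widths)}"
        )

    if pop_names is not None and not isinstance(pop_names, (list, tuple)):
        pop_names = [
            s.strip()
            for s in Path(pop_names).read_text().splitlines()
            if s.strip()
        ]
    if pop_names is not None and len(pop_names) != len(blocks):
        raise GenepopParseError(
            f"{path}: {len(pop_names)} population names for {len(blocks)} blocks"
        )

    ids: list[str] = []
    pops: list[str] = []
    raw_calls: list[list[tuple[int, int] | None]] = []
    for b, block in enumerate(blocks):
        if pop_names is not None:
            name = pop_names[b]
        else:
            name = block[-1][0] if block else f"pop{b + 1}"
        for label, tokens, lineno in block:
            row: list[tuple[int, int] | None] = []
            for t in tokens:
                a, bb = int(t[:width]), int(t[width:])
                if a == 0 and bb == 0:
                    row.append(None)
                elif a == 0 or bb == 0:
                    raise GenepopParseError(
                        f"{path}: half-missing genotype '{t}' at line {lineno}"
                    )
                else:
                    row.append((a, bb))
            ids.append(label)
            pops.append(name)
            raw_calls.append(row)

    return GenotypeDataset.from_codes(locus_ids, ids, raw_calls, pops)


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    title: str = "exsitu genotype export",
    digit_width: int = 3,
    pop_names_path: str | Path | None = None,
) -> None:
    """Write a dataset as GENEPOP, grouping individuals by population label.

    Raises if any allele code does not fit in ``digit_width`` digits. When
    ``pop_names_path`` is given, block names are written there (one per
    line) so a re-read reproduces the population labels exactly.
    """
    limit = 10**digit_width
    for locus in dataset.loci:
        for code in locus.alleles:
            if not (0 < code < limit):
                raise ValueError(
                    f"allele code {code} at {locus.locus_id} does not fit in "
                    f"{digit_width} digits"
                )
    order: dict[str, list[int]] = {}
    for i, p in enumerate(dataset.populations):
        order.setdefault(p, []).append(i)

    out = [title]
    out.extend(l.locus_id for l in dataset.loci)
    for pop, rows in order.items():
        out.append("Pop")
        for i in rows:
            toks = []
            for l, locus in enumerate(dataset.loci):
                a, b = dataset.G[i, l]
                if a == MISSING:
                    toks.append("0" * (2 * digit_width))
                else:
                    toks.append(
                        f"{locus.alleles[a]:0{digit_width}d}"
                        f"{locus.alleles[b]:0{digit_width}d}"
                    )
            out.append(f"{dataset.ids[i]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")
    if pop_names_path is not None:
        Path(pop_names_path).write_text("\n".join(order) + "\n")


# -- metadata sidecar ----------------------------------------------------

_META_COLS = ("sex", "source_collection", "known_origin")


def write_metadata(dataset: GenotypeDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": dataset.ids,
            "population": dataset.populations,
            "sex": dataset.sex,
            "source_collection": dataset.source,
            "known_origin": [k if k is not None else "" for k in dataset.known_origin],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def apply_metadata(dataset: GenotypeDataset, path: str | Path) -> GenotypeDataset:
    """Attach sex/source/known-origin columns from a TSV sidecar in place."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: metadata TSV needs an individual_id column")
    ds = dataset.copy()
    for _, row in df.iterrows():
        iid = row["individual_id"]
        if iid not in ds._index:
            continue
        i = ds.row(iid)
        if "sex" in df.columns and row["sex"]:
            ds.sex[i] = row["sex"]
        if "source_collection" in df.columns and row["source_collection"]:
            ds.source[i] = row["source_collection"]
        if "known_origin" in df.columns and row["known_origin"]:
            ds.known_origin[i] = row["known_origin"]
    return ds
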