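"""Lexical cognate matrices: reading, coverage filtering, binarization.

A cognate dataset starts life as a wide table — one row per language, one
column per lexical concept (item), each cell holding the cognate-class
label(s) the language uses for that concept, or nothing when the concept is
undocumented.  The analysis-ready form is a binary presence/absence matrix
with one column per (item, class) pair, ``?`` marking block-wise missing
data, plus one all-absent "ascertainment" column at the head of every item
block; that extra column is what lets the likelihood condition on the fact
that cognate coding never yields an all-absent character.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "LanguageSample", "CognateAssignments", "CognateMatrix",
    "read_cognate_table", "filter_items_by_coverage", "binarize",
    "add_ascertainment_columns", "write_nexus", "read_nexus",
]

MISSING = -1          # internal cell code for '?'
ASC_LABEL = "ASC"     # class label reserved for ascertainment columns


@dataclass(frozen=True)
class LanguageSample:
    """One sampled language doculect with its classification and location."""
    name: str
    branch: str | None = None
    area: str | None = None
    lat: float | None = None
    lon: float | None = None


@dataclass
class CognateAssignments:
    """Raw (language x item) -> set-of-class-labels assignments.

    ``None`` marks a missing cell (concept undocumented for the language);
    a non-empty frozenset carries one class per word, several for synonyms.
    """
    languages: list[str]
    items: list[str]
    data: dict[tuple[str, str], frozenset[str] | None] = field(repr=False,
                                                               default_factory=dict)

    def classes_for(self, item: str) -> list[str]:
        seen: dict[str, None] = {}
        for lang in self.languages:
            cell = self.data.get((lang, item))
            if cell:
                for c in sorted(cell):
                    seen.setdefault(c, None)
        return list(seen)

    def coverage(self, item: str) -> float:
        obs = sum(1 for lang in self.languages
                  if self.data.get((lang, item)) is not None)
        return obs / len(self.languages)


class CognateMatrix:
    """Binary presence/absence matrix with item-blocked columns.

    Attributes
    ----------
    languages : list of language names (row order)
    columns : list of ``(item, class_label)`` pairs; the class label
        :data:`ASC_LABEL` marks an ascertainment column
    cells : int8 array, values ``1`` (present), ``0`` (absent),
        ``-1`` (missing, rendered as ``?``)
    item_blocks : mapping item -> (start, stop) contiguous column range
    """

    def __init__(self, languages: list[str],
                 columns: list[tuple[str, str]],
                 cells: np.ndarray,
                 has_ascertainment: bool = False):
        self.languages = list(languages)
        self.columns = list(columns)
        self.cells = np.asarray(cells, dtype=np.int8)
        self.has_ascertainment = has_ascertainment
        if self.cells.shape != (len(self.languages), len(self.columns)):
            raise ValueError("cell array shape does not match languages/columns")
        blocks: dict[str, list[int]] = {}
        prev: str | None = None
        for j, (item, _) in enumerate(self.columns):
            if item != prev:
                if item in blocks:
                    raise ValueError(f"item {item!r} columns are interleaved")
                blocks[item] = [j, j + 1]
                prev = item
            else:
                blocks[item][1] = j + 1
        self.item_blocks: dict[str, tuple[int, int]] = {
            k: (a, b) for k, (a, b) in blocks.items()}
        self.items = list(self.item_blocks)
        self._check_invariants()

    def _check_invariants(self) -> None:
        asc = self.ascertainment_mask()
        if self.has_ascertainment:
            for item, (s, e) in self.item_blocks.items():
                if self.columns[s][1] != ASC_LABEL:
                    raise ValueError(
                        f"item {item!r}: ascertainment column is not first")
                col = self.cells[:, s]
                if np.any(col == 1):
                    raise ValueError(
                        f"item {item!r}: ascertainment column contains a 1")
        elif np.any(asc):
            raise ValueError("matrix not flagged as ascertained but has "
                             f"{asc.sum()} {ASC_LABEL} columns")
        # block-wise missingness: if any cell in a block is '?', all are
        for item, (s, e) in self.item_blocks.items():
            block = self.cells[:, s:e]
            some = np.any(block == MISSING, axis=1)
            all_ = np.all(block == MISSING, axis=1)
            if np.any(some & ~all_):
                bad = np.where(some & ~all_)[0][0]
                raise ValueError(
                    f"language {self.languages[bad]!r} is partially missing "
                    f"for item {item!r} (missing must be block-wise)")

    # -- queries -------------------------------------------------------- #
    @property
    def n_languages(self) -> int:
        return len(self.languages)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def ascertainment_mask(self) -> np.ndarray:
        return np.asarray([cls == ASC_LABEL for _, cls in self.columns])

    def classes_per_item(self) -> dict[str, int]:
        asc = self.ascertainment_mask()
        out = {}
        for item, (s, e) in self.item_blocks.items():
            out[item] = int(np.sum(~asc[s:e]))
        return out

    def row(self, language: str) -> np.ndarray:
        return self.cells[self.languages.index(language)]

    def present_columns(self, language: str) -> list[int]:
        """Indices of non-ascertainment columns where the language has a 1."""
        r = self.row(language)
        asc = self.ascertainment_mask()
        return [j for j in range(self.n_columns) if r[j] == 1 and not asc[j]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CognateMatrix):
            return NotImplemented
        return (self.languages == other.languages
                and self.columns == other.columns
                and self.has_ascertainment == other.has_ascertainment
                and np.array_equal(self.cells, other.cells))

    def copy(self) -> "CognateMatrix":
        return CognateMatrix(self.languages, list(self.columns),
                             self.cells.copy(), self.has_ascertainment)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CognateMatrix {self.n_languages} languages x "
                f"{self.n_columns} columns ({len(self.item_blocks)} items, "
                f"ascertainment={'yes' if self.has_ascertainment else 'no'})>")


# ---------------------------------------------------------------------- #
# reading the raw wide table
# ---------------------------------------------------------------------- #
def read_cognate_table(path, delimiter: str | None = None,
                       synonym_sep: str = ";") -> CognateAssignments:
    """Read a wide language-by-concept table of cognate class labels.

    The header row names the concepts; the first column holds language
    names.  A cell may hold one class label, several separated by
    ``synonym_sep`` (synonyms), or be empty/'?' (missing).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [r for r in reader if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty table")
    header = [c.strip() for c in rows[0][1:]]
    if not header or any(not h for h in header):
        raise ValueError(f"{path}: empty concept header")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate concept names in header")
    languages: list[str] = []
    data: dict[tuple[str, str], frozenset[str] | None] = {}
    for r in rows[1:]:
        name = r[0].strip()
        if name in languages:
            raise ValueError(f"{path}: duplicate language name {name!r}")
        languages.append(name)
        for item, raw in zip(header, list(r[1:]) + [""] * (len(header) - len(r) + 1)):
            raw = raw.strip()
            if raw in ("", "?"):
                data[(name, item)] = None
            else:
                labels = frozenset(x.strip() for x in raw.split(synonym_sep)
                                   if x.strip())
                data[(name, item)] = labels if labels else None
    return CognateAssignments(languages, header, data)


def filter_items_by_coverage(assignments: CognateAssignments,
                             threshold: float = 0.70) -> CognateAssignments:
    """Keep items documented in strictly more than ``threshold`` of languages.

    The retention rule is *strictly greater than*: an item observed in
    exactly 70% of the sample does not pass a 0.70 threshold.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    if threshold == 0:
        keep = [it for it in assignments.items if assignments.coverage(it) > 0]
    else:
        keep = [it for it in assignments.items
                if assignments.coverage(it) > threshold]
    data = {(lang, it): assignments.data.get((lang, it))
            for lang in assignments.languages for it in keep}
    return CognateAssignments(list(assignments.languages), keep, data)


def binarize(assignments: CognateAssignments) -> CognateMatrix:
    """Expand class assignments into a binary item-blocked matrix.

    One column per distinct (item, class); within an item block a language
    scores 1 on every class it carries (synonyms give several 1s), 0 on the
    rest, and the whole block is ``?`` when the item is undocumented.
    """
    if not assignments.items or not assignments.languages:
        raise ValueError("empty assignments")
    columns: list[tuple[str, str]] = []
    cols_cells: list[np.ndarray] = []
    for item in assignments.items:
        classes = assignments.classes_for(item)
        for cls in classes:
            col = np.empty(len(assignments.languages), dtype=np.int8)
            for i, lang in enumerate(assignments.languages):
                cell = assignments.data.get((lang, item))
                if cell is None:
                    col[i] = MISSING
                else:
                    col[i] = 1 if cls in cell else 0
            columns.append((item, cls))
            cols_cells.append(col)
    cells = np.stack(cols_cells, axis=1) if cols_cells else \
        np.zeros((len(assignments.languages), 0), dtype=np.int8)
    return CognateMatrix(assignments.languages, columns, cells,
                         has_ascertainment=False)


def add_ascertainment_columns(matrix: CognateMatrix) -> CognateMatrix:
    """Prepend an all-absent correction column to every item block.

    The new column is 0 for languages with data for the item and ``?``
    where the whole block is missing; afterwards the column count equals
    (number of cognate classes) + (number of items).
    """
    if matrix.has_ascertainment:
        raise ValueError("matrix already carries ascertainment columns")
    columns: list[tuple[str, str]] = []
    pieces: list[np.ndarray] = []
    for item in matrix.items:
        s, e = matrix.item_blocks[item]
        block = matrix.cells[:, s:e]
        asc = np.where(np.all(block == MISSING, axis=1), MISSING, 0
                       ).astype(np.int8)[:, None]
        columns.append((item, ASC_LABEL))
        columns.extend(matrix.columns[s:e])
        pieces.append(np.concatenate([asc, block], axis=1))
    cells = np.concatenate(pieces, axis=1)
    return CognateMatrix(matrix.languages, columns, cells,
                         has_ascertainment=True)


# ---------------------------------------------------------------------- #
# NEXUS serialization
# ---------------------------------------------------------------------- #
def _quote(name: str) -> str:
    return f"'{name}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`<>-]", name) else name


def write_nexus(matrix: CognateMatrix, path) -> None:
    """Write a standard-datatype NEXUS file with per-item charsets.

    Column identity (item and class, including ascertainment flags) is
    carried in CHARSTATELABELS as ``item__class``; an ASSUMPTIONS block
    holds one charset per item so downstream tools see the block structure.
    """
    sym = {1: "1", 0: "0", MISSING: "?"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={matrix.n_languages} "
                 f"NCHAR={matrix.n_columns};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
        fh.write("  CHARSTATELABELS\n")
        labels = [f"    {j + 1} {_quote(f'{item}__{cls}')}"
                  for j, (item, cls) in enumerate(matrix.columns)]
        fh.write(",\n".join(labels) + ";\n")
        fh.write("  MATRIX\n")
        width = max(len(_quote(l)) for l in matrix.languages) + 2
        for i, lang in enumerate(matrix.languages):
            row = "".join(sym[int(v)] for v in matrix.cells[i])
            fh.write(f"    {_quote(lang):<{width}}{row}\n")
        fh.write("  ;\nEND;\n\nBEGIN ASSUMPTIONS;\n")
        for item, (s, e) in matrix.item_blocks.items():
            fh.write(f"  CHARSET {_quote(item)} = {s + 1}-{e};\n")
        fh.write("END;\n")


_TOKEN = re.compile(r"'[^']*'|\S+")


def _unquote(tok: str) -> str:
    return tok[1:-1] if tok.startswith("'") and tok.endswith("'") else tok


def read_nexus(path) -> CognateMatrix:
    """Read a matrix written by :func:`write_nexus` (round-trip exact)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    if not lines or not lines[0].strip().upper().startswith("#NEXUS"):
        raise ValueError(f"{path}:1: not a NEXUS file")
    ntax = nchar = None
    columns: list[tuple[str, str]] = []
    languages: list[str] = []
    rows: list[list[int]] = []
    mode = None
    inv = {"1": 1, "0": 0, "?": MISSING}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("DIMENSIONS"):
            m = re.search(r"NTAX\s*=\s*(\d+)", upper)
            m2 = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            if not (m and m2):
                raise ValueError(f"{path}:{lineno}: bad DIMENSIONS line")
            ntax, nchar = int(m.group(1)), int(m2.group(1))
        elif upper.startswith("CHARSTATELABELS"):
            mode = "labels"
        elif upper.startswith("MATRIX"):
            mode = "matrix"
        elif line == ";" or upper.startswith("END;"):
            mode = None
        elif mode == "labels":
            for part in line.rstrip(";").split(","):
                part = part.strip()
                if not part:
                    continue
                toks = _TOKEN.findall(part)
                if len(toks) != 2:
                    raise ValueError(f"{path}:{lineno}: bad charstatelabel "
                                     f"{part!r}")
                name = _unquote(toks[1])
                if "__" not in name:
                    raise ValueError(f"{path}:{lineno}: column label {name!r} "
                                     "lacks item__class structure")
                item, cls = name.split("__", 1)
                columns.append((item, cls))
        elif mode == "matrix":
            toks = _TOKEN.findall(line)
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: bad matrix row")
            languages.append(_unquote(toks[0]))
            symbols = "".join(toks[1:])
            try:
                rows.append([inv[c] for c in symbols])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: bad state symbol "
                                 f"{exc.args[0]!r}") from None
    if ntax is None or nchar is None:
        raise ValueError(f"{path}: missing DIMENSIONS")
    if len(languages) != ntax:
        raise ValueError(f"{path}: expected {ntax} taxa, found {len(languages)}")
    if len(columns) != nchar:
        raise ValueError(f"{path}: expected {nchar} charstatelabels, found "
                         f"{len(columns)}")
    cells = np.asarray(rows, dtype=np.int8)
    if cells.shape[1] != nchar:
        raise ValueError(f"{path}: matrix row length != NCHAR")
    has_asc = any(cls == ASC_LABEL for _, cls in columns)
    return CognateMatrix(languages, columns, cells, has_ascertainment=has_asc)


def write_language_metadata(samples: Iterable[LanguageSample], path) -> None:
    """Plain TSV of language, branch, area, lat, lon."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("language\tbranch\tarea\tlat\tlon\n")
        for s in samples:
            fh.write(f"{s.name}\t{s.branch or ''}\t{s.area or ''}\t"
                     f"{'' if s.lat is None else s.lat}\t"
                     f"{'' if s.lon is None else s.lon}\n")


def read_language_metadata(path) -> list[LanguageSample]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            parts += [""] * (5 - len(parts))
            name, branch, area, lat, lon = parts[:5]
            out.append(LanguageSample(
                name, branch or None, area or None,
                float(lat) if lat else None, float(lon) if lon else None))
    names = [s.name for s in out]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate language names")
    return out
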