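"""The two-part network distribution format.

Part I connects dependency paths to themes: one row per path with the raw
support for each theme and a 0/1 flag marking membership in each theme's
flagship set.  Part II connects sentences to dependency paths: one row per
(document, sentence, entity pair, path) with the 14 fields below, sorted
alphabetically by entity pair so that different sentences about the same
two entities sit next to each other.  Because the same pair can appear in
many rows, the network the file encodes is a multigraph.

Both parts are tab-separated UTF-8 with '\\n' line endings and no quoting;
tabs inside free-text fields are replaced by spaces on write (logged).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus import PathRecord
from .schema import ThemeSchema

logger = logging.getLogger(__name__)

PART2_COLUMNS = [
    "pmid",
    "sentence_number",
    "entity1_formatted",
    "entity1_location",
    "entity2_formatted",
    "entity2_location",
    "entity1_raw",
    "entity2_raw",
    "entity1_db_id",
    "entity2_db_id",
    "entity1_type",
    "entity2_type",
    "dependency_path",
    "sentence_tokenized",
]

_LOCATION = re.compile(r"^(\d+),\s*(\d+)$")


class FormatError(ValueError):
    """A distribution file violates the expected layout."""


def _clean(value: str) -> str:
    if "\t" in value:
        logger.warning("tab inside a field replaced by a space")
        value = value.replace("\t", " ")
    return value


# ---------------------------------------------------------------------------
# Part I
# ---------------------------------------------------------------------------


def part1_columns(schema: ThemeSchema, relationship_type: str) -> list[str]:
    symbols = schema.symbols(relationship_type)
    return (
        ["dependency_path"]
        + [f"support_{s}" for s in symbols]
        + [f"flagship_{s}" for s in symbols]
    )


def write_part1(
    rows: pd.DataFrame,
    schema: ThemeSchema,
    relationship_type: str,
    destination: str | Path,
) -> None:
    """Write the path-theme table (Part I).

    ``rows`` is the support frame from :func:`litnet.scoring.compute_supports`
    (indexed by path).  Rows with all-zero supports are rejected: a path
    that never co-occurred with any flagship path has no place in the
    table.
    """
    symbols = schema.symbols(relationship_type)
    support_cols = [f"support_{s}" for s in symbols]
    flag_cols = [f"flagship_{s}" for s in symbols]
    missing = [c for c in support_cols + flag_cols if c not in rows.columns]
    if missing:
        # themes with no labeled clusters simply have zero support everywhere
        logger.info("filling %d unlabeled theme columns with zeros", len(missing))
        rows = rows.copy()
        for c in missing:
            rows[c] = 0
    if (rows[support_cols].sum(axis=1) == 0).any():
        raise FormatError("rows with all-zero supports cannot be written")
    with open(destination, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(part1_columns(schema, relationship_type)) + "\n")
        for path, row in rows.iterrows():
            cells = [_clean(str(path))]
            cells += [str(int(row[c])) for c in support_cols]
            cells += [str(int(row[c])) for c in flag_cols]
            fh.write("\t".join(cells) + "\n")


def read_part1(
    source: str | Path, schema: ThemeSchema, relationship_type: str
) -> pd.DataFrame:
    """Read Part I back into a support frame in schema column order.

    Shuffled theme columns are accepted as long as the header names match
    the schema's themes; the frame is reordered on read.
    """
    expected = set(part1_columns(schema, relationship_type))
    lines = Path(source).read_text("utf-8").splitlines()
    if not lines:
        raise FormatError("empty Part I file")
    header = lines[0].split("\t")
    if set(header) != expected:
        raise FormatError(
            f"line 1: header {header} does not match the schema for {relationship_type}"
        )
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"line {ln}: expected {len(header)} columns, got {len(cells)}")
        rec = dict(zip(header, cells))
        records.append(rec)
    frame = pd.DataFrame(records)
    frame = frame.set_index("dependency_path")
    frame.index.name = "path"
    ordered = [c for c in part1_columns(schema, relationship_type) if c != "dependency_path"]
    frame = frame[ordered].astype(int)
    return frame


# ---------------------------------------------------------------------------
# Part II
# ---------------------------------------------------------------------------


def _record_to_row(rec: PathRecord) -> list[str]:
    return [
        _clean(rec.doc_id),
        str(rec.sentence_number),
        _clean(rec.entity1_formatted),
        f"{rec.entity1_start}, {rec.entity1_end}",
        _clean(rec.entity2_formatted),
        f"{rec.entity2_start}, {rec.entity2_end}",
        _clean(rec.entity1_raw),
        _clean(rec.entity2_raw),
        _clean(rec.entity1_db_id),
        _clean(rec.entity2_db_id),
        _clean(rec.entity1_type),
        _clean(rec.entity2_type),
        _clean(rec.path),
        _clean(rec.sentence),
    ]


def write_part2(records: Sequence[PathRecord], destination: str | Path) -> None:
    """Write sentence-level records (Part II), sorted by entity pair.

    The sort key is (first entity formatted, second entity formatted);
    the input order is preserved within a pair (stable sort), and no
    deduplication is performed — the network is a multigraph.
    """
    ordered = sorted(records, key=lambda r: (r.entity1_formatted, r.entity2_formatted))
    with open(destination, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PART2_COLUMNS) + "\n")
        for rec in ordered:
            fh.write("\t".join(_record_to_row(rec)) + "\n")


def _parse_location(field: str, ln: int) -> tuple[int, int]:
    m = _LOCATION.match(field)
    if not m:
        raise FormatError(f"line {ln}: malformed location field {field!r}")
    return int(m.group(1)), int(m.group(2))


def read_part2(source: str | Path) -> list[PathRecord]:
    """Read Part II back into records; lossless for files this package wrote."""
    lines = Path(source).read_text("utf-8").splitlines()
    if not lines:
        return []
    if lines[0].split("\t") != PART2_COLUMNS:
        raise FormatError("line 1: unexpected Part II header")
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(PART2_COLUMNS):
            raise FormatError(
                f"line {ln}: expected {len(PART2_COLUMNS)} columns, got {len(cells)}"
            )
        (
            pmid,
            snum,
            e1f,
            loc1,
            e2f,
            loc2,
            e1r,
            e2r,
            id1,
            id2,
            t1,
            t2,
            path,
            sentence,
        ) = cells
        s1, e1 = _parse_location(loc1, ln)
        s2, e2 = _parse_location(loc2, ln)
        records.append(
            PathRecord(
                doc_id=pmid,
                sentence_number=int(snum),
                entity1_formatted=e1f,
                entity1_start=s1,
                entity1_end=e1,
                entity2_formatted=e2f,
                entity2_start=s2,
                entity2_end=e2,
                entity1_raw=e1r,
                entity2_raw=e2r,
                entity1_db_id=id1,
                entity2_db_id=id2,
                entity1_type=t1,
                entity2_type=t2,
                path=path,
                sentence=sentence,
            )
        )
    return records
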