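"""Readers and writers for the plate-based screen.

Covers multi-page TIFF stacks, the plate folder convention
``{screen}/{plate}/{well}_{channel}.tif`` (wells zero-padded, e.g. ``A01``),
the per-embryo qualitative annotation table, per-treatment gross-morphology
counts, compound-library plus ATC metadata, and the combined results
workbook (XLSX with a mirrored CSV).

All readers validate and reject malformed input rather than coercing it;
every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import datetime
import io
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .image_processing import ZStack

__all__ = [
    "CATEGORIES",
    "ABNORMALITY_CATEGORIES",
    "GROSS_RATIO_FIELDS",
    "WellAddress",
    "CompoundRecord",
    "AnnotationRecord",
    "GrossMorphologyRecord",
    "FormatError",
    "read_stack",
    "write_stack",
    "stack_path",
    "load_annotations",
    "write_annotations",
    "load_gross_morphology",
    "write_gross_morphology",
    "load_library",
    "write_results",
    "read_results",
    "atc_d_level",
]

#: Closed vocabulary of the ten qualitative phenotype categories.
CATEGORIES: Tuple[str, ...] = (
    "rpa_maj",
    "rpa_mod",
    "rpa_min",
    "empty",
    "glom_malform",
    "glomsep_maj",
    "glomsep_mod",
    "glomsep_min",
    "liver-panc_pheno",
    "normal_kidney",
)

#: Categories describing an abnormal phenotype ("normal_kidney" and "empty"
#: are handled separately: the former is mutually exclusive with these, the
#: latter with everything).
ABNORMALITY_CATEGORIES: Tuple[str, ...] = tuple(
    c for c in CATEGORIES if c not in ("normal_kidney", "empty")
)

#: The six gross-morphology parameters scored as per-treatment ratios.
GROSS_RATIO_FIELDS: Tuple[str, ...] = (
    "curved_back_tail",
    "edema_mild",
    "edema_severe",
    "heartbeat_alteration",
    "somite_malformation",
    "yolk_necrosis",
)


class FormatError(ValueError):
    """A file failed structural validation."""


# ---------------------------------------------------------------------------
# Well addressing and plate folder convention
# ---------------------------------------------------------------------------

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on a 96-well plate: plate ID, row letter A–H, column 1–12."""

    plate: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-H]", self.row):
            raise ValueError(f"row must be a letter A-H, got {self.row!r}")
        if not 1 <= int(self.column) <= 12:
            raise ValueError(f"column must be 1-12, got {self.column!r}")

    @property
    def label(self) -> str:
        """Zero-padded well label, e.g. ``A01``."""
        return f"{self.row}{self.column:02d}"

    @classmethod
    def parse(cls, plate: str, well: str) -> "WellAddress":
        m = _WELL_RE.match(well.strip())
        if not m:
            raise FormatError(f"cannot parse well label {well!r}")
        return cls(plate=plate, row=m.group(1).upper(), column=int(m.group(2)))


def stack_path(screen_dir, well: WellAddress, channel: str = "GFP") -> Path:
    """Path of a well's stack under ``{screen}/{plate}/{well}_{channel}.tif``."""
    return Path(screen_dir) / well.plate / f"{well.label}_{channel}.tif"


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_stack(stack: ZStack, path) -> None:
    """Write a :class:`~nephroscreen.image_processing.ZStack` as multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.pixels,
        metadata={
            "channel": stack.channel,
            "slice_spacing_um": stack.slice_spacing_um,
        },
    )


def read_stack(path) -> ZStack:
    """Read a multi-page TIFF into a ZStack (lossless round trip)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such stack file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pixels = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"not a readable TIFF stack: {path}: {exc}") from exc
    if pixels.ndim == 2:
        pixels = pixels[None, :, :]
    if pixels.ndim != 3:
        raise FormatError(f"stack {path} is not a 2-D image series")
    return ZStack(
        pixels=pixels,
        channel=str(meta.get("channel", "GFP")),
        slice_spacing_um=float(meta.get("slice_spacing_um", 15.0)),
    )


# ---------------------------------------------------------------------------
# Qualitative annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    """Qualitative categories assigned to one embryo in one well."""

    well: WellAddress
    embryo: int
    categories: FrozenSet[str]

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise FormatError(f"unknown categories {sorted(unknown)}")
        if not self.categories:
            raise FormatError("an annotation must carry at least one category")
        if "normal_kidney" in self.categories and (
            set(self.categories) & set(ABNORMALITY_CATEGORIES)
        ):
            raise FormatError(
                "normal_kidney conflicts with abnormality categories: "
                f"{sorted(self.categories)}"
            )
        if "empty" in self.categories and len(self.categories) > 1:
            raise FormatError(f"'empty' excludes all other tags: {sorted(self.categories)}")


ANNOTATION_COLUMNS = ("plate", "well", "embryo", "categories")


def load_annotations(path) -> List[AnnotationRecord]:
    """Read the annotation CSV (plate, well, embryo, ';'-separated categories)."""
    df = pd.read_csv(path, dtype={"plate": str, "well": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation file {path} lacks columns {sorted(missing)}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        cats = frozenset(
            c.strip() for c in str(row.categories).split(";") if c.strip()
        )
        try:
            records.append(
                AnnotationRecord(
                    well=WellAddress.parse(str(row.plate), str(row.well)),
                    embryo=int(row.embryo),
                    categories=cats,
                )
            )
        except (FormatError, ValueError) as exc:
            problems.append(f"row {i + 2}: {exc}")
    if problems:
        raise FormatError(
            f"annotation file {path} failed validation:\n" + "\n".join(problems)
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    rows = [
        (
            r.well.plate,
            r.well.label,
            r.embryo,
            ";".join(sorted(r.categories)),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gross morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrossMorphologyRecord:
    """Stereo-microscope counts for one treatment group before mounting.

    Heartbeat alterations are recorded per subtype (faster/slower/absent);
    edema per severity (mild/severe).  Mortality is tracked separately from
    the scored parameters.  ``total_exposed`` defaults to the 20 embryos
    exposed per compound.
    """

    treatment: str
    curved_back_tail: int = 0
    edema_mild: int = 0
    edema_severe: int = 0
    heartbeat_faster: int = 0
    heartbeat_slower: int = 0
    heartbeat_absent: int = 0
    somite_malformation: int = 0
    yolk_necrosis: int = 0
    mortality: int = 0
    total_exposed: int = 20

    def __post_init__(self) -> None:
        if self.total_exposed <= 0:
            raise FormatError("total_exposed must be positive")
        for name in (
            "curved_back_tail",
            "edema_mild",
            "edema_severe",
            "heartbeat_faster",
            "heartbeat_slower",
            "heartbeat_absent",
            "somite_malformation",
            "yolk_necrosis",
            "mortality",
        ):
            v = getattr(self, name)
            if v < 0 or v > self.total_exposed:
                raise FormatError(
                    f"count {name}={v} outside [0, total_exposed={self.total_exposed}]"
                )
        if self.edema_mild + self.edema_severe > self.total_exposed:
            raise FormatError("edema severity counts exceed total exposed")
        if (
            self.heartbeat_faster + self.heartbeat_slower + self.heartbeat_absent
            > self.total_exposed
        ):
            raise FormatError("heartbeat subtype counts exceed total exposed")

    @property
    def heartbeat_alteration(self) -> int:
        return self.heartbeat_faster + self.heartbeat_slower + self.heartbeat_absent


GROSS_COLUMNS = (
    "treatment",
    "curved_back_tail",
    "edema_mild",
    "edema_severe",
    "heartbeat_faster",
    "heartbeat_slower",
    "heartbeat_absent",
    "somite_malformation",
    "yolk_necrosis",
    "mortality",
    "total_exposed",
)


def load_gross_morphology(path) -> List[GrossMorphologyRecord]:
    df = pd.read_csv(path, dtype={"treatment": str})
    missing = set(GROSS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gross table {path} lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {c: (str(getattr(row, c)) if c == "treatment" else int(getattr(row, c)))
                  for c in GROSS_COLUMNS}
        records.append(GrossMorphologyRecord(**kwargs))
    return records


def write_gross_morphology(records: Iterable[GrossMorphologyRecord], path) -> None:
    rows = [[getattr(r, c) for c in GROSS_COLUMNS] for r in records]
    pd.DataFrame(rows, columns=list(GROSS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Compound library and ATC classification
# ---------------------------------------------------------------------------

ATC_D_LEVEL_LEN = 5  # chemical subgroup: first five characters of the code


def atc_d_level(code: str) -> str:
    """D-level (chemical subgroup) prefix of a full ATC code, e.g. M01AE01 → M01AE."""
    code = code.strip().upper()
    if not re.fullmatch(r"[A-Z]\d{2}[A-Z]{2}(\d{2})?", code):
        raise FormatError(f"malformed ATC code {code!r}")
    return code[:ATC_D_LEVEL_LEN]


@dataclass(frozen=True)
class CompoundRecord:
    """Library metadata for one compound, with its ATC D-level group."""

    compound_id: str
    name: str
    library_position: str = ""
    atc_codes: Tuple[str, ...] = ()
    d_level: str = "N/A"

    def __post_init__(self) -> None:
        if self.d_level != "N/A":
            if not any(c.startswith(self.d_level) for c in self.atc_codes):
                raise FormatError(
                    f"D-level {self.d_level!r} is not a prefix of any ATC code "
                    f"{self.atc_codes}"
                )


def load_library(compound_file, atc_file) -> List[CompoundRecord]:
    """Join the compound table with ATC codes into CompoundRecords.

    ``compound_file`` needs columns ``compound_id, name`` (optionally
    ``library_position``); ``atc_file`` needs ``compound_id, atc_code``
    (one row per code).  Compounds without any mapped code are assigned the
    D-level ``"N/A"``.
    """
    comp = pd.read_csv(compound_file, dtype=str)
    for col in ("compound_id", "name"):
        if col not in comp.columns:
            raise FormatError(f"compound table lacks column {col!r}")
    if comp["compound_id"].duplicated().any():
        dups = comp.loc[comp["compound_id"].duplicated(), "compound_id"].tolist()
        raise FormatError(f"duplicate compound IDs: {dups}")
    atc = pd.read_csv(atc_file, dtype=str)
    for col in ("compound_id", "atc_code"):
        if col not in atc.columns:
            raise FormatError(f"ATC table lacks column {col!r}")
    codes_by_id: Dict[str, List[str]] = {}
    for row in atc.itertuples(index=False):
        codes_by_id.setdefault(str(row.compound_id), []).append(str(row.atc_code))
    records = []
    for row in comp.itertuples(index=False):
        cid = str(row.compound_id)
        codes = tuple(sorted(codes_by_id.get(cid, ())))
        d_level = atc_d_level(codes[0]) if codes else "N/A"
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row.name),
                library_position=str(getattr(row, "library_position", "") or ""),
                atc_codes=codes,
                d_level=d_level,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Results workbook
# ---------------------------------------------------------------------------

_FIXED_STAMP = datetime.datetime(2000, 1, 1)
_ZIP_STAMP = (1980, 1, 1, 0, 0, 0)


def _deterministic_xlsx(df: pd.DataFrame, path: Path, sheet: str) -> None:
    """Write an XLSX whose bytes depend only on the table contents.

    openpyxl stamps the current time into the core properties and the zip
    entries; both are pinned so identical runs produce byte-identical
    workbooks.
    """
    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = sheet
    ws.append(list(df.columns))
    for row in df.itertuples(index=False):
        ws.append([None if (isinstance(v, float) and np.isnan(v)) else v for v in row])
    wb.properties.created = _FIXED_STAMP
    wb.properties.modified = _FIXED_STAMP
    buf = io.BytesIO()
    wb.save(buf)
    buf.seek(0)
    stamp = _FIXED_STAMP.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    out = io.BytesIO()
    with zipfile.ZipFile(buf) as src, zipfile.ZipFile(
        out, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in sorted(src.namelist()):
            data = src.read(name)
            if name == "docProps/core.xml":
                # openpyxl stamps the save time regardless of the pinned
                # properties; rewrite both timestamps to the fixed value
                data = re.sub(
                    rb'(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:)',
                    rb"\g<1>" + stamp + rb"\g<2>",
                    data,
                )
            info = zipfile.ZipInfo(name, date_time=_ZIP_STAMP)
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, data)
    path.write_bytes(out.getvalue())


def write_results(table, path) -> Path:
    """Write the assembled per-treatment results as an XLSX workbook.

    ``table`` is a :class:`~nephroscreen.scoring.ScreenResultTable` (or its
    underlying DataFrame).  A CSV mirror with the same stem is written next
    to the workbook.  Returns the workbook path.
    """
    df = table.frame if hasattr(table, "frame") else pd.DataFrame(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _deterministic_xlsx(df, path, sheet="results")
    df.to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_results(path) -> pd.DataFrame:
    """Load a results workbook back into a DataFrame (lossless for numerics)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such results workbook: {path}")
    return pd.read_excel(path, sheet_name="results")
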