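"""Hierarchical, exhaustive grouping of ICD codes into condition classes.

Diagnosis codes from ICD-8, ICD-9 and ICD-10 (US and Swedish dialects) are
grouped into condition classes nested under biological systems.  The grouping
is stored as closed lexical prefix intervals (e.g. ``I20``–``I25``), which
mirrors the block structure of the ICD and makes exhaustiveness and
non-overlap checkable at load time.  The packaged default map partitions the
ICD-10 code space into 263 condition classes under 31 biological systems
following the WHO chapter/block layout.

Classes whose parent system is a symptom/finding or health-service chapter
carry ``ambiguous=True`` and can be excluded from headline signal tables.
"""
from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

VALID_VERSIONS = (8, 9, 10)
VALID_DIALECTS = ("US", "SE", "*")


class TaxonomyError(ValueError):
    """Raised for malformed codes, overlapping intervals or missing crosswalks."""


def normalize_code(raw: str) -> str:
    """Normalize an ICD code: strip dots and whitespace, uppercase."""
    code = raw.strip().replace(".", "").upper()
    if not code:
        raise TaxonomyError("empty ICD code")
    return code


def _check_lexical(code: str, version: int) -> None:
    if version == 10:
        if not (code[0].isalpha() and len(code) >= 2 and code[1].isdigit()):
            raise TaxonomyError(f"{code!r} is not a valid ICD-10 code")
    else:  # ICD-8/9: numeric, or E/V-prefixed supplementary codes
        body = code[1:] if code[0] in "EV" else code
        if not body or not body.isdigit():
            raise TaxonomyError(f"{code!r} is not a valid ICD-{version} code")


@dataclass(frozen=True)
class IcdCode:
    """A normalized diagnosis code with its ICD version and dialect."""

    code: str
    version: int = 10
    dialect: str = "US"

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", normalize_code(self.code))
        if self.version not in VALID_VERSIONS:
            raise TaxonomyError(f"unknown ICD version {self.version!r}")
        if self.dialect not in VALID_DIALECTS:
            raise TaxonomyError(f"unknown dialect {self.dialect!r}")
        _check_lexical(self.code, self.version)

    @property
    def prefix(self) -> str:
        """Block prefix used for interval classification.

        ICD-10 blocks are identified by the first three characters; ICD-8/9
        E-codes carry four significant leading characters (e.g. ``E800``).
        """
        if self.version != 10 and self.code.startswith("E"):
            return self.code[:4]
        return self.code[:3]


@dataclass(frozen=True)
class ConditionClass:
    class_id: str
    class_name: str
    system_id: str
    system_name: str
    ambiguous_flag: bool = False


@dataclass(frozen=True)
class _Interval:
    start: str
    end: str  # inclusive
    version: int
    dialect: str
    class_id: str

    def contains(self, prefix: str) -> bool:
        return self.start <= prefix <= self.end


@dataclass
class TaxonomyMap:
    """Validated interval mapping from ICD codes to condition classes.

    ``entries`` are kept sorted per (version, dialect) key so classification
    is a binary search on the interval starts.
    """

    entries: list[_Interval]
    classes: dict[str, ConditionClass]
    crosswalks: dict[tuple[int, int], dict[str, frozenset[str]]] = field(default_factory=dict)
    _index: dict[tuple[int, str], tuple[list[str], list[_Interval]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity and non-overlap; build the search index."""
        self._index.clear()
        by_key: dict[tuple[int, str], list[_Interval]] = {}
        for iv in self.entries:
            if iv.class_id not in self.classes:
                raise TaxonomyError(f"interval {iv.start}-{iv.end} references unknown class {iv.class_id!r}")
            if iv.start > iv.end:
                raise TaxonomyError(f"interval start {iv.start!r} exceeds end {iv.end!r}")
            by_key.setdefault((iv.version, iv.dialect), []).append(iv)
        for key, ivs in by_key.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise TaxonomyError(
                        f"overlapping intervals for ICD-{key[0]} ({key[1]}): "
                        f"{a.start}-{a.end} ({a.class_id}) clashes with "
                        f"{b.start}-{b.end} ({b.class_id})"
                    )
            self._index[key] = ([iv.start for iv in ivs], ivs)

    @property
    def n_classes(self) -> int:
        return len({iv.class_id for iv in self.entries})

    @property
    def n_systems(self) -> int:
        return len({self.classes[iv.class_id].system_id for iv in self.entries})

    def summary(self) -> dict[str, int]:
        return {"n_classes": self.n_classes, "n_systems": self.n_systems,
                "n_intervals": len(self.entries)}

    # -- classification ---------------------------------------------------
    def _lookup(self, version: int, dialect: str) -> list[tuple[list[str], list[_Interval]]]:
        out = []
        for d in (dialect, "*"):
            if (version, d) in self._index:
                out.append(self._index[(version, d)])
        return out

    def classify(self, code: IcdCode) -> ConditionClass:
        """Return the unique condition class whose interval contains ``code``."""
        for starts, ivs in self._lookup(code.version, code.dialect):
            i = bisect.bisect_right(starts, code.prefix) - 1
            if i >= 0 and ivs[i].contains(code.prefix):
                return self.classes[ivs[i].class_id]
        raise TaxonomyError(
            f"code {code.code} (ICD-{code.version}, {code.dialect}) falls outside every interval"
        )

    # -- crosswalks -------------------------------------------------------
    def crosswalk(self, code: IcdCode, target_version: int) -> frozenset[IcdCode]:
        """Map ``code`` to the set of equivalent codes in ``target_version``.

        An empty set means the crosswalk table lists no equivalent; a missing
        (source, target) table raises ``TaxonomyError``.
        """
        key = (code.version, target_version)
        if key not in self.crosswalks:
            raise TaxonomyError(f"no crosswalk loaded for ICD-{key[0]} -> ICD-{key[1]}")
        targets = self.crosswalks[key].get(code.code, frozenset())
        return frozenset(IcdCode(t, target_version, code.dialect) for t in targets)


# -- file loading ---------------------------------------------------------

_REQUIRED_COLS = {"code_start", "code_end", "icd_version", "dialect",
                  "class_id", "class_name", "system_id", "system_name"}


def _parse_version(token: str) -> int:
    tok = str(token).strip().upper().removeprefix("ICD-").removeprefix("ICD")
    try:
        v = int(tok)
    except ValueError:
        raise TaxonomyError(f"unknown ICD version token {token!r}") from None
    if v not in VALID_VERSIONS:
        raise TaxonomyError(f"unknown ICD version token {token!r}")
    return v


def _truthy(token) -> bool:
    return str(token).strip().lower() in {"1", "true", "t", "yes", "y"}


def load_taxonomy(mapping_file: str | Path,
                  crosswalk_files: Iterable[str | Path] = ()) -> TaxonomyMap:
    """Load and validate a taxonomy from a delimited-text mapping file.

    The file is UTF-8 CSV/TSV with a header row containing at least
    ``code_start, code_end, icd_version, dialect, class_id, class_name,
    system_id, system_name`` and optionally ``ambiguous``.
    """
    path = Path(mapping_file)
    with path.open(newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not _REQUIRED_COLS <= set(reader.fieldnames):
            missing = _REQUIRED_COLS - set(reader.fieldnames or ())
            raise TaxonomyError(f"{path}: missing columns {sorted(missing)}")
        entries: list[_Interval] = []
        classes: dict[str, ConditionClass] = {}
        for row in reader:
            version = _parse_version(row["icd_version"])
            dialect = row["dialect"].strip().upper() or "*"
            if dialect not in VALID_DIALECTS:
                raise TaxonomyError(f"unknown dialect {row['dialect']!r}")
            cc = ConditionClass(
                class_id=row["class_id"].strip(),
                class_name=row["class_name"].strip(),
                system_id=row["system_id"].strip(),
                system_name=row["system_name"].strip(),
                ambiguous_flag=_truthy(row.get("ambiguous", "0")),
            )
            prev = classes.setdefault(cc.class_id, cc)
            if prev != cc:
                raise TaxonomyError(f"class {cc.class_id!r} redefined inconsistently")
            entries.append(_Interval(
                start=normalize_code(row["code_start"])[:3].ljust(3, "0")
                if version == 10 else normalize_code(row["code_start"]),
                end=normalize_code(row["code_end"])[:3].ljust(3, "0")
                if version == 10 else normalize_code(row["code_end"]),
                version=version, dialect=dialect, class_id=cc.class_id,
            ))
    tax = TaxonomyMap(entries=entries, classes=classes)
    for cw in crosswalk_files:
        load_crosswalk(cw, into=tax)
    return tax


def load_crosswalk(path: str | Path, into: TaxonomyMap) -> TaxonomyMap:
    """Load a code-level crosswalk table (source_code, source_version,
    target_code, target_version) into an existing map."""
    tmp: dict[tuple[int, int], dict[str, set[str]]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        need = {"source_code", "source_version", "target_code", "target_version"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise TaxonomyError(f"{path}: crosswalk needs columns {sorted(need)}")
        for row in reader:
            key = (_parse_version(row["source_version"]), _parse_version(row["target_version"]))
            tmp.setdefault(key, {}).setdefault(
                normalize_code(row["source_code"]), set()
            ).add(normalize_code(row["target_code"]))
    for key, table in tmp.items():
        merged = dict(into.crosswalks.get(key, {}))
        for src, tgts in table.items():
            merged[src] = frozenset(merged.get(src, frozenset()) | tgts)
        into.crosswalks[key] = merged
    return into


def default_taxonomy() -> TaxonomyMap:
    """The packaged WHO ICD-10 chapter/block map: 263 classes, 31 systems."""
    ref = resources.files("clockshift").joinpath("data/default_taxonomy.csv")
    with resources.as_file(ref) as path:
        return load_taxonomy(path)
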