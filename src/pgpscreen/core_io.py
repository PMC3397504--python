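"""Data model and CSV/JSON input-output.

The central containers are :class:`DescriptorTable` (a compound-by-descriptor
numeric matrix, e.g. a PaDEL export) and :class:`LabeledDataset` (the table
joined to Y/N class labels for up to three assay endpoints: P-gp inhibition,
ATPase activation and monolayer efflux).  Packaged fixtures transcribe the
published label tables for the 59-compound modelling set, the 47-compound
external set and the three rationally selected 20-compound test sets.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ENDPOINTS = ("inhibition", "atpase", "efflux")

# The literature uses both spellings for clarithromycin; both resolve to the
# single id used by the 59-compound fixture.
_ID_ALIASES = {"clarithromycin": "clarythromycin"}


class LoadError(ValueError):
    """Raised when an input file violates the data-model invariants."""


def canonical_id(compound_id: str) -> str:
    """Canonical matching key for a compound id.

    Whitespace is stripped and collapsed to underscores and the comparison is
    case-insensitive; known alternative spellings are aliased.
    """
    key = re.sub(r"\s+", "_", str(compound_id).strip()).casefold()
    return _ID_ALIASES.get(key, key)


def _display_id(compound_id: str) -> str:
    return re.sub(r"\s+", "_", str(compound_id).strip())


@dataclass(frozen=True)
class ClassLabel:
    """A binary assay class label, Y or N.

    ``confident=False`` marks labels assigned inside an assay's non-confident
    zone; such labels still carry a definite Y/N value.
    """

    value: str
    confident: bool = True

    def __post_init__(self) -> None:
        if self.value not in ("Y", "N"):
            raise ValueError(f"label value must be 'Y' or 'N', got {self.value!r}")

    @property
    def is_positive(self) -> bool:
        return self.value == "Y"


class ProfileCategory(str, Enum):
    """Three-assay profile category (inhibition, ATPase activation, efflux)."""

    TRUE_INHIBITOR = "true_inhibitor"   # Y N N
    SUBSTRATE = "substrate"             # Y Y Y
    NON_SUBSTRATE = "non_substrate"     # N N N
    OTHER = "other"


class DescriptorTable:
    """Compound-by-descriptor numeric matrix.

    Rows are compounds (unique ids), columns are numeric molecular
    descriptors (unique names).  All values must be finite; missing values
    are a hard load error, never imputed.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = [_display_id(i) for i in data.index]
        canon = [canonical_id(i) for i in data.index]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise LoadError(f"duplicate compound ids: {dupes}")
        if len(set(data.columns)) != len(data.columns):
            raise LoadError("duplicate descriptor names")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise LoadError(f"non-numeric descriptor value: {exc}") from exc
        if values.size and not np.isfinite(values).all():
            rows, cols = np.where(~np.isfinite(values))
            r, c = rows[0], cols[0]
            raise LoadError(
                f"non-finite descriptor value at compound "
                f"{data.index[r]!r}, descriptor {data.columns[c]!r}"
            )
        self._data = data.astype(float)
        self._canon_index = {c: i for i, c in enumerate(canon)}

    # -- container surface -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def compound_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, compound_id: str) -> bool:
        return canonical_id(compound_id) in self._canon_index

    def row(self, compound_id: str) -> pd.Series:
        try:
            pos = self._canon_index[canonical_id(compound_id)]
        except KeyError:
            raise KeyError(f"unknown compound id {compound_id!r}") from None
        return self._data.iloc[pos]

    def subset(self, compound_ids: Iterable[str]) -> "DescriptorTable":
        pos = [self._canon_index[canonical_id(c)] for c in compound_ids]
        return DescriptorTable(self._data.iloc[pos])

    def select(self, descriptor_names: Iterable[str]) -> "DescriptorTable":
        return DescriptorTable(self._data.loc[:, list(descriptor_names)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DescriptorTable) and self._data.equals(other._data)


@dataclass
class LabeledDataset:
    """A DescriptorTable joined to per-endpoint Y/N class labels."""

    table: DescriptorTable
    labels: dict[str, dict[str, ClassLabel]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        table_canon = {canonical_id(c) for c in self.table.compound_ids}
        for endpoint, lab in self.labels.items():
            if endpoint not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {endpoint!r}")
            lab_canon = {canonical_id(c) for c in lab}
            if lab_canon - table_canon:
                raise ValueError(f"labels for unknown compounds in {endpoint!r}")
            if table_canon - lab_canon:
                missing = sorted(table_canon - lab_canon)[:3]
                raise ValueError(
                    f"compounds missing a {endpoint!r} label, e.g. {missing}"
                )

    @property
    def endpoints(self) -> list[str]:
        return [e for e in ENDPOINTS if e in self.labels]

    def label(self, endpoint: str, compound_id: str) -> ClassLabel:
        lab = self.labels[endpoint]
        canon = canonical_id(compound_id)
        for cid, value in lab.items():
            if canonical_id(cid) == canon:
                return value
        raise KeyError(compound_id)

    def label_vector(self, endpoint: str) -> np.ndarray:
        """Y/N labels as a string array aligned with the table's rows."""
        lab = {canonical_id(c): v for c, v in self.labels[endpoint].items()}
        return np.array(
            [lab[canonical_id(c)].value for c in self.table.compound_ids]
        )

    def y01(self, endpoint: str) -> np.ndarray:
        """Labels encoded 0/1 (Y = 1), aligned with the table's rows."""
        return (self.label_vector(endpoint) == "Y").astype(int)

    def class_counts(self, endpoint: str) -> tuple[int, int]:
        """(n_Y, n_N) for one endpoint."""
        y = self.y01(endpoint)
        return int(y.sum()), int(len(y) - y.sum())

    def subset(self, compound_ids: Iterable[str]) -> "LabeledDataset":
        ids = list(compound_ids)
        table = self.table.subset(ids)
        keep = {canonical_id(c) for c in ids}
        labels = {
            e: {c: v for c, v in lab.items() if canonical_id(c) in keep}
            for e, lab in self.labels.items()
        }
        return LabeledDataset(table, labels, dict(self.meta))


@dataclass
class ExternalSet:
    """An externally assayed compound series with a potency flag.

    ``strong_inhibitor`` marks inhibitors at least as potent as the reference
    inhibitor elacridar.
    """

    dataset: LabeledDataset
    strong_inhibitor: dict[str, bool]


# ---------------------------------------------------------------------------
# readers / writers


def read_descriptor_table(path: str | Path, id_column: str = "compound_id") -> DescriptorTable:
    """Read a descriptor CSV (header row, id column, numeric cells)."""
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"empty descriptor table: {path}") from exc
    if id_column not in raw.columns:
        raise LoadError(f"id column {id_column!r} not found in {path}")
    if raw.empty:
        raise LoadError(f"descriptor table has no rows: {path}")
    raw = raw.set_index(id_column)
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = raw.index[bad.argmax()]
            raise LoadError(
                f"non-numeric cell {raw[col][bad].iloc[0]!r} at compound "
                f"{row!r}, descriptor {col!r} in {path}"
            )
        numeric[col] = converted
    return DescriptorTable(pd.DataFrame(numeric, index=raw.index))


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="compound_id")


def read_label_table(path: str | Path) -> dict[str, dict[str, ClassLabel]]:
    """Read a label CSV with a compound id column and one Y/N column per endpoint."""
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"empty label table: {path}") from exc
    if "compound_id" not in raw.columns:
        raise LoadError(f"'compound_id' column not found in {path}")
    endpoints = [c for c in raw.columns if c in ENDPOINTS]
    if not endpoints:
        raise LoadError(f"no endpoint columns among {list(raw.columns)} in {path}")
    labels: dict[str, dict[str, ClassLabel]] = {e: {} for e in endpoints}
    for _, row in raw.iterrows():
        cid = _display_id(row["compound_id"])
        for e in endpoints:
            token = str(row[e]).strip().upper()
            if token not in ("Y", "N"):
                raise LoadError(
                    f"invalid label {row[e]!r} for compound {cid!r}, "
                    f"endpoint {e!r} in {path}"
                )
            labels[e][cid] = ClassLabel(token)
    for e in endpoints:
        if not labels[e]:
            raise LoadError(f"empty endpoint column {e!r} in {path}")
    return labels


def write_label_table(labels: Mapping[str, Mapping[str, ClassLabel]], path: str | Path) -> None:
    endpoints = [e for e in ENDPOINTS if e in labels]
    ids: list[str] = []
    for e in endpoints:
        for cid in labels[e]:
            if cid not in ids:
                ids.append(cid)
    rows = [
        {"compound_id": cid, **{e: labels[e][cid].value for e in endpoints}}
        for cid in ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_path(name: str) -> Path:
    return Path(resources.files("pgpscreen").joinpath("data", name))  # type: ignore[arg-type]


def load_fixture(name: str):
    """Load a packaged fixture.

    ``dataset59``
        The 59-compound modelling set with all three endpoint labels
        (descriptor table is empty: the published tables carry labels only).
    ``external47``
        The 47-compound external series as an :class:`ExternalSet` with the
        strong-inhibitor potency flag.
    ``testsets``
        Mapping endpoint -> list of the 20 rationally selected test-set ids.
    """
    if name == "dataset59":
        labels = read_label_table(_fixture_path("dataset59_labels.csv"))
        ids = list(labels["inhibition"])
        table = DescriptorTable(pd.DataFrame(index=ids))
        return LabeledDataset(table, labels)
    if name == "external47":
        path = _fixture_path("external47_labels.csv")
        raw = pd.read_csv(path, dtype=str)
        labels = read_label_table(path)
        ids = list(labels["inhibition"])
        table = DescriptorTable(pd.DataFrame(index=ids))
        strong = {
            _display_id(r["compound_id"]): str(r["strong_inhibitor"]).lower() == "true"
            for _, r in raw.iterrows()
        }
        return ExternalSet(LabeledDataset(table, labels), strong)
    if name == "testsets":
        raw = pd.read_csv(_fixture_path("testsets.csv"), dtype=str)
        dataset = load_fixture("dataset59")
        canon_to_id = {canonical_id(c): c for c in dataset.table.compound_ids}
        out = {}
        for endpoint in ENDPOINTS:
            members = []
            for name_ in raw[endpoint]:
                canon = canonical_id(name_)
                if canon not in canon_to_id:
                    raise LoadError(
                        f"test-set compound {name_!r} not in the 59-compound set"
                    )
                members.append(canon_to_id[canon])
            out[endpoint] = members
        return out
    raise ValueError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# generic JSON reports


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(report, path: str | Path) -> None:
    """Write any result object as deterministic, sorted-key JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_to_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
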