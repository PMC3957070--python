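"""Input/output and encoding for the tabular formats the classifier consumes.

Four kinds of input share a sample index:

* omics matrices (gene expression, copy-number values, ...) as TSV with a
  header row of feature ids and a leading column of sample ids;
* a clinical covariate table (TSV) whose columns are declared binary,
  categorical or numeric;
* pathway membership in standard GMT (set id, description, member genes);
* a binary outcome label per sample (``-1``/``+1``, or ``0``/``1`` with
  ``0`` mapped to ``-1``).

Categorical clinical covariates are one-hot (Boolean) encoded; missing
clinical values receive an explicit ``<col>=missing`` indicator rather than
being imputed.  Blocks from different assays are aligned on the intersection
of their sample ids, since every base kernel must be computed over one common
sample set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "ClinicalTable",
    "PathwayCollection",
    "LabelVector",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_labels",
    "write_labels",
    "encode_clinical",
    "align_samples",
]

#: strings treated as a missing clinical value
MISSING_MARKERS = {"", "NA", "NaN", "nan", "None"}


@dataclass
class OmicsBlock:
    """One data type's sample x feature matrix.

    Parameters
    ----------
    name
        Data-type tag, e.g. ``"EXP"``, ``"CNV"`` or ``"CLIN"``.
    samples, features
        Ordered, unique identifiers for rows and columns.
    values
        Real matrix with ``len(samples)`` rows and ``len(features)`` columns;
        all entries finite.
    """

    name: str
    samples: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.features = [str(f) for f in self.features]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.samples, "sample id")
        _check_unique(self.features, "feature id")
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"block {self.name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.samples)} samples x {len(self.features)} features"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.name!r}: non-finite value at sample "
                f"{self.samples[i]!r}, feature {self.features[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_index(self, ids: list[str]) -> np.ndarray:
        """Column positions of ``ids``; raises naming the first absent id."""
        lookup = {f: i for i, f in enumerate(self.features)}
        missing = [f for f in ids if f not in lookup]
        if missing:
            raise KeyError(
                f"feature {missing[0]!r} not present in block {self.name!r}"
            )
        return np.array([lookup[f] for f in ids], dtype=int)

    def subset_samples(self, order: list[str]) -> "OmicsBlock":
        """New block restricted to ``order`` (which must exist), in that order."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = [lookup[s] for s in order]
        return OmicsBlock(self.name, list(order), list(self.features),
                          self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)


@dataclass
class ClinicalTable:
    """Clinical covariates as observed strings plus declared column kinds.

    ``kinds`` maps column name to ``"binary"``, ``"categorical"`` or
    ``"numeric"``.  Values equal to one of :data:`MISSING_MARKERS` are missing.
    """

    samples: list[str]
    data: pd.DataFrame          # dtype str, index = samples
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        _check_unique(self.samples, "sample id")
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds declared for absent columns: {sorted(unknown)}")
        for col in self.data.columns:
            if col not in self.kinds:
                raise ValueError(f"no kind declared for clinical column {col!r}")
            if self.kinds[col] not in ("binary", "categorical", "numeric"):
                raise ValueError(f"unknown kind {self.kinds[col]!r} for column {col!r}")

    def subset_samples(self, order: list[str]) -> "ClinicalTable":
        return ClinicalTable(list(order), self.data.loc[list(order)], dict(self.kinds))


@dataclass
class PathwayCollection:
    """Ordered named gene sets: list of (pathway id, description, member ids)."""

    entries: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([e[0] for e in self.entries], "pathway id")
        for pid, _, members in self.entries:
            if len(members) < 1:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def members(self, pathway_id: str) -> set[str]:
        for pid, _, members in self.entries:
            if pid == pathway_id:
                return set(members)
        raise KeyError(f"unknown pathway id {pathway_id!r}")


@dataclass
class LabelVector:
    """Binary outcome per sample; +1 = survivor at the horizon, -1 = non-survivor."""

    samples: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.y = np.asarray(self.y, dtype=int)
        _check_unique(self.samples, "sample id")
        if self.y.shape != (len(self.samples),):
            raise ValueError("label vector length does not match sample count")
        bad = set(np.unique(self.y)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}; found {sorted(bad)}")

    def subset_samples(self, order: list[str]) -> "LabelVector":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = [lookup[s] for s in order]
        return LabelVector(list(order), self.y[idx])

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, data_type: str, delimiter: str = "\t") -> OmicsBlock:
    """Read a sample x feature matrix from delimited text.

    The file must have one header row of feature ids and one leading column of
    sample ids.  Duplicate ids and non-numeric cells are reported with the
    offending id or coordinates.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    samples = [str(s) for s in df.index]
    features = [str(c) for c in df.columns]
    _check_unique(samples, "sample id")
    _check_unique(features, "feature id")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric cell {raw[i, j]!r} at sample "
                f"{samples[i]!r}, feature {features[j]!r}"
            )
        values[:, j] = col
    return OmicsBlock(data_type, samples, features, values)


def write_matrix(block: OmicsBlock, path, delimiter: str = "\t",
                 float_format: str = "%.10g") -> None:
    block.to_frame().to_csv(path, sep=delimiter, float_format=float_format,
                            index_label="sample")


def read_gmt(path) -> PathwayCollection:
    """Read gene sets from GMT: pathway id TAB description TAB genes...

    Duplicate genes within a line are dropped (order preserved); lines with
    fewer than three fields and duplicate pathway ids are errors.
    """
    entries: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc = fields[0], fields[1]
            if pid in seen:
                raise ValueError(f"{path}: duplicate pathway id {pid!r}")
            seen.add(pid)
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            entries.append((pid, desc, members))
    return PathwayCollection(entries)


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, desc, members in pathways:
            fh.write("\t".join([pid, desc, *members]) + "\n")


def read_clinical(path, kinds: dict[str, str], delimiter: str = "\t") -> ClinicalTable:
    """Read the clinical covariate table; ``kinds`` declares each column's type."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.map(str)
    return ClinicalTable(list(df.index), df, dict(kinds))


def read_labels(path, delimiter: str = "\t") -> LabelVector:
    """Read a two-column (sample id, label) file; 0/1 labels are mapped to -1/+1.

    A single header line is tolerated and skipped if its second field is not a
    valid label.
    """
    samples: list[str] = []
    raw: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                lab = int(fields[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{path}: line {lineno}: label {fields[1]!r} is not an integer"
                ) from None
            if lab not in (-1, 0, 1):
                raise ValueError(
                    f"{path}: line {lineno}: label must be -1, 0 or 1, got {lab}"
                )
            samples.append(fields[0])
            raw.append(-1 if lab == 0 else lab)
    return LabelVector(samples, np.array(raw, dtype=int))


def write_labels(labels: LabelVector, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample{delimiter}label\n")
        for s, lab in zip(labels.samples, labels.y):
            fh.write(f"{s}{delimiter}{int(lab)}\n")


# ---------------------------------------------------------------------------
# clinical encoding and sample alignment
# ---------------------------------------------------------------------------

def _binary_reference_level(levels: list[str]) -> str:
    # conventionally encode the "positive"/truthy level when recognizable
    lv = set(levels)
    for truthy in ({"0", "1"}, {"no", "yes"}, {"false", "true"}, {"F", "T"}):
        if lv == truthy:
            return sorted(lv)[1]
    return sorted(levels)[0]


def encode_clinical(table: ClinicalTable,
                    features: list[str] | None = None) -> OmicsBlock:
    """Boolean-encode clinical covariates into an omics-like block tagged "CLIN".

    Binary columns become a single 0/1 indicator ``col=level``; categorical
    columns with L levels become L one-hot indicators; numeric columns pass
    through unchanged.  A missing value zeroes the column's indicators and
    raises an extra ``col=missing`` indicator.  Columns with a single observed
    level are dropped with a warning.

    When ``features`` is given (the feature list of a previously encoded
    training block), exactly that feature layout is reproduced, so held-out
    samples can be encoded against a training-derived schema; levels unseen in
    the schema simply leave their group all-zero.
    """
    if len(table.samples) == 0:
        raise ValueError("clinical table is empty")
    cols: dict[str, np.ndarray] = {}
    n = len(table.samples)

    for col in table.data.columns:
        kind = table.kinds[col]
        obs = table.data[col].astype(str)
        miss = obs.isin(MISSING_MARKERS).to_numpy()
        if kind == "numeric":
            vals = pd.to_numeric(obs.where(~miss, other="0"), errors="coerce")
            if vals.isna().any():
                i = int(np.flatnonzero(vals.isna())[0])
                raise ValueError(
                    f"numeric clinical column {col!r}: non-numeric value "
                    f"{obs.iloc[i]!r} for sample {table.samples[i]!r}"
                )
            cols[col] = vals.to_numpy(dtype=float)
            if miss.any():
                cols[f"{col}=missing"] = miss.astype(float)
            continue
        levels = sorted(set(obs[~miss]))
        if features is None and len(levels) < 2:
            warnings.warn(
                f"clinical column {col!r} has a single observed level; dropped",
                stacklevel=2,
            )
            continue
        if kind == "binary":
            use_levels = [_binary_reference_level(levels)] if levels else []
        else:
            use_levels = levels
        for level in use_levels:
            cols[f"{col}={level}"] = ((obs == level) & ~miss).to_numpy(dtype=float)
        if miss.any() or features is not None:
            cols[f"{col}=missing"] = miss.astype(float)

    if features is not None:
        mat = np.zeros((n, len(features)))
        for j, f in enumerate(features):
            if f in cols:
                mat[:, j] = cols[f]
        return OmicsBlock("CLIN", list(table.samples), list(features), mat)

    if not cols:
        raise ValueError("no encodable clinical columns")
    names = list(cols)
    mat = np.column_stack([cols[f] for f in names])
    return OmicsBlock("CLIN", list(table.samples), names, mat)


def covariate_of_feature(feature: str) -> str:
    """Original covariate name behind an encoded clinical feature name."""
    return feature.split("=", 1)[0]


def align_samples(blocks: list[OmicsBlock], labels: LabelVector,
                  ) -> tuple[list[OmicsBlock], LabelVector]:
    """Restrict all blocks and labels to their common samples, in label order.

    Raises if the intersection is empty; logs (warns) when samples are dropped.
    Idempotent: aligning already-aligned inputs is a no-op.
    """
    if not blocks:
        raise ValueError("at least one block required")
    common = set(labels.samples)
    for b in blocks:
        common &= set(b.samples)
    if not common:
        raise ValueError("sample intersection across blocks and labels is empty")
    order = [s for s in labels.samples if s in common]
    n_in = max(len(labels.samples), *(b.n_samples for b in blocks))
    if len(order) < n_in:
        warnings.warn(
            f"sample alignment dropped {n_in - len(order)} sample(s) not shared "
            "by all inputs",
            stacklevel=2,
        )
    return [b.subset_samples(order) for b in blocks], labels.subset_samples(order)
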