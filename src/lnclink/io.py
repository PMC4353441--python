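"""Domain types and tabular readers/writers shared across the pipeline.

All on-disk formats are tab-separated UTF-8 with ``.`` as the decimal mark:

* expression matrix — first column ``probe_id``, one column per sample,
  linear-scale intensities on ingest;
* sample metadata — columns ``sample_id``, ``strain``, ``timepoint_weeks``,
  ``treatment`` (``sham``/``IR``), ``replicate`` (plus optional ``dose_cGy``);
* probe annotation — columns ``probe_id``, ``probe_class``
  (``lncRNA``/``mRNA``), ``gene_symbol`` (may be empty);
* gene signature — one gene symbol per line.

Every writer emits the dialect its reader parses, and a write/read
round-trip reproduces the in-memory object exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"

PROBE_CLASSES = ("lncRNA", "mRNA")
TREATMENTS = ("sham", "IR")


class ValidationError(ValueError):
    """Raised when an input file or object violates a documented contract."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity table, the pipeline's central object.

    ``data`` is a float DataFrame indexed by probe id with one column per
    sample.  ``scale`` records whether values are raw linear intensities or
    log2-transformed signals; operations that only make sense on one scale
    check the flag instead of guessing.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(list(self.data.index), "probe_id")
        _check_unique(list(self.data.columns), "sample_id")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.scale == LINEAR and np.any(values <= 0):
            r, c = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"non-positive linear intensity at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a linear-scale expression matrix TSV, preserving row/column order."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected a probe-id column plus sample columns")
    probe_col = df.columns[0]
    probes = df[probe_col].tolist()
    _check_unique(probes, "probe_id")
    _check_unique(list(df.columns[1:]), "sample_id")
    values = df.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at probe "
            f"{probes[r]!r}, sample {values.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at probe {probes[r]!r}, sample {values.columns[c]!r}"
        )
    # numpy's string->float conversion is correctly rounded (pandas' fast
    # parser can be off by one ulp), keeping write/read round-trips bit-exact
    exact = pd.DataFrame(
        values.to_numpy().astype(np.float64),
        index=pd.Index(probes, name="probe_id"),
        columns=values.columns,
    )
    return ExpressionMatrix(exact, scale=LINEAR)


def write_expression_matrix(m: ExpressionMatrix, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = m.data.copy()
        out.index.name = "probe_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("sample_id", "strain", "timepoint_weeks", "treatment", "replicate")


def group_label(strain: str, timepoint_weeks: float, treatment: str) -> str:
    """Canonical experimental-group label, e.g. ``BALBc_4w_IR``."""
    return f"{strain}_{timepoint_weeks:g}w_{treatment}"


@dataclass
class SampleTable:
    """Per-sample design factors defining the experimental groups.

    A group is the unique (strain, timepoint_weeks, treatment) combination;
    the emulated study design yields 8 groups of 3 biological replicates.
    The derived ``group`` column is a pure function of those three factors.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in SAMPLE_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"sample table missing required column {col!r}")
        _check_unique(df["sample_id"].tolist(), "sample_id")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(
                f"unknown treatment value(s) {sorted(bad)}; expected one of {TREATMENTS}"
            )
        df = df.copy()
        df["timepoint_weeks"] = pd.to_numeric(df["timepoint_weeks"])
        df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        df["group"] = [
            group_label(s, t, tr)
            for s, t, tr in zip(df["strain"], df["timepoint_weeks"], df["treatment"])
        ]
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    @property
    def groups(self) -> dict[str, list]:
        """Mapping group label -> sample ids, in canonical group order."""
        order = self.group_order()
        by_group = self.data.groupby("group")["sample_id"].apply(list).to_dict()
        return {g: by_group[g] for g in order}

    def group_order(self) -> list[str]:
        """Canonical order: strain, then week ascending, then sham before IR."""
        keys = self.data[["strain", "timepoint_weeks", "treatment", "group"]].drop_duplicates()
        keys = keys.assign(_tr=keys["treatment"].map({"sham": 0, "IR": 1}))
        keys = keys.sort_values(["strain", "timepoint_weeks", "_tr"], kind="stable")
        return keys["group"].tolist()

    def select(self, predicate) -> list:
        """Sample ids matching a predicate (callable on rows, or a factor dict)."""
        return select_samples(self, predicate)


def select_samples(samples: SampleTable, predicate) -> list:
    if callable(predicate):
        mask = samples.data.apply(predicate, axis=1)
    elif isinstance(predicate, Mapping):
        mask = pd.Series(True, index=samples.data.index)
        for key, val in predicate.items():
            if key not in samples.data.columns:
                raise ValidationError(f"unknown sample factor {key!r} in contrast selector")
            mask &= samples.data[key] == val
    else:
        raise ValidationError("predicate must be callable or a factor mapping")
    return samples.data.loc[mask, "sample_id"].tolist()


def read_sample_metadata(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path) -> None:
    out = samples.data.drop(columns=["group"])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# ProbeAnnotation and GeneSet
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """probe_id -> class (lncRNA/mRNA) and gene symbol (may be empty).

    Gene symbols are matched case-insensitively throughout the pipeline;
    probes with an empty symbol can never match a signature.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("probe_id", "probe_class", "gene_symbol"):
            if col not in df.columns:
                raise ValidationError(f"probe annotation missing column {col!r}")
        _check_unique(df["probe_id"].tolist(), "probe_id")
        bad = set(df["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown probe class(es) {sorted(bad)}; expected one of {PROBE_CLASSES}"
            )
        df = df.copy()
        df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
        self.data = df.set_index("probe_id", drop=False)

    def probes_of_class(self, probe_class: str) -> list:
        return self.data.loc[self.data["probe_class"] == probe_class, "probe_id"].tolist()

    def classes_for(self, probe_ids: Iterable) -> pd.Series:
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"probe(s) missing from annotation: {missing[:5]}")
        return self.data.loc[list(probe_ids), "probe_class"]

    def symbols_for(self, probe_ids: Iterable, upper: bool = True) -> pd.Series:
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"probe(s) missing from annotation: {missing[:5]}")
        sym = self.data.loc[list(probe_ids), "gene_symbol"]
        return sym.str.upper() if upper else sym


@dataclass(frozen=True)
class GeneSet:
    """Unordered set of gene symbols, case-normalized to upper case."""

    symbols: frozenset = field(default_factory=frozenset)
    name: str = ""

    @staticmethod
    def from_symbols(symbols: Iterable[str], name: str = "") -> "GeneSet":
        cleaned = [s.strip().upper() for s in symbols if s and s.strip()]
        return GeneSet(frozenset(cleaned), name)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.symbols


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_signature(path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line signature file, deduplicating symbols."""
    with open(path, encoding="utf-8") as fh:
        raw = [line.strip() for line in fh]
    raw = [s for s in raw if s and not s.startswith("#")]
    gs = GeneSet.from_symbols(raw, name or str(path))
    dropped = len(raw) - len(gs)
    if dropped:
        logger.info("signature %s: removed %d duplicate symbol(s)", gs.name, dropped)
    if not len(gs):
        logger.warning("signature %s is empty", gs.name)
    return gs


def write_gene_signature(gs: GeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(gs.symbols):
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# Contrast
# ---------------------------------------------------------------------------


@dataclass
class Contrast:
    """A two-group comparison with its significance and fold-change cutoffs.

    ``group_a``/``group_b`` are either callables over sample-table rows or
    factor dicts such as ``{"strain": "BALBc", "timepoint_weeks": 4,
    "treatment": "sham"}``.  The two printed cutoff regimes of the emulated
    study are p<0.05 / FC>1.5 for the radiation response and p<0.001 /
    FC>1.5 for the strain baseline; both inequalities are strict.
    """

    name: str
    group_a: Callable | Mapping
    group_b: Callable | Mapping
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if not (self.p_cutoff > 0):
            raise ValidationError(f"contrast {self.name}: p_cutoff must be > 0")
        if not (self.fc_cutoff >= 1):
            raise ValidationError(f"contrast {self.name}: fc_cutoff must be >= 1")

    def resolve(self, samples: SampleTable) -> tuple[list, list]:
        a = select_samples(samples, self.group_a)
        b = select_samples(samples, self.group_b)
        if not a or not b:
            raise ValidationError(f"contrast {self.name}: a group resolved to no samples")
        if set(a) & set(b):
            raise ValidationError(f"contrast {self.name}: groups overlap")
        return a, b


# ---------------------------------------------------------------------------
# Generic table I/O (DE tables, edge tables, reports)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, header_comment: str | None = None, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
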