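"""Readers and writers for the tabular formats the pipeline touches.

All tables are plain text: a GCT-like tab/comma-delimited expression matrix
(id column + one column per sample), a CSV clinical table, a long- or
wide-format alteration table, and CSV outputs.  Parsers validate rather than
silently coerce; sample-id joins elsewhere in the pipeline are by exact
string match after whitespace trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("rmpa")

ALTERATION_CLASSES = ("amplification", "deletion", "mutation")

CHROMOSOME_ARMS = tuple(
    f"{c}{a}" for c in list(range(1, 23)) + ["X"] for a in ("p", "q")
)


class ParseError(ValueError):
    """Raised when an input file violates the declared format."""


class ValidationError(ValueError):
    """Raised when parsed values violate a table invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe/gene x sample matrix of log2 expression values.

    ``usable`` flags rows with nonzero variance; zero-variance rows stay in
    the matrix but are excluded from correlation rankings downstream.
    """

    values: pd.DataFrame  # rows = probes/genes, columns = samples

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate row ids: {list(dupes)}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def usable(self) -> pd.Series:
        """Boolean per row: nonzero variance (usable for correlation)."""
        arr = self.values.to_numpy()
        return pd.Series(arr.std(axis=1) > 0, index=self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeAnnotation:
    """Mapping probe_id -> gene symbol; many probes may map to one gene.

    Unannotated probes are represented by the explicit marker ``"---"``.
    """

    mapping: pd.Series  # index = probe_id, values = gene symbol
    UNANNOTATED = "---"

    def gene_of(self, probe_id: str) -> str:
        return str(self.mapping.get(probe_id, self.UNANNOTATED))

    def genes_of(self, probe_ids: Iterable[str]) -> set[str]:
        genes = {self.gene_of(p) for p in probe_ids}
        genes.discard(self.UNANNOTATED)
        return genes


@dataclass
class ClinicalTable:
    """Per-sample survival time (months), event flag, grade, age, morphology.

    ``usable_for_survival`` is False where time or event is missing; such
    samples are retained for other analyses.
    """

    data: pd.DataFrame  # index = sample id

    REQUIRED = ("time", "event")

    def __post_init__(self) -> None:
        d = self.data
        bad_event = d["event"].dropna()[~d["event"].dropna().isin([0, 1])]
        if len(bad_event):
            raise ValidationError(
                f"event values outside {{0,1}} for samples {list(bad_event.index)}"
            )
        nonpos = d["time"].dropna()[d["time"].dropna() <= 0]
        if len(nonpos):
            raise ValidationError(
                f"non-positive survival time for samples {list(nonpos.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def usable_for_survival(self) -> pd.Series:
        return self.data["time"].notna() & self.data["event"].notna()


@dataclass
class CopyNumberMatrix:
    """Gene x sample log2 copy-number ratios with optional arm annotation."""

    values: pd.DataFrame  # rows = genes, columns = samples
    arm_map: pd.Series | None = None  # gene -> chromosome arm

    def __post_init__(self) -> None:
        if self.arm_map is not None:
            bad = set(self.arm_map.unique()) - set(CHROMOSOME_ARMS)
            if bad:
                raise ValidationError(f"unknown chromosome arms: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AlterationTable:
    """Binary gene x sample indicators, one layer per alteration class.

    ``any_alteration`` is the elementwise OR of the class layers.
    """

    layers: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        unknown = set(self.layers) - set(ALTERATION_CLASSES)
        if unknown:
            raise ValidationError(
                f"unknown alteration classes {sorted(unknown)}; "
                f"accepted: {list(ALTERATION_CLASSES)}"
            )
        shapes = {layer.shape for layer in self.layers.values()}
        if len(shapes) > 1:
            raise ValidationError("alteration layers have inconsistent shapes")
        for name, layer in self.layers.items():
            vals = layer.to_numpy()
            if not np.isin(vals, [0, 1]).all():
                raise ValidationError(f"non-binary entries in layer '{name}'")

    @property
    def any_alteration(self) -> pd.DataFrame:
        layers = list(self.layers.values())
        out = layers[0].copy()
        for layer in layers[1:]:
            out = out | layer.astype(bool)
        return out.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(next(iter(self.layers.values())).index)

    @property
    def sample_ids(self) -> list[str]:
        return list(next(iter(self.layers.values())).columns)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _read_numeric_matrix(
    path: str | Path, dialect: str, missing_policy: str, what: str
) -> pd.DataFrame:
    """Shared parser for id-column + sample-column numeric matrices."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    if df.columns.size == 0:
        raise ParseError(f"{path}: header line has no sample columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ParseError(f"{path}: duplicate row id(s): {list(dupes)}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # distinguish declared-missing cells from malformed numerics
    missing_tokens = {"", "na", "nan", "null", "none"}
    is_missing = df.isna() | df.apply(
        lambda col: col.astype(str).str.strip().str.lower().isin(missing_tokens)
    )
    malformed = numeric.isna() & ~is_missing
    if malformed.to_numpy().any():
        r, c = np.argwhere(malformed.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row "
            f"{numeric.index[r]!r}, column {numeric.columns[c]!r}"
        )

    if numeric.isna().to_numpy().any():
        if missing_policy == "drop-row":
            before = len(numeric)
            numeric = numeric.dropna(axis=0)
            logger.info(
                "%s: dropped %d row(s) with missing values", what, before - len(numeric)
            )
        elif missing_policy == "impute-row-mean":
            row_means = numeric.mean(axis=1)
            numeric = numeric.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
            logger.info("%s: imputed missing values with row means", what)
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")
    logger.info("%s: read %d rows x %d samples from %s", what, *numeric.shape, path)
    return numeric.astype(float)


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    missing_policy: str = "drop-row",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a probe/gene x sample log2 expression matrix.

    First column holds row ids, first row sample ids.  ``transpose`` handles
    sample-per-row files.  Missing cells follow ``missing_policy``
    ({"drop-row", "impute-row-mean"}); malformed numerics raise
    :class:`ParseError` naming the cell.
    """
    values = _read_numeric_matrix(path, dialect, missing_policy, "expression")
    if transpose:
        values = values.T
    return ExpressionMatrix(values)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    expr.values.to_csv(path, sep=_sep(dialect), index_label="id")


def read_probe_annotation(path: str | Path, dialect: str = "tsv") -> ProbeAnnotation:
    """Read a two-column probe_id -> gene_symbol table."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs probe and gene columns")
    probes = df.iloc[:, 0].str.strip()
    genes = df.iloc[:, 1].fillna(ProbeAnnotation.UNANNOTATED).str.strip()
    if probes.duplicated().any():
        dupes = probes[probes.duplicated()].unique()
        raise ParseError(f"{path}: probe(s) annotated more than once: {list(dupes)}")
    return ProbeAnnotation(pd.Series(genes.values, index=probes.values))


def write_probe_annotation(
    ann: ProbeAnnotation, path: str | Path, dialect: str = "tsv"
) -> None:
    pd.DataFrame({"probe_id": ann.mapping.index, "gene_symbol": ann.mapping.values}).to_csv(
        path, sep=_sep(dialect), index=False
    )


def read_clinical_table(path: str | Path, dialect: str = "csv") -> ClinicalTable:
    """Read the per-sample clinical table (sample, time, event, grade, age, morphology)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str).str.strip()
    missing = [c for c in ClinicalTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col, default in (("grade", "unknown"), ("age", np.nan), ("morphology", None)):
        if col not in df.columns:
            df[col] = default
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    table = ClinicalTable(df)
    n_unusable = int((~table.usable_for_survival).sum())
    if n_unusable:
        logger.info("clinical: %d sample(s) unusable for survival analysis", n_unusable)
    return table


def write_clinical_table(
    clinical: ClinicalTable, path: str | Path, dialect: str = "csv"
) -> None:
    clinical.data.to_csv(path, sep=_sep(dialect), index_label="sample")


def read_copy_number_matrix(
    path: str | Path,
    dialect: str = "tsv",
    arm_map_path: str | Path | None = None,
    missing_policy: str = "drop-row",
) -> CopyNumberMatrix:
    """Read a gene x sample log2 copy-number ratio matrix plus optional arm map."""
    values = _read_numeric_matrix(path, dialect, missing_policy, "copy-number")
    arm_map = None
    if arm_map_path is not None:
        df = pd.read_csv(arm_map_path, sep=_sep(dialect), dtype=str)
        arm_map = pd.Series(
            df.iloc[:, 1].str.strip().values, index=df.iloc[:, 0].str.strip().values
        )
    return CopyNumberMatrix(values, arm_map)


def write_copy_number_matrix(
    cnv: CopyNumberMatrix,
    path: str | Path,
    dialect: str = "tsv",
    arm_map_path: str | Path | None = None,
) -> None:
    cnv.values.to_csv(path, sep=_sep(dialect), index_label="gene")
    if arm_map_path is not None and cnv.arm_map is not None:
        pd.DataFrame({"gene": cnv.arm_map.index, "arm": cnv.arm_map.values}).to_csv(
            arm_map_path, sep=_sep(dialect), index=False
        )


def read_alteration_table(
    path: str | Path, dialect: str = "csv", layout: str = "long"
) -> AlterationTable:
    """Read binary alteration calls.

    ``layout="long"``: columns (gene, sample, class), one row per event.
    ``layout="wide"``: columns (gene, class, <sample>...), binary cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if layout == "long":
        if df.shape[1] < 3:
            raise ParseError(f"{path}: long layout needs gene, sample, class columns")
        genes = sorted(df.iloc[:, 0].str.strip().unique())
        samples = sorted(df.iloc[:, 1].str.strip().unique())
        layers = {
            cls: pd.DataFrame(0, index=genes, columns=samples, dtype=int)
            for cls in ALTERATION_CLASSES
        }
        for _, row in df.iterrows():
            gene, sample, cls = (str(x).strip() for x in row.iloc[:3])
            if cls not in ALTERATION_CLASSES:
                raise ParseError(
                    f"{path}: unknown alteration class {cls!r}; "
                    f"accepted: {list(ALTERATION_CLASSES)}"
                )
            layers[cls].loc[gene, sample] = 1
        return AlterationTable(layers)
    if layout == "wide":
        if df.shape[1] < 3:
            raise ParseError(f"{path}: wide layout needs gene, class, sample columns")
        gene_col, class_col = df.columns[0], df.columns[1]
        bad = set(df[class_col].str.strip().unique()) - set(ALTERATION_CLASSES)
        if bad:
            raise ParseError(
                f"{path}: unknown alteration class(es) {sorted(bad)}; "
                f"accepted: {list(ALTERATION_CLASSES)}"
            )
        layers = {}
        genes = sorted(df[gene_col].str.strip().unique())
        samples = list(df.columns[2:])
        for cls in ALTERATION_CLASSES:
            sub = df[df[class_col].str.strip() == cls]
            layer = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
            for _, row in sub.iterrows():
                layer.loc[str(row[gene_col]).strip()] = (
                    pd.to_numeric(row.iloc[2:]).astype(int).values
                )
            layers[cls] = layer
        return AlterationTable(layers)
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def write_alteration_table(alt: AlterationTable, path: str | Path, dialect: str = "csv") -> None:
    """Write in long layout (gene, sample, class), one row per event."""
    rows = []
    for cls in ALTERATION_CLASSES:
        layer = alt.layers.get(cls)
        if layer is None:
            continue
        for gene, sample in zip(*np.nonzero(layer.to_numpy())):
            rows.append((layer.index[gene], layer.columns[sample], cls))
    out = pd.DataFrame(rows, columns=["gene", "sample", "class"]).sort_values(
        ["gene", "sample", "class"]
    )
    out.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# result writer
# ---------------------------------------------------------------------------

def write_results(
    assignments,  # SubtypeAssignment (duck-typed to avoid circular import)
    path: str | Path,
    stats_tables: Mapping[str, pd.DataFrame] | None = None,
    out_dir: str | Path | None = None,
) -> None:
    """Write per-sample subtype assignments (and optional stats tables) as CSV.

    Column order is deterministic and output is byte-stable across reruns
    with the same seed.  An empty cohort produces a header-only file.
    """
    df = assignments.to_frame()
    if df.empty:
        logger.warning("write_results: empty cohort, writing header-only file")
    df.to_csv(path, index_label="sample")
    if stats_tables:
        out_dir = Path(out_dir if out_dir is not None else Path(path).parent)
        for name, table in stats_tables.items():
            table.to_csv(out_dir / f"{name}.csv")
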