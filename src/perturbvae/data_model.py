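"""Domain types and IO for L1000-style perturbation expression data.

The universal input is a samples x genes matrix of moderated z-scores
(level-5 style, values expected in [-10, 10]) with per-sample perturbation
metadata: which perturbagen was applied (a small molecule or a single-gene
knockdown), in which cell line, and optionally a perturbagen-class (PCL)
label and the knocked-down gene symbol.

Supported on disk: GCT #1.2 text matrices and plain delimited tables, both
with a delimited sidecar metadata table keyed by ``sample_id``. Drug-target
truth sets are two-column delimited tables (drug id, target gene symbol).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPRESSION_RANGE = 10.0

PERT_TYPES = {"small_molecule", "knockdown", "control", "generated"}

META_COLUMNS = [
    "sample_id",
    "perturbagen_id",
    "pert_type",
    "cell_line",
    "pcl_label",
    "target_gene",
]

ROLES = ("SMP", "GP", "SMGP", "SMC", "SMCNP")

# Proteasome inhibitors forming an outlier distribution in merged sets.
DEFAULT_EXCLUDED_PERTURBAGENS = ("bortezomib", "MG-132")


class DataError(Exception):
    """Base class for data-layer failures."""


class FormatError(DataError):
    """Malformed file header or structure."""


class ParseError(DataError):
    """Non-numeric or otherwise unparseable cell."""


class RangeError(DataError):
    """Expression value outside the expected z-score range."""


class SchemaError(DataError):
    """Required metadata field missing or inconsistent."""


class EmptyResultError(DataError):
    """A filter removed every sample."""


@dataclass
class ExpressionDataset:
    """Samples x genes z-score matrix plus per-sample perturbation metadata.

    Attributes
    ----------
    matrix : ndarray, shape (n_samples, n_genes)
    gene_ids : list of str, ordered gene symbols / probe ids
    sample_meta : DataFrame with columns ``META_COLUMNS``; ``pcl_label`` and
        ``target_gene`` may be null.
    provenance : free-form record of how the dataset was assembled
        (per-rule removal counts, source paths).
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SchemaError("expression matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.sample_meta):
            raise SchemaError(
                f"matrix has {self.matrix.shape[0]} rows but metadata has "
                f"{len(self.sample_meta)} samples"
            )
        if self.matrix.shape[1] != len(self.gene_ids):
            raise SchemaError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.gene_ids)} gene ids were given"
            )
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                self.sample_meta[col] = None
        ids = self.sample_meta["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate sample_id {dup!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise RangeError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def subset(self, mask) -> "ExpressionDataset":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_ids=list(self.gene_ids),
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
            provenance=dict(self.provenance),
        )


@dataclass
class DatasetAssemblySpec:
    """Filter thresholds for assembling analysis datasets.

    ``major_cell_line_min``: a cell line is "major" when it has strictly
    more than this many samples (of the relevant perturbagen type).
    ``major_pcl_min``: a PCL is "major" when at least this many samples
    were treated with its perturbagens.
    ``include_controls``: whether vehicle/control samples from retained
    cell lines are kept in the assembled set.
    """

    major_cell_line_min: int = 10000
    major_pcl_min: int = 150
    exclude_perturbagens: tuple = DEFAULT_EXCLUDED_PERTURBAGENS
    include_controls: bool = False

    def __post_init__(self) -> None:
        if self.major_cell_line_min <= 0 or self.major_pcl_min <= 0:
            raise ValueError("assembly thresholds must be strictly positive")


@dataclass
class DrugTargetTable:
    """Known (drug id, target gene symbol) pairs; a drug may map to
    several genes. Drug ids that differ only by case/whitespace are
    treated as the same perturbagen."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if list(t.columns[:2]) != ["drug_id", "gene"]:
            t.columns = ["drug_id", "gene"] + list(t.columns[2:])
        t["drug_id"] = t["drug_id"].astype(str).str.strip()
        t["_key"] = t["drug_id"].str.casefold()
        t["gene"] = t["gene"].astype(str).str.strip()
        t = t.drop_duplicates(subset=["_key", "gene"]).drop(columns="_key")
        self.table = t.reset_index(drop=True)

    def targets_of(self, drug_id: str) -> list[str]:
        key = str(drug_id).strip().casefold()
        hit = self.table["drug_id"].str.casefold() == key
        return list(self.table.loc[hit, "gene"])

    @property
    def drugs(self) -> list[str]:
        return list(self.table["drug_id"].unique())

    @classmethod
    def read(cls, path, sep: str = "\t") -> "DrugTargetTable":
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["drug_id", "gene"], dtype=str)
        return cls(df)

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, header=False, index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_range(matrix: np.ndarray, permissive: bool) -> None:
    if not np.all(np.isfinite(matrix)):
        raise RangeError("matrix contains non-finite values")
    if permissive:
        return
    bad = np.abs(matrix) > EXPRESSION_RANGE
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise RangeError(
            f"value {matrix[r, c]:g} at row {r}, column {c} outside "
            f"[-{EXPRESSION_RANGE:g}, {EXPRESSION_RANGE:g}]; "
            "pass permissive=True to accept"
        )


def _default_meta(sample_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": sample_ids,
        "perturbagen_id": None,
        "pert_type": None,
        "cell_line": None,
        "pcl_label": None,
        "target_gene": None,
    })


def _read_sidecar(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise SchemaError(f"{meta_path}: sidecar metadata lacks 'sample_id'")
    return meta


def _parse_gct(path) -> tuple[np.ndarray, list[str], list[str]]:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer GCT dimensions") from exc
        body = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if body.shape != (n_rows, n_cols + 2):
        raise FormatError(
            f"{path}: header declares {n_rows}x{n_cols} but table is "
            f"{body.shape[0]}x{body.shape[1] - 2}"
        )
    gene_ids = body.iloc[:, 0].astype(str).tolist()
    sample_ids = list(body.columns[2:])
    values = body.iloc[:, 2:]
    for j, col in enumerate(values.columns):
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any():
            i = int(coerced.isna().idxmax())
            raise ParseError(
                f"{path}: non-numeric value {values[col].iloc[i]!r} at "
                f"gene row {i}, sample column {j}"
            )
    # GCT is genes x samples; normalise to samples x genes.
    matrix = values.to_numpy(dtype=float).T
    return matrix, gene_ids, sample_ids


def _parse_delimited(path, sep) -> tuple[np.ndarray, list[str], list[str]]:
    body = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if body.shape[1] < 1:
        raise FormatError(f"{path}: delimited matrix has no data columns")
    for j, col in enumerate(body.columns):
        coerced = pd.to_numeric(body[col], errors="coerce")
        if coerced.isna().any():
            bad_pos = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value at row {bad_pos}, column {j}"
            )
    # rows = samples, columns = genes
    matrix = body.to_numpy(dtype=float)
    sample_ids = [str(i) for i in body.index]
    gene_ids = [str(c) for c in body.columns]
    return matrix, gene_ids, sample_ids


def load_expression(path, format: str | None = None, meta_path=None,
                    sep: str = "\t", permissive: bool = False) -> ExpressionDataset:
    """Load an expression matrix (GCT #1.2 or delimited) with sidecar metadata.

    GCT files are genes x samples and are transposed on load; delimited
    files are samples x genes with sample ids in the first column. When
    ``meta_path`` is None, ``<path>.meta.tsv`` is used if it exists.
    """
    if format is None:
        format = "gct" if str(path).endswith(".gct") else "delimited"
    if format == "gct":
        matrix, gene_ids, sample_ids = _parse_gct(path)
    elif format == "delimited":
        matrix, gene_ids, sample_ids = _parse_delimited(path, sep)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(gene_ids) < 2:
        raise FormatError(f"{path}: need at least 2 genes, found {len(gene_ids)}")
    _check_range(matrix, permissive)

    if meta_path is None:
        candidate = str(path) + ".meta.tsv"
        meta_path = candidate if os.path.exists(candidate) else None
    if meta_path is not None:
        meta = _read_sidecar(meta_path)
        meta = meta.set_index("sample_id").reindex(sample_ids).reset_index()
    else:
        meta = _default_meta(sample_ids)
    meta = meta.where(pd.notna(meta), None)
    return ExpressionDataset(matrix=matrix, gene_ids=gene_ids, sample_meta=meta,
                             provenance={"source": str(path), "format": format})


def save_expression(data: ExpressionDataset, path, format: str | None = None,
                    sep: str = "\t") -> None:
    """Write a dataset as GCT #1.2 or delimited matrix plus metadata sidecar."""
    if format is None:
        format = "gct" if str(path).endswith(".gct") else "delimited"
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{data.n_genes}\t{data.n_samples}\n")
            header = ["NAME", "Description"] + data.sample_ids
            fh.write("\t".join(header) + "\n")
            for g, row in zip(data.gene_ids, data.matrix.T):
                cells = [g, "na"] + [repr(float(v)) for v in row]
                fh.write("\t".join(cells) + "\n")
    elif format == "delimited":
        df = pd.DataFrame(data.matrix, index=data.sample_ids, columns=data.gene_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep=sep, float_format=None)
    else:
        raise ValueError(f"unknown format {format!r}")
    meta = data.sample_meta[META_COLUMNS]
    meta.to_csv(str(path) + ".meta.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _major_cell_line_mask(meta: pd.DataFrame, pert_type: str, threshold: int):
    sub = meta["pert_type"] == pert_type
    counts = meta.loc[sub, "cell_line"].value_counts()
    major = set(counts[counts > threshold].index)
    return sub & meta["cell_line"].isin(major), major


def assemble_dataset(data: ExpressionDataset, spec: DatasetAssemblySpec,
                     role: str) -> ExpressionDataset:
    """Assemble one of the analysis datasets by role.

    SMP: small-molecule samples from major cell lines (strictly more than
    ``major_cell_line_min`` small-molecule samples). GP: the same for
    knockdowns. SMGP: union of SMP and GP minus samples treated with
    ``exclude_perturbagens`` (outlier proteasome inhibitors). SMC: SMP
    samples carrying a PCL label. SMCNP: SMC minus excluded perturbagens.

    The returned dataset's ``provenance['removed']`` maps each applied rule
    to the number of samples it removed.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    meta = data.sample_meta
    if role in ("SMC", "SMCNP") and meta["pcl_label"].isna().all():
        raise SchemaError(f"role {role} requires pcl_label metadata")
    if meta["pert_type"].isna().any():
        raise SchemaError("assembly requires pert_type for every sample")

    removed: dict[str, int] = {}
    n0 = data.n_samples

    def cell_line_pass(pert_type):
        mask, major = _major_cell_line_mask(meta, pert_type, spec.major_cell_line_min)
        if spec.include_controls:
            mask = mask | ((meta["pert_type"] == "control")
                           & meta["cell_line"].isin(major))
        return mask.to_numpy()

    if role in ("SMP", "SMC", "SMCNP"):
        keep = cell_line_pass("small_molecule")
        removed["not_small_molecule_or_minor_cell_line"] = int(n0 - keep.sum())
    elif role == "GP":
        keep = cell_line_pass("knockdown")
        removed["not_knockdown_or_minor_cell_line"] = int(n0 - keep.sum())
    else:  # SMGP
        sm = cell_line_pass("small_molecule")
        gp = cell_line_pass("knockdown")
        keep = sm | gp
        removed["minor_cell_line_or_control"] = int(n0 - keep.sum())

    if role in ("SMGP", "SMCNP"):
        excl_keys = {str(p).casefold() for p in spec.exclude_perturbagens}
        excl = meta["perturbagen_id"].astype(str).str.casefold().isin(excl_keys)
        excl = excl.to_numpy()
        removed["excluded_perturbagen"] = int((keep & excl).sum())
        keep = keep & ~excl

    if role in ("SMC", "SMCNP"):
        unlabeled = meta["pcl_label"].isna().to_numpy()
        removed["no_pcl_label"] = int((keep & unlabeled).sum())
        keep = keep & ~unlabeled

    if not keep.any():
        raise EmptyResultError(f"role {role}: every sample was filtered out")
    out = data.subset(keep)
    out.provenance["role"] = role
    out.provenance["removed"] = removed
    out.provenance["n_input"] = n0
    return out


def filter_major_pcls(data: ExpressionDataset, min_samples: int = 150):
    """PCLs with at least ``min_samples`` treated samples.

    Returns (pcl_label, sample_count) pairs sorted by count descending,
    ties by label.
    """
    labels = data.sample_meta["pcl_label"].dropna()
    counts = labels.value_counts()
    major = counts[counts >= min_samples]
    return sorted(
        [(str(lbl), int(n)) for lbl, n in major.items()],
        key=lambda t: (-t[1], t[0]),
    )
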