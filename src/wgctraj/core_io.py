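"""Shared domain types and text I/O for the contrast-trajectory pipeline.

All tabular interchange is tab-separated UTF-8 with a mandatory header row and
"." as the decimal mark.  Vertex indices are 0-based everywhere.  Ages are
floating-point years; timepoint labels are explicit and never inferred from
age ordering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("wgctraj")

DX_LEVELS = ("ASD", "TD")
TIMEPOINT_LEVELS = ("baseline", "followup", "single")
SEX_LEVELS = ("M", "F")

#: Mandatory cohort-manifest columns, in canonical order.
COHORT_COLUMNS = ("subject_id", "dx", "site", "scanner", "sex", "timepoint", "age")


class FormatError(ValueError):
    """A file does not conform to the expected dialect or schema."""


class IntegrityError(ValueError):
    """Data are well-formed but violate a cross-record invariant."""


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-subject metadata: diagnosis, site, scanner, sex, age per timepoint.

    Wraps a :class:`pandas.DataFrame` whose rows are scans (one row per
    subject and timepoint).  Longitudinal subjects appear twice, with
    ``timepoint`` "baseline"/"followup" and a strictly larger follow-up age.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"cohort manifest missing mandatory column(s): {missing}")
        df = self.df.reset_index(drop=True)
        df["subject_id"] = df["subject_id"].astype(str)
        for col in ("dx", "site", "scanner", "sex", "timepoint"):
            df[col] = df[col].astype(str)
        df["age"] = pd.to_numeric(df["age"])
        if df[["dx", "site", "scanner"]].isin(["", "nan"]).any().any():
            raise IntegrityError("empty dx/site/scanner entries in cohort manifest")
        bad_dx = set(df["dx"]) - set(DX_LEVELS)
        if bad_dx:
            raise FormatError(f"unknown dx level(s) {sorted(bad_dx)}; expected {DX_LEVELS}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINT_LEVELS)
        if bad_tp:
            raise FormatError(
                f"unknown timepoint label(s) {sorted(bad_tp)}; expected {TIMEPOINT_LEVELS}"
            )
        if (df["age"] <= 0).any():
            bad = df.loc[df["age"] <= 0, "subject_id"].tolist()
            raise ValueError(f"non-positive age for subject(s) {bad}")
        dup = df.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "timepoint"]].itertuples(index=False)
            raise IntegrityError(
                "duplicate (subject_id, timepoint) rows: "
                + ", ".join(f"({s}, {t})" for s, t in pairs)
            )
        # Longitudinal consistency: baseline/followup come in pairs, aging forward.
        long_df = df[df["timepoint"].isin(("baseline", "followup"))]
        for sid, grp in long_df.groupby("subject_id"):
            tps = set(grp["timepoint"])
            if tps != {"baseline", "followup"}:
                raise IntegrityError(
                    f"longitudinal subject {sid} must have exactly one baseline and "
                    f"one followup row (got {sorted(tps)})"
                )
            age_b = float(grp.loc[grp["timepoint"] == "baseline", "age"].iloc[0])
            age_f = float(grp.loc[grp["timepoint"] == "followup", "age"].iloc[0])
            if age_f <= age_b:
                raise IntegrityError(
                    f"subject {sid}: follow-up age {age_f} not greater than baseline {age_b}"
                )
        object.__setattr__(self, "df", df)

    # -- convenience accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def row_keys(self) -> list[tuple[str, str]]:
        """(subject_id, timepoint) key per row — the unique row identifier."""
        return list(zip(self.df["subject_id"], self.df["timepoint"]))

    def counts_by_site(self) -> pd.DataFrame:
        """Number of scans per (site, dx), one column per diagnosis."""
        return self.df.groupby(["site", "dx"]).size().unstack(fill_value=0)

    def subset(self, mask: Sequence[bool]) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask, dtype=bool)].copy())

    def one_row_per_subject(self) -> "CohortTable":
        """First row per subject (baseline for longitudinal pairs), in order
        of first appearance — matches the row order of per-subject angle
        matrices built from a two-scans-per-subject stack.  Timepoints are
        relabelled "single" since the slice no longer carries the pair."""
        df = self.df.drop_duplicates(subset="subject_id").copy()
        df["timepoint"] = "single"
        return CohortTable(df)


@dataclass
class VertexMap:
    """Per-vertex scalar values on a shared surface template."""

    values: np.ndarray
    template_id: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    @property
    def n_vertices(self) -> int:
        return self.values.size

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("vertex map contains non-finite values without a mask")


@dataclass
class SubjectMatrix:
    """Stacked per-vertex maps, one row per cohort row (scan).

    ``row_ids`` carries the subject_id per row; for longitudinal stacks the
    accompanying :class:`CohortTable` slice disambiguates timepoints — row i
    of the matrix always corresponds to cohort row i.
    """

    row_ids: list[str]
    values: np.ndarray
    kind: str = "wgc"  # wgc | angle | zscored_angle

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.row_ids = [str(r) for r in self.row_ids]
        if self.values.shape[0] != len(self.row_ids):
            raise IntegrityError(
                f"{len(self.row_ids)} row ids but {self.values.shape[0]} matrix rows"
            )
        nan_rows = np.isnan(self.values).all(axis=1)
        if nan_rows.any():
            # Angle rows can be masked wholesale (zero age-denominator events
            # hit every vertex of a subject at once); raw data cannot.
            if self.kind == "wgc":
                raise IntegrityError("subject matrix contains an all-NaN row")
            warnings.warn(
                f"{int(nan_rows.sum())} fully-masked subject row(s) in {self.kind} matrix",
                stacklevel=2,
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]


@dataclass
class SurfaceMesh:
    """Triangulated surface standing in for the common average template."""

    vertex_coords: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (T, 3) 0-based vertex indices
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        V = self.n_vertices
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= V:
            raise IntegrityError("triangle indices out of range [0, V)")
        used = np.zeros(V, dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            orphans = np.flatnonzero(~used)
            raise IntegrityError(f"vertices not in any triangle: {orphans[:10].tolist()}")
        if not self.is_connected():
            raise IntegrityError("mesh is not edge-connected")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), i < j."""
        if self._edges is None:
            tri = self.triangles
            pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
            pairs.sort(axis=1)
            self._edges = np.unique(pairs, axis=0)
        return self._edges

    def adjacency(self) -> csr_matrix:
        e = self.edges
        V = self.n_vertices
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(V, V)).tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        d = self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    @property
    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_cohort(path: str | Path) -> CohortTable:
    """Read a tab-separated cohort manifest.

    The header must name at least ``subject_id, dx, site, scanner, sex,
    timepoint, age``; unknown columns are preserved on the wrapped frame.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse cohort manifest {path}: {exc}") from exc
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False)


def read_subject_matrix(
    path: str | Path, cohort: CohortTable, kind: str = "wgc"
) -> SubjectMatrix:
    """Read a subjects x vertices TSV and reorder rows to match ``cohort``.

    The first column must be ``subject_id``; an optional second column
    ``timepoint`` disambiguates longitudinal stacks.  Every cohort row must
    be present exactly once, and every file row must belong to the cohort.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged rows in subject matrix {path}: {exc}") from exc
    if "subject_id" not in df.columns:
        raise FormatError("subject matrix must have a leading subject_id column")
    if kind == "wgc" and df.isna().any().any():
        raise FormatError(f"ragged or non-numeric rows in subject matrix {path}")
    has_tp = "timepoint" in df.columns
    meta_cols = ["subject_id"] + (["timepoint"] if has_tp else [])
    value_cols = [c for c in df.columns if c not in meta_cols]
    if has_tp:
        keys = list(zip(df["subject_id"], df["timepoint"]))
        wanted = cohort.row_keys
    else:
        keys = df["subject_id"].tolist()
        wanted = cohort.subject_ids
    index = {k: i for i, k in enumerate(keys)}
    unknown = [k for k in keys if k not in set(wanted)]
    if unknown:
        raise IntegrityError(f"matrix rows absent from cohort: {unknown[:5]}")
    try:
        order = [index[k] for k in wanted]
    except KeyError as exc:
        raise IntegrityError(f"cohort row {exc.args[0]!r} missing from matrix") from exc
    values = df[value_cols].to_numpy(dtype=float)[order]
    return SubjectMatrix(row_ids=[str(s) for s in cohort.subject_ids], values=values, kind=kind)


def write_subject_matrix(
    matrix: SubjectMatrix, path: str | Path, cohort: CohortTable | None = None
) -> None:
    """Write a subjects x vertices TSV (columns v0..v{V-1}).

    When ``cohort`` is given (required for longitudinal stacks) a timepoint
    column is included so the file round-trips unambiguously.
    """
    cols = {"subject_id": matrix.row_ids}
    if cohort is not None:
        if cohort.subject_ids != matrix.row_ids:
            raise IntegrityError("cohort row order does not match matrix row order")
        cols["timepoint"] = cohort.df["timepoint"].tolist()
    out = pd.DataFrame(cols)
    vals = pd.DataFrame(matrix.values, columns=[f"v{i}" for i in range(matrix.n_vertices)])
    pd.concat([out, vals], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_vertex_map(vmap: VertexMap, path: str | Path, mask: np.ndarray | None = None) -> None:
    """Write one value per line, preceded by a ``# template_id=...`` header.

    Masked vertices are written as ``nan``; NaN without a mask is an error.
    """
    values = vmap.values
    if mask is None and not np.all(np.isfinite(values)):
        raise ValueError("vertex map contains NaN/inf but no mask was supplied")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# template_id={vmap.template_id}\n")
        for v in values:
            fh.write(f"{v:.17g}\n")


def read_vertex_map(path: str | Path) -> VertexMap:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# template_id="):
            raise FormatError(f"{path}: missing '# template_id=' header line")
        template_id = first.split("=", 1)[1]
        values = np.array([float(line) for line in fh if line.strip()], dtype=float)
    return VertexMap(values=values, template_id=template_id)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    payload = {
        "vertex_coords": mesh.vertex_coords.tolist(),
        "triangles": mesh.triangles.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_mesh(path: str | Path) -> SurfaceMesh:
    payload = json.loads(Path(path).read_text())
    return SurfaceMesh(
        vertex_coords=np.asarray(payload["vertex_coords"], dtype=float),
        triangles=np.asarray(payload["triangles"], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load the single YAML configuration file (sections per pipeline stage)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a YAML mapping of stage sections")
    return cfg


def resolve_option(cli_value, config: dict | None, section: str, key: str, default=None):
    """Config twin resolution: CLI flag wins over config, config over default."""
    if cli_value is not None:
        return cli_value
    if config and section in config and key in config[section]:
        return config[section][key]
    return default
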