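"""Rate-of-change "angle" metrics for white-gray contrast.

For a longitudinal pair of scans the per-vertex angle is

    alpha = arctan( (WGC_flp - WGC_bsl) / (age_flp - age_bsl) ),

the arctangent of the yearly contrast change.  The cross-sectional analogue
replaces the within-subject difference by mean pairwise differences against
the subject's peers — same diagnostic group within the same acquisition
site — which cancels additive site effects:

    alpha_i = arctan( sum_{j != i} (WGC_i - WGC_j) / sum_{j != i} (age_i - age_j) ).

Angles are strictly inside (-pi/2, pi/2).  Before modelling, angle matrices
are z-scored per vertex across subjects (sample sd, n-1) to emphasise the
shape of the distribution over its magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import CohortTable, SubjectMatrix, VertexMap, logger

#: Cells (site x dx) smaller than this are dropped by `filter_small_cells`.
DEFAULT_MIN_CELL = 4


@dataclass
class AngleMap:
    """Per-vertex angle values (radians) for one subject."""

    values: np.ndarray
    sample_kind: str  # "lngt" | "crsc"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.abs(finite).max() >= np.pi / 2:
            raise ValueError("angle values must lie strictly inside (-pi/2, pi/2)")


def longitudinal_angle(
    wgc_bsl: VertexMap, wgc_flp: VertexMap, age_bsl: float, age_flp: float
) -> AngleMap:
    """Within-subject angle from a baseline/follow-up scan pair."""
    if age_flp <= age_bsl:
        raise ValueError(
            f"follow-up age {age_flp} must exceed baseline age {age_bsl}"
        )
    if wgc_bsl.n_vertices != wgc_flp.n_vertices:
        raise ValueError("baseline and follow-up maps differ in vertex count")
    rate = (wgc_flp.values - wgc_bsl.values) / (age_flp - age_bsl)
    return AngleMap(values=np.arctan(rate), sample_kind="lngt")


def longitudinal_angles(matrix: SubjectMatrix, cohort: CohortTable) -> SubjectMatrix:
    """Stack per-subject longitudinal angles from a two-rows-per-subject matrix.

    Output rows follow the order in which subjects first appear in the cohort.
    """
    df = cohort.df
    ids, values = [], []
    for sid in dict.fromkeys(df["subject_id"]):
        rows = np.flatnonzero((df["subject_id"] == sid).to_numpy())
        tp = df["timepoint"].iloc[rows]
        i_b = rows[list(tp).index("baseline")]
        i_f = rows[list(tp).index("followup")]
        amap = longitudinal_angle(
            VertexMap(matrix.values[i_b]),
            VertexMap(matrix.values[i_f]),
            float(df["age"].iloc[i_b]),
            float(df["age"].iloc[i_f]),
        )
        ids.append(sid)
        values.append(amap.values)
    return SubjectMatrix(row_ids=ids, values=np.vstack(values), kind="angle")


def cross_sectional_angle(matrix: SubjectMatrix, cohort: CohortTable) -> SubjectMatrix:
    """Per-subject cross-sectional angles against same-site, same-dx peers.

    Subjects whose age equals the mean age of their peers have a zero
    denominator at every vertex; their whole row is masked (NaN) with a
    warning rather than the subject being dropped.
    """
    df = cohort.df
    if len(df) != matrix.n_subjects:
        raise ValueError("cohort and matrix row counts differ")
    W = matrix.values
    ages = df["age"].to_numpy(dtype=float)
    out = np.full_like(W, np.nan)
    for (site, dx), idx in df.groupby(["site", "dx"]).indices.items():
        n = len(idx)
        if n < 2:
            raise ValueError(f"singleton cell (site={site}, dx={dx}); need >= 2 subjects")
        if n < DEFAULT_MIN_CELL:
            warnings.warn(
                f"cell (site={site}, dx={dx}) has only {n} subjects", stacklevel=2
            )
        Wc = W[idx]
        ac = ages[idx]
        num = n * Wc - Wc.sum(axis=0)  # sum_{j != i} (W_i - W_j), vectorised
        den = n * ac - ac.sum()
        zero = den == 0
        if zero.any():
            bad = [df["subject_id"].iloc[idx[k]] for k in np.flatnonzero(zero)]
            warnings.warn(
                f"zero age denominator for subject(s) {bad} in cell "
                f"(site={site}, dx={dx}); rows masked",
                stacklevel=2,
            )
        den_safe = np.where(zero, 1.0, den)
        cell_alpha = np.arctan(num / den_safe[:, None])
        cell_alpha[zero] = np.nan
        out[idx] = cell_alpha
    return SubjectMatrix(row_ids=matrix.row_ids, values=out, kind="angle")


def standardize(matrix: SubjectMatrix, axis: str = "vertex") -> SubjectMatrix:
    """Z-score an angle matrix (sample sd, ddof=1).

    ``axis="vertex"`` standardises each vertex column across subjects (the
    default used throughout the pipeline); ``axis="pooled"`` uses the single
    pooled mean and sd of all finite entries.  Zero-variance columns map to 0.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("standardisation needs at least 2 subjects")
    if axis == "vertex":
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (X - mean) / sd_safe
        Z[:, sd == 0] = 0.0
    elif axis == "pooled":
        finite = X[np.isfinite(X)]
        sd = finite.std(ddof=1)
        Z = (X - finite.mean()) / (sd if sd > 0 else 1.0)
        if sd == 0:
            Z[:] = 0.0
    else:
        raise ValueError("axis must be 'vertex' or 'pooled'")
    return SubjectMatrix(row_ids=matrix.row_ids, values=Z, kind="zscored_angle")


def filter_small_cells(
    cohort: CohortTable,
    matrix: SubjectMatrix | None = None,
    min_cell: int = DEFAULT_MIN_CELL,
) -> tuple[CohortTable, SubjectMatrix | None]:
    """Drop sites where either diagnostic group has fewer than ``min_cell``
    subjects — the standard data-preparation filter before angle computation."""
    df = cohort.df
    counts = df.groupby(["site", "dx"])["subject_id"].nunique().unstack(fill_value=0)
    for dx in ("ASD", "TD"):
        if dx not in counts.columns:
            counts[dx] = 0
    keep_sites = counts.index[(counts["ASD"] >= min_cell) & (counts["TD"] >= min_cell)]
    keep = df["site"].isin(keep_sites).to_numpy()
    dropped = sorted(set(df["site"]) - set(keep_sites))
    if dropped:
        logger.info("filter_small_cells: dropping site(s) %s", dropped)
    out_cohort = cohort.subset(keep)
    out_matrix = None
    if matrix is not None:
        out_matrix = SubjectMatrix(
            row_ids=[r for r, k in zip(matrix.row_ids, keep) if k],
            values=matrix.values[keep],
            kind=matrix.kind,
        )
    return out_cohort, out_matrix
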