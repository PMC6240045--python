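"""Synthetic cohorts, meshes and vertex-wise contrast data.

The generator plants a known diagnosis-dependent linear age trajectory in
white-gray contrast (WGC) at every vertex of a sphere-like template mesh, so
that each downstream stage — angle metrics, PLS, the Bayesian classifier,
severity prediction and motion QC — can be exercised and validated without
any imaging data.

The default cross-sectional specification mirrors the published multi-site
study structure it emulates: 14 acquisition sites with fixed per-site ASD/TD
group sizes (totalling 359 male subjects, 146 ASD), per-site age means and
standard deviations, and a Siemens/Philips scanner split.  The default
longitudinal specification is 12 ASD and 9 TD subjects over two sites with a
fixed 2.31-year inter-scan interval around a 12.75-year baseline mean.

Effect sizes (WGC units/year) are NOT published quantities: they are
synthetic-only choices, documented in the methods note, sized so that the
planted sign pattern is detectable at the study's sample sizes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull

from .contrast import smooth_matrix
from .core_io import CohortTable, SubjectMatrix, SurfaceMesh, VertexMap

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition site: group sizes and age distributions (years)."""

    name: str
    scanner: str
    n_asd: int
    n_td: int
    age_asd: tuple[float, float]  # (mean, sd)
    age_td: tuple[float, float]


#: Default cross-sectional site structure (14 sites, 146 ASD + 213 TD = 359).
DEFAULT_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("CMU", "Siemens", 6, 6, (22.5, 2.6), (24.7, 4.8)),
    SiteSpec("KKI", "Philips", 11, 17, (10.4, 1.5), (10.2, 1.2)),
    SiteSpec("LEUVEN_1", "Philips", 8, 10, (22.4, 3.2), (24.0, 3.0)),
    SiteSpec("LEUVEN_2", "Philips", 8, 8, (13.4, 1.1), (14.9, 1.5)),
    SiteSpec("NYU", "Siemens", 25, 30, (14.5, 7.0), (12.3, 3.9)),
    SiteSpec("TRINITY", "Philips", 13, 11, (16.6, 2.9), (17.1, 3.7)),
    SiteSpec("UCLA_1", "Siemens", 6, 9, (14.0, 3.6), (13.4, 1.5)),
    SiteSpec("ETH_1", "Philips", 6, 17, (21.3, 4.4), (22.6, 4.5)),
    SiteSpec("GU_1", "Siemens", 9, 15, (10.7, 1.7), (10.7, 1.5)),
    SiteSpec("KKI_2", "Philips", 10, 44, (11.0, 1.3), (10.5, 1.2)),
    SiteSpec("NYU_2", "Siemens", 22, 16, (8.8, 3.0), (8.8, 1.8)),
    SiteSpec("OHSU_1", "Siemens", 6, 7, (12.0, 2.7), (8.9, 0.7)),
    SiteSpec("TCD_1", "Philips", 12, 18, (14.3, 3.3), (15.7, 3.2)),
    SiteSpec("UCLA_2", "Siemens", 4, 5, (12.0, 1.8), (10.8, 2.9)),
)

#: Default longitudinal site structure (12 ASD + 9 TD over two Siemens sites).
DEFAULT_LONGITUDINAL_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("UCLA", "Siemens", 6, 4, (12.75, 2.0), (12.75, 2.0)),
    SiteSpec("UPSM", "Siemens", 6, 5, (12.75, 2.0), (12.75, 2.0)),
)


@dataclass
class SimulationSpec:
    """Everything the generator needs besides the planted effect template."""

    n_vertices: int = 500
    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    longitudinal_sites: tuple[SiteSpec, ...] = DEFAULT_LONGITUDINAL_SITES
    scan_interval_years: float = 2.31
    site_offset_sd: float = 0.01
    scanner_offset_sd: float = 0.005
    subject_intercept_sd: float = 0.0
    subject_slope_sd: float = 0.002
    noise_sd: float = 0.002
    baseline_wgc_mean: float = 1.25
    age_anchor: str = "cell"  # "cell" | "site" | "global"
    ados_noise_sd: float = 0.0
    rng_seed: int = 0
    min_age_years: float = 3.0

    def __post_init__(self) -> None:
        if self.age_anchor not in ("cell", "site", "global"):
            raise ValueError("age_anchor must be 'cell', 'site' or 'global'")
        for name in (
            "site_offset_sd",
            "scanner_offset_sd",
            "subject_intercept_sd",
            "subject_slope_sd",
            "noise_sd",
            "ados_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for s in tuple(self.sites) + tuple(self.longitudinal_sites):
            if s.n_asd < 1 or s.n_td < 1:
                raise ValueError(f"site {s.name}: group sizes must be >= 1")

    def metadata(self) -> dict:
        """JSON-serialisable record of the spec, including the seed."""
        return asdict(self)


@dataclass
class EffectTemplate:
    """Planted per-vertex WGC-change slopes for the two diagnostic groups."""

    slope_td: VertexMap  # WGC units / year
    slope_asd: VertexMap
    negative_fraction: float  # measured fraction with slope_asd < slope_td
    patch_spec: tuple = ()

    def recount_negative_fraction(self) -> float:
        return float(np.mean(self.slope_asd.values < self.slope_td.values))


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

#: Radius of the synthetic spherical template, mm (brain-scale).
SPHERE_RADIUS_MM = 100.0


def make_mesh(n_vertices: int, seed: int = 0) -> SurfaceMesh:
    """Triangulated sphere-like template with near-uniform vertex spacing.

    Vertices are a Fibonacci lattice on a sphere of radius 100 mm, rotated by
    a seed-dependent random rotation; triangles come from the convex hull.
    """
    if n_vertices < 12:
        raise ValueError(f"need at least 12 vertices, got {n_vertices}")
    rng = np.random.default_rng(seed)
    i = np.arange(n_vertices, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n_vertices
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # random rotation keeps the lattice orientation seed-dependent
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = pts @ q.T * SPHERE_RADIUS_MM
    hull = ConvexHull(pts)
    return SurfaceMesh(vertex_coords=pts, triangles=hull.simplices)


def expected_uniform_spacing(n_vertices: int, radius: float = SPHERE_RADIUS_MM) -> float:
    """Hexagonal-packing estimate of nearest-neighbour spacing on a sphere."""
    area_per_vertex = 4.0 * np.pi * radius**2 / n_vertices
    return float(np.sqrt(2.0 * area_per_vertex / np.sqrt(3.0)))


# ---------------------------------------------------------------------------
# Effect template
# ---------------------------------------------------------------------------

#: Synthetic-only effect sizes (WGC units/year); see docs/methods.md.
DEFAULT_SLOPE_TD = -0.008
DEFAULT_SLOPE_CONTRAST = 0.012
DEFAULT_FIELD_FWHM_MM = 40.0


def _grow_patch(mesh: SurfaceMesh, seed_vertex: int, radius_mm: float) -> np.ndarray:
    """Connected vertex set grown by breadth-first search in mesh-edge hops
    until the hop count covers the requested geodesic radius."""
    n_hops = max(0, int(np.ceil(radius_mm / mesh.mean_edge_length)))
    adj = mesh.adjacency()
    visited = {int(seed_vertex)}
    frontier = deque([(int(seed_vertex), 0)])
    while frontier:
        v, d = frontier.popleft()
        if d >= n_hops:
            continue
        for nb in adj.indices[adj.indptr[v] : adj.indptr[v + 1]]:
            if int(nb) not in visited:
                visited.add(int(nb))
                frontier.append((int(nb), d + 1))
    return np.fromiter(visited, dtype=np.int64)


def make_effect_template(
    mesh: SurfaceMesh,
    negative_fraction: float = 0.81,
    patch_spec: tuple = (),
    seed: int = 0,
    slope_td: float = DEFAULT_SLOPE_TD,
    slope_contrast: float = DEFAULT_SLOPE_CONTRAST,
    field_fwhm_mm: float = DEFAULT_FIELD_FWHM_MM,
) -> EffectTemplate:
    """Plant a spatially coherent sign pattern of group slope differences.

    ``negative_fraction`` of the vertices get slope_asd < slope_td (the
    mutual-decrease regime); the remainder get the opposite sign, emulating
    focal increases.  ``patch_spec`` entries (seed_vertex, radius_mm, sign)
    force connected "primary-sensory-like" patches to a given sign before the
    global fraction is balanced on the remaining free vertices, so the
    measured fraction always honours ``negative_fraction`` to within 1/V.
    """
    if not 0.0 <= negative_fraction <= 1.0:
        raise ValueError("negative_fraction must lie in [0, 1]")
    V = mesh.n_vertices
    rng = np.random.default_rng(seed)
    field = smooth_matrix(rng.standard_normal((1, V)), mesh, field_fwhm_mm)[0]

    forced = np.zeros(V, dtype=int)  # -1 forced negative, +1 forced positive
    for seed_vertex, radius_mm, sign in patch_spec:
        if sign not in (-1, 1):
            raise ValueError(f"patch sign must be -1 or +1, got {sign}")
        forced[_grow_patch(mesh, seed_vertex, radius_mm)] = sign

    n_neg = int(round(negative_fraction * V))
    n_forced_neg = int((forced == -1).sum())
    n_forced_pos = int((forced == 1).sum())
    if n_forced_pos > V - n_neg:
        raise ValueError(
            f"positive patches cover {n_forced_pos} vertices, more than the "
            f"{V - n_neg} allowed by negative_fraction={negative_fraction}"
        )
    if n_forced_neg > n_neg:
        raise ValueError(
            f"negative patches cover {n_forced_neg} vertices, more than the "
            f"{n_neg} allowed by negative_fraction={negative_fraction}"
        )
    negative = forced == -1
    free = np.flatnonzero(forced == 0)
    n_more = n_neg - n_forced_neg
    # most-negative field values become the decrease region: coherent blobs
    order = free[np.argsort(field[free], kind="stable")]
    negative[order[:n_more]] = True

    delta = np.where(negative, -slope_contrast, slope_contrast)
    tid = "synthetic-sphere"
    template = EffectTemplate(
        slope_td=VertexMap(np.full(V, slope_td), template_id=tid),
        slope_asd=VertexMap(slope_td + delta, template_id=tid),
        negative_fraction=float(negative.mean()),
        patch_spec=tuple(patch_spec),
    )
    assert abs(template.negative_fraction - negative_fraction) <= 1.0 / V + 1e-12
    return template


# ---------------------------------------------------------------------------
# Cohort + data simulation
# ---------------------------------------------------------------------------


def _sample_ages(rng, mean: float, sd: float, n: int, min_age: float) -> np.ndarray:
    ages = rng.normal(mean, sd, size=n)
    return np.clip(ages, min_age, None)


def _offsets(rng, names: list[str], sd: float) -> dict[str, float]:
    return {name: float(rng.normal(0.0, sd)) for name in names}


def simulate_cross_sectional(
    spec: SimulationSpec, template: EffectTemplate
) -> tuple[CohortTable, SubjectMatrix]:
    """Generate the cross-sectional cohort and its WGC matrix.

    Per subject i at age a:
    WGC_v = baseline + slope_dx,v (a - age_ref) + site_offset + scanner_offset
            + N(0, noise_sd), with age_ref the cohort grand mean age.
    """
    if template.slope_td.n_vertices != spec.n_vertices:
        raise ValueError("template vertex count does not match spec.n_vertices")
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for site in spec.sites:
        for dx, n, (mean, sd) in (
            ("ASD", site.n_asd, site.age_asd),
            ("TD", site.n_td, site.age_td),
        ):
            for age in _sample_ages(rng, mean, sd, n, spec.min_age_years):
                rows.append(
                    {
                        "subject_id": f"crsc-{site.name}-{dx}-{len(rows):04d}",
                        "dx": dx,
                        "site": site.name,
                        "scanner": site.scanner,
                        "sex": "M",
                        "timepoint": "single",
                        "age": float(age),
                    }
                )
    cohort = CohortTable(pd.DataFrame(rows))
    matrix = _wgc_from_trajectories(cohort, spec, template, rng)
    return cohort, matrix


def simulate_longitudinal(
    spec: SimulationSpec, template: EffectTemplate
) -> tuple[CohortTable, SubjectMatrix]:
    """Generate the longitudinal cohort: two rows (scans) per subject.

    Baseline and follow-up WGC come from the same per-subject trajectory with
    independent measurement noise; the inter-scan interval is fixed at
    ``spec.scan_interval_years``.
    """
    if template.slope_td.n_vertices != spec.n_vertices:
        raise ValueError("template vertex count does not match spec.n_vertices")
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 1)))
    rows = []
    sid = 0
    for site in spec.longitudinal_sites:
        for dx, n, (mean, sd) in (
            ("ASD", site.n_asd, site.age_asd),
            ("TD", site.n_td, site.age_td),
        ):
            for age_bsl in _sample_ages(rng, mean, sd, n, spec.min_age_years):
                subject = f"lngt-{site.name}-{dx}-{sid:03d}"
                sid += 1
                for tp, age in (
                    ("baseline", age_bsl),
                    ("followup", age_bsl + spec.scan_interval_years),
                ):
                    rows.append(
                        {
                            "subject_id": subject,
                            "dx": dx,
                            "site": site.name,
                            "scanner": site.scanner,
                            "sex": "M",
                            "timepoint": tp,
                            "age": float(age),
                        }
                    )
    cohort = CohortTable(pd.DataFrame(rows))
    matrix = _wgc_from_trajectories(cohort, spec, template, rng)
    return cohort, matrix


def _wgc_from_trajectories(
    cohort: CohortTable, spec: SimulationSpec, template: EffectTemplate, rng
) -> SubjectMatrix:
    df = cohort.df
    if spec.age_anchor == "global":
        ref = float(df["age"].mean())
        age_ref = {k: ref for k in zip(df["site"], df["dx"])}
    elif spec.age_anchor == "site":
        by_site = df.groupby("site")["age"].mean().to_dict()
        age_ref = {k: by_site[k[0]] for k in zip(df["site"], df["dx"])}
    else:
        # "cell": anchor each (site, dx) cell at its own mean age.  The
        # planted effect is then a pure rate-of-change difference with no
        # static level difference between diagnostic groups — slopes anchored
        # at a shared reference would otherwise leak a level difference
        # wherever the groups' age distributions are imbalanced.
        age_ref = df.groupby(["site", "dx"])["age"].mean().to_dict()
    site_off = _offsets(rng, sorted(df["site"].unique()), spec.site_offset_sd)
    scan_off = _offsets(rng, sorted(df["scanner"].unique()), spec.scanner_offset_sd)
    intercepts = {
        sid: float(rng.normal(0.0, spec.subject_intercept_sd))
        for sid in dict.fromkeys(df["subject_id"])
    }
    # per-subject "developmental tempo": a global offset to the slope map,
    # the main source of between-subject angle spread within a group
    tempo = {
        sid: float(rng.normal(0.0, spec.subject_slope_sd))
        for sid in dict.fromkeys(df["subject_id"])
    }
    slopes = {"TD": template.slope_td.values, "ASD": template.slope_asd.values}
    V = spec.n_vertices
    values = np.empty((len(df), V))
    for i, row in enumerate(df.itertuples(index=False)):
        mean_map = (
            spec.baseline_wgc_mean
            + (slopes[row.dx] + tempo[row.subject_id])
            * (row.age - age_ref[(row.site, row.dx)])
            + site_off[row.site]
            + scan_off[row.scanner]
            + intercepts[row.subject_id]
        )
        values[i] = mean_map + rng.normal(0.0, spec.noise_sd, size=V)
    return SubjectMatrix(row_ids=df["subject_id"].tolist(), values=values, kind="wgc")


# ---------------------------------------------------------------------------
# Behavioural scores
# ---------------------------------------------------------------------------

#: Social+communication totals are clipped to a plausible range.
ADOS_TOTAL_RANGE = (0, 22)
ADOS_LATENT_CENTER = 10.0
ADOS_LATENT_SCALE = 4.0


def simulate_ados(
    cohort: CohortTable,
    expression: np.ndarray,
    target_r: float = 0.42,
    seed: int = 0,
    extra_noise_sd: float = 0.0,
) -> CohortTable:
    """Attach ADOS social+communication totals to the ASD subjects.

    ``expression`` is one scalar per cohort row measuring how strongly the
    subject expresses the planted pattern (e.g. a brain score).  For ASD rows
    with positive expression, the integer total is generated so that its
    sample correlation with log(expression) approximates ``target_r``; ASD
    rows with non-positive expression receive totals from the marginal score
    distribution.  TD rows get no score.  ADOS modules are assigned from age
    (a synthetic convention: <10 y module 2, 10-16 y module 3, else 4).
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie in (0, 1)")
    df = cohort.df.copy()
    expression = np.asarray(expression, dtype=float).reshape(-1)
    if expression.size != len(df):
        raise ValueError("expression must have one value per cohort row")
    asd = (df["dx"] == "ASD").to_numpy()
    if not asd.any():
        raise ValueError("cohort contains no ASD subjects to score")
    rng = np.random.default_rng(seed)

    latent = np.full(len(df), np.nan)
    pos = asd & (expression > 0)
    if pos.any():
        logx = np.log(expression[pos])
        sd = logx.std(ddof=1)
        z = (logx - logx.mean()) / (sd if sd > 0 else 1.0)
        noise = rng.standard_normal(pos.sum())
        latent[pos] = target_r * z + np.sqrt(1.0 - target_r**2) * noise
    rest = asd & ~pos
    latent[rest] = rng.standard_normal(rest.sum())
    if extra_noise_sd > 0:
        latent[asd] += rng.normal(0.0, extra_noise_sd, size=asd.sum())

    totals = np.round(ADOS_LATENT_CENTER + ADOS_LATENT_SCALE * latent[asd])
    totals = np.clip(totals, *ADOS_TOTAL_RANGE).astype(int)

    # keep one score per subject: both rows of a longitudinal pair share it
    df.loc[asd, "ados_social_comm_total"] = totals.astype(float)
    df["ados_module"] = np.where(
        df["age"] < 10, 2, np.where(df["age"] < 16, 3, 4)
    ).astype(float)
    df.loc[~asd, "ados_module"] = np.nan
    first = df.groupby("subject_id")["ados_social_comm_total"].transform("first")
    df["ados_social_comm_total"] = first
    return CohortTable(df)


# ---------------------------------------------------------------------------
# Motion toy volumes
# ---------------------------------------------------------------------------


def simulate_motion_volume(
    shape: tuple[int, int, int] = (32, 32, 32),
    ringing_amplitude: float = 0.0,
    seed: int = 0,
    ripple_cycles: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth toy volume plus a sinusoidal "ringing" ripple along one axis.

    Returns (intensities, white-matter mask); the mask marks the central
    half-width block of the volume.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("shape must be 3-D with every axis >= 16")
    if ringing_amplitude < 0:
        raise ValueError("ringing amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    base = 1.0 + 0.2 * base / max(base.std(), 1e-12)
    z = np.arange(shape[0], dtype=float)
    ripple = ringing_amplitude * np.sin(2.0 * np.pi * ripple_cycles * z / shape[0])
    vol = base + ripple[:, None, None]
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(s // 4, s - s // 4) for s in shape)
    mask[sl] = True
    return vol, mask
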