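"""White-gray contrast and surface smoothing.

WGC at a vertex is the ratio of the T1-weighted intensity sampled 1 mm inside
the white surface (sub-white) to the intensity sampled 1 mm outside
(supra-white).  Smoothing is iterated edge-weighted diffusion on the template
mesh whose accumulated kernel width matches a requested Gaussian FWHM — the
standard heat-kernel approximation to geodesic Gaussian smoothing.

This module starts from already-sampled intensity pairs; the geometric
machinery that produces them (distance maps, surface deformation) belongs to
the upstream surface-extraction pipeline and is out of scope here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import diags, identity

from .core_io import SurfaceMesh, VertexMap, logger

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class IntensitySamplePair:
    """Sub-/supra-white intensity maps sampled on the same template."""

    sub_white: VertexMap
    supra_white: VertexMap

    def __post_init__(self) -> None:
        if self.sub_white.n_vertices != self.supra_white.n_vertices:
            raise ValueError("sub- and supra-white maps differ in vertex count")


def compute_wgc(samples: IntensitySamplePair) -> VertexMap:
    """Elementwise sub/supra intensity ratio.

    Vertices with non-positive supra-white intensity are masked (NaN) with a
    warning — never mapped to infinity.
    """
    sub = samples.sub_white.values
    supra = samples.supra_white.values
    bad = ~(supra > 0)
    if bad.any():
        warnings.warn(
            f"masking {int(bad.sum())} vertex(es) with non-positive supra-white intensity",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, sub / np.where(bad, 1.0, supra))
    return VertexMap(values=ratio, template_id=samples.sub_white.template_id)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given FWHM: sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    return fwhm_mm / FWHM_PER_SIGMA


def _diffusion_operator(mesh: SurfaceMesh, sigma_mm: float) -> tuple:
    """Doubly-stochastic one-step smoother and the step count for ``sigma_mm``.

    One step is P = I - (w / d_max) L with L the graph Laplacian: symmetric,
    rows and columns summing to 1, so constants and map totals are preserved
    exactly.  The step count follows n = ceil(2 (sigma / h)^2) with h the mean
    edge length; the per-step weight w is then solved so that n steps of the
    walk accumulate the target per-axis positional variance sigma^2 (edge
    vectors lie in the surface, so half the mean squared edge displacement
    counts per tangent axis).
    """
    adj = mesh.adjacency()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    d_max = degrees.max()
    h = mesh.mean_edge_length
    n_steps = int(math.ceil(2.0 * (sigma_mm / h) ** 2))
    # mean over vertices of the summed squared edge lengths at that vertex
    lengths2 = mesh.edge_lengths() ** 2
    per_vertex_sum = np.zeros(mesh.n_vertices)
    e = mesh.edges
    np.add.at(per_vertex_sum, e[:, 0], lengths2)
    np.add.at(per_vertex_sum, e[:, 1], lengths2)
    mean_sq_step = per_vertex_sum.mean()  # at w = d_max (full hop)
    w = 2.0 * sigma_mm**2 * d_max / (n_steps * mean_sq_step)
    w = min(w, 0.95)  # keep the diagonal of P strictly positive
    lap = diags(degrees, format="csr") - adj
    P = identity(mesh.n_vertices, format="csr") - (w / d_max) * lap
    return P, n_steps


def smooth_on_mesh(vmap: VertexMap, mesh: SurfaceMesh, fwhm_mm: float) -> VertexMap:
    """Smooth a vertex map with an approximate Gaussian kernel of given FWHM."""
    out = smooth_matrix(vmap.values[None, :], mesh, fwhm_mm)[0]
    return VertexMap(values=out, template_id=vmap.template_id)


def smooth_matrix(values: np.ndarray, mesh: SurfaceMesh, fwhm_mm: float) -> np.ndarray:
    """Row-wise mesh smoothing of a (subjects x vertices) array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"map has {values.shape[1]} vertices but mesh has {mesh.n_vertices}"
        )
    sigma = fwhm_to_sigma(fwhm_mm)
    if fwhm_mm < mesh.mean_edge_length:
        warnings.warn(
            f"FWHM {fwhm_mm} mm below mean edge length "
            f"{mesh.mean_edge_length:.3g} mm; returning input unchanged",
            stacklevel=2,
        )
        return values.copy()
    P, n_steps = _diffusion_operator(mesh, sigma)
    logger.debug("smoothing: %d diffusion steps for FWHM %.3g mm", n_steps, fwhm_mm)
    out = values.T  # (V, n) — sparse matmul on the left
    for _ in range(n_steps):
        out = P @ out
    return np.ascontiguousarray(out.T)
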