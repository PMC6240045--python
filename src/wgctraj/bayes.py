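"""Bayesian diagnostic prediction from angle distributions.

Cross-sectional angle distributions (standardised) per diagnostic class are
fit with a Gumbel (extreme-value) likelihood,

    P(alpha | dx) = sigma^-1 exp((±alpha - mu)/sigma) exp(-exp((±alpha - mu)/sigma)),

with the skew orientation (the ± sign) chosen per class by the Pearson
correlation between the fitted density and the empirical histogram.  The
class prior is a sigmoid in the angle, with a slope set by the PLS bootstrap
ratio at the vertex or region,

    P(dx) = [1 + exp(± x BSR / BSR_max)]^-1,

positive sign for TD, negative for ASD, so a negative BSR (greater contrast
decrease in ASD) makes low angles favour ASD.  Posteriors multiply
likelihood and prior (in log space) and are normalised over the two classes.
Longitudinal subjects, standardised with their own sample's moments, are
classified by maximum posterior; ties go to TD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_expit, logsumexp

from .core_io import CohortTable, SubjectMatrix, VertexMap

CLASSES = ("ASD", "TD")


@dataclass
class EVParams:
    """Fitted Gumbel likelihood for one diagnostic class."""

    mu: float
    sigma: float
    orientation: str  # "plus" | "minus" — the ± sign applied to alpha
    fit_quality: float  # Pearson r between fitted density and histogram

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("scale parameter sigma must be positive")
        if self.orientation not in ("plus", "minus"):
            raise ValueError("orientation must be 'plus' or 'minus'")

    def _z(self, x) -> np.ndarray:
        s = 1.0 if self.orientation == "plus" else -1.0
        return (s * np.asarray(x, dtype=float) - self.mu) / self.sigma

    def logpdf(self, x) -> np.ndarray:
        z = self._z(x)
        return z - np.exp(z) - np.log(self.sigma)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))


@dataclass
class PriorSpec:
    """Sigmoid prior parameters derived from a PLS BSR map."""

    bsr: float
    bsr_max: float
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.bsr_max <= 0:
            raise ValueError("bsr_max must be positive")
        if abs(self.bsr) > self.bsr_max + 1e-12:
            raise ValueError("|bsr| cannot exceed bsr_max")
        if not np.all(np.isfinite(self.domain)):
            raise ValueError("prior domain must be finite")


@dataclass
class PredictionResult:
    subject_ids: list[str]
    posterior_asd: np.ndarray
    predicted: list[str]
    true_dx: list[str]
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "posterior_asd": self.posterior_asd,
                "predicted_dx": self.predicted,
                "true_dx": self.true_dx,
            }
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _density_correlation(x: np.ndarray, params: EVParams) -> float:
    """Pearson r between the fitted density and a Freedman-Diaconis histogram."""
    counts, edges = np.histogram(x, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fitted = params.pdf(centers)
    if counts.std() == 0 or fitted.std() == 0:
        return 0.0
    return float(np.corrcoef(counts, fitted)[0, 1])


def fit_ev_likelihood(alphas: np.ndarray) -> EVParams:
    """Maximum-likelihood Gumbel fit with data-driven skew orientation.

    Both orientations are fit (the "plus" form is left-skewed in alpha, the
    "minus" form right-skewed); the one whose density correlates better with
    the empirical histogram is retained.
    """
    x = np.asarray(alphas, dtype=float).reshape(-1)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 finite values, got {x.size}")
    if x.std() == 0:
        raise ValueError("degenerate (constant) angle sample")
    # plus orientation: pdf ~ exp(z - e^z), z = (x - mu)/sigma  (Gumbel minimum)
    loc_l, scale_l = stats.gumbel_l.fit(x)
    plus = EVParams(mu=loc_l, sigma=scale_l, orientation="plus", fit_quality=0.0)
    plus.fit_quality = _density_correlation(x, plus)
    # minus orientation: z = (-x - mu)/sigma  <=>  Gumbel maximum with loc -mu
    loc_r, scale_r = stats.gumbel_r.fit(x)
    minus = EVParams(mu=-loc_r, sigma=scale_r, orientation="minus", fit_quality=0.0)
    minus.fit_quality = _density_correlation(x, minus)
    return plus if plus.fit_quality >= minus.fit_quality else minus


# ---------------------------------------------------------------------------
# Prior and posterior
# ---------------------------------------------------------------------------


def log_prior(x, spec: PriorSpec, dx: str) -> np.ndarray:
    """Log sigmoid prior; the argument is clipped to the training domain."""
    if dx not in CLASSES:
        raise ValueError(f"dx must be one of {CLASSES}")
    xc = np.clip(np.asarray(x, dtype=float), spec.domain[0], spec.domain[1])
    s = 1.0 if dx == "TD" else -1.0
    # P = 1 / (1 + exp(s x bsr / bsr_max)) = expit(-s x bsr / bsr_max)
    return log_expit(-s * xc * spec.bsr / spec.bsr_max)


def prior_probability(x, spec: PriorSpec, dx: str) -> np.ndarray:
    """Sigmoid class prior; P(TD|x) + P(ASD|x) = 1 for every x."""
    return np.exp(log_prior(x, spec, dx))


def posterior(x, ev_asd: EVParams, ev_td: EVParams, spec: PriorSpec | None):
    """Two-class posterior (p_asd, p_td), computed in log space.

    ``spec=None`` means a flat prior (the posterior ratio then equals the
    likelihood ratio).
    """
    x = np.asarray(x, dtype=float)
    la = ev_asd.logpdf(x)
    lt = ev_td.logpdf(x)
    if spec is not None:
        la = la + log_prior(x, spec, "ASD")
        lt = lt + log_prior(x, spec, "TD")
    norm = logsumexp(np.stack([la, lt]), axis=0)
    return np.exp(la - norm), np.exp(lt - norm)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def confusion_metrics(
    true_dx, predicted
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy).

    Sensitivity is the fraction of ASD correctly predicted as ASD,
    specificity the fraction of TD correctly predicted as TD.  A metric whose
    class is absent is reported as None (missing), never as 0.
    """
    t = np.asarray(true_dx, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    bad = set(t) | set(p) - set(CLASSES)
    if not set(t) <= set(CLASSES) or not set(p) <= set(CLASSES):
        raise ValueError(f"labels outside {CLASSES}: {sorted(bad - set(CLASSES))}")
    asd = t == "ASD"
    td = t == "TD"
    sens = float((p[asd] == "ASD").mean()) if asd.any() else None
    spec = float((p[td] == "TD").mean()) if td.any() else None
    acc = float((p == t).mean()) if t.size else None
    return sens, spec, acc


def _region_means(values: np.ndarray, region: np.ndarray) -> np.ndarray:
    return np.nanmean(values[:, region], axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    return (x - np.nanmean(x)) / (sd if sd > 0 else 1.0)


def _resolve_region(region, n_vertices: int) -> np.ndarray:
    if region is None:
        return np.arange(n_vertices)
    region = np.asarray(region)
    if region.dtype == bool:
        region = np.flatnonzero(region)
    region = region.astype(np.int64)
    if region.size == 0:
        raise ValueError("empty region")
    if region.min() < 0 or region.max() >= n_vertices:
        raise ValueError("region indices outside [0, V)")
    return region


def train_predict(
    crsc_angles: SubjectMatrix,
    crsc_cohort: CohortTable,
    lngt_angles: SubjectMatrix,
    lngt_cohort: CohortTable,
    bsr: VertexMap,
    region=None,
    mode: str = "region_mean",
) -> PredictionResult:
    """Train on cross-sectional angles, classify longitudinal subjects.

    Both angle matrices must already be standardised with their own sample's
    moments.  ``mode="region_mean"`` (default) feeds each subject's mean
    standardised angle over the region to a single model whose prior uses the
    region-mean BSR; ``mode="vertex_posterior_mean"`` instead averages
    per-vertex posterior ASD probabilities over the region.
    """
    for m, name in ((crsc_angles, "cross-sectional"), (lngt_angles, "longitudinal")):
        if m.kind != "zscored_angle":
            raise ValueError(f"{name} angles must be standardised (kind='zscored_angle')")
    V = crsc_angles.n_vertices
    region = _resolve_region(region, V)
    train_dx = crsc_cohort.df["dx"].to_numpy()
    if not {"ASD", "TD"} <= set(train_dx):
        raise ValueError("both classes must be present in the training cohort")
    bsr_vals = bsr.values
    bsr_max = float(np.nanmax(np.abs(bsr_vals)))
    if bsr_max <= 0:
        raise ValueError("BSR map is identically zero; no usable prior")

    test_ids = lngt_angles.row_ids
    true_dx = lngt_cohort.one_row_per_subject().df["dx"].tolist()
    if len(true_dx) != len(test_ids):
        raise ValueError("longitudinal cohort does not match angle matrix rows")

    if mode == "region_mean":
        # Region means are re-standardised per sample (each with its own
        # moments): region averaging compresses the two samples' scales
        # differently, and the model compares distribution shapes, not
        # magnitudes.  For a single-vertex region this is an identity
        # (columns are already z-scored).
        x_train = _zscore(_region_means(crsc_angles.values, region))
        ev = {
            dx: fit_ev_likelihood(x_train[train_dx == dx]) for dx in CLASSES
        }
        spec = PriorSpec(
            bsr=float(np.clip(np.nanmean(bsr_vals[region]), -bsr_max, bsr_max)),
            bsr_max=bsr_max,
            domain=(float(np.nanmin(x_train)), float(np.nanmax(x_train))),
        )
        x_test = _zscore(_region_means(lngt_angles.values, region))
        p_asd, _ = posterior(x_test, ev["ASD"], ev["TD"], spec)
    elif mode == "vertex_posterior_mean":
        p_vertex = np.empty((len(test_ids), region.size))
        for j, v in enumerate(region):
            x_train = crsc_angles.values[:, v]
            ev = {dx: fit_ev_likelihood(x_train[train_dx == dx]) for dx in CLASSES}
            spec = PriorSpec(
                bsr=float(np.clip(bsr_vals[v], -bsr_max, bsr_max)),
                bsr_max=bsr_max,
                domain=(float(np.nanmin(x_train)), float(np.nanmax(x_train))),
            )
            p_vertex[:, j], _ = posterior(
                lngt_angles.values[:, v], ev["ASD"], ev["TD"], spec
            )
        p_asd = p_vertex.mean(axis=1)
    else:
        raise ValueError("mode must be 'region_mean' or 'vertex_posterior_mean'")

    predicted = ["ASD" if p > 0.5 else "TD" for p in p_asd]  # tie -> TD
    sens, spec_, acc = confusion_metrics(true_dx, predicted)
    return PredictionResult(
        subject_ids=list(test_ids),
        posterior_asd=np.asarray(p_asd, dtype=float),
        predicted=predicted,
        true_dx=list(true_dx),
        sensitivity=sens,
        specificity=spec_,
        accuracy=acc,
    )


def vertexwise_maps(
    crsc_angles: SubjectMatrix,
    crsc_cohort: CohortTable,
    lngt_angles: SubjectMatrix,
    lngt_cohort: CohortTable,
    bsr: VertexMap,
    cutoff: float = 0.5,
) -> tuple[VertexMap, VertexMap, np.ndarray]:
    """Single-vertex models at every vertex.

    Returns (sensitivity map, specificity map, mutual->cutoff mask); the mask
    is True where both metrics strictly exceed ``cutoff`` (default 50%),
    which screens out trivial all-one-class predictors.  Vertices where the
    single-vertex fit fails are masked NaN.
    """
    V = crsc_angles.n_vertices
    sens = np.full(V, np.nan)
    spec = np.full(V, np.nan)
    for v in range(V):
        try:
            res = train_predict(
                crsc_angles, crsc_cohort, lngt_angles, lngt_cohort, bsr, region=[v]
            )
        except ValueError:
            continue
        sens[v] = np.nan if res.sensitivity is None else res.sensitivity
        spec[v] = np.nan if res.specificity is None else res.specificity
    mask = (sens > cutoff) & (spec > cutoff)
    tid = bsr.template_id
    return VertexMap(sens, tid), VertexMap(spec, tid), mask
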