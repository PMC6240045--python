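"""Proxy calibrated severity scores and severity prediction from brain scores.

ADOS social+communication totals are mapped to module/age-comparable
calibrated severity scores (1-10) through a lookup table.  The published
calibration tables are not redistributable from this package: the bundled
``synthetic_css_table.tsv`` is a clearly-labelled synthetic identity
placeholder (severity = total clipped to [1, 10]); supply a real table in the
same TSV schema for real analyses.

Severity prediction follows a windowed-residual linear model: an ordinary
least squares fit of severity on cross-sectional brain scores (BrSc), plus
the mean training residual inside a window around the new BrSc value, the
window half-width w being 5% of the maximum training BrSc.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FormatError

TABLE_COLUMNS = ("ados_module", "age_min", "age_max", "total_min", "total_max", "severity")


class SeverityLookupError(KeyError):
    """A (module, age, total) cell is not covered by the calibration table."""


@dataclass
class SeverityTable:
    """Calibration lookup (module, age band, social+communication total) -> 1-10."""

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"severity table missing column(s): {missing}")
        sev = self.table["severity"]
        if ((sev < 1) | (sev > 10)).any():
            raise ValueError("severity values must lie in [1, 10]")

    def lookup(self, total: int, module: int, age: float) -> float:
        """Scalar lookup; raises :class:`SeverityLookupError` for uncovered cells."""
        t = self.table
        hit = t[
            (t["ados_module"] == module)
            & (t["age_min"] <= age)
            & (age < t["age_max"])
            & (t["total_min"] <= total)
            & (total <= t["total_max"])
        ]
        if hit.empty:
            raise SeverityLookupError(
                f"no calibration entry for module={module}, age={age}, total={total}"
            )
        return float(hit["severity"].iloc[0])


def read_severity_table(path: str | Path, provenance: str | None = None) -> SeverityTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SeverityTable(table=df, provenance=provenance or str(path))


def synthetic_severity_table() -> SeverityTable:
    """The bundled synthetic identity placeholder table."""
    with resources.files("wgctraj").joinpath("data/synthetic_css_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return SeverityTable(table=df, provenance="synthetic identity placeholder")


def proxy_severity(total, module, age, table: SeverityTable):
    """Calibrated severity for scalar or vector inputs.

    Scalars raise on uncovered cells; vector inputs return NaN for uncovered
    or missing rows together with a list of per-row reasons (empty string for
    successful lookups) — never a silent default.
    """
    if np.isscalar(total):
        return table.lookup(int(total), int(module), float(age))
    total = np.asarray(total, dtype=float)
    module = np.asarray(module, dtype=float)
    age = np.asarray(age, dtype=float)
    out = np.full(total.shape, np.nan)
    reasons = []
    for i in range(total.size):
        if not (np.isfinite(total[i]) and np.isfinite(module[i])):
            reasons.append("missing ADOS total or module")
            continue
        try:
            out[i] = table.lookup(int(total[i]), int(module[i]), float(age[i]))
            reasons.append("")
        except SeverityLookupError as exc:
            reasons.append(str(exc))
    return out, reasons


# ---------------------------------------------------------------------------
# Brain-score correlations
# ---------------------------------------------------------------------------


def correlate_log_brainscore(brsc, scores) -> tuple[float, float, int]:
    """Pearson correlation of log(BrSc+) with behavioural scores.

    Subjects with non-positive brain scores or missing scores are excluded
    (the positive part of the brain-score distribution on the log scale).
    Returns (r, p, n_used).
    """
    brsc = np.asarray(brsc, dtype=float).reshape(-1)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if brsc.size != scores.size:
        raise ValueError("paired vectors differ in length")
    use = (brsc > 0) & np.isfinite(scores)
    n_used = int(use.sum())
    if n_used < 3:
        raise ValueError(f"fewer than 3 usable pairs (got {n_used})")
    r, p = stats.pearsonr(np.log(brsc[use]), scores[use])
    return float(r), float(p), n_used


# ---------------------------------------------------------------------------
# Windowed-residual severity model
# ---------------------------------------------------------------------------


@dataclass
class SeverityModel:
    beta0: float
    beta1: float
    training_brsc: np.ndarray
    training_residuals: np.ndarray
    window_w: float

    def __post_init__(self) -> None:
        if self.window_w <= 0:
            raise ValueError("window width must be positive")


#: The residual window is this fraction of the maximum training BrSc.
WINDOW_FRACTION = 0.05


def fit_severity_model(brsc_crsc, severity_crsc) -> SeverityModel:
    """OLS severity ~ BrSc; residuals are stored for the windowed correction."""
    b = np.asarray(brsc_crsc, dtype=float).reshape(-1)
    s = np.asarray(severity_crsc, dtype=float).reshape(-1)
    use = np.isfinite(b) & np.isfinite(s)
    b, s = b[use], s[use]
    if b.size < 3:
        raise ValueError("need at least 3 finite training pairs")
    if np.ptp(b) == 0:
        raise ValueError("constant BrSc: slope is unidentifiable")
    fit = stats.linregress(b, s)
    residuals = s - (fit.intercept + fit.slope * b)
    return SeverityModel(
        beta0=float(fit.intercept),
        beta1=float(fit.slope),
        training_brsc=b,
        training_residuals=residuals,
        window_w=WINDOW_FRACTION * float(b.max()),
    )


def predict_severity(model: SeverityModel, brsc_new) -> np.ndarray:
    """S_i = beta0 + beta1 BrSc_i + mean{eps_k : |BrSc_k - BrSc_i| < w}.

    The window is open and centred in BrSc units; an empty window contributes
    no correction (the prediction falls back to the plain linear term).
    """
    b = np.asarray(brsc_new, dtype=float).reshape(-1)
    linear = model.beta0 + model.beta1 * b
    corr = np.zeros_like(linear)
    for i, bi in enumerate(b):
        in_window = np.abs(model.training_brsc - bi) < model.window_w
        if in_window.any():
            corr[i] = model.training_residuals[in_window].mean()
    return linear + corr
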