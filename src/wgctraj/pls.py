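"""Mean-centred task PLS over subjects x vertices with group structure.

The group-mean matrix (groups x vertices) is centred by the unweighted grand
mean of group means and decomposed by SVD; each latent variable (LV) pairs a
group contrast (design scores U S) with a vertex pattern (saliences, the
right singular vectors).  Permutation of group labels gives per-LV
significance; within-group bootstrap resampling gives per-vertex standard
errors and the bootstrap ratio BSR = salience / SE.  A subject's brain score
is the projection of their mean-centred data onto an LV's BSR map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import CohortTable, SubjectMatrix, VertexMap, logger


@dataclass
class GroupDesign:
    """Group label per subject plus a fixed group ordering."""

    group_of_subject: np.ndarray
    group_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.group_of_subject = np.asarray(self.group_of_subject, dtype=object)
        if not self.group_order:
            self.group_order = tuple(dict.fromkeys(self.group_of_subject))
        counts = {g: int((self.group_of_subject == g).sum()) for g in self.group_order}
        if len(self.group_order) < 2:
            raise ValueError("need at least 2 groups")
        missing = [g for g, c in counts.items() if c == 0]
        if missing:
            raise ValueError(f"empty group(s): {missing}")
        extra = set(self.group_of_subject) - set(self.group_order)
        if extra:
            raise ValueError(f"subjects with labels outside group_order: {sorted(extra)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group_of_subject == group)

    @classmethod
    def from_cohort(cls, cohort: CohortTable, by: str = "dx_site") -> "GroupDesign":
        """Build dx x site or dx x scanner groups, one row per cohort row.

        For longitudinal cohorts pass a one-row-per-subject slice matching
        the angle matrix (angles already collapse the two scans).
        """
        df = cohort.df
        key = {"dx_site": "site", "dx_scanner": "scanner"}[by]
        labels = (df["dx"] + "_" + df[key]).to_numpy(dtype=object)
        order = []
        for second in dict.fromkeys(df[key]):
            for dx in ("ASD", "TD"):
                lab = f"{dx}_{second}"
                if (labels == lab).any():
                    order.append(lab)
        return cls(group_of_subject=labels, group_order=tuple(order))

    def dx_contrast(self) -> np.ndarray:
        """+1 for ASD_* groups, -1 for TD_* groups (orientation helper)."""
        return np.array([1.0 if g.startswith("ASD") else -1.0 for g in self.group_order])


@dataclass
class PLSResult:
    singular_values: np.ndarray  # (k,), non-increasing
    covariance_explained: np.ndarray  # (k,), sums to 1
    design_scores: np.ndarray  # (groups, k) = U S
    design_vectors: np.ndarray  # (groups, k) = U (unit-norm columns)
    vertex_saliences: np.ndarray  # (V, k)
    group_order: tuple[str, ...]
    degenerate: bool = False
    bsr: np.ndarray | None = None  # (V, k), NaN where bootstrap SE == 0
    group_CIs: np.ndarray | None = None  # (groups, k, 2) percentile bounds
    perm_p: np.ndarray | None = None  # (k,)
    brain_scores: np.ndarray | None = None  # (subjects, k)

    @property
    def n_lv(self) -> int:
        return self.singular_values.size


@dataclass
class ConjunctionMap:
    """Per-vertex sign agreement of two BSR maps and the global fractions."""

    category: np.ndarray  # strings
    fractions: dict[str, float]

    CATEGORIES = ("both_negative", "both_positive", "crsc_pos_lngt_neg", "lngt_pos_crsc_neg")


# ---------------------------------------------------------------------------
# Core decomposition
# ---------------------------------------------------------------------------


def _group_means(X: np.ndarray, design: GroupDesign) -> np.ndarray:
    return np.vstack([X[design.indices(g)].mean(axis=0) for g in design.group_order])


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, SubjectMatrix) else np.asarray(X, dtype=float)


def mean_centered_pls(X, design: GroupDesign) -> PLSResult:
    """SVD of the grand-mean-centred group-mean matrix."""
    Xv = _values(X)
    if Xv.shape[0] != design.group_of_subject.size:
        raise ValueError("design length does not match number of subjects")
    for g in design.group_order:
        if design.indices(g).size < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    M = _group_means(Xv, design)
    Mc = M - M.mean(axis=0)
    U, S, Wt = np.linalg.svd(Mc, full_matrices=False)
    # deterministic sign: largest-magnitude element of each salience positive
    for k in range(S.size):
        j = np.argmax(np.abs(Wt[k]))
        if Wt[k, j] < 0:
            Wt[k] = -Wt[k]
            U[:, k] = -U[:, k]
    total = float((S**2).sum())
    degenerate = total == 0.0
    if degenerate:
        logger.warning("rank-0 centred group-mean matrix: all singular values are 0")
        cov = np.zeros_like(S)
    else:
        cov = S**2 / total
    return PLSResult(
        singular_values=S,
        covariance_explained=cov,
        design_scores=U * S,
        design_vectors=U,
        vertex_saliences=Wt.T,
        group_order=design.group_order,
        degenerate=degenerate,
    )


def orient_to_contrast(result: PLSResult, contrast: np.ndarray, lv: int = 0) -> PLSResult:
    """Flip one LV so its design scores correlate positively with ``contrast``.

    SVD signs are arbitrary per LV; fixing LV1 against the ASD-minus-TD
    contrast makes BSR signs comparable across samples (negative = greater
    decrease in ASD), which the conjunction analysis requires.
    """
    contrast = np.asarray(contrast, dtype=float)
    if float(result.design_scores[:, lv] @ contrast) < 0:
        result.design_scores[:, lv] = -result.design_scores[:, lv]
        result.design_vectors[:, lv] = -result.design_vectors[:, lv]
        result.vertex_saliences[:, lv] = -result.vertex_saliences[:, lv]
        if result.bsr is not None:
            result.bsr[:, lv] = -result.bsr[:, lv]
        if result.group_CIs is not None:
            result.group_CIs[:, lv, :] = -result.group_CIs[:, lv, ::-1]
        if result.brain_scores is not None:
            result.brain_scores[:, lv] = -result.brain_scores[:, lv]
    return result


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def permutation_test(
    X, design: GroupDesign, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Per-LV permutation p-values, p = (1 + #{S_perm >= S_obs}) / (1 + n_perm).

    Group labels are reassigned by resampling without replacement (a full
    permutation of the label vector), preserving group sizes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xv = _values(X)
    obs = mean_centered_pls(Xv, design).singular_values
    rng = np.random.default_rng(seed)
    labels = design.group_of_subject
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = GroupDesign(
            group_of_subject=rng.permutation(labels), group_order=design.group_order
        )
        s_perm = mean_centered_pls(Xv, perm).singular_values
        exceed += s_perm >= obs
    return (1.0 + exceed) / (1.0 + n_perm)


def _align_to_reference(
    saliences: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match LV order and sign to a reference by maximal absolute correlation.

    Returns (column order, signs) to apply to the resampled decomposition.
    Guards against axis swaps/flips across bootstrap replicates.
    """
    k = ref.shape[1]
    C = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            ra = ref[:, a] - ref[:, a].mean()
            rb = saliences[:, b] - saliences[:, b].mean()
            denom = np.linalg.norm(ra) * np.linalg.norm(rb)
            C[a, b] = (ra @ rb) / denom if denom > 0 else 0.0
    order = np.full(k, -1)
    signs = np.ones(k)
    taken = set()
    for a in np.argsort(-np.abs(C).max(axis=1)):  # most decisive rows first
        b = max(
            (j for j in range(k) if j not in taken),
            key=lambda j: abs(C[a, j]),
        )
        order[a] = b
        signs[a] = 1.0 if C[a, b] >= 0 else -1.0
        taken.add(b)
    return order, signs


def bootstrap_bsr(
    X, design: GroupDesign, n_boot: int = 500, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap ratios and design-score confidence intervals.

    Subjects are resampled with replacement within group (assignments fixed);
    each replicate's saliences are sign/order-aligned to the original before
    the standard error is taken.  BSR = original salience / bootstrap SE,
    masked (NaN) where SE is zero.  CIs are 95% percentile intervals of the
    aligned design scores.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Xv = _values(X)
    original = mean_centered_pls(Xv, design)
    ref = original.vertex_saliences
    k = original.n_lv
    rng = np.random.default_rng(seed)
    group_idx = [design.indices(g) for g in design.group_order]
    sal_boots = np.empty((n_boot, Xv.shape[1], k))
    ds_boots = np.empty((n_boot, design.n_groups, k))
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx, size=idx.size, replace=True) for idx in group_idx])
        labels = np.concatenate(
            [np.repeat(g, idx.size) for g, idx in zip(design.group_order, group_idx)]
        )
        boot_design = GroupDesign(group_of_subject=labels, group_order=design.group_order)
        res = mean_centered_pls(Xv[take], boot_design)
        order, signs = _align_to_reference(res.vertex_saliences, ref)
        sal_boots[b] = res.vertex_saliences[:, order] * signs
        ds_boots[b] = res.design_scores[:, order] * signs
    se = sal_boots.std(axis=0, ddof=1)
    # saliences are unit-norm columns, so an SE at float-noise level means a
    # degenerate (identical-resample) vertex: mask rather than explode
    usable = se > 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(usable, ref / np.where(usable, se, 1.0), np.nan)
    group_CIs = np.stack(
        [np.percentile(ds_boots, 2.5, axis=0), np.percentile(ds_boots, 97.5, axis=0)],
        axis=-1,
    )
    return bsr, group_CIs


def run_pls(
    X,
    design: GroupDesign,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int = 0,
) -> PLSResult:
    """Full PLS: decomposition, permutation test, bootstrap BSR, brain scores."""
    result = mean_centered_pls(X, design)
    ss = np.random.SeedSequence(seed)
    s_perm, s_boot = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    result.perm_p = permutation_test(X, design, n_perm=n_perm, seed=s_perm)
    result.bsr, result.group_CIs = bootstrap_bsr(X, design, n_boot=n_boot, seed=s_boot)
    result.brain_scores = brain_scores(X, result)
    return result


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def brain_scores(X, result: PLSResult, projection: str = "bsr") -> np.ndarray:
    """Subject expression of each LV pattern.

    The mean-centred data matrix is projected onto the BSR maps (the stated
    convention of this pipeline); ``projection="salience"`` gives the
    classical task-PLS variant.
    """
    Xv = _values(X)
    if projection == "bsr":
        if result.bsr is None:
            raise RuntimeError("brain scores with projection='bsr' require bootstrap BSR")
        proj = np.nan_to_num(result.bsr, nan=0.0)
    elif projection == "salience":
        proj = result.vertex_saliences
    else:
        raise ValueError("projection must be 'bsr' or 'salience'")
    Xc = Xv - Xv.mean(axis=0)
    return Xc @ proj


def conjunction(bsr_lngt: VertexMap, bsr_crsc: VertexMap) -> ConjunctionMap:
    """Sign-agreement categories between longitudinal and cross-sectional BSR.

    A BSR of exactly zero counts as negative (decrease); this is logged and
    occurs with measure zero on continuous data.
    """
    a = bsr_lngt.values
    b = bsr_crsc.values
    if a.size != b.size:
        raise ValueError("BSR maps differ in vertex count")
    n_zero = int(((a == 0) | (b == 0)).sum())
    if n_zero:
        logger.info("conjunction: %d zero-BSR vertices counted as negative", n_zero)
    a_neg = a <= 0
    b_neg = b <= 0
    category = np.where(
        a_neg & b_neg,
        "both_negative",
        np.where(
            ~a_neg & ~b_neg,
            "both_positive",
            np.where(~b_neg, "crsc_pos_lngt_neg", "lngt_pos_crsc_neg"),
        ),
    )
    fractions = {c: float((category == c).mean()) for c in ConjunctionMap.CATEGORIES}
    return ConjunctionMap(category=category, fractions=fractions)


def bsr_band_ttest(
    bsr_lv: np.ndarray,
    X,
    cohort: CohortTable,
    side: str = "min",
) -> dict:
    """Two-sample t-test on the mean angle over a one-sd BSR band.

    ``side="min"`` selects vertices with BSR within one standard deviation
    above the minimum BSR; ``side="max"`` within one sd below the maximum.
    Subjects' mean angles over the band are compared between dx groups.
    """
    bsr_lv = np.asarray(bsr_lv, dtype=float)
    finite = np.isfinite(bsr_lv)
    if side == "min":
        lo = np.nanmin(bsr_lv)
        band = finite & (bsr_lv <= lo + np.nanstd(bsr_lv))
    elif side == "max":
        hi = np.nanmax(bsr_lv)
        band = finite & (bsr_lv >= hi - np.nanstd(bsr_lv))
    else:
        raise ValueError("side must be 'min' or 'max'")
    Xv = _values(X)
    subject_means = Xv[:, band].mean(axis=1)
    dx = cohort.df["dx"].to_numpy()
    t, p = stats.ttest_ind(subject_means[dx == "ASD"], subject_means[dx == "TD"])
    return {
        "n_vertices": int(band.sum()),
        "t": float(t),
        "p": float(p),
        "mean_asd": float(subject_means[dx == "ASD"].mean()),
        "mean_td": float(subject_means[dx == "TD"].mean()),
    }
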