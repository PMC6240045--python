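"""End-to-end study replicates on synthetic data.

One replicate emulates the full design: generate an effect template and both
samples, compute angles (cross-sectional against same-site same-dx peers,
longitudinal within subject), z-score per vertex, run both PLS analyses with
bootstrap, orient LV1 to the ASD-minus-TD contrast, and derive the BSR
conjunction plus the cross-sample diagnostic prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import angle as angle_mod
from . import bayes, pls, synthetic_data
from .core_io import CohortTable, SubjectMatrix, VertexMap


@dataclass
class StudyReplicate:
    template: synthetic_data.EffectTemplate
    crsc_cohort: CohortTable
    crsc_angles: SubjectMatrix  # z-scored
    lngt_cohort: CohortTable
    lngt_angles: SubjectMatrix  # z-scored
    pls_crsc: pls.PLSResult
    pls_lngt: pls.PLSResult
    conjunction: pls.ConjunctionMap
    prediction: bayes.PredictionResult


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_replicate(
    seed: int,
    n_vertices: int = 400,
    negative_fraction: float = 0.81,
    n_perm: int = 200,
    n_boot: int = 200,
    slope_contrast: float = synthetic_data.DEFAULT_SLOPE_CONTRAST,
    predict: bool = True,
    spec_overrides: dict | None = None,
) -> StudyReplicate:
    """Simulate and analyse one full synthetic study."""
    s_mesh, s_tpl, s_sim, s_pls_c, s_pls_l = child_seeds(seed, 5)
    mesh = synthetic_data.make_mesh(n_vertices, seed=s_mesh)
    template = synthetic_data.make_effect_template(
        mesh, negative_fraction=negative_fraction, seed=s_tpl,
        slope_contrast=slope_contrast,
    )
    spec = synthetic_data.SimulationSpec(
        n_vertices=n_vertices, rng_seed=s_sim, **(spec_overrides or {})
    )
    crsc_cohort, crsc_wgc = synthetic_data.simulate_cross_sectional(spec, template)
    lngt_cohort, lngt_wgc = synthetic_data.simulate_longitudinal(spec, template)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-cell warnings on toy-scale data
        crsc_cohort, crsc_wgc = angle_mod.filter_small_cells(crsc_cohort, crsc_wgc)
        crsc_z = angle_mod.standardize(angle_mod.cross_sectional_angle(crsc_wgc, crsc_cohort))
        lngt_z = angle_mod.standardize(angle_mod.longitudinal_angles(lngt_wgc, lngt_cohort))

    lngt_subjects = lngt_cohort.one_row_per_subject()
    design_c = pls.GroupDesign.from_cohort(crsc_cohort, by="dx_scanner")
    design_l = pls.GroupDesign.from_cohort(lngt_subjects, by="dx_site")
    res_c = pls.run_pls(crsc_z, design_c, n_perm=n_perm, n_boot=n_boot, seed=s_pls_c)
    res_l = pls.run_pls(lngt_z, design_l, n_perm=n_perm, n_boot=n_boot, seed=s_pls_l)
    res_c = pls.orient_to_contrast(res_c, design_c.dx_contrast())
    res_l = pls.orient_to_contrast(res_l, design_l.dx_contrast())

    conj = pls.conjunction(VertexMap(res_l.bsr[:, 0]), VertexMap(res_c.bsr[:, 0]))

    prediction = None
    if predict:
        prediction = bayes.train_predict(
            crsc_z, crsc_cohort, lngt_z, lngt_cohort, VertexMap(res_c.bsr[:, 0])
        )
    return StudyReplicate(
        template=template,
        crsc_cohort=crsc_cohort,
        crsc_angles=crsc_z,
        lngt_cohort=lngt_cohort,
        lngt_angles=lngt_z,
        pls_crsc=res_c,
        pls_lngt=res_l,
        conjunction=conj,
        prediction=prediction,
    )
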