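"""Shared fixtures.

The Monte Carlo reference build and the cohort replicate study are expensive,
so they are computed once per session and shared between the unit tests and
the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hemoscope import skin_optics as so
from hemoscope import synthetic_data as sd
from hemoscope.hemodynamics import (
    BVP_BAND,
    VASO_BAND,
    Waveform,
    band_integrated_power,
    extract_bvp,
    extract_vasomotion,
)
from hemoscope.study_analysis import compare_conditions, percent_change

N2_TRAIN_SEED = 20250921
N2_TEST_SEED = 915273
N2_PHOTONS = 10_000
COHORT_BASE_SEED = 424242
N_REPLICATES = 50


def recording_band_powers(rec: sd.SyntheticRecording) -> tuple[float, float]:
    """(BVP band power, vasomotion band power) of one synthetic recording."""
    ctb = Waveform(rec.series.c_tb, rec.fs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bvp = band_integrated_power(extract_bvp(ctb), BVP_BAND).value
        vaso = band_integrated_power(extract_vasomotion(ctb), VASO_BAND).value
    return bvp, vaso


@pytest.fixture(scope="session")
def n2_bundle():
    """Fitted N2 regression with training pairs and held-out recovery R^2.

    300 training and 50 held-out spectra at 1e4 photons per wavelength,
    the conditions of the calibrated-model round trip.
    """
    train = so.build_reference_set(300, photons=N2_PHOTONS, seed=N2_TRAIN_SEED)
    held_out = so.build_reference_set(50, photons=N2_PHOTONS, seed=N2_TEST_SEED)
    train_pairs = [(c, so.spectrum_to_tristimulus(s)) for c, s in train]
    reg = so.fit_concentration_regression(train_pairs)
    xyz = np.array([so.spectrum_to_tristimulus(s).as_array() for _, s in held_out])
    truth = np.array([[c.c_m, c.c_hbo, c.c_hbr] for c, _ in held_out])
    pred, _ = so.apply_concentration_regression(xyz, reg)
    resid = truth - pred
    r2 = 1.0 - (resid**2).sum(0) / ((truth - truth.mean(0)) ** 2).sum(0)
    hbt_truth = truth[:, 1] + truth[:, 2]
    hbt_pred = pred[:, 1] + pred[:, 2]
    r2_hbt = 1.0 - ((hbt_truth - hbt_pred) ** 2).sum() / (
        (hbt_truth - hbt_truth.mean()) ** 2
    ).sum()
    return {
        "regression": reg,
        "train_pairs": train_pairs,
        "held_out_r2": r2,
        "held_out_r2_hbt": float(r2_hbt),
    }


def run_cohort_replicate(seed: int) -> dict:
    """One full pooled-cohort study: powers, paired tests, percent changes."""
    rest_bvp, task_bvp, rest_vaso, task_vaso = [], [], [], []
    for i, experiment in enumerate(sorted(sd.EXPERIMENT_TEMPLATES)):
        cohort = sd.generate_cohort(experiment, seed=seed + 1000 * i)
        for rest, task in cohort:
            rb, rv = recording_band_powers(rest)
            tb, tv = recording_band_powers(task)
            rest_bvp.append(rb)
            task_bvp.append(tb)
            rest_vaso.append(rv)
            task_vaso.append(tv)
    bvp_cmp = compare_conditions(rest_bvp, task_bvp, metric="bvp_power")
    vaso_cmp = compare_conditions(rest_vaso, task_vaso, metric="vasomotion_power")
    return {
        "n": len(rest_bvp),
        "bvp_p": bvp_cmp.p_value,
        "vaso_p": vaso_cmp.p_value,
        "bvp_percent_change": percent_change(
            float(np.mean(rest_bvp)), float(np.mean(task_bvp))
        ),
        "vaso_percent_change": percent_change(
            float(np.mean(rest_vaso)), float(np.mean(task_vaso))
        ),
    }


@pytest.fixture(scope="session")
def cohort_replicates():
    """Fifty seeded replicates of the pooled (n=32) rest/stress study."""
    return [
        run_cohort_replicate(COHORT_BASE_SEED + 97 * rep)
        for rep in range(N_REPLICATES)
    ]
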