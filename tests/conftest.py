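"""Shared fixtures: generated trials are expensive enough to cache at
session scope."""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vestigait import synthetic_gait as sg
from vestigait import preprocess as pp
from vestigait.trial_io import SubjectMeta


def hs_draw(**overrides) -> sg.SubjectDraw:
    base = dict(subject_id="S01", group="HS", severity=0.5, speed=1.29,
                cadence=112.0, step_width=0.10, ml_sway=0.018, coupling=0.35,
                height=1.70, mass=72.0)
    base.update(overrides)
    return sg.SubjectDraw(**base)


def noise_free(profile: sg.ImpairmentProfile) -> sg.ImpairmentProfile:
    return dataclasses.replace(
        profile, placement_noise_sd=0.0, timing_noise_sd=0.0,
        kinematic_noise_sd=0.0, walk_drift_step=0.0)


@pytest.fixture(scope="session")
def hs_trial_truth():
    """One comfortable-gait trial of an average control walker, with its
    ground-truth sidecar."""
    trial, truth = sg.generate_trial(sg.PRESETS["HS"], "comfortable_gait",
                                     hs_draw(), seed=1)
    return trial, truth


@pytest.fixture(scope="session")
def processed_trial(hs_trial_truth):
    trial, _ = hs_trial_truth
    return pp.add_virtual_markers(pp.lowpass(trial))


@pytest.fixture(scope="session")
def standing_trial():
    return sg.generate_standing_trial(seed=5)


@pytest.fixture
def hs_meta():
    return SubjectMeta("S01", "HS", height=1.70, mass=72.0)


def rotate_trial(trial, angle_deg: float):
    """Rotate every marker about the vertical axis through the origin."""
    th = np.radians(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    markers = {lb: arr @ R.T for lb, arr in trial.markers.items()}
    return trial.copy_with(markers=markers)
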