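"""Published summary statistics of the three-task stress study.

The package is designed around a three-experiment study of peripheral
hemodynamics under cognitive and psychological stress (auditory tone, Stroop
color-word task, mental arithmetic). The raw videos are not public; what the
study reports are per-task condition means (with standard errors) of the
vasomotion band power, the peripheral pulse (BVP) band power and the PRV
LF/HF ratio. Those printed summary cells are shipped here as inputs for the
pooling and percent-change arithmetic.
"""

from __future__ import annotations

from .study_analysis import TaskSummary

__all__ = ["three_task_study_summaries", "STUDY_SUBJECT_COUNTS"]

#: Subjects per experiment (auditory, stroop, mental arithmetic).
STUDY_SUBJECT_COUNTS = {"auditory": 10, "stroop": 11, "mat": 11}

# (rest mean, rest SE, task mean, task SE) per metric; powers in vol%^2,
# LF/HF dimensionless.
_CELLS = {
    "auditory": {
        "vasomotion_power": (60.3, 42.2, 31.5, 14.0),
        "bvp_power": (0.864, 0.509, 0.690, 0.225),
        "prv_lf_hf": (0.897, 0.397, 0.920, 0.520),
    },
    "stroop": {
        "vasomotion_power": (48.6, 21.6, 29.0, 10.6),
        "bvp_power": (1.130, 0.521, 0.563, 0.210),
        "prv_lf_hf": (0.458, 0.086, 0.374, 0.071),
    },
    "mat": {
        "vasomotion_power": (20.5, 20.3, 3.71, 1.35),
        "bvp_power": (0.272, 0.156, 0.208, 0.063),
        "prv_lf_hf": (0.370, 0.110, 0.513, 0.114),
    },
}

#: Pooled ("all tasks") cells as printed: metric -> (rest, task).
POOLED_CELLS = {
    "vasomotion_power": (42.6, 21.1),
    "bvp_power": (0.752, 0.481),
    "prv_lf_hf": (0.565, 0.593),
}


def three_task_study_summaries() -> list[TaskSummary]:
    """The per-task printed summary cells as :class:`TaskSummary` objects."""
    out = []
    for task, cells in _CELLS.items():
        n = STUDY_SUBJECT_COUNTS[task]
        means = {"rest": {}, "task": {}}
        ses = {"rest": {}, "task": {}}
        for metric, (rm, rse, tm, tse) in cells.items():
            means["rest"][metric] = rm
            ses["rest"][metric] = rse
            means["task"][metric] = tm
            ses["task"][metric] = tse
        out.append(TaskSummary(task, n, means, ses))
    return out
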