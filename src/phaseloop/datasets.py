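"""Published per-participant summaries used as worked-example inputs.

Five participants (P01-P05) of a real-time closed-loop alpha-phase
visual-stimulation experiment, with triggers generated online by a
Yule-Walker (yw) or adaptive LMS (lms) AR forecaster targeting the alpha
peak (0 rad) or trough (pi rad), in an eyes-open resting condition and a
visual-task condition. For each condition the tables give the trial count,
the phase-locking factor (PLF), Rayleigh's Z (``zplf``) and the circular
mean angle at time-zero, all evaluated offline.

These numbers are *inputs* for the participant-averaging statistics
(:func:`phaseloop.circstats.zplf_all`, the arithmetic mean of per-
participant Z values, and :func:`phaseloop.circstats.circular_mean`); the
package recomputes the published condition averages from them.
"""

from __future__ import annotations

__all__ = ["RESTING", "VISUAL", "CONDITIONS"]

CONDITIONS = [
    ("yw", "peak"),
    ("lms", "peak"),
    ("yw", "trough"),
    ("lms", "trough"),
]

#: Resting condition, participants P01-P05 in order.
RESTING = {
    "n_trials": {
        ("yw", "peak"): [3598, 3491, 3192, 3230, 3326],
        ("lms", "peak"): [3156, 3093, 3038, 3089, 3159],
        ("yw", "trough"): [3710, 3433, 3099, 3268, 3340],
        ("lms", "trough"): [3276, 3075, 2993, 3053, 3139],
    },
    "plf": {
        ("yw", "peak"): [0.057, 0.104, 0.090, 0.101, 0.146],
        ("lms", "peak"): [0.059, 0.103, 0.171, 0.125, 0.122],
        ("yw", "trough"): [0.019, 0.075, 0.155, 0.146, 0.155],
        ("lms", "trough"): [0.047, 0.126, 0.149, 0.107, 0.133],
    },
    "zplf": {
        ("yw", "peak"): [11.872, 37.831, 26.283, 33.569, 71.307],
        ("lms", "peak"): [11.102, 32.895, 89.706, 48.528, 47.381],
        ("yw", "trough"): [1.432, 19.778, 74.474, 70.241, 80.566],
        ("lms", "trough"): [7.378, 51.678, 66.55, 35.50, 55.752],
    },
    "mean_angle": {
        ("yw", "peak"): [-0.475, -0.228, -0.350, -0.271, -0.216],
        ("lms", "peak"): [-0.154, -0.108, -0.369, -0.337, -0.333],
        ("yw", "trough"): [-3.009, 2.821, 2.923, 2.920, 2.872],
        ("lms", "trough"): [2.580, 2.761, 2.956, 2.613, 2.827],
    },
}

#: Visual-task condition, participants P01-P05 in order.
VISUAL = {
    "zplf": {
        ("yw", "peak"): [158.59, 105.10, 112.73, 142.02, 190.26],
        ("lms", "peak"): [255.83, 153.43, 39.500, 85.397, 93.699],
        ("yw", "trough"): [14.760, 23.016, 5.326, 69.912, 4.871],
        ("lms", "trough"): [333.357, 8.146, 17.461, 128.927, 103.984],
    },
    "mean_angle": {
        ("yw", "peak"): [0.478, -0.481, -0.169, -0.655, -0.883],
        ("lms", "peak"): [0.158, -0.407, -0.117, -0.603, -0.657],
        ("yw", "trough"): [0.708, -2.030, 2.643, -2.810, -2.673],
        ("lms", "trough"): [0.449, -1.090, -2.112, -3.067, -2.167],
    },
}
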