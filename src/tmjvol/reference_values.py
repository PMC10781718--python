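"""Published cohort summary values used as defaults and worked-example inputs.

Estimated marginal means (SE) per timepoint and post-hoc pairwise
differences (later minus earlier visit) for the five joint-space outcomes,
as published for the 35-patient / 70-joint TOVRO cohort (T1 observed in 19
patients).  These are *inputs*: the simulation module uses them as default
generating means, and the worked-example utilities recompute the published
percentage changes from them.
"""
from __future__ import annotations

TIMEPOINTS = ("T0", "T1", "T2", "T3")
OUTCOMES = ("Vjs", "Vajs", "Vpjs", "Vmjs", "Vljs")

PAIRS = (("T0", "T1"), ("T0", "T2"), ("T0", "T3"), ("T1", "T2"), ("T1", "T3"), ("T2", "T3"))

N_PATIENTS = 35
N_JOINTS = 70
N_T1_OBSERVED = 19

#: estimated marginal mean (mm^3) per outcome per timepoint
ESTIMATED_MEANS = {
    "Vjs": {"T0": 1110.99, "T1": 1459.21, "T2": 1253.05, "T3": 1245.53},
    "Vajs": {"T0": 566.30, "T1": 654.71, "T2": 567.91, "T3": 567.49},
    "Vpjs": {"T0": 544.10, "T1": 827.22, "T2": 684.50, "T3": 674.82},
    "Vmjs": {"T0": 661.31, "T1": 810.34, "T2": 687.67, "T3": 682.56},
    "Vljs": {"T0": 449.10, "T1": 672.35, "T2": 564.69, "T3": 559.10},
}

#: standard error (mm^3) of each estimated mean
ESTIMATED_SES = {
    "Vjs": {"T0": 49.48, "T1": 64.45, "T2": 48.44, "T3": 48.97},
    "Vajs": {"T0": 20.79, "T1": 24.16, "T2": 20.33, "T3": 20.36},
    "Vpjs": {"T0": 24.99, "T1": 32.27, "T2": 26.08, "T3": 26.75},
    "Vmjs": {"T0": 36.80, "T1": 49.44, "T2": 35.74, "T3": 36.24},
    "Vljs": {"T0": 19.57, "T1": 25.91, "T2": 20.15, "T3": 19.93},
}

#: post-hoc pairwise differences (mm^3), later visit minus earlier visit,
#: keyed by (earlier, later)
PAIRWISE_DIFFERENCES = {
    "Vjs": {
        ("T0", "T1"): 348.29, ("T0", "T2"): 142.06, ("T0", "T3"): 134.54,
        ("T1", "T2"): -206.17, ("T1", "T3"): -213.69, ("T2", "T3"): -7.52,
    },
    "Vajs": {
        ("T0", "T1"): 88.41, ("T0", "T2"): 1.61, ("T0", "T3"): 1.19,
        ("T1", "T2"): -86.80, ("T1", "T3"): -87.21, ("T2", "T3"): -0.42,
    },
    "Vpjs": {
        ("T0", "T1"): 283.12, ("T0", "T2"): 140.40, ("T0", "T3"): 130.72,
        ("T1", "T2"): -142.72, ("T1", "T3"): -152.40, ("T2", "T3"): -9.69,
    },
    "Vmjs": {
        ("T0", "T1"): 149.02, ("T0", "T2"): 26.35, ("T0", "T3"): 21.25,
        ("T1", "T2"): -122.67, ("T1", "T3"): -127.78, ("T2", "T3"): -5.11,
    },
    "Vljs": {
        ("T0", "T1"): 223.26, ("T0", "T2"): 115.59, ("T0", "T3"): 109.98,
        ("T1", "T2"): -107.67, ("T1", "T3"): -113.26, ("T2", "T3"): -5.59,
    },
}
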