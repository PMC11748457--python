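"""Reference values from the published two-scenario skink habitat analysis
that this package re-implements: per-model evaluation metrics with their
composite gamma scores, the randomized-pairing tally table, and the
per-grade habitat areas under the current climate and future climate
periods. Used as worked examples for the scoring, tally and area-accounting
arithmetic."""

# (scenario, group, model label, CSI, KAPPA, AUC, TSS, reported gamma)
GAMMA_TABLE = [
    ("scenario1", 1, "GLM(1)", 0.467, 0.597, 0.956, 0.850, 0.359),
    ("scenario1", 2, "XGBOOST(4)", 0.583, 0.712, 0.971, 0.748, 0.377),
    ("scenario1", 3, "ANN(9)", 0.421, 0.542, 0.929, 0.789, 0.335),
    ("scenario1", 4, "GBM(2)", 0.500, 0.632, 0.960, 0.799, 0.361),
    ("scenario1", 5, "GLM(5)", 0.467, 0.597, 0.966, 0.840, 0.359),
    ("scenario1", 6, "ANN(7)", 0.444, 0.569, 0.943, 0.799, 0.344),
    ("scenario1", 7, "ANN(5)", 0.571, 0.698, 0.972, 0.940, 0.398),
    ("scenario1", 8, "EMmodels(1)", 0.837, 0.903, 0.993, 0.944, 0.460),
    ("scenario1", 9, "GLM(4)", 0.471, 0.597, 0.959, 0.880, 0.363),
    ("scenario1", 10, "MAXENT(4)", 0.353, 0.468, 0.917, 0.780, 0.315),
    ("scenario2", 1, "MAXENT(4)", 0.455, 0.596, 0.961, 0.829, 0.355),
    ("scenario2", 2, "MAXENT(10)", 0.400, 0.517, 0.951, 0.810, 0.335),
    ("scenario2", 3, "GLM(3)", 0.417, 0.554, 0.974, 0.870, 0.352),
    ("scenario2", 4, "XGBOOST(7)", 0.500, 0.637, 0.972, 0.637, 0.311),
    ("scenario2", 5, "GLM(6)", 0.389, 0.508, 0.943, 0.749, 0.324),
    ("scenario2", 6, "MARS(1)", 0.533, 0.662, 0.978, 0.890, 0.383),
    ("scenario2", 7, "GLM(3)", 0.643, 0.758, 0.994, 0.940, 0.417),
    ("scenario2", 8, "FDA(9)", 0.471, 0.597, 0.969, 0.809, 0.356),
    ("scenario2", 9, "GBM(10)", 0.583, 0.712, 0.965, 0.748, 0.376),
    ("scenario2", 10, "GBM(5)", 0.400, 0.527, 0.958, 0.718, 0.325),
]

# per-repetition pairing tallies: (control, test, equality, fragmentation)
PAIRING_TALLY = [
    (2, 8, 6, 11),
    (4, 5, 7, 0),
    (2, 13, 1, 10),
    (4, 10, 2, 4),
    (2, 2, 12, 1),
    (4, 7, 5, 5),
    (1, 9, 6, 6),
    (8, 0, 8, 0),
    (2, 9, 5, 3),
    (5, 11, 0, 10),
]

# current-climate per-grade areas, 1e4 km^2
AREAS_SCENARIO1 = {"highly": 61.95, "moderately": 69.94, "poorly": 52.35, "unsuitable": 773.61}
AREAS_SCENARIO2 = {"highly": 37.19, "moderately": 30.62, "poorly": 72.30, "unsuitable": 817.74}

# future-period suitable-class areas (no unsuitable row reported), 1e4 km^2
AREAS_SSP126_2050 = {"highly": 36.82, "moderately": 17.34, "poorly": 75.45}
AREAS_SSP126_2090 = {"highly": 36.34, "moderately": 37.30, "poorly": 36.89}
AREAS_SSP585_2050 = {"highly": 40.64, "moderately": 39.04, "poorly": 65.74}
AREAS_SSP585_2090 = {"highly": 66.16, "moderately": 40.25, "poorly": 60.74}
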