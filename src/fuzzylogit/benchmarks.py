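"""Published reference values for validating the metric and defuzzification
engines.

These fixtures are reported results from the clinical benchmarking study of
the fuzzy logistic regression framework: the confusion matrices of its
two-predictor motivating example, per-dataset scores of the fuzzy model
(and one SMOTE-KNN column) across twelve clinical datasets, and the largest
TFN coefficient per dataset with its published crisp estimate and odds
ratio.  They serve as fixed inputs for arithmetic checks — this package
recomputes the derived quantities from them; it does not re-run the
original clinical analyses.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

__all__ = [
    "MOTIVATING_CONFUSIONS",
    "MOTIVATING_SCORES",
    "BENCHMARK_DATASETS",
    "FLR_F1",
    "SMOTE_FLR_F1",
    "FLR_MCC",
    "SMOTE_KNN_SENSITIVITY",
    "LARGEST_COEFFICIENTS",
]

# Motivating example: X1-only model (imbalance pathology), X1+X2 model
# (separation-inflated), and the X1+X2 model scored on the new-data sample
# (over-fitting exposed).
MOTIVATING_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "model_I": ConfusionMatrix(TP=4, TN=82, FP=2, FN=11),
    "model_II": ConfusionMatrix(TP=14, TN=83, FP=1, FN=1),
    "model_II_dataset_II": ConfusionMatrix(TP=4, TN=39, FP=1, FN=6),
}

# Reported (sensitivity, specificity, F1, MCC) for the three examples above.
MOTIVATING_SCORES: dict[str, tuple[float, float, float, float]] = {
    "model_I": (0.267, 0.976, 0.381, 0.365),
    "model_II": (0.933, 0.988, 0.933, 0.921),
    "model_II_dataset_II": (0.400, 0.975, 0.533, 0.500),
}

BENCHMARK_DATASETS = [
    "breast_cancer",
    "breast_cancer_wisconsin_prognostic",
    "breast_cancer_wisconsin_diagnostic",
    "hepatitis",
    "pima_indians_diabetes",
    "liver_disorders",
    "spectf_heart",
    "fertility",
    "diabetic_retinopathy_debrecen",
    "breast_cancer_coimbra",
    "parkinsons_disease",
    "heart_failure",
]

# Per-dataset published scores (order follows BENCHMARK_DATASETS).
FLR_F1 = [0.818, 0.830, 0.813, 0.801, 0.825, 0.839,
          0.898, 0.927, 0.894, 0.926, 0.898, 0.846]
SMOTE_FLR_F1 = [0.938, 0.976, 0.973, 0.942, 0.866, 0.968,
                0.934, 0.883, 0.866, 0.855, 0.843, 0.850]
FLR_MCC = [0.725, 0.795, 0.788, 0.798, 0.756, 0.756,
           0.842, 0.756, 0.816, 0.841, 0.786, 0.824]
SMOTE_KNN_SENSITIVITY = [0.644, 0.568, 0.939, 0.567, 0.569, 0.618,
                         0.903, 0.497, 0.660, 0.612, 0.621, 0.481]

# Largest TFN coefficient per dataset with the published crisp
# (centre-of-gravity) estimate and odds ratio exp(beta).  The published
# odds ratios follow from the crisp estimates at their printed 3-decimal
# precision.
LARGEST_COEFFICIENTS: list[tuple[str, str, tuple[float, float, float],
                                 float, float]] = [
    ("breast_cancer", "X4", (-1.796, -1.308, -0.593), -1.232, 0.292),
    ("breast_cancer_wisconsin_prognostic", "X12",
     (1.507, 1.642, 1.779), 1.643, 5.171),
    ("breast_cancer_wisconsin_diagnostic", "X28",
     (1.022, 1.492, 1.645), 1.386, 3.999),
    ("hepatitis", "varices", (-1.935, -1.595, -0.582), -1.371, 0.254),
    ("pima_indians_diabetes", "X1", (-1.772, -0.803, 0.131), -0.815, 0.443),
    ("liver_disorders", "alkphos", (-1.087, -1.072, -0.919), -1.026, 0.358),
    ("spectf_heart", "F9S", (-1.973, -1.403, -1.384), -1.587, 0.205),
    ("fertility", "X3", (-1.939, -1.656, 0.244), -1.117, 0.327),
    ("diabetic_retinopathy_debrecen", "X15",
     (1.068, 1.885, 1.995), 1.649, 5.202),
    ("breast_cancer_coimbra", "HOMA", (-1.567, -1.400, -0.780), -1.249, 0.287),
    ("parkinsons_disease", "tqwt_mean_dec_30",
     (1.715, 1.733, 1.974), 1.807, 6.092),
    ("heart_failure", "diabetes", (-1.808, -0.831, -0.530), -1.056, 0.348),
]
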