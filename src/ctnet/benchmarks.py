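"""Published per-subject benchmark results used as statistics inputs.

Per-subject classification accuracies (percent) reported in the benchmark
literature for the BCI Competition IV-2a (subjects A01-A09) and IV-2b
(B01-B09) datasets, under the subject-specific and leave-one-subject-out
protocols.  These printed rows are the worked-example inputs for the
statistical evaluation chain (aggregation, kappa conversion, exact Wilcoxon
tests); the package does not re-derive them from raw recordings.
"""

SUBJECTS_IV2A = [f"A0{i}" for i in range(1, 10)]
SUBJECTS_IV2B = [f"B0{i}" for i in range(1, 10)]

# subject-specific protocol, BCI IV-2a (4 classes)
IV2A_SUBJECT_SPECIFIC = {
    "ShallowConvNet": [82.64, 55.21, 92.01, 74.31, 72.92, 59.72, 81.60, 83.33, 79.51],
    "DeepConvNet":    [82.29, 44.79, 90.63, 76.04, 77.43, 68.06, 92.01, 83.33, 85.42],
    "EEGNet":         [88.19, 56.94, 93.06, 71.18, 70.49, 62.85, 87.15, 82.64, 84.03],
    "Conformer":      [85.07, 48.96, 91.32, 78.47, 75.00, 65.28, 87.85, 87.15, 79.86],
    "CTNet":          [90.97, 73.61, 96.53, 84.72, 77.08, 64.24, 86.11, 84.38, 85.07],
}

# subject-specific protocol, BCI IV-2b (2 classes)
IV2B_SUBJECT_SPECIFIC = {
    "ShallowConvNet": [77.81, 61.79, 83.13, 97.50, 93.13, 83.44, 92.50, 91.88, 85.00],
    "DeepConvNet":    [75.00, 67.50, 81.56, 97.81, 91.56, 82.50, 90.31, 93.13, 87.50],
    "EEGNet":         [78.75, 67.50, 85.94, 97.50, 94.69, 90.00, 93.13, 92.50, 89.38],
    "Conformer":      [73.13, 67.50, 79.06, 97.19, 96.88, 83.13, 93.13, 92.81, 90.00],
    "CTNet":          [78.75, 71.07, 84.38, 97.19, 97.81, 87.81, 94.06, 94.69, 90.63],
}

# leave-one-subject-out protocol
IV2A_LOSO = {
    "ShallowConvNet": [66.84, 46.53, 67.53, 52.26, 34.38, 39.76, 65.45, 71.18, 66.84],
    "DeepConvNet":    [68.58, 47.40, 78.99, 52.26, 50.87, 41.84, 69.44, 71.70, 60.24],
    "EEGNet":         [69.79, 42.01, 79.51, 50.87, 35.76, 37.15, 65.80, 67.36, 63.37],
    "Conformer":      [68.75, 37.33, 69.62, 43.58, 29.51, 35.24, 58.33, 74.48, 63.89],
    "CTNet":          [69.27, 43.92, 79.34, 55.38, 43.92, 36.11, 65.10, 70.66, 64.06],
}

IV2B_LOSO = {
    "ShallowConvNet": [74.03, 63.53, 59.72, 82.84, 82.43, 80.97, 74.86, 72.37, 77.78],
    "DeepConvNet":    [74.03, 65.15, 63.47, 80.81, 82.70, 74.86, 81.39, 76.32, 77.92],
    "EEGNet":         [74.44, 69.26, 62.36, 80.41, 83.24, 75.56, 79.86, 73.55, 77.50],
    "Conformer":      [71.39, 62.35, 65.28, 82.97, 80.41, 69.31, 75.00, 76.32, 78.61],
    "CTNet":          [76.25, 71.03, 66.39, 81.76, 83.11, 77.22, 79.17, 73.56, 77.92],
}

N_CLASSES = {"iv2a": 4, "iv2b": 2}
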