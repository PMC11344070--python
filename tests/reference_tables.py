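"""Frozen fixtures: per-dataset family-mean accuracies (%) and AUCs from a
published four-species evaluation report (six pairwise datasets, four
one-vs-all datasets, K10 protocol).  The aggregation code must reproduce
the report's printed bottom-row means and rounded difference rows from
these per-dataset columns alone.
"""

DATASETS = (
    "Human_vs_Gorilla", "Human_vs_Mouse", "Human_vs_Rat",
    "Mouse_vs_Gorilla", "Mouse_vs_Rat", "Rat_vs_Gorilla",
    "Human_vs_All", "Gorilla_vs_All", "Rat_vs_All", "Mouse_vs_All",
)

# solo vs hybrid vs ensemble DL comparison
SDL_ETA = (89.31, 81.21, 83.19, 94.11, 91.23, 92.31, 85.10, 93.53, 89.43, 87.68)
SDL_ALPHA = (0.8998, 0.8203, 0.8397, 0.9518, 0.9212, 0.9295,
             0.8545, 0.9421, 0.9104, 0.8947)
HDL_ETA = (92.19, 82.99, 85.57, 96.68, 94.30, 95.38, 85.88, 95.95, 90.54, 89.30)
HDL_ALPHA = (0.9336, 0.8384, 0.8766, 0.9704, 0.9575, 0.9611,
             0.8738, 0.9702, 0.9174, 0.9046)
EDL_ETA = (95.29, 85.77, 87.92, 97.28, 95.66, 96.03, 88.65, 97.45, 93.06, 91.74)
EDL_ALPHA = (0.9575, 0.8636, 0.8851, 0.9737, 0.9735, 0.9696,
             0.8934, 0.9765, 0.9390, 0.9240)
# printed bottom rows / difference rows
SDL_MEAN_ETA, SDL_MEAN_ALPHA = 88.71, 0.8964
HDL_MEAN_ETA, HDL_MEAN_ALPHA = 90.88, 0.9204
EDL_MEAN_ETA, EDL_MEAN_ALPHA = 92.89, 0.9356
D1_ETA, D1_ALPHA = 2.17, 2.40   # HDL vs SDL
D2_ETA, D2_ALPHA = 2.01, 1.52   # EDL vs HDL
D3_ETA, D3_ALPHA = 4.18, 3.92   # EDL vs SDL

# ensemble DL with vs without convolutional stages
WOCNN_ETA = (95.21, 83.89, 86.89, 96.44, 95.58, 95.85, 88.44, 97.18, 92.90, 91.61)
WOCNN_ALPHA = (0.9528, 0.8435, 0.8727, 0.9712, 0.9674, 0.9693,
               0.8904, 0.9750, 0.9320, 0.9207)
WCNN_ETA = (95.33, 86.70, 88.44, 97.70, 95.70, 96.12, 88.75, 97.58, 93.14, 91.81)
WCNN_ALPHA = (0.9598, 0.8737, 0.8914, 0.9749, 0.9765, 0.9697,
              0.8950, 0.9772, 0.9426, 0.9256)
WOCNN_MEAN_ETA, WCNN_MEAN_ETA = 92.40, 93.13
WOCNN_MEAN_ALPHA, WCNN_MEAN_ALPHA = 0.9295, 0.9387
C1_ETA, C1_ALPHA = 0.73, 0.92

# solo vs voting-ensemble ML
SML_ETA = (79.82, 67.82, 76.13, 84.23, 81.60, 85.18, 75.73, 84.91, 81.24, 78.95)
SML_ALPHA = (0.8044, 0.6975, 0.7792, 0.8603, 0.8260, 0.8552,
             0.7514, 0.8464, 0.8113, 0.7825)
EML_ETA = (88.32, 74.69, 83.69, 90.84, 86.97, 92.03, 79.12, 91.39, 86.94, 84.04)
EML_ALPHA = (0.8893, 0.7431, 0.8460, 0.9179, 0.8792, 0.9273,
             0.8094, 0.9096, 0.8829, 0.8546)
SML_MEAN_ETA, SML_MEAN_ALPHA = 79.56, 0.8014
EML_MEAN_ETA, EML_MEAN_ALPHA = 85.80, 0.8660
M1_ETA, M1_ALPHA = 6.24, 6.46   # EML vs SML
E1_ETA, E1_ALPHA = 7.09, 6.96   # EDL vs EML

# K-protocol sweep of the 24 DL models: per-protocol grand means
PROTOCOL_METRICS = {
    "Accuracy(%)": {"K2": 85.96, "K4": 87.20, "K5": 88.54, "K10": 90.82},
    "AUC": {"K2": 0.8634, "K4": 0.8863, "K5": 0.9019, "K10": 0.9175},
    "Recall(%)": {"K2": 86.06, "K4": 87.73, "K5": 88.98, "K10": 91.39},
    "Precision(%)": {"K2": 85.18, "K4": 86.59, "K5": 87.67, "K10": 90.01},
    "F1(%)": {"K2": 85.62, "K4": 87.16, "K5": 88.32, "K10": 90.69},
}
# printed K10-minus-K{5,4,2} difference rows (AUC differences are x100)
PROTOCOL_DIFFS = {
    "Accuracy(%)": {"D1": 2.28, "D2": 3.62, "D3": 4.86},
    "AUC": {"D1": 1.56, "D2": 3.12, "D3": 5.41},
}
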