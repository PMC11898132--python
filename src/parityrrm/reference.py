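"""Published genetic-parameter estimates for litter size in the two
Barbarine selection lines (liability scale).

These are the reported posterior-mean variance components, heritabilities
and permanent-environment fractions for the prolific (3-category) and
conventional (2-category) lines under the threshold repeatability and
second-order random-regression models. They serve as worked-example
inputs and as cross-checks for the ratio identities
h2 = sa / (sa + sp + se) and c2 = sp / (sa + sp + se).

Each row: (parity, sigma2_a, sigma2_p, sigma2_e, h2, c2); parity None
marks the repeatability model.
"""

PUBLISHED_ESTIMATES = {
    "prolific": {
        "repeatability": [(None, 0.060, 0.043, 0.306, 0.14, 0.10)],
        "random_regression": [
            (1, 0.060, 0.582, 0.769, 0.04, 0.41),
            (2, 0.065, 0.219, 0.735, 0.06, 0.21),
            (3, 0.104, 0.110, 0.735, 0.11, 0.12),
            (4, 0.119, 0.076, 0.735, 0.13, 0.08),
            (5, 0.130, 0.085, 0.794, 0.13, 0.08),
            (6, 0.231, 0.251, 0.794, 0.18, 0.20),
        ],
    },
    "conventional": {
        "repeatability": [(None, 0.223, 0.273, 1.003, 0.15, 0.18)],
        "random_regression": [
            (1, 0.822, 1.768, 1.003, 0.23, 0.49),
            (2, 0.338, 0.577, 1.066, 0.17, 0.29),
            (3, 0.387, 0.635, 1.003, 0.19, 0.31),
            (4, 0.422, 0.738, 1.003, 0.20, 0.34),
            (5, 0.526, 0.656, 1.003, 0.24, 0.30),
            (6, 1.406, 1.130, 1.066, 0.39, 0.31),
        ],
    },
}

#: reported across-parity mean c2 per line under the random-regression model
PUBLISHED_MEAN_C2 = {"prolific": 0.18, "conventional": 0.34}
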