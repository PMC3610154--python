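"""Critical bounds for the studentized range q = (max-min)/s under normality.

Two-sided bounds (equal tail mass alpha/2 each side) per sample size n,
derived once by Monte-Carlo simulation of the null distribution
(10^6 standard-normal samples per n, fixed seed); values are frozen here
so the normality quick test is deterministic and self-contained.
"""

# (n, alpha) -> (lower, upper)
DAVID_BOUNDS = {
    (3, 0.05): (1.7452, 1.9998),
    (3, 0.01): (1.7347, 2.0000),
    (4, 0.05): (1.9142, 2.4393),
    (4, 0.01): (1.8178, 2.4475),
    (5, 0.05): (2.0796, 2.7822),
    (5, 0.01): (1.9870, 2.8128),
    (6, 0.05): (2.2193, 3.0561),
    (6, 0.01): (2.1140, 3.1149),
    (7, 0.05): (2.3342, 3.2816),
    (7, 0.01): (2.2180, 3.3683),
    (8, 0.05): (2.4329, 3.4714),
    (8, 0.01): (2.3083, 3.5857),
    (9, 0.05): (2.5178, 3.6345),
    (9, 0.01): (2.3886, 3.7718),
    (10, 0.05): (2.5949, 3.7760),
    (10, 0.01): (2.4588, 3.9338),
    (11, 0.05): (2.6633, 3.9049),
    (11, 0.01): (2.5245, 4.0811),
    (12, 0.05): (2.7239, 4.0162),
    (12, 0.01): (2.5833, 4.2093),
    (13, 0.05): (2.7815, 4.1158),
    (13, 0.01): (2.6360, 4.3232),
    (14, 0.05): (2.8351, 4.2116),
    (14, 0.01): (2.6867, 4.4311),
    (15, 0.05): (2.8851, 4.2940),
    (15, 0.01): (2.7342, 4.5235),
    (16, 0.05): (2.9309, 4.3713),
    (16, 0.01): (2.7780, 4.6175),
    (17, 0.05): (2.9739, 4.4467),
    (17, 0.01): (2.8187, 4.6965),
    (18, 0.05): (3.0133, 4.5110),
    (18, 0.01): (2.8578, 4.7760),
    (19, 0.05): (3.0521, 4.5754),
    (19, 0.01): (2.8940, 4.8455),
    (20, 0.05): (3.0878, 4.6338),
    (20, 0.01): (2.9292, 4.9108),
    (25, 0.05): (3.2454, 4.8732),
    (25, 0.01): (3.0799, 5.1806),
    (30, 0.05): (3.3728, 5.0634),
    (30, 0.01): (3.2038, 5.3995),
    (35, 0.05): (3.4808, 5.2173),
    (35, 0.01): (3.3055, 5.5712),
    (40, 0.05): (3.5740, 5.3426),
    (40, 0.01): (3.3966, 5.7115),
    (45, 0.05): (3.6559, 5.4508),
    (45, 0.01): (3.4766, 5.8289),
    (50, 0.05): (3.7298, 5.5461),
    (50, 0.01): (3.5496, 5.9314),
    (60, 0.05): (3.8565, 5.7037),
    (60, 0.01): (3.6720, 6.1019),
    (70, 0.05): (3.9616, 5.8304),
    (70, 0.01): (3.7781, 6.2397),
    (80, 0.05): (4.0515, 5.9356),
    (80, 0.01): (3.8659, 6.3530),
    (90, 0.05): (4.1327, 6.0314),
    (90, 0.01): (3.9478, 6.4469),
    (100, 0.05): (4.2052, 6.1090),
    (100, 0.01): (4.0172, 6.5335),
}

SUPPORTED_N = sorted({n for (n, _a) in DAVID_BOUNDS})
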