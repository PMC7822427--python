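"""Published per-treatment trait summaries for the four maize root types.

Each cell is the treatment mean, its standard error over n = 4 replicate
plants, and the compact-letter-display superscript printed with it.  These
values calibrate the synthetic-data generator and drive the deterministic
worked examples (percent changes, interaction effect sizes).
"""

TREATMENTS: tuple[str, ...] = ("Control", "Drought", "Heat", "Combined")

N_REPLICATES: int = 4

ROOT_TYPES: tuple[str, ...] = (
    "primary",
    "seminal",
    "primary_lateral",
    "seminal_lateral",
)

# (root_type, trait) -> (unit, ((mean, se, letters) for each treatment in
# TREATMENTS order)).  Letters are the published Tukey groupings at
# alpha = 0.05 and are carried for reference only; nothing downstream
# recomputes from them.
TABLE_CELLS: dict[tuple[str, str], tuple[str, tuple[tuple[float, float, str], ...]]] = {
    # --- primary root axis -------------------------------------------------
    ("primary", "fresh_weight"): ("g", (
        (0.128, 0.008, "a"), (0.131, 0.001, "a"), (0.147, 0.001, "a"), (0.162, 0.021, "a"))),
    ("primary", "dry_weight"): ("g", (
        (0.0111, 0.0009, "b"), (0.0116, 0.0006, "b"), (0.0131, 0.0003, "b"), (0.0168, 0.0017, "a"))),
    ("primary", "length"): ("cm", (
        (49, 1, "a"), (71, 6, "a"), (57, 4, "a"), (66, 12, "a"))),
    ("primary", "surface_area"): ("cm2", (
        (9.460, 0.009, "a"), (10.669, 0.896, "a"), (9.723, 0.587, "a"), (10.415, 1.766, "a"))),
    ("primary", "RLR"): ("cm/g", (
        (63, 4, "b"), (123, 12, "a"), (83, 2, "b"), (117, 15, "a"))),
    ("primary", "RMR"): ("g/g", (
        (0.01381, 0.00016, "c"), (0.01840, 0.00002, "b"), (0.02004, 0.00051, "b"), (0.02702, 0.00205, "a"))),
    ("primary", "fineness"): ("cm/cm3", (
        (336, 11, "c"), (531, 11, "a"), (396, 8, "b"), (500, 6, "a"))),
    ("primary", "tissue_density"): ("g/cm3", (
        (0.075, 0.007, "c"), (0.097, 0.006, "b"), (0.097, 0.003, "b"), (0.117, 0.007, "a"))),
    ("primary", "root_zone"): ("cm", (
        (9, 1, "a,b"), (3, 1, "b"), (9, 3, "a"), (7, 1, "a,b"))),
    ("primary", "branching_zone"): ("cm", (
        (42, 2, "b"), (65, 5, "a"), (48, 1, "a,b"), (64, 11, "a"))),
    ("primary", "branching_density"): ("n/cm", (
        (4.961, 0.101, "a"), (3.389, 0.051, "c"), (4.276, 0.027, "b"), (4.152, 0.284, "b"))),
    # --- seminal root axis -------------------------------------------------
    ("seminal", "fresh_weight"): ("g", (
        (0.285, 0.031, "a"), (0.172, 0.029, "b"), (0.205, 0.043, "a,b"), (0.176, 0.018, "b"))),
    ("seminal", "dry_weight"): ("g", (
        (0.021, 0.004, "a"), (0.015, 0.003, "a"), (0.014, 0.004, "a"), (0.018, 0.002, "a"))),
    ("seminal", "length"): ("cm", (
        (64, 7, "a"), (64, 7, "a"), (63, 8, "a"), (51, 2, "a"))),
    ("seminal", "surface_area"): ("cm2", (
        (11, 1, "a"), (10, 1, "a"), (12, 2, "a"), (10, 1, "a"))),
    ("seminal", "RLR"): ("cm/g", (
        (82, 13, "a"), (103, 14, "a"), (97, 14, "a"), (83, 1, "a"))),
    ("seminal", "RMR"): ("g/g", (
        (0.027, 0.002, "a"), (0.023, 0.002, "a"), (0.027, 0.007, "a"), (0.031, 0.003, "a"))),
    ("seminal", "fineness"): ("cm/cm3", (
        (294, 47, "b"), (463, 21, "a"), (435, 55, "a"), (362, 24, "a,b"))),
    ("seminal", "tissue_density"): ("g/cm3", (
        (0.094, 0.007, "a,b"), (0.064, 0.023, "b"), (0.091, 0.003, "a,b"), (0.124, 0.001, "a"))),
    ("seminal", "root_zone"): ("cm", (
        (7, 1, "a,b"), (8, 2, "a,b"), (12, 3, "a"), (6, 1, "b"))),
    ("seminal", "branching_zone"): ("cm", (
        (54, 5, "a"), (55, 6, "a"), (57, 14, "a"), (44, 3, "a"))),
    ("seminal", "branching_density"): ("n/cm", (
        (2.8, 0.1, "b"), (2.9, 0.1, "b"), (4.5, 0.4, "a"), (3.0, 0.2, "b"))),
    # --- primary lateral roots --------------------------------------------
    ("primary_lateral", "fresh_weight"): ("g", (
        (0.212, 0.012, "b"), (0.280, 0.047, "a,b"), (0.315, 0.040, "a"), (0.225, 0.001, "a,b"))),
    ("primary_lateral", "dry_weight"): ("g", (
        (0.022, 0.004, "a"), (0.016, 0.001, "a"), (0.021, 0.003, "a"), (0.020, 0.001, "a"))),
    ("primary_lateral", "length"): ("cm", (
        (557, 8, "c"), (691, 35, "b,c"), (757, 82, "b"), (1028, 33, "a"))),
    ("primary_lateral", "surface_area"): ("cm2", (
        (34.6, 0.7, "b"), (37.2, 2.7, "b"), (45.8, 4.8, "a"), (53.3, 0.1, "a"))),
    ("primary_lateral", "number"): ("n", (
        (208, 16, "a"), (225, 14, "a"), (200, 2, "a"), (247, 27, "a"))),
    ("primary_lateral", "average_length"): ("cm", (
        (2.860, 0.136, "b"), (3.076, 0.039, "b"), (3.640, 0.384, "a,b"), (4.486, 0.578, "a"))),
    ("primary_lateral", "RLR"): ("cm/g", (
        (736, 41, "c"), (1195, 63, "b"), (1125, 75, "b"), (1650, 90, "a"))),
    ("primary_lateral", "RMR"): ("g/g", (
        (0.0324, 0.0079, "a"), (0.0220, 0.0003, "a"), (0.0308, 0.0031, "a"), (0.0330, 0.0016, "a"))),
    ("primary_lateral", "fineness"): ("cm/cm3", (
        (3257, 44, "c"), (4018, 56, "b"), (3512, 76, "c"), (4670, 288, "a"))),
    ("primary_lateral", "tissue_density"): ("g/cm3", (
        (0.134, 0.027, "a"), (0.093, 0.005, "a"), (0.097, 0.005, "a"), (0.093, 0.006, "a"))),
    # --- seminal lateral roots --------------------------------------------
    ("seminal_lateral", "fresh_weight"): ("g", (
        (0.0600, 0.0114, "a,b"), (0.0355, 0.0048, "b"), (0.1323, 0.0459, "a"), (0.0149, 0.0002, "b"))),
    ("seminal_lateral", "dry_weight"): ("g", (
        (0.0051, 0.0010, "a"), (0.0035, 0.0006, "a,b"), (0.0025, 0.0008, "b"), (0.0013, 0.0002, "b"))),
    ("seminal_lateral", "length"): ("cm", (
        (113, 7, "a"), (104, 1, "a,b"), (105, 13, "a,b"), (79, 14, "b"))),
    ("seminal_lateral", "surface_area"): ("cm2", (
        (8.5, 1.3, "a"), (7.5, 0.1, "a"), (3.7, 0.6, "b"), (4.5, 0.9, "b"))),
    ("seminal_lateral", "number"): ("n", (
        (149, 21, "a,b"), (169, 18, "a,b"), (202, 23, "a"), (134, 5, "b"))),
    ("seminal_lateral", "average_length"): ("cm", (
        (0.872, 0.151, "a"), (0.707, 0.081, "a"), (0.563, 0.136, "a"), (0.530, 0.094, "a"))),
    ("seminal_lateral", "RLR"): ("cm/g", (
        (147, 1, "a,b"), (178, 2, "a"), (151, 12, "a,b"), (128, 19, "b"))),
    ("seminal_lateral", "RMR"): ("g/g", (
        (0.0066, 0.0010, "a"), (0.0032, 0.0001, "b"), (0.0041, 0.0015, "a,b"), (0.0021, 0.0003, "b"))),
    ("seminal_lateral", "fineness"): ("cm/cm3", (
        (2728, 48, "b"), (2416, 0, "b"), (3630, 376, "b"), (6283, 1176, "a"))),
    ("seminal_lateral", "tissue_density"): ("g/cm3", (
        (0.095, 0.004, "a"), (0.085, 0.015, "a"), (0.101, 0.036, "a"), (0.102, 0.022, "a"))),
}
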