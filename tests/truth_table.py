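"""Hand-computed classification truth table.

Each case is (case id, diagnosis records, expected merged group ids).
Records are (icd10_code, quarter, qualifier).  Expectations were derived by
hand from the catalog rules: M2Q groups need accepted-qualifier records in
two distinct quarters, M1Q groups in one; sub-rules 1a (I20/I25,
confirmed-or-status-post) vs 1b (I21-I24, status-post only) and 4a
(bronchitis, M1Q confirmed) vs 4b (COPD, M2Q) are evaluated separately but
report the merged group; ICD matching is by code prefix at printed
precision.
"""

TRUTH_TABLE = [
    # --- M2Q basics (hypertension, group 7) ---
    ("m2q_two_quarters", [("I10", 1, "confirmed"), ("I10", 3, "confirmed")], {7}),
    ("m2q_one_quarter", [("I10", 1, "confirmed")], set()),
    ("m2q_same_quarter_twice",
     [("I10", 1, "confirmed"), ("I10", 1, "confirmed")], set()),
    ("m2q_mixed_codes_same_group",
     [("I10", 1, "confirmed"), ("I12", 4, "status_post")], {7}),
    ("m2q_status_post_pair",
     [("I10", 2, "status_post"), ("I15", 3, "status_post")], {7}),
    ("m2q_other_not_accepted",
     [("I10", 1, "other"), ("I10", 2, "confirmed")], set()),
    # --- M1Q basics (intestinal infections, group 9) ---
    ("m1q_confirmed_once", [("A02", 2, "confirmed")], {9}),
    ("m1q_status_post_rejected", [("A02", 2, "status_post")], set()),
    ("m1q_other_rejected", [("A02", 2, "other")], set()),
    # --- sub-rule 1a vs 1b ---
    ("1b_status_post_two_quarters",
     [("I21", 1, "status_post"), ("I23", 3, "status_post")], {1}),
    ("1b_confirmed_rejected",
     [("I21", 1, "confirmed"), ("I23", 3, "confirmed")], set()),
    ("1a_confirmed_and_status_post",
     [("I20", 1, "confirmed"), ("I25", 2, "status_post")], {1}),
    ("subrules_do_not_combine",
     [("I20", 1, "confirmed"), ("I21", 2, "status_post")], set()),
    ("1a_two_quarters_plus_1b_single",
     [("I20", 1, "confirmed"), ("I20", 2, "confirmed"),
      ("I21", 3, "status_post")], {1}),
    # --- sub-rule 4a (M1Q bronchitis) vs 4b (M2Q COPD) ---
    ("4a_single_confirmed", [("J20", 1, "confirmed")], {4}),
    ("4a_status_post_rejected", [("J20", 1, "status_post")], set()),
    ("4b_two_quarters",
     [("J44", 1, "confirmed"), ("J44", 2, "confirmed")], {4}),
    ("4b_single_quarter", [("J44", 1, "confirmed")], set()),
    ("4a_and_4b_merge_to_one_group",
     [("J40", 3, "confirmed"), ("J44", 1, "confirmed"),
      ("J47", 2, "confirmed")], {4}),
    # --- prefix matching ---
    ("prefix_four_digit_codes",
     [("I10.90", 1, "confirmed"), ("I10.0", 4, "status_post")], {7}),
    ("r07_0_exact", [("R07.0", 3, "confirmed")], {11}),
    ("r07_1_not_matched", [("R07.1", 3, "confirmed")], set()),
    ("r07_bare_not_matched", [("R07", 3, "confirmed")], set()),
    ("prefix_without_dot",
     [("I100", 1, "confirmed"), ("I10", 2, "confirmed")], {7}),
    ("prefix_child_of_range_member",
     [("I05", 1, "confirmed"), ("I05.1", 2, "confirmed")], {3}),
    # --- range boundaries ---
    ("range_upper_bound_inside",
     [("I15", 2, "confirmed"), ("I15", 4, "confirmed")], {7}),
    ("range_upper_bound_outside",
     [("I16", 2, "confirmed"), ("I16", 4, "confirmed")], set()),
    ("range_a09_inside", [("A09", 1, "confirmed")], {9}),
    ("range_a10_outside", [("A10", 1, "confirmed")], set()),
    ("range_j03_inside", [("J03", 2, "confirmed")], {11}),
    ("range_j05_outside", [("J05", 2, "confirmed")], set()),
    # --- one case per remaining group ---
    ("heart_failure_other_breaks_m2q",
     [("I50", 1, "confirmed"), ("I50", 2, "other")], set()),
    ("circulatory_r00",
     [("I49", 1, "confirmed"), ("R00", 3, "confirmed")], {3}),
    ("circulatory_duplicates_one_quarter",
     [("I70", 1, "status_post"), ("I70", 1, "status_post"),
      ("I70", 2, "status_post")], {3}),
    ("circulatory_pair", [("I83", 2, "status_post"), ("I87", 3, "confirmed")], {3}),
    ("alcohol_opioids",
     [("F10", 1, "confirmed"), ("F11", 2, "confirmed")], {5}),
    ("alcohol_single_quarter", [("F10", 1, "confirmed")], set()),
    ("back_pain", [("M42", 1, "confirmed"), ("M54", 2, "confirmed")], {6}),
    ("gastro_m1q", [("K52", 4, "confirmed")], {8}),
    ("gastro_status_post_rejected", [("K52", 4, "status_post")], set()),
    ("ent_j06", [("J06", 2, "confirmed")], {11}),
    ("influenza_j12", [("J12", 1, "confirmed")], {10}),
    ("influenza_two_codes_one_group",
     [("J12", 1, "confirmed"), ("J13", 2, "confirmed")], {10}),
    ("depression_status_post",
     [("F32", 1, "status_post"), ("F33", 3, "status_post")], {12}),
    ("diabetes_e16",
     [("E16", 1, "confirmed"), ("E16", 2, "status_post")], {13}),
    ("diabetes_same_quarter",
     [("E10", 1, "confirmed"), ("E14", 1, "status_post")], set()),
    ("gonarthrosis",
     [("M17", 1, "status_post"), ("M17", 2, "confirmed")], {14}),
    ("heart_failure_ok",
     [("I50", 2, "status_post"), ("I50.1", 4, "confirmed")], {2}),
    # --- multi-group patients and degenerates ---
    ("three_groups",
     [("I10", 1, "confirmed"), ("I11", 2, "confirmed"),
      ("A00", 1, "confirmed"), ("E11", 1, "confirmed"),
      ("E11", 3, "confirmed")], {7, 9, 13}),
    ("two_m1q_groups",
     [("J18", 4, "confirmed"), ("H66", 1, "confirmed")], {10, 11}),
    ("m2q_pair_plus_m2q_failure",
     [("I48", 1, "confirmed"), ("I48", 2, "confirmed"),
      ("I10", 3, "confirmed"), ("I14", 4, "status_post"),
      ("M17", 1, "confirmed")], {3, 7}),
    ("off_catalog_code", [("Z99", 1, "confirmed")], set()),
    ("no_records", [], set()),
]

assert len(TRUTH_TABLE) >= 50
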