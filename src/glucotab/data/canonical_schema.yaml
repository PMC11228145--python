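# Canonical clinical schema: 2 demographic attributes + 37 medical-test
# indicators in six panels (B-G), plus the blood-glucose regression target.
target_name: blood_glucose
attributes:
  - {id: A1, name: Age, group: A, kind: numeric}
  - {id: A2, name: Gender, group: A, kind: categorical}
  - {id: B1, name: Aspartate Aminotransferase (AST), group: B, kind: numeric}
  - {id: B2, name: Alanine Aminotransferase (ALT), group: B, kind: numeric}
  - {id: B3, name: Alkaline Phosphatase (ALP), group: B, kind: numeric}
  - {id: B4, name: Gamma-Glutamyl Transferase (GGT), group: B, kind: numeric}
  - {id: B5, name: Total Protein, group: B, kind: numeric}
  - {id: B6, name: Albumin, group: B, kind: numeric}
  - {id: B7, name: Globulin, group: B, kind: numeric}
  - {id: B8, name: Albumin/Globulin Ratio, group: B, kind: numeric}
  - {id: C1, name: Urea, group: C, kind: numeric}
  - {id: C2, name: Creatinine, group: C, kind: numeric}
  - {id: C3, name: Uric Acid, group: C, kind: numeric}
  - {id: D1, name: Triglycerides (TG), group: D, kind: numeric}
  - {id: D2, name: Total Cholesterol (TC), group: D, kind: numeric}
  - {id: D3, name: High-Density Lipoprotein Cholesterol (HDL-C), group: D, kind: numeric}
  - {id: D4, name: Low-Density Lipoprotein Cholesterol (LDL-C), group: D, kind: numeric}
  - {id: E1, name: Hepatitis B Surface Antigen (HBsAg), group: E, kind: numeric}
  - {id: E2, name: Hepatitis B Surface Antibody (HBsAb), group: E, kind: numeric}
  - {id: E3, name: Hepatitis B e Antigen (HBeAg), group: E, kind: numeric}
  - {id: E4, name: Hepatitis B e Antibody (HBeAb), group: E, kind: numeric}
  - {id: E5, name: Hepatitis B Core Antibody (HBcAb), group: E, kind: numeric}
  - {id: F1, name: White Blood Cell Count (WBC), group: F, kind: numeric}
  - {id: F2, name: Red Blood Cell Count (RBC), group: F, kind: numeric}
  - {id: F3, name: Hemoglobin (HGB), group: F, kind: numeric}
  - {id: F4, name: Hematocrit (HCT), group: F, kind: numeric}
  - {id: F5, name: Mean Corpuscular Volume (MCV), group: F, kind: numeric}
  - {id: F6, name: Mean Corpuscular Hemoglobin (MCH), group: F, kind: numeric}
  - {id: F7, name: Mean Corpuscular Hemoglobin Concentration (MCHC), group: F, kind: numeric}
  - {id: F8, name: Red Cell Distribution Width (RDW), group: F, kind: numeric}
  - {id: F9, name: Platelet Count, group: F, kind: numeric}
  - {id: F10, name: Mean Platelet Volume (MPV), group: F, kind: numeric}
  - {id: F11, name: Platelet Distribution Width (PDW), group: F, kind: numeric}
  - {id: F12, name: Plateletcrit (PCT), group: F, kind: numeric}
  - {id: G1, name: Neutrophils Percentage, group: G, kind: numeric}
  - {id: G2, name: Lymphocytes Percentage, group: G, kind: numeric}
  - {id: G3, name: Monocytes Percentage, group: G, kind: numeric}
  - {id: G4, name: Eosinophils Percentage, group: G, kind: numeric}
  - {id: G5, name: Basophils Percentage, group: G, kind: numeric}
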