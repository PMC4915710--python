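"""Reference metadata tables used as analysis inputs.

``outcome_panel()`` returns the 32-outcome consortium panel (disease class
and case/control/total sample sizes) over which the cross-consortium
analysis runs; these sample sizes feed the instrument-strength F-statistic.
``grs_gwas_annotation()`` returns the rsid/locus/position annotation of the
18 genome-wide-significant CRP instrument SNPs.  Neither table carries
effect estimates: weights and outcome statistics are user inputs (or come
from :mod:`grsmr.simulate`).
"""

from __future__ import annotations

import pandas as pd

#: Fraction of ln CRP variance explained by each instrument.
GRS_CRP_R2 = 0.02   # 4 SNPs tagging the CRP gene
GRS_GWAS_R2 = 0.05  # 18 genome-wide significant SNPs

_PANEL = [
    # (outcome, class, cases, controls, total)
    ("celiac_disease", "autoimmune_inflammatory", 4533, 10750, 15283),
    ("ibd", "autoimmune_inflammatory", 13020, 34774, 47794),
    ("crohn_disease", "autoimmune_inflammatory", 6333, 15056, 21389),
    ("ulcerative_colitis", "autoimmune_inflammatory", 6687, 19718, 26405),
    ("psoriasis_vulgaris", "autoimmune_inflammatory", 4007, 4934, 8941),
    ("psoriatic_arthritis", "autoimmune_inflammatory", 1946, 4934, 6880),
    ("cutaneous_psoriasis", "autoimmune_inflammatory", 1363, 3517, 4880),
    ("rheumatoid_arthritis", "autoimmune_inflammatory", 5538, 20167, 25705),
    ("systemic_lupus_erythematosus", "autoimmune_inflammatory", 1311, 3340, 4651),
    ("systemic_sclerosis", "autoimmune_inflammatory", 2356, 5187, 7543),
    ("type_1_diabetes", "autoimmune_inflammatory", 9934, 16956, 26890),
    ("knee_osteoarthritis", "autoimmune_inflammatory", 5755, 18505, 24260),
    ("coronary_artery_disease", "cardiovascular", 60801, 123504, 184305),
    ("systolic_blood_pressure", "cardiovascular", None, None, 69368),
    ("diastolic_blood_pressure", "cardiovascular", None, None, 69372),
    ("ischemic_stroke_all", "cardiovascular", 3548, 5972, 9520),
    ("ischemic_stroke_cardioembolic", "cardiovascular", 790, 5972, 6762),
    ("ischemic_stroke_large_vessel", "cardiovascular", 844, 5972, 6816),
    # total = cases + controls (source tables print both 6,522 and 6,552;
    # only the sum is internally consistent)
    ("ischemic_stroke_small_vessel", "cardiovascular", 580, 5972, 6552),
    ("body_mass_index", "metabolic", None, None, 123865),
    ("type_2_diabetes", "metabolic", 6698, 15872, 22570),
    ("chronic_kidney_disease", "metabolic", 6271, 68083, 74354),
    ("egfr_creatinine", "metabolic", None, None, 74354),
    ("serum_albumin", "metabolic", None, None, 53189),
    ("serum_protein", "metabolic", None, None, 25537),
    # total = cases + controls (source tables print both 12,663 and 12,263)
    ("amyotrophic_lateral_sclerosis", "neurodegenerative", 4133, 8130, 12263),
    ("alzheimer_disease", "neurodegenerative", 4663, 8357, 13020),
    ("parkinson_disease", "neurodegenerative", 5333, 12019, 17352),
    ("autism", "psychiatric", 90, 1476, 1566),
    ("bipolar_disorder", "psychiatric", 7481, 9250, 16731),
    ("major_depressive_disorder", "psychiatric", 9240, 9519, 18759),
    ("schizophrenia", "psychiatric", 34241, 45604, 79845),
]

_GRS_GWAS_SNPS = [
    # (rsid, locus, chrom, pos)
    ("rs2847281", "PTPN2", "18", 12811593),
    ("rs340029", "RORA", "15", 58682257),
    ("rs6901250", "GPRC6A", "6", 117220718),
    ("rs10745954", "ASCL1", "12", 102007224),
    ("rs4705952", "IRF1", "5", 131867517),
    ("rs12037222", "PABPC4", "1", 39837548),
    ("rs12239046", "NLRP3", "1", 245668218),
    ("rs6734238", "IL1F10", "2", 113557501),
    ("rs13233571", "BCL7B", "7", 72609167),
    ("rs9987289", "PPP1R3B", "8", 9220768),
    ("rs1260326", "GCKR", "2", 27584444),
    ("rs4129267", "IL6R", "1", 152692888),
    ("rs1800961", "HNF4A", "20", 42475778),
    ("rs4420065", "LEPR", "1", 5934049),
    ("rs10521222", "SALL1", "16", 49716211),
    ("rs1183910", "HNF1A", "12", 119905190),
    ("rs2794520", "CRP", "1", 157945440),
    ("rs4420638", "APOC1", "19", 50114786),
]


def outcome_panel() -> pd.DataFrame:
    """The 32-outcome panel with disease class and sample sizes.

    ``outcome_type`` is binary where case/control counts exist and
    quantitative otherwise.
    """
    df = pd.DataFrame(_PANEL, columns=["outcome", "disease_class", "n_cases",
                                       "n_controls", "n_total"])
    df["outcome_type"] = ["quantitative" if pd.isna(c) else "binary"
                          for c in df["n_cases"]]
    df["n_cases"] = df["n_cases"].astype("Int64")
    df["n_controls"] = df["n_controls"].astype("Int64")
    return df


def grs_gwas_annotation() -> pd.DataFrame:
    """rsid/locus/position annotation of the 18-SNP genome-wide instrument."""
    return pd.DataFrame(_GRS_GWAS_SNPS, columns=["rsid", "locus", "chrom", "pos"])
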