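{
  "_comment": "17 bilateral ROI features aggregated from AAL region labels, plus the cerebellar vermis. Feature value = mean GMV of member regions, computed per hemisphere.",
  "features": {
    "frontal": ["Frontal_Sup", "Frontal_Mid", "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Med_Orb"],
    "temporal": ["Temporal_Sup", "Temporal_Mid", "Temporal_Inf", "Temporal_Pole_Sup"],
    "parietal": ["Parietal_Sup", "Parietal_Inf", "Angular", "SupraMarginal", "Precuneus"],
    "occipital": ["Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Calcarine", "Cuneus", "Lingual"],
    "insula": ["Insula"],
    "cingulate": ["Cingulate_Ant", "Cingulate_Mid", "Cingulate_Post"],
    "sensorimotor": ["Precentral", "Postcentral", "Paracentral_Lobule", "Supp_Motor_Area"],
    "broca": ["Frontal_Inf_Orb", "Rolandic_Oper"],
    "cerebellum": ["Cerebellum_Crus1", "Cerebellum_Crus2", "Cerebellum_4_5", "Cerebellum_6", "Cerebellum_8"],
    "hippocampus": ["Hippocampus"],
    "parahippocampus": ["ParaHippocampal"],
    "amygdala": ["Amygdala"],
    "caudate": ["Caudate"],
    "putamen": ["Putamen"],
    "pallidum": ["Pallidum"],
    "accumbens": ["Accumbens"],
    "thalamus": ["Thalamus"]
  },
  "hemisphere_suffixes": {"left": "_L", "right": "_R"},
  "midline": {"vermis": ["Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7", "Vermis_8", "Vermis_9", "Vermis_10"]}
}
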