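{
 "0": {
  "DN_HistogramMode_5": -0.25069434379698363,
  "DN_HistogramMode_10": -0.026934050858167247,
  "CO_f1ecac": 0.7035010783318973,
  "CO_FirstMin_ac": 3.0,
  "CO_HistogramAMI_even_2_5": 0.1029468147128191,
  "CO_trev_1_num": -0.2723073083794854,
  "MD_hrv_classic_pnn40": 0.98989898989899,
  "SB_BinaryStats_mean_longstretch1": 6.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.0036730945821854912,
  "PD_PeriodicityWang_th0_01": 3.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.09225426824485768,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 1.0,
  "FC_LocalSimple_mean1_tauresrat": 0.3333333333333333,
  "DN_OutlierInclude_p_001_mdrmd": 0.040000000000000036,
  "DN_OutlierInclude_n_001_mdrmd": 0.1399999999999999,
  "SP_Summaries_welch_rect_area_5_1": 0.24523886298974482,
  "SB_BinaryStats_diff_longstretch0": 5.0,
  "SB_MotifThree_quantile_hh": 2.16046590651602,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.17142857142857143,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.8285714285714286,
  "SP_Summaries_welch_rect_centroid": 1.3253594007332812,
  "FC_LocalSimple_mean3_stderr": 1.1559687349737224
 },
 "1": {
  "DN_HistogramMode_5": 0.6951685682411157,
  "DN_HistogramMode_10": -0.5217752354536291,
  "CO_f1ecac": 1.601971142557328,
  "CO_FirstMin_ac": 9.0,
  "CO_HistogramAMI_even_2_5": 0.09630365991579291,
  "CO_trev_1_num": -0.47436629946709635,
  "MD_hrv_classic_pnn40": 0.9595959595959596,
  "SB_BinaryStats_mean_longstretch1": 11.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.008310249307479225,
  "PD_PeriodicityWang_th0_01": 14.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.13873346857828625,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 4.0,
  "FC_LocalSimple_mean1_tauresrat": 0.2,
  "DN_OutlierInclude_p_001_mdrmd": -0.29000000000000004,
  "DN_OutlierInclude_n_001_mdrmd": -0.10999999999999999,
  "SP_Summaries_welch_rect_area_5_1": 0.5632488506560422,
  "SB_BinaryStats_diff_longstretch0": 4.0,
  "SB_MotifThree_quantile_hh": 2.0084211068170026,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.42857142857142855,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.37142857142857144,
  "SP_Summaries_welch_rect_centroid": 0.44178646691109374,
  "FC_LocalSimple_mean3_stderr": 0.9899538461535272
 },
 "2": {
  "DN_HistogramMode_5": -0.2240958975714611,
  "DN_HistogramMode_10": 5.355206646839861e-05,
  "CO_f1ecac": 2.9410686971141913,
  "CO_FirstMin_ac": 9.0,
  "CO_HistogramAMI_even_2_5": 0.31210035777077666,
  "CO_trev_1_num": 0.05490690639804753,
  "MD_hrv_classic_pnn40": 0.9595959595959596,
  "SB_BinaryStats_mean_longstretch1": 11.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.0027700831024930752,
  "PD_PeriodicityWang_th0_01": 17.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.15471902172165794,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 3.0,
  "FC_LocalSimple_mean1_tauresrat": 0.2,
  "DN_OutlierInclude_p_001_mdrmd": -0.16000000000000003,
  "DN_OutlierInclude_n_001_mdrmd": 0.010000000000000009,
  "SP_Summaries_welch_rect_area_5_1": 0.7927159730572357,
  "SB_BinaryStats_diff_longstretch0": 8.0,
  "SB_MotifThree_quantile_hh": 1.8826256634576821,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.4,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.17142857142857143,
  "SP_Summaries_welch_rect_centroid": 0.34361169648640627,
  "FC_LocalSimple_mean3_stderr": 0.8378199648613063
 },
 "3": {
  "DN_HistogramMode_5": 0.2885060918865314,
  "DN_HistogramMode_10": 0.0015220697480791134,
  "CO_f1ecac": 0.5476317267586748,
  "CO_FirstMin_ac": 1.0,
  "CO_HistogramAMI_even_2_5": 0.07041441706953022,
  "CO_trev_1_num": -0.2520187977752447,
  "MD_hrv_classic_pnn40": 0.9595959595959596,
  "SB_BinaryStats_mean_longstretch1": 7.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.001088324320647553,
  "PD_PeriodicityWang_th0_01": 4.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.05460741038652284,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 1.0,
  "FC_LocalSimple_mean1_tauresrat": 1.0,
  "DN_OutlierInclude_p_001_mdrmd": 0.0,
  "DN_OutlierInclude_n_001_mdrmd": 0.18999999999999995,
  "SP_Summaries_welch_rect_area_5_1": 0.11301817827034742,
  "SB_BinaryStats_diff_longstretch0": 4.0,
  "SB_MotifThree_quantile_hh": 2.1872973290564657,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.8285714285714286,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.6,
  "SP_Summaries_welch_rect_centroid": 1.767145867644375,
  "FC_LocalSimple_mean3_stderr": 1.152642867147034
 },
 "4": {
  "DN_HistogramMode_5": -0.2793903510370812,
  "DN_HistogramMode_10": -0.489721007611021,
  "CO_f1ecac": 2.0634659481192204,
  "CO_FirstMin_ac": 6.0,
  "CO_HistogramAMI_even_2_5": 0.15810913276726368,
  "CO_trev_1_num": 0.15492511785905694,
  "MD_hrv_classic_pnn40": 0.9393939393939394,
  "SB_BinaryStats_mean_longstretch1": 10.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.027777777777777783,
  "PD_PeriodicityWang_th0_01": 11.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.1647575169308133,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 2.0,
  "FC_LocalSimple_mean1_tauresrat": 0.25,
  "DN_OutlierInclude_p_001_mdrmd": 0.25,
  "DN_OutlierInclude_n_001_mdrmd": 0.6200000000000001,
  "SP_Summaries_welch_rect_area_5_1": 0.6222052426694719,
  "SB_BinaryStats_diff_longstretch0": 7.0,
  "SB_MotifThree_quantile_hh": 2.0522715083286216,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.17142857142857143,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.8,
  "SP_Summaries_welch_rect_centroid": 0.5399612373357813,
  "FC_LocalSimple_mean3_stderr": 0.9809907716154339
 },
 "5": {
  "DN_HistogramMode_5": -0.5628603298715742,
  "DN_HistogramMode_10": -0.13526308459830605,
  "CO_f1ecac": 3.1266081430237085,
  "CO_FirstMin_ac": 9.0,
  "CO_HistogramAMI_even_2_5": 0.2963716970242827,
  "CO_trev_1_num": -0.02540137355289568,
  "MD_hrv_classic_pnn40": 0.9393939393939394,
  "SB_BinaryStats_mean_longstretch1": 9.0,
  "SB_TransitionMatrix_3ac_sumdiagcov": 0.0110803324099723,
  "PD_PeriodicityWang_th0_01": 17.0,
  "CO_Embed2_Dist_tau_d_expfit_meandiff": 0.25190299919790377,
  "IN_AutoMutualInfoStats_40_gaussian_fmmi": 4.0,
  "FC_LocalSimple_mean1_tauresrat": 0.2,
  "DN_OutlierInclude_p_001_mdrmd": -0.010000000000000009,
  "DN_OutlierInclude_n_001_mdrmd": -0.030000000000000027,
  "SP_Summaries_welch_rect_area_5_1": 0.8354330476835089,
  "SB_BinaryStats_diff_longstretch0": 6.0,
  "SB_MotifThree_quantile_hh": 1.8422735659793688,
  "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": 0.4,
  "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.17142857142857143,
  "SP_Summaries_welch_rect_centroid": 0.34361169648640627,
  "FC_LocalSimple_mean3_stderr": 0.79557968439919
 }
}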