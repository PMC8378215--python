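study_key,material,K,n,pressure_kpa,nozzle_mm,l_lower_mm,flow_ul_s,mss_kpa,viability_pct,cell,cell_class,time_tag,incomplete
chang_hepg2,3% w/v alginate,8.587,0.76,0-275.79,0.150-0.400,12,0.6-226,0-2.17,42.97-83.84,HepG2 (liver hepatocellular carcinoma cell),carcinoma,0-24h,False
khalil_rhec,1.5% w/v alginate,1.259,0.7,55.12-220.48,0.250,12,0.4-1.6,0.41-1.65,73.44-84.38,RHEC (rat heart endothelial cell line),endothelial,,False
nair_ramec,1.5% w/v alginate,1.259,0.7,34.45-275.60,0.250,12,0.3-2.7,0.32-2.66,50-80,RAMEC (rat adrenal medulla endothelial cell),endothelial,,False
li_3t3,5% w/v alginate,10.82,0.54,200-500,0.250,20,2.3-12.6,0.68-1.708,78.91-98.83,3T3 (mouse embryonic fibroblast),fibroblast,,False
wuest_hmsc,2% w/v alginate,2,0.87,0-275.60,0.150,12.70,0.1-0.3,0-1.05,83.2-99.02,hMSC (human mesenchymal stem cell),stem,,False
ouyang_esc,1% w/v Alg:5-10%Gel,8.183,0.546,,0.250,,0.700,200-600,10-60,ESC (embryonic stem cell),stem,,True
paxton_hmsc,AlgGel,13.3,0.608,100.00,0.200,12.22,0.6-3.8,0.58-3.79,56.25-96.88,hMSC (human mesenchymal stem cell),stem,,False
ning_l8_rsc96,0.2% w/v alginate,25.60,0.35,50.00,0.200,6.35,1.5-197,0.41-5.05,81.25-94.73,"L8 (rat myoblast cell), RSC96 (rat Schwann cell)",line,,False
ning_rsc96_l8_huvec,2% w/v alginate,10.39,0.41,,0.200,11,5-17,00.457-0.76,67.75-98.8,"RSC96, L8, HUVEC (human umbilical vein endothelial cell)",line,,False
gelatin_silk_hmsc,Geltin-Silk fibroin,,,,0.200,6.35,,0.440,90.00,hMSC (human mesenchymal stem cell),stem,,True
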