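name,compound_class,sum_formula,accurate_mass,logp,logp_predicted,rt_rp_min,rt_hilic_min,paired_median_pct,paired_code,unpaired_highest_pct,unpaired_highest_group,unpaired_code,pattern
Alanine,amino acid,C3H7NO2,89.047678,-2.85,0,0.9,6.8,74,***,172,>144 h,***,steady_increase
Arginine,amino acid,C6H14N4O2,174.11167,-4.2,0,0.8,9.4,-16,***,27,12-24 h,ns,stable
Histidine,amino acid,C6H9N3O2,155.06947,-3.32,0,0.8,8.3,33,***,71,>144 h,***,lag_then_increase
Leucine/isoleucine,amino acid,C6H13NO2,131.09462,-1.52,0,1.9,5.3,17,***,51,>144 h,***,lag_then_increase
Lysine,amino acid,C6H14N2O2,146.10552,-3.05,0,0.8,9.6,15,***,57,>144 h,***,lag_then_increase
Methionine,amino acid,C5H11NO2S,149.05104,-1.87,0,1.3,5.6,14,***,45,>144 h,***,lag_then_increase
Ornithine,amino acid,C5H12N2O2,132.08987,-4.22,0,0.7,9.7,-12,***,-25,72-96 h,***,stable
Phenylalanine,amino acid,C9H11NO2,165.07897,-1.38,0,3.9,5.1,17,***,59,>144 h,***,lag_then_increase
Proline,amino acid,C5H9NO2,115.06332,-2.7,1,0.9,6.2,-23,***,-41,96-120 h,***,steady_increase
Serine,amino acid,C3H7NO3,105.04259,-3.07,0,0.9,7.1,-2,ns,23,>144 h,***,stable
Threonine,amino acid,C4H9NO3,119.05824,-2.94,0,0.9,6.8,0,ns,-15,24-36 h,***,stable
Tryptophane,amino acid,C11H12N2O2,204.08987,-1.06,0,5.0,5.4,9,***,42,>144 h,***,steady_increase
Tyrosine,amino acid,C9H11NO3,181.07389,-2.26,0,1.9,6.0,24,***,79,>144 h,***,lag_then_increase
Valine,amino acid,C5H11NO2,117.07897,-2.26,0,0.9,5.9,-8,***,-14,24-36 h,***,steady_increase
Carnitine (C0),carnitine,C7H15NO3,161.10519,-2.9,1,0.9,,99,***,274,>144 h,***,steady_increase
Acetylcarnitine (C2),carnitine,C9H17NO4,203.11575,-2.4,1,1.1,,82,***,227,72-96 h,***,steady_increase
Propionylcarnitine (C3),carnitine,C10H19NO4,217.13140,-2.3,1,2.2,,42,***,98,72-96 h,***,steady_increase
Octanoylcarnitine (C8),carnitine,C15H29NO4,287.20965,-1.2,1,10.2,,-11,**,35,72-96 h,ns,stable
Decanoylcarnitine (C10),carnitine,C17H33NO4,315.24095,-0.85,1,12.1,,-63,***,-80,>144 h,***,decrease
Lauroylcarnitine (C12),carnitine,C19H38NO4,344.27953,0.03,1,13.3,,-37,***,-54,120-144 h,**,decrease
Myristoylcarnitine (C14),carnitine,C21H42NO4,372.31083,0.86,1,14.2,,8,*,73,72-96 h,**,stable
Palmitoylcarnitine (C16),carnitine,C23H46NO4,400.34213,1.77,1,14.9,,22,***,70,72-96 h,***,lag_then_increase
Stearoylcarnitine (C18),carnitine,C25H50NO4,428.37343,2.62,1,15.3,,40,***,123,120-144 h,***,steady_increase
Creatinine,amino acid,C4H7N3O,113.05891,-1.76,0,1.0,4.7,33,***,97,>144 h,***,steady_increase
Kynurenine,carbonyl compound,C10H12N2O3,208.08479,-1.9,1,3.7,,3,**,62,96-120 h,***,stable
Taurine,organosulfonic acid,C2H7NO3S,125.01466,-2.2,1,0.9,6.7,141,***,379,120-144 h,***,steady_increase
Cholic acid,bile acid,C24H40O5,408.28757,2.02,0,14.1,,166,***,1190,>144 h,***,lag_then_increase
Inosine,nucleoside,C10H12N4O5,268.08077,-2.1,0,3.7,,27,***,54,72-96 h,***,stable
Uracil,pyrimidine,C4H4N2O2,112.02727,-1.07,0,1.5,2.1,74,***,176,>144 h,***,steady_increase
Uric acid,purine,C5H4N4O3,168.02834,-2.17,0,1.7,6.0,8,***,49,>144 h,***,lag_then_increase
Cortisol,steroid,C21H30O5,362.20932,1.61,0,11.1,,-23,***,30,12-24 h,ns,decrease
lyso PC 16:0,phospholipid,C24H50NO7P,495.33249,1.83,1,15.5,,-13,***,-20,120-144 h,***,stable
lyso PC 18:1,phospholipid,C26H52NO7P,521.34814,2.38,1,15.6,,-21,***,-38,120-144 h,***,stable
lyso PE 18:0,phospholipid,,,,,15.8,,75,***,104,>144 h,***,steady_increase
PC 34:1,phospholipid,,,,,18.0,,-1,ns,6,96-120 h,ns,stable
PC 36:2,phospholipid,,,,,18.2,,-4,***,-15,>144 h,***,stable
PE 34:1,phospholipid,,,,,17.6,,29,***,53,>144 h,***,steady_increase
PE 36:4,phospholipid,,,,,17.2,,20,***,26,>144 h,***,steady_increase
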