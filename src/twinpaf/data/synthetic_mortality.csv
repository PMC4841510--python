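disease_name,region,year,deaths
Coronary heart disease death,Western Europe (synthetic),2000,1000000
Lung cancer,Western Europe (synthetic),2000,180000
Colorectal cancer,Western Europe (synthetic),2000,110000
Breast cancer (female),Western Europe (synthetic),2000,90000
Prostate cancer (male),Western Europe (synthetic),2000,70000
Stomach cancer,Western Europe (synthetic),2000,60000
Pancreatic cancer,Western Europe (synthetic),2000,50000
Leukemia,Western Europe (synthetic),2000,35000
Bladder cancer,Western Europe (synthetic),2000,30000
Ovarian cancer (female),Western Europe (synthetic),2000,25000
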