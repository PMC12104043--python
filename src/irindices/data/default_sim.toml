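# Default synthetic-cohort configuration.
# Emulates a fasting adult biobank cohort: four glycemic groups with
# log-normal biochemistry marginals given as [median, q1, q3] on the
# measurement scale, coupled by a Gaussian copula with the rank
# correlations below.

n = 7875
sex_proportion_male = 0.409
missing_rate = 0.01
hba1c_missing_rate = 0.002
nonfasting_fraction = 0.0
nonfasting_tg_multiplier = 1.3
t2d_treatment_rate = 0.8
family_history_rate = 0.73
borderline_fraction = 0.0
seed = 0

[group_proportions]
normal = 0.61616
prediabetes = 0.17405
newly_diagnosed = 0.01896
t2d = 0.19083

[lipid_drug_rate_by_group]
normal = 0.02
prediabetes = 0.12
newly_diagnosed = 0.15
t2d = 0.45

# copula variable order: glucose, insulin, c_peptide, tg, hdl, bmi
rank_correlation = [
    [ 1.00,  0.35,  0.35,  0.25, -0.15,  0.25],
    [ 0.35,  1.00,  0.60,  0.35, -0.30,  0.45],
    [ 0.35,  0.60,  1.00,  0.35, -0.30,  0.45],
    [ 0.25,  0.35,  0.35,  1.00, -0.45,  0.35],
    [-0.15, -0.30, -0.30, -0.45,  1.00, -0.35],
    [ 0.25,  0.45,  0.45,  0.35, -0.35,  1.00],
]

[group_distributions.normal]
age = [34.0, 27.0, 42.0]
glucose = [4.80, 4.50, 5.10]
insulin = [59.08, 42.40, 83.40]
c_peptide = [0.60, 0.46, 0.77]
hba1c = [5.20, 5.00, 5.40]
tg = [0.90, 0.70, 1.30]
hdl = [1.44, 1.20, 1.72]
bmi = [27.62, 24.30, 31.46]

[group_distributions.prediabetes]
age = [46.0, 37.0, 54.3]
glucose = [5.50, 5.00, 5.90]
insulin = [85.48, 61.16, 119.54]
c_peptide = [0.82, 0.64, 1.03]
hba1c = [5.80, 5.70, 6.00]
tg = [1.20, 0.90, 1.60]
hdl = [1.30, 1.10, 1.55]
bmi = [31.25, 27.79, 35.03]

[group_distributions.newly_diagnosed]
age = [53.0, 45.0, 60.0]
glucose = [7.10, 5.70, 9.20]
insulin = [83.40, 55.60, 125.78]
c_peptide = [0.78, 0.58, 1.04]
hba1c = [6.90, 6.20, 8.10]
tg = [1.40, 1.00, 1.90]
hdl = [1.30, 1.07, 1.54]
bmi = [32.36, 28.27, 35.61]

[group_distributions.t2d]
age = [53.0, 45.0, 60.0]
glucose = [7.10, 5.70, 9.20]
insulin = [83.40, 55.60, 125.78]
c_peptide = [0.78, 0.58, 1.04]
hba1c = [6.90, 6.20, 8.10]
tg = [1.40, 1.00, 1.90]
hdl = [1.30, 1.07, 1.54]
bmi = [32.36, 28.27, 35.61]
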