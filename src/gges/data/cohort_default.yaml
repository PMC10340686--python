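# Default synthetic NSCLC-cohort specification.
#
# Marginal targets (means/SDs/category proportions) follow the published
# cohort summary; the dependency structure among body-composition variables
# is this package's own choice and every structural coefficient lives here so
# simulations are reproducible and auditable.  Nodes are listed in topological
# order of the ground-truth graph.  "sex" is coded 1 = female, 0 = male.
# Outcome nodes (role: outcome) are sinks by construction.
#
# Published height/weight marginals (174.4 +/- 43.0 cm, 66.3 +/- 4.02 kg) are
# internally inconsistent with the BMI row and would generate impossible
# bodies; weight is instead derived (linearized) from BMI x height^2 with
# height ~ sex-dependent Normal around 170 cm.

n: 363
seed: 0

categorical:
  sex:        {values: [1, 0], probs: [0.4628, 0.5372]}
  race:       {values: [1, 2, 3], probs: [0.8981, 0.0937, 0.0082]}
  SMOKE_HX_CODED: {values: [1, 2], probs: [0.62, 0.38]}
  HISTO_CODED:    {values: [1, 2, 3], probs: [0.58, 0.30, 0.12]}
  t_stage:    {values: [0, 1, 2, 3, 4], probs: [0.0165, 0.3802, 0.4325, 0.1295, 0.0413]}
  n_stage:    {values: [0, 1, 2], probs: [0.6942, 0.1873, 0.1185]}

continuous:
  age:    {intercept: 68.3, parents: {}, noise_sd: 9.45}
  BMI:    {intercept: 27.8, parents: {}, noise_sd: 5.98}
  height: {intercept: 176.0, parents: {sex: -12.0}, noise_sd: 7.0}
  weight: {intercept: -161.1, parents: {BMI: 2.89, height: 0.945}, noise_sd: 1.0}
  volume_visceral_fat:
    {intercept: -3.94, parents: {BMI: 0.25, sex: -1.2, age: 0.03}, noise_sd: 0.8}
  volume_subcutaneous_fat:
    {intercept: -2.4, parents: {BMI: 0.35, sex: 1.5}, noise_sd: 1.2}
  volume_intermuscular_fat:
    {intercept: -0.87, parents: {BMI: 0.05, age: 0.01}, noise_sd: 0.3}
  volume_muscle:
    {intercept: 1.82, parents: {height: 0.12, sex: -4.0, age: -0.05}, noise_sd: 1.5}
  volume_bone:
    {intercept: -1.45, parents: {height: 0.04, sex: -0.8}, noise_sd: 0.5}
  density_visceral_fat:
    {intercept: -78.1, parents: {BMI: -0.5}, noise_sd: 4.0}
  density_subcutaneous_fat:
    {intercept: -86.9, parents: {BMI: -0.4}, noise_sd: 4.0}
  density_muscle:
    {intercept: 56.6, parents: {BMI: -0.3, age: -0.15}, noise_sd: 4.0}
  density_bone:
    {intercept: 321.2, parents: {age: -1.2, sex: -20.0}, noise_sd: 30.0}
  mass_visceral_fat:
    {intercept: 0.92, parents: {volume_visceral_fat: 0.92, density_visceral_fat: 0.01}, noise_sd: 0.1}
  mass_subcutaneous_fat:
    {intercept: 0.98, parents: {volume_subcutaneous_fat: 0.92, density_subcutaneous_fat: 0.01}, noise_sd: 0.15}
  mass_intermuscular_fat:
    {intercept: 0.0, parents: {volume_intermuscular_fat: 0.92}, noise_sd: 0.05}
  mass_bone:
    {intercept: -0.02, parents: {volume_bone: 1.2, density_bone: 0.004}, noise_sd: 0.2}
  TNM_stage:
    {intercept: 0.0, parents: {t_stage: 1.0, n_stage: 1.5}, noise_sd: 0.3}

# Binary recurrence: logistic over stage and body composition.  The intercept
# is rescaled analytically (probit approximation to the logistic) so the
# population mean matches target_mean despite the latent-scale variance.
recurrence:
  name: Recur
  target_mean: 0.67
  parents:
    TNM_stage: 0.55
    density_muscle: -0.10
    volume_visceral_fat: 0.30
    mass_subcutaneous_fat: 0.18

# Continuous recurrence-free survival (months): linear plus Gaussian noise,
# truncated below at 0.  Mean/SD are free parameters of the emulator.
survival:
  name: Rec_free_survival_months
  target_mean: 12.53
  noise_sd: 15.5
  parents:
    t_stage: -3.0
    SMOKE_HX_CODED: 3.0
    height: 0.15
    mass_intermuscular_fat: -3.0
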