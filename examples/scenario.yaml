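# Example head-to-head trial scenario for `basalsim run-trial`.
n_subjects: 100
schedule: morning        # morning | evening
rule: A                  # titration rule A (80-130 mg/dL) or B (70-89 mg/dL)
weeks_uptitration: 8
weeks_stable: 4
b0_U_per_kg: 0.3         # glargine starting dose; degludec dose is matched
fpg_mg_dl: 172.9         # baseline fasting glucose target
n_splits: 100            # parallel-design random splits
seeds:
  population: 1
  calibration: 1
  meals: 100
  iov: 200
  splits: 3
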