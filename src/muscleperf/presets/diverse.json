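{
 "name": "diverse",
 "datasets": [
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "16lb",
   "load_factor": 1.45
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "16lb",
   "load_factor": 1.45
  },
  {
   "subject": "young",
   "subject_factor": 1.0,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "elderly",
   "subject_factor": 0.8,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "pad",
   "subject_factor": 0.55,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "pad",
   "subject_factor": 0.55,
   "load": "exhaustion",
   "load_factor": 1.9
  },
  {
   "subject": "pad",
   "subject_factor": 0.55,
   "load": "4lb",
   "load_factor": 0.7
  },
  {
   "subject": "pad",
   "subject_factor": 0.55,
   "load": "exhaustion",
   "load_factor": 1.9
  }
 ],
 "map_shape": [
  64,
  64
 ],
 "voxels_per_dataset": 2000,
 "snr": 20.0,
 "region_base_medians": [
  52.0,
  85.0,
  137.0
 ],
 "sigma_log": 0.55,
 "dataset_jitter": 0.12,
 "f_clip": [
  3.0,
  420.0
 ]
}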