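{
 "name": "homogeneous",
 "datasets": [
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  },
  {
   "subject": "young",
   "subject_factor": 0.9,
   "load": "8lb",
   "load_factor": 1.0
  }
 ],
 "map_shape": [
  64,
  64
 ],
 "voxels_per_dataset": 2000,
 "snr": 20.0,
 "region_base_medians": [
  45.0,
  75.0,
  120.0
 ],
 "sigma_log": 0.75,
 "dataset_jitter": 0.12,
 "f_clip": [
  3.0,
  420.0
 ]
}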